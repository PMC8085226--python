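import numpy as np
import pytest

from tubestab import LoadState, Mode, ShellMaterial, TubeGeometry


@pytest.fixture
def unit_material() -> ShellMaterial:
    """lam = mu = 1, kappa = 1e-4: E2d = 8/3, nu2d = 1/3, gamma ~ 6.1e-3."""
    return ShellMaterial(lam=1.0, mu=1.0, kappa=1e-4)


@pytest.fixture
def unit_geometry() -> TubeGeometry:
    """Unit radius, aspect ratio R/L = 1/50 as for the embryonic aorta."""
    return TubeGeometry(R=1.0, L=50.0)


@pytest.fixture
def aorta_geometry() -> TubeGeometry:
    """Dorsal-aorta-like numbers: R = 14 um, L = 50 R, wall h = 0.5 um."""
    return TubeGeometry(R=14.0, L=700.0, h=0.5)


def single_mode_field(mode: Mode, amplitudes, n_phi: int, n_z: int, L: float) -> np.ndarray:
    """Real displacement field of one stored mode on a periodic grid."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    z = np.linspace(0.0, L, n_z, endpoint=False)
    P, Z = np.meshgrid(phi, z, indexing="ij")
    phase = np.exp(1j * (mode.k * Z + mode.n * P))
    a = np.asarray(amplitudes, dtype=complex)
    return np.array([2.0 * np.real(a[j] * phase) for j in range(3)])
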