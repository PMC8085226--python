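"""Synthetic deformed tube surfaces and their re-measurement.

This is the package's no-external-data test bed: build a tube surface from
the displacement ansatz (homogeneous dilation plus Fourier corrugation
modes), sample its radius like a segmentation pipeline would (with additive
Gaussian noise), and recover the corrugation wave vector from the
periodogram of the mean-radius profile.  Defaults emulate the embryonic
dorsal aorta: radius 12-16 µm, length ~50 radii, a sinusoidal thin/thick
pattern along the axis, and ~1% radius measurement noise.

The surface parametrization in cylindrical coordinates is

    x' = (R + u_r) cos(phi) - u_phi sin(phi)
    y' = (R + u_r) sin(phi) + u_phi cos(phi)
    z' = z + u_z

with the displacement field u = u0 + u', u0 = [eps_phiphi0 R, 0, eps_zz0 z]
the homogeneous part and u' the synthesized modes,
``u'_j = 2 Re(A_j exp(i (k z + n phi)))`` per stored mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .elasticity import TubeGeometry
from .shell_stability import HomogeneousStrain, Mode, ModeAmplitudes

__all__ = [
    "SurfaceGrid",
    "RadiusProfile",
    "generate_surface",
    "measure_radius_profile",
    "estimate_wavevector",
    "export_obj",
    "export_csv",
]

#: Peak must exceed this multiple of the median spectral floor to count as
#: a significant corrugation.
SPECTRAL_FLOOR_FACTOR = 3.0


@dataclass(frozen=True)
class SurfaceGrid:
    """Tube surface sampled on a periodic (phi, z) grid.

    ``x, y, z`` are (Nphi, Nz) coordinate arrays; ``phi`` and ``z_param``
    are the material-coordinate samples (uniform, periodic in phi).
    """

    phi: np.ndarray
    z_param: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    geometry: TubeGeometry

    @property
    def n_phi(self) -> int:
        return len(self.phi)

    @property
    def n_z(self) -> int:
        return len(self.z_param)


@dataclass(frozen=True)
class RadiusProfile:
    """Measured radius samples of a tube surface.

    ``samples`` is the per-(phi, z) distance from the tube axis; ``mean`` is
    the per-z azimuthal average — the quantity a diameter-over-arclength
    measurement yields.
    """

    z: np.ndarray
    mean: np.ndarray
    samples: np.ndarray
    noise_sd: float
    L: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.z, "mean_radius": self.mean})


def generate_surface(
    geometry: TubeGeometry,
    strain0: HomogeneousStrain | None = None,
    modes: list[tuple[Mode, ModeAmplitudes]] | None = None,
    n_phi: int = 64,
    n_z: int = 256,
) -> SurfaceGrid:
    """Synthesize a tube surface from homogeneous strain plus Fourier modes.

    Each stored mode contributes ``2 Re(A_j exp(i (k z + n phi)))`` to the
    displacement component ``j`` (the conjugate partner is implied, so the
    field is real).  The grid must resolve every mode: ``n_phi > 2 |n|`` and
    ``n_z > 2 |m|`` with ``m = k L / (2 pi)``.

    With no modes and zero strain the result is an exact cylinder of radius
    R; with strain only, a cylinder of radius ``R (1 + eps_phiphi0)`` and
    length ``L (1 + eps_zz0)``.
    """
    modes = modes or []
    R, L = geometry.R, geometry.L
    for mode, _ in modes:
        m_axial = mode.k * L / (2.0 * math.pi)
        if 2 * abs(mode.n) >= n_phi:
            raise ValueError(
                f"grid under-resolved: |n|={abs(mode.n)} needs n_phi > {2 * abs(mode.n)}"
            )
        if 2 * m_axial >= n_z:
            raise ValueError(
                f"grid under-resolved: k={mode.k:.4g} (m={m_axial:.2f}) needs n_z > {2 * m_axial:.0f}"
            )

    phi = np.linspace(0.0, 2.0 * math.pi, n_phi, endpoint=False)
    z = np.linspace(0.0, L, n_z, endpoint=False)
    P, Z = np.meshgrid(phi, z, indexing="ij")

    u = np.zeros((3,) + P.shape)
    if strain0 is not None:
        u[0] += strain0.eps_phiphi0 * R
        u[2] += strain0.eps_zz0 * Z
    for mode, amps in modes:
        phase = np.exp(1j * (mode.k * Z + mode.n * P))
        a = amps.as_array()
        for j in range(3):
            u[j] += 2.0 * np.real(a[j] * phase)

    ur, uph, uz = u
    x = (R + ur) * np.cos(P) - uph * np.sin(P)
    y = (R + ur) * np.sin(P) + uph * np.cos(P)
    z3 = Z + uz
    radii = np.hypot(x, y)
    if np.any(radii <= 0):
        raise ValueError("deformation too large: non-positive radii on the surface")
    return SurfaceGrid(phi=phi, z_param=z, x=x, y=y, z=z3, geometry=geometry)


def measure_radius_profile(
    surface: SurfaceGrid, noise_sd: float = 0.0, seed: int | None = 0
) -> RadiusProfile:
    """Re-measure the radius of a surface, with optional Gaussian noise.

    The radius of each node is its distance from the tube (z) axis; noise
    with standard deviation ``noise_sd`` emulates segmentation error and is
    deterministic for a fixed seed.  Azimuthal averaging attenuates the
    noise on the mean profile by ``1/sqrt(n_phi)``.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    r = np.hypot(surface.x, surface.y)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return RadiusProfile(
        z=surface.z_param.copy(),
        mean=r.mean(axis=0),
        samples=r,
        noise_sd=noise_sd,
        L=surface.geometry.L,
    )


def estimate_wavevector(profile: RadiusProfile, geometry: TubeGeometry | None = None) -> dict:
    """Dominant corrugation wave vector of a mean-radius profile.

    Takes the discrete spectrum of the mean profile (mean removed), finds
    the largest nonzero-frequency peak, and quantizes the estimate to the
    grid ``k = 2 pi j / L``.  The peak is significant when it exceeds
    ``SPECTRAL_FLOOR_FACTOR`` times the median spectral amplitude of the
    nonzero bins; a pure-noise profile is flagged insignificant.

    Returns a dict with ``k_hat``, ``amplitude_hat`` (half the peak-to-peak
    modulation of a single cosine, i.e. the stored-mode |A|), and
    ``significant``.
    """
    n_z = len(profile.mean)
    if n_z < 16:
        raise ValueError(f"need at least 16 z samples, got {n_z}")
    L = profile.L if geometry is None else geometry.L
    spectrum = np.abs(np.fft.rfft(profile.mean - profile.mean.mean()))
    amps = spectrum[1:]  # drop the (zeroed) mean bin
    peak_idx = int(np.argmax(amps)) + 1
    floor = float(np.median(amps))
    significant = bool(amps[peak_idx - 1] > SPECTRAL_FLOOR_FACTOR * floor) if floor > 0 else bool(
        amps[peak_idx - 1] > 0
    )
    k_hat = 2.0 * math.pi * peak_idx / L
    # rfft amplitude of 2*Re(A e^{ikz}) sampled on n_z points is n_z*|A|
    amplitude_hat = float(spectrum[peak_idx] / n_z)
    return {"k_hat": k_hat, "amplitude_hat": amplitude_hat, "significant": significant}


def export_obj(surface: SurfaceGrid, path) -> None:
    """Write the surface as a triangulated Wavefront OBJ mesh."""
    import trimesh

    n_phi, n_z = surface.n_phi, surface.n_z
    verts = np.column_stack(
        [surface.x.ravel(), surface.y.ravel(), surface.z.ravel()]
    )
    faces = []
    for i in range(n_phi):
        i2 = (i + 1) % n_phi
        for j in range(n_z - 1):
            a = i * n_z + j
            b = i2 * n_z + j
            faces.append([a, b, b + 1])
            faces.append([a, b + 1, a + 1])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    mesh.export(str(path))


def export_csv(surface: SurfaceGrid, path) -> None:
    """Write the surface node table (phi, z_param, x, y, z) as CSV."""
    n_phi, n_z = surface.n_phi, surface.n_z
    P, Z = np.meshgrid(surface.phi, surface.z_param, indexing="ij")
    pd.DataFrame(
        {
            "phi": P.ravel(),
            "z_param": Z.ravel(),
            "x": surface.x.ravel(),
            "y": surface.y.ravel(),
            "z": surface.z.ravel(),
        }
    ).to_csv(path, index=False)
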