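"""Per-mode linear stability of the loaded cylindrical membrane.

The tube is pre-strained homogeneously by the pressure difference ``deltaP``
and the axial stress ``sigma_zz``; small perturbations around that state are
expanded in Fourier modes

    u'_j(phi, z) = sum over stored modes of  2 Re( A_j exp(i (k z + n phi)) ),

with integer azimuthal wave number ``n`` and axial wave vector ``k`` (for a
finite tube ``k_m = 2 pi m / L``).  The quadratic part of the elastic energy
is block-diagonal in the modes; each mode carries a 3x3 Hermitian stability
matrix ``M`` acting on the complex amplitude triple ``A = (A_r, A_phi, A_z)``:

    dPhi = 2 pi R L * sum_modes  M_ij A_i conj(A_j).

Note the index pairing ``M_ij A_i conj(A_j)`` (equal to ``A^T M conj(A)``,
not the more common ``A^dagger M A``); since ``M`` is Hermitian both forms
are real and give identical determinants, but the off-diagonal phases follow
this convention.  Each stored mode with ``(n, m) != (0, 0)`` represents the
conjugate +/- pair jointly; the self-conjugate homogeneous (0, 0) mode
requires real amplitudes and counts twice.

The cylindrical shape is linearly stable when ``det M > 0`` for every
non-rigid mode.  Rigid-body content — translations and rotation, i.e. the
zero rows of the (n=0, k=0) matrix and the Goldstone modes at ``|n|=1, k=0``
— never counts as an instability.  An elastic surrounding (Winkler-type
radial pinning with coefficient ``C``) adds ``+C`` to the radial diagonal
entry ``M11`` and lifts the Goldstone zeros.

An independent energy oracle integrates the explicit quadratic energy
density of the displacement field on a (phi, z) grid, providing a
matrix-free cross-check of ``M``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elasticity import ShellMaterial, TubeGeometry

__all__ = [
    "LoadState",
    "Environment",
    "Mode",
    "ModeAmplitudes",
    "HomogeneousStrain",
    "StabilityMatrix",
    "homogeneous_strain",
    "stability_matrix",
    "mode_energy",
    "energy_numeric_oracle",
    "is_mode_stable",
    "scan_stability",
    "StabilityReport",
]

#: Default azimuthal scan range.
DEFAULT_N_MAX = 10
#: Number of points of the default log-spaced k grid.
DEFAULT_K_POINTS = 400
#: det values below this (relative to the elastic scale) are treated as zero.
DET_TOLERANCE = 1e-9


@dataclass(frozen=True)
class LoadState:
    """Homogeneous loading: pressure difference and axial stress.

    ``deltaP > 0`` dilates the tube; ``sigma_zz < 0`` compresses it axially.
    The linearized description assumes ``|deltaP*R|, |sigma_zz| << lam, mu``;
    violating that is a soft condition (a warning, not an error).
    """

    deltaP: float = 0.0
    sigma_zz: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.deltaP) and np.isfinite(self.sigma_zz)):
            raise ValueError("loads must be finite")

    def check_validity(self, material: ShellMaterial, geometry: TubeGeometry) -> None:
        """Warn when loads leave the small-load validity regime."""
        scale = min(material.lam if material.lam > 0 else np.inf, material.mu)
        if max(abs(self.deltaP * geometry.R), abs(self.sigma_zz)) > 0.2 * scale:
            warnings.warn(
                "loads are not small compared to the Lame coefficients; "
                "the linearized stability results are approximate",
                stacklevel=3,
            )


@dataclass(frozen=True)
class Environment:
    """Elastic surrounding of the tube.

    ``C`` is the phenomenological radial pinning coefficient (force/length^3)
    of the surrounding tissue matrix; tangential pinning is neglected.
    """

    C: float = 0.0

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError(f"pinning coefficient C must be >= 0, got {self.C}")


FREE = Environment(C=0.0)


@dataclass(frozen=True)
class Mode:
    """Fourier mode labels: integer azimuthal ``n`` and axial ``k >= 0``."""

    n: int
    k: float

    def __post_init__(self) -> None:
        if int(self.n) != self.n:
            raise ValueError(f"azimuthal wave number n must be an integer, got {self.n}")
        if self.k < 0:
            raise ValueError("store k >= 0; negative modes are the conjugates")

    @classmethod
    def from_m(cls, n: int, m: int, geometry: TubeGeometry) -> "Mode":
        """Discrete axial mode ``k_m = 2 pi m / L`` of a finite tube."""
        return cls(n=n, k=2.0 * np.pi * m / geometry.L)


@dataclass(frozen=True)
class ModeAmplitudes:
    """Complex amplitude triple ``(A_r, A_phi, A_z)`` of one stored mode."""

    A: tuple[complex, complex, complex]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.A, dtype=complex)


@dataclass(frozen=True)
class HomogeneousStrain:
    """Linear strains of the symmetric pre-deformed state."""

    eps_phiphi0: float
    eps_zz0: float


@dataclass(frozen=True)
class StabilityMatrix:
    """The 3x3 Hermitian per-mode stability matrix with its provenance."""

    M: np.ndarray
    mode: Mode
    material: ShellMaterial
    geometry: TubeGeometry
    load: LoadState
    env: Environment = field(default=FREE)

    @property
    def det(self) -> float:
        """Determinant of M; real because M is Hermitian."""
        d = np.linalg.det(self.M)
        return float(d.real)

    def to_json(self) -> str:
        """JSON dump of the matrix entries (for debugging)."""
        return json.dumps(
            {
                "n": self.mode.n,
                "k": self.mode.k,
                "det": self.det,
                "M_real": np.real(self.M).tolist(),
                "M_imag": np.imag(self.M).tolist(),
            }
        )


def homogeneous_strain(
    material: ShellMaterial, geometry: TubeGeometry, load: LoadState
) -> HomogeneousStrain:
    """Equilibrium strains of the axisymmetric pre-stressed cylinder.

    Minimizing the membrane energy over homogeneous dilations gives

        eps_phiphi0 = (dP*R*(lam + 4 mu) - 2 lam sigma_zz) / (8 mu (lam + mu))
        eps_zz0     = (2 sigma_zz (lam + 2 mu) - dP*R*(lam - 2 mu)) / (8 mu (lam + mu))

    both vanishing with the loads.
    """
    lam, mu = material.lam, material.mu
    denom = 8.0 * mu * (lam + mu)
    if denom == 0:
        raise ZeroDivisionError("mu*(lam + mu) must be nonzero")
    dPR = load.deltaP * geometry.R
    s = load.sigma_zz
    return HomogeneousStrain(
        eps_phiphi0=(dPR * (lam + 4.0 * mu) - 2.0 * lam * s) / denom,
        eps_zz0=(2.0 * s * (lam + 2.0 * mu) - dPR * (lam - 2.0 * mu)) / denom,
    )


def stability_matrix(
    material: ShellMaterial,
    geometry: TubeGeometry,
    load: LoadState,
    env: Environment = FREE,
    mode: Mode = Mode(0, 0.0),
) -> StabilityMatrix:
    """Assemble the per-mode 3x3 Hermitian stability matrix.

    With ``X = R^2 k^2 + n^2`` the entries are (radial, azimuthal, axial
    ordering; ``dP = deltaP``, ``s = sigma_zz``):

        M11 = (lam+2mu)/R^2 + kappa X^2/R^4 + dP (X + n^2 - 2)/(2R) + s k^2 + C
        M12 = -i n (kappa X/R^4 + (lam+2mu)/R^2)            = conj(M21)
        M13 = -i k (lam - dP R)/R                           = conj(M31)
        M22 = n^2 (R^2 (lam+2mu) + kappa)/R^4 + (mu + s/4 + 3 dP R/8) k^2
        M23 = n k ((lam+mu)/R - s/(4R) - 3 dP/8)            = M32
        M33 = (lam+2mu) k^2 + (mu + s/4 + 3 dP R/8) n^2/R^2

    The radial pinning coefficient ``C`` enters only M11.  Hermiticity holds
    exactly by construction.
    """
    lam, mu, kappa = material.lam, material.mu, material.kappa
    R = geometry.R
    dP, s = load.deltaP, load.sigma_zz
    n, k = float(mode.n), mode.k
    X = R * R * k * k + n * n

    M = np.zeros((3, 3), dtype=complex)
    M[0, 0] = (
        (lam + 2 * mu) / R**2
        + kappa * X * X / R**4
        + dP * (X + n * n - 2.0) / (2.0 * R)
        + s * k * k
        + env.C
    )
    M[0, 1] = -1j * n * (kappa * X / R**4 + (lam + 2 * mu) / R**2)
    M[1, 0] = np.conj(M[0, 1])
    M[0, 2] = -1j * k * (lam - dP * R) / R
    M[2, 0] = np.conj(M[0, 2])
    M[1, 1] = n * n * (R * R * (lam + 2 * mu) + kappa) / R**4 + (
        mu + s / 4.0 + 3.0 * dP * R / 8.0
    ) * k * k
    M[1, 2] = n * k * ((lam + mu) / R - s / (4.0 * R) - 3.0 * dP / 8.0)
    M[2, 1] = np.conj(M[1, 2])
    M[2, 2] = (lam + 2 * mu) * k * k + (mu + s / 4.0 + 3.0 * dP * R / 8.0) * n * n / R**2
    return StabilityMatrix(M=M, mode=mode, material=material, geometry=geometry, load=load, env=env)


def mode_energy(
    Mmat: StabilityMatrix, A: ModeAmplitudes | np.ndarray, geometry: TubeGeometry
) -> float:
    """Energy of one stored mode, ``2 pi R L * sum_ij M_ij A_i conj(A_j)``.

    A stored mode with ``(n, k) != (0, 0)`` accounts for its conjugate pair;
    the self-conjugate homogeneous mode counts twice and must carry real
    amplitudes.  The result is real to 1e-12 relative (Hermitian form).
    """
    a = A.as_array() if isinstance(A, ModeAmplitudes) else np.asarray(A, dtype=complex)
    mode = Mmat.mode
    self_conjugate = mode.n == 0 and mode.k == 0.0
    if self_conjugate and np.max(np.abs(a.imag)) > 1e-14 * max(1.0, np.max(np.abs(a))):
        raise ValueError("the self-conjugate (n=0, k=0) mode requires real amplitudes")
    # paper-style pairing: sum_ij M_ij A_i conj(A_j) = A^T M conj(A)
    quad = a @ Mmat.M @ np.conj(a)
    if abs(quad) > 0 and abs(quad.imag) > 1e-12 * abs(quad):
        raise FloatingPointError("mode energy is not real; matrix is not Hermitian")
    factor = 2.0 if self_conjugate else 1.0
    return float(factor * 2.0 * np.pi * geometry.R * geometry.L * quad.real)


def _dphi(f: np.ndarray) -> np.ndarray:
    """Spectral d/dphi on axis 0 (phi uniform on [0, 2pi))."""
    n_phi = f.shape[0]
    F = np.fft.fft(f, axis=0)
    ik = 1j * np.fft.fftfreq(n_phi, d=1.0 / n_phi)
    return np.real(np.fft.ifft(F * ik[:, None], axis=0))


def _dz_periodic(f: np.ndarray, L: float, order: int = 4) -> np.ndarray:
    """Periodic finite-difference d/dz on axis 1 (z uniform on [0, L))."""
    n_z = f.shape[1]
    dz = L / n_z
    if order == 4:
        return (
            -np.roll(f, -2, axis=1)
            + 8.0 * np.roll(f, -1, axis=1)
            - 8.0 * np.roll(f, 1, axis=1)
            + np.roll(f, 2, axis=1)
        ) / (12.0 * dz)
    return (np.roll(f, -1, axis=1) - np.roll(f, 1, axis=1)) / (2.0 * dz)


def energy_numeric_oracle(
    field: np.ndarray,
    material: ShellMaterial,
    geometry: TubeGeometry,
    load: LoadState,
    env: Environment = FREE,
    include_volume_stretch_coupling: bool = True,
) -> float:
    """Quadratic energy of a displacement field by direct surface quadrature.

    Parameters
    ----------
    field : ndarray, shape (3, Nphi, Nz)
        Real displacement components ``(u_r, u_phi, u_z)`` sampled on a
        uniform periodic grid, phi on [0, 2pi) and z on [0, L).
    include_volume_stretch_coupling : bool
        The explicit load integrands of the linearized energy miss the
        quadratic cross term of the enclosed volume with the axial stretch,
        ``-(deltaP/2) * u_r * dz(u_z)`` (the volume element carries a factor
        ``1 + dz(u_z)``).  With the term included (default) the oracle
        reproduces the stability matrix exactly; without it the radial-axial
        coupling differs by ``deltaP*R/2`` in M13, which this keyword exposes
        rather than absorbs.

    The integrand combines the linearized membrane strain energy
    (``eps_zz = dz u_z``, ``eps_phiphi = (dphi u_phi + u_r)/R``,
    ``eps_zphi = (dz u_phi + dphi u_z / R)/2``), the load integrands
    ``sigma_zz J1 + R deltaP J2``, the bending term ``kappa/2 * dH^2`` with
    ``dH = (dphi^2 u_r + R^2 dz^2 u_r - dphi u_phi)/R^2``, and the pinning
    term ``C/2 u_r^2``.  Derivatives are spectral in phi and 4th-order
    periodic finite differences in z.

    Raises
    ------
    ValueError
        If the field is not a (3, Nphi, Nz) real array or the grid is too
        coarse for the finite-difference stencils.
    """
    u = np.asarray(field, dtype=float)
    if u.ndim != 3 or u.shape[0] != 3:
        raise ValueError(f"field must have shape (3, Nphi, Nz), got {u.shape}")
    n_phi, n_z = u.shape[1], u.shape[2]
    if n_phi < 8 or n_z < 8:
        raise ValueError("grid too coarse: need at least 8 points per direction")

    lam, mu, kappa = material.lam, material.mu, material.kappa
    R, L = geometry.R, geometry.L
    dP, s = load.deltaP, load.sigma_zz
    ur, uph, uz = u

    dphi_ur = _dphi(ur)
    dphi_uph = _dphi(uph)
    dphi_uz = _dphi(uz)
    dz_ur = _dz_periodic(ur, L)
    dz_uph = _dz_periodic(uph, L)
    dz_uz = _dz_periodic(uz, L)

    eps_zz = dz_uz
    eps_phph = (dphi_uph + ur) / R
    eps_zph = (dz_uph + dphi_uz / R) / 2.0
    elastic = lam / 2.0 * (eps_zz + eps_phph) ** 2 + mu * (
        eps_zz**2 + eps_phph**2 + 2.0 * eps_zph**2
    )

    shear_like = (dz_uph - dphi_uz / R) ** 2
    J1 = 0.5 * dz_ur**2 + shear_like / 8.0
    J2 = (
        0.5 * J1
        + shear_like / 8.0
        + (dz_uph * dphi_uz - dz_uz * dphi_uph) / (2.0 * R)
        + dphi_ur * (dphi_ur - uph) / (2.0 * R**2)
        - ur * (ur + dphi_uph + R * dz_uz) / (2.0 * R**2)
    )

    dH = (_dphi(dphi_ur) + R * R * _dz_periodic(dz_ur, L) - dphi_uph) / R**2

    density = elastic + s * J1 + R * dP * J2 + kappa / 2.0 * dH**2 + env.C / 2.0 * ur**2
    # linear term of the pressure work; integrates to zero on a periodic grid
    density = density + (dP / 2.0) * dphi_uph
    if include_volume_stretch_coupling:
        density = density - (dP / 2.0) * ur * dz_uz

    dS = R * (2.0 * np.pi / n_phi) * (L / n_z)
    return float(np.sum(density) * dS)


def _is_rigid(mode: Mode) -> bool:
    """Rigid-body content: (n=0, k=0) and the |n|=1, k=0 Goldstone pair."""
    return mode.k == 0.0 and abs(mode.n) <= 1


def is_mode_stable(Mmat: StabilityMatrix) -> bool:
    """Stability of a single mode: ``det M > 0`` (rigid modes count stable).

    The determinant is compared against a small tolerance scaled by the
    elastic entry scale, so Goldstone zeros are not misread as instabilities.
    """
    if _is_rigid(Mmat.mode):
        return True
    scale = max(np.max(np.abs(Mmat.M)), 1e-300) ** 3
    return Mmat.det > -DET_TOLERANCE * scale


@dataclass
class StabilityReport:
    """Result of a mode scan: per-mode determinants and the verdict."""

    table: pd.DataFrame
    stable: bool
    violating: list[tuple[int, float]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, columns=["n", "k", "detM", "stable"])

    def summary(self) -> dict:
        worst = None
        if self.violating:
            sub = self.table[~self.table["stable"]]
            row = sub.loc[sub["detM"].idxmin()]
            worst = {"n": int(row["n"]), "k": float(row["k"]), "detM": float(row["detM"])}
        return {
            "stable": bool(self.stable),
            "n_modes_scanned": int(len(self.table)),
            "n_violating": len(self.violating),
            "worst_mode": worst,
        }

    def to_json(self) -> str:
        return json.dumps(self.summary())


def default_k_grid(material: ShellMaterial, geometry: TubeGeometry, num: int = DEFAULT_K_POINTS) -> np.ndarray:
    """Log-spaced k grid reaching beyond the corrugation wave vector.

    The critical corrugation mode sits near ``k R ~ gamma**-0.5``, so the
    grid spans ``k R`` from 1e-2 up to ``max(10, 3/gamma)``.
    """
    from .elasticity import normalized_gamma

    gamma = normalized_gamma(material, geometry)
    upper = max(10.0, 3.0 / gamma) if gamma > 0 else 10.0
    return np.logspace(np.log10(1e-2), np.log10(upper), num) / geometry.R


def scan_stability(
    material: ShellMaterial,
    geometry: TubeGeometry,
    load: LoadState,
    env: Environment = FREE,
    n_max: int = DEFAULT_N_MAX,
    k_grid: np.ndarray | None = None,
) -> StabilityReport:
    """Scan ``det M`` over modes ``n in [0, n_max]`` and a k grid.

    ``k = 0`` is always included so transversal (``k=0, |n| >= 2``) modes are
    covered; rigid-body modes are excluded from the verdict.  Negative ``n``
    are conjugates of positive ``n`` and carry the same determinant.
    """
    if n_max < 2:
        raise ValueError(f"n_max must be >= 2 to cover transversal modes, got {n_max}")
    load.check_validity(material, geometry)
    if k_grid is None:
        k_grid = default_k_grid(material, geometry)
    k_values = np.concatenate(([0.0], np.asarray(k_grid, dtype=float)))
    if np.any(k_values < 0):
        raise ValueError("k grid must be non-negative")

    rows = []
    for n in range(0, n_max + 1):
        for k in k_values:
            mode = Mode(n=n, k=float(k))
            Mmat = stability_matrix(material, geometry, load, env, mode)
            rows.append(
                {
                    "n": n,
                    "k": float(k),
                    "detM": Mmat.det,
                    "rigid": _is_rigid(mode),
                    "stable": is_mode_stable(Mmat),
                }
            )
    table = pd.DataFrame(rows)
    violating = [
        (int(r["n"]), float(r["k"]))
        for _, r in table.iterrows()
        if not r["stable"]
    ]
    return StabilityReport(table=table, stable=not violating, violating=violating)
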