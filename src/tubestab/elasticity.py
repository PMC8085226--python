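"""Material description of a thin elastic tubular membrane.

The vessel wall is modeled as a two-dimensional isotropic elastic sheet
characterized by in-plane Lamé coefficients ``lam`` and ``mu`` (units
force/length), a bending rigidity ``kappa`` (units force·length, i.e. an
energy), and — derived from those — a 2D Young modulus ``E2d`` and a 2D
Poisson ratio ``nu2d``.  All stability results of the package are naturally
expressed in the three dimensionless control parameters

* ``p     = deltaP * R / E2d``    — normalized pressure difference,
* ``sigma = sigma_zz / E2d``      — normalized axial stress,
* ``gamma = sqrt(kappa / (E2d * R**2))`` — normalized bending rigidity,

so dimensional quantities are accepted in any single consistent unit set
(default convention: lengths in µm, 2D moduli and stresses in nN/µm, kappa
in nN·µm) and converted at the boundary.

Sign conventions, used consistently across the package:

* ``deltaP > 0`` dilates the tube (internal pressure excess);
* ``sigma_zz < 0`` is axial compression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, types only
    from .shell_stability import LoadState

__all__ = [
    "ShellMaterial",
    "TubeGeometry",
    "DimensionlessState",
    "lame_from_engineering",
    "bending_rigidity_fvk",
    "normalized_gamma",
    "nondimensionalize",
    "dimensionalize",
]

#: Largest 2D Poisson ratio accepted by dimensional code paths.  lam diverges
#: as nu2d -> 1; the exactly incompressible case is served by the normalized
#: closed forms in :mod:`tubestab.phase_diagram`.
NU2D_MAX = 0.999

_ROUNDTRIP_RTOL = 1e-12


@dataclass(frozen=True)
class ShellMaterial:
    """2D elastic constants of the membrane.

    Parameters
    ----------
    lam : float
        First in-plane Lamé coefficient (force/length).
    mu : float
        In-plane shear modulus (force/length); must be positive.
    kappa : float
        Bending rigidity (force·length); must be non-negative.
    """

    lam: float
    mu: float
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise ValueError(f"shear modulus mu must be positive, got {self.mu}")
        if not (self.lam + self.mu > 0):
            raise ValueError(
                f"lam + mu must be positive for E2d > 0, got lam={self.lam}, mu={self.mu}"
            )
        if self.kappa < 0:
            raise ValueError(f"bending rigidity kappa must be >= 0, got {self.kappa}")

    @property
    def e2d(self) -> float:
        """2D Young modulus, ``4*mu*(lam + mu)/(lam + 2*mu)``."""
        return 4.0 * self.mu * (self.lam + self.mu) / (self.lam + 2.0 * self.mu)

    @property
    def nu2d(self) -> float:
        """2D Poisson ratio, ``lam/(lam + 2*mu)``; lies in (-1, 1)."""
        return self.lam / (self.lam + 2.0 * self.mu)

    @classmethod
    def from_engineering(cls, e2d: float, nu2d: float, kappa: float = 0.0) -> "ShellMaterial":
        """Build a material from the (E2d, nu2d) parametrization."""
        lam, mu = lame_from_engineering(e2d, nu2d)
        return cls(lam=lam, mu=mu, kappa=kappa)


@dataclass(frozen=True)
class TubeGeometry:
    """Relaxed geometry of the tube.

    Parameters
    ----------
    R : float
        Relaxed (unloaded) radius.
    L : float
        Tube length; the aspect ratio ``R/L`` controls the Euler threshold.
    h : float, optional
        Wall thickness, used only to derive ``kappa`` via the
        Föppl–von-Kármán relation; must satisfy ``0 < h < R`` when given.
    """

    R: float
    L: float
    h: float | None = None

    def __post_init__(self) -> None:
        if not (self.R > 0):
            raise ValueError(f"radius R must be positive, got {self.R}")
        if not (self.L > 0):
            raise ValueError(f"length L must be positive, got {self.L}")
        if self.h is not None and not (0 < self.h < self.R):
            raise ValueError(f"wall thickness must satisfy 0 < h < R, got h={self.h}, R={self.R}")

    @property
    def aspect(self) -> float:
        """Radius-to-length ratio ``R/L``."""
        return self.R / self.L


@dataclass(frozen=True)
class DimensionlessState:
    """Normalized control-parameter point ``(p, sigma, gamma)``."""

    p: float
    sigma: float
    gamma: float

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not (math.isfinite(self.p) and math.isfinite(self.sigma)):
            raise ValueError("p and sigma must be finite")


def lame_from_engineering(e2d: float, nu2d: float) -> tuple[float, float]:
    """Invert the 2D engineering constants to Lamé coefficients.

    Returns ``lam = E2d*nu/(1 - nu**2)`` and ``mu = E2d/(2*(1 + nu))``, the
    inverse of ``E2d = 4*mu*(lam + mu)/(lam + 2*mu)`` and
    ``nu2d = lam/(lam + 2*mu)``.

    Raises
    ------
    ValueError
        If ``e2d <= 0`` or ``nu2d`` is outside ``(-1, NU2D_MAX]``.  Values
        at and beyond 1 make ``lam`` diverge; the incompressible limit is
        handled by the normalized formulas in :mod:`tubestab.phase_diagram`.
    """
    if not (e2d > 0):
        raise ValueError(f"E2d must be positive, got {e2d}")
    if not (-1.0 < nu2d <= NU2D_MAX):
        raise ValueError(
            f"nu2d must lie in (-1, {NU2D_MAX}] for dimensional code, got {nu2d}"
        )
    lam = e2d * nu2d / (1.0 - nu2d * nu2d)
    mu = e2d / (2.0 * (1.0 + nu2d))
    return lam, mu


def bending_rigidity_fvk(e2d: float, h: float, nu2d: float) -> float:
    """Föppl–von-Kármán bending rigidity of a thin plate of thickness ``h``.

    ``kappa = E2d * h**2 / (12 * (1 - nu2d**2))``.
    """
    if not (e2d > 0 and h > 0):
        raise ValueError(f"E2d and h must be positive, got E2d={e2d}, h={h}")
    if not (-1.0 < nu2d < 1.0):
        raise ValueError(f"nu2d must lie in (-1, 1), got {nu2d}")
    return e2d * h * h / (12.0 * (1.0 - nu2d * nu2d))


def normalized_gamma(material: ShellMaterial, geometry: TubeGeometry) -> float:
    """Normalized bending rigidity ``gamma = sqrt(kappa/(E2d * R**2))``.

    With the Föppl–von-Kármán ``kappa`` this is identically
    ``h / (R * sqrt(12 * (1 - nu2d**2)))``.  For the embryonic dorsal aorta
    (h ≈ 0.5 µm, R ≈ 14 µm, nu2d ≈ 0.9) the formula gives gamma ≈ 0.0237,
    commonly quoted rounded to ~1/50.
    """
    return math.sqrt(material.kappa / (material.e2d * geometry.R**2))


def nondimensionalize(
    load: "LoadState", material: ShellMaterial, geometry: TubeGeometry
) -> DimensionlessState:
    """Map a dimensional load to the normalized ``(p, sigma, gamma)`` point."""
    e2d = material.e2d
    return DimensionlessState(
        p=load.deltaP * geometry.R / e2d,
        sigma=load.sigma_zz / e2d,
        gamma=normalized_gamma(material, geometry),
    )


def dimensionalize(
    state: DimensionlessState, material: ShellMaterial, geometry: TubeGeometry
) -> "LoadState":
    """Inverse of :func:`nondimensionalize`; round-trips to 1e-12 relative."""
    from .shell_stability import LoadState

    e2d = material.e2d
    return LoadState(deltaP=state.p * e2d / geometry.R, sigma_zz=state.sigma * e2d)
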