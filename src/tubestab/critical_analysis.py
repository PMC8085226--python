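"""Critical loads and wave vectors of the four instability classes.

Each threshold is available through two routes:

* ``analytic`` — the closed-form expression obtained from the per-mode
  stability matrix in the small-load, thin-wall limit;
* ``numeric``  — bracketed root finding on the determinant (or the relevant
  principal block) of the exact stability matrix, independent of the closed
  forms.

Classes
-------
corrugation
    Axisymmetric (n = 0) varicose mode with finite wave vector; driven by
    axial compression, stabilized by internal pressure.  Radial pinning C
    renormalizes the Young modulus, ``E2d' = E2d + C R^2``.
euler
    Long-wave bending (n = 1) of the tube axis under axial compression.
transversal
    Ovalization (k = 0, |n| >= 2) under external pressure excess.
plate
    Buckling of a single approximately flat cell of size ``a = R`` with
    pinned borders, the planar ``R -> inf`` limit of the radial block.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .elasticity import ShellMaterial, TubeGeometry
from .shell_stability import FREE, Environment, LoadState, Mode, stability_matrix

__all__ = [
    "CriticalResult",
    "corrugation_wavevector",
    "corrugation_critical_stress",
    "euler_determinant_coefficients",
    "euler_buckling_stress",
    "transversal_buckling_pressure",
    "plate_buckling_stress",
    "plate_strip_lc",
]

#: Normalized-sigma refinement tolerance of the bracketed root search.
SIGMA_XTOL = 1e-12
#: Lower edge of the sigma bracket, in units of E2d.
SIGMA_BRACKET = -0.5


@dataclass(frozen=True)
class CriticalResult:
    """A critical load with the mode that attains it.

    ``critical_value`` is a stress for corrugation/euler/plate and a pressure
    difference for transversal buckling; ``mode`` is the critical ``(n, k)``.
    """

    kind: str
    critical_value: float
    mode: Mode
    method: str


def corrugation_wavevector(
    material: ShellMaterial,
    geometry: TubeGeometry,
    deltaP: float = 0.0,
    env: Environment = FREE,
) -> float:
    """Critical wave vector of the axisymmetric corrugation mode.

    For the free tube,

        k^2 = sqrt( (4 mu (lam+mu) - dP R (dP R - lam + 2 mu))
                    / (kappa (lam + 2 mu) R^2) ),

    which at ``deltaP = 0`` reduces to ``k R = gamma**-0.5``.  Radial pinning
    adds ``C R^2 (lam + 2 mu)`` to the numerator (the effective-modulus
    substitution ``E2d -> E2d + C R^2``), recovering the pinned ``deltaP = 0``
    selection ``k^2 = sqrt((E2d + C R^2)/(kappa R^2))``.

    Raises
    ------
    ValueError
        If ``kappa = 0`` or the radicand is not positive (pressure too large
        for a corrugation threshold within the model).
    """
    lam, mu, kappa = material.lam, material.mu, material.kappa
    R = geometry.R
    if kappa <= 0:
        raise ValueError("corrugation wave vector requires kappa > 0")
    dPR = deltaP * R
    numer = 4.0 * mu * (lam + mu) - dPR * (dPR - lam + 2.0 * mu) + env.C * R * R * (lam + 2.0 * mu)
    if numer <= 0:
        raise ValueError(
            "no corrugation wave vector: pressure too large for the varicose branch"
        )
    k2 = math.sqrt(numer / (kappa * (lam + 2.0 * mu) * R * R))
    return math.sqrt(k2)


def _sigma_root_at_k(
    material: ShellMaterial,
    geometry: TubeGeometry,
    deltaP: float,
    env: Environment,
    k: float,
) -> float | None:
    """Solve the n=0 block ``M11 M33 - |M13|^2 = 0`` for sigma_zz at fixed k.

    Returns None when the determinant does not change sign inside the
    bracket ``[SIGMA_BRACKET * E2d, 0]``.
    """

    def det_block(sigma: float) -> float:
        Mm = stability_matrix(
            material, geometry, LoadState(deltaP=deltaP, sigma_zz=sigma), env, Mode(0, k)
        ).M
        return float((Mm[0, 0] * Mm[2, 2] - Mm[0, 2] * Mm[2, 0]).real)

    e2d = material.e2d
    lo, hi = SIGMA_BRACKET * e2d, 0.0
    f_lo, f_hi = det_block(lo), det_block(hi)
    if f_lo == 0.0:
        return lo
    if f_lo * f_hi > 0:
        return None
    return float(
        optimize.brentq(det_block, lo, hi, xtol=SIGMA_XTOL * e2d, rtol=8.9e-16)
    )


def corrugation_critical_stress(
    material: ShellMaterial,
    geometry: TubeGeometry,
    deltaP: float = 0.0,
    env: Environment = FREE,
    method: str = "analytic",
) -> CriticalResult:
    """Critical axial stress of the corrugation (varicose) instability.

    analytic
        ``sigma = -dP R/2 (1 + 2 (2 nu2d - 1) sqrt(kappa/(E' R^2)))
        - 2 sqrt(kappa E')/R`` with the pinning-renormalized modulus
        ``E' = E2d + C R^2``.
    numeric
        Per k, a bracketed root of the exact axisymmetric determinant block
        in sigma; the least-|sigma| root over a log k grid, refined by
        bounded minimization.  Raises if no root exists in the bracket.
    """
    lam, mu, kappa = material.lam, material.mu, material.kappa
    R = geometry.R
    if kappa <= 0:
        raise ValueError("corrugation threshold requires kappa > 0")

    if method == "analytic":
        e_eff = material.e2d + env.C * R * R
        nu = material.nu2d
        sigma = -deltaP * R / 2.0 * (
            1.0 + 2.0 * (2.0 * nu - 1.0) * math.sqrt(kappa / (e_eff * R * R))
        ) - 2.0 * math.sqrt(kappa * e_eff) / R
        k_star = corrugation_wavevector(material, geometry, deltaP, env)
        return CriticalResult("corrugation", sigma, Mode(0, k_star), "analytic")

    if method != "numeric":
        raise ValueError(f"unknown method {method!r}")

    # coarse pass on a log grid around the expected selection k R ~ gamma^-1/2
    gamma = math.sqrt(kappa / (material.e2d * R * R))
    k_grid = np.logspace(
        math.log10(0.02 / math.sqrt(gamma)), math.log10(50.0 / math.sqrt(gamma)), 160
    ) / R
    best_k, best_sigma = None, None
    for k in k_grid:
        sigma = _sigma_root_at_k(material, geometry, deltaP, env, float(k))
        if sigma is not None and (best_sigma is None or sigma > best_sigma):
            best_k, best_sigma = float(k), sigma
    if best_k is None:
        raise ValueError("no corrugation root found in the sigma bracket")

    idx = int(np.argmin(np.abs(k_grid - best_k)))
    lo = float(k_grid[max(0, idx - 1)])
    hi = float(k_grid[min(len(k_grid) - 1, idx + 1)])

    def neg_sigma(k: float) -> float:
        sigma = _sigma_root_at_k(material, geometry, deltaP, env, k)
        return np.inf if sigma is None else -sigma

    res = optimize.minimize_scalar(neg_sigma, bounds=(lo, hi), method="bounded")
    if np.isfinite(res.fun) and -res.fun > best_sigma:
        best_k, best_sigma = float(res.x), float(-res.fun)
    return CriticalResult("corrugation", best_sigma, Mode(0, best_k), "numeric")


@functools.lru_cache(maxsize=1)
def _euler_coefficient_functions():
    """Lambdified coefficients a1..a4 of det M(n=1) = sum_i a_i k^(2i).

    Generated symbolically from the stability matrix at n = 1 (free tube,
    C = 0, where the determinant has no constant term).  Cached; sympy runs
    once per process.
    """
    import sympy as sp

    lam, mu, kap, R, dP, s, k = sp.symbols("lam mu kap R dP s k", real=True)
    n = 1
    X = R**2 * k**2 + n**2
    M = sp.Matrix(
        [
            [
                (lam + 2 * mu) / R**2
                + kap * X**2 / R**4
                + dP * (X + n**2 - 2) / (2 * R)
                + s * k**2,
                -sp.I * n * (kap * X / R**4 + (lam + 2 * mu) / R**2),
                -sp.I * k * (lam - dP * R) / R,
            ],
            [
                sp.I * n * (kap * X / R**4 + (lam + 2 * mu) / R**2),
                n**2 * (R**2 * (lam + 2 * mu) + kap) / R**4
                + (mu + s / 4 + 3 * dP * R / 8) * k**2,
                n * k * ((lam + mu) / R - s / (4 * R) - 3 * dP / 8),
            ],
            [
                sp.I * k * (lam - dP * R) / R,
                n * k * ((lam + mu) / R - s / (4 * R) - 3 * dP / 8),
                (lam + 2 * mu) * k**2 + (mu + s / 4 + 3 * dP * R / 8) * n**2 / R**2,
            ],
        ]
    )
    det = sp.expand(M.det())
    poly = sp.Poly(det, k)
    coeffs = {deg: poly.coeff_monomial(k**deg) for deg in (2, 4, 6, 8)}
    assert poly.coeff_monomial(sp.Integer(1)) == 0, "free term must vanish (Goldstone)"
    args = (lam, mu, kap, R, dP, s)
    return tuple(sp.lambdify(args, sp.simplify(coeffs[d]), "numpy") for d in (2, 4, 6, 8))


def euler_determinant_coefficients(
    material: ShellMaterial, geometry: TubeGeometry, load: LoadState
) -> tuple[float, float, float, float]:
    """Numeric values of (a1, a2, a3, a4) in ``det M(n=1) = sum a_i k^(2i)``."""
    funcs = _euler_coefficient_functions()
    args = (
        material.lam,
        material.mu,
        material.kappa,
        geometry.R,
        load.deltaP,
        load.sigma_zz,
    )
    return tuple(float(f(*args)) for f in funcs)


def euler_buckling_stress(
    material: ShellMaterial,
    geometry: TubeGeometry,
    deltaP: float = 0.0,
    k: float | None = None,
    method: str = "analytic",
) -> CriticalResult:
    """Critical axial stress of long-wave (n = 1) Euler buckling.

    ``k`` is the dimensional axial wave vector; defaults to the fundamental
    ``2 pi / L``.  Validity requires ``k R << 1`` (warned otherwise).

    analytic
        ``sigma = -2 mu ((lam+mu) R^2 + kappa) / ((lam+2mu) R^2 + kappa)
        * (k R)^2``; in the incompressible, kappa-small limit the normalized
        threshold is ``-(1/2) (k R)^2``.
    numeric
        Root in sigma of the truncated determinant ``a1 + a2 (k R)^2 = 0``
        with coefficients generated symbolically from det M(n=1); the k^6
        and k^8 terms are dropped exactly as in the long-wave estimate, and
        the full coefficient set is available through
        :func:`euler_determinant_coefficients`.
    """
    lam, mu, kappa = material.lam, material.mu, material.kappa
    R = geometry.R
    if k is None:
        k = 2.0 * math.pi / geometry.L
    if k == 0.0:
        return CriticalResult("euler", 0.0, Mode(1, 0.0), method)
    k_norm = k * R
    if k_norm > 0.3:
        warnings.warn(
            f"Euler estimate assumes k*R << 1; got k*R = {k_norm:.3g}", stacklevel=2
        )

    if method == "analytic":
        sigma = (
            -2.0
            * mu
            * ((lam + mu) * R * R + kappa)
            / ((lam + 2.0 * mu) * R * R + kappa)
            * k_norm**2
        )
        return CriticalResult("euler", sigma, Mode(1, k), "analytic")

    if method != "numeric":
        raise ValueError(f"unknown method {method!r}")

    def truncated(sigma: float) -> float:
        a1, a2, _, _ = euler_determinant_coefficients(
            material, geometry, LoadState(deltaP=deltaP, sigma_zz=sigma)
        )
        # det in the normalized wave vector: a_i multiply k^(2i) with k
        # dimensional; evaluate at the requested k
        return a1 * k * k + a2 * k**4

    e2d = material.e2d
    lo, hi = SIGMA_BRACKET * e2d, 0.0
    if truncated(lo) * truncated(hi) > 0:
        raise ValueError("no Euler root in the sigma bracket")
    sigma = float(optimize.brentq(truncated, lo, hi, xtol=SIGMA_XTOL * e2d, rtol=8.9e-16))
    return CriticalResult("euler", sigma, Mode(1, k), "numeric")


def _transversal_pressure_numeric_single(
    material: ShellMaterial, geometry: TubeGeometry, env: Environment, n: int
) -> float:
    """Root in deltaP of the exact k=0 block ``M11 M22 - |M12|^2 = 0``.

    The block is linear in deltaP at k = 0, so two evaluations determine the
    root exactly.
    """

    def block(dP: float) -> float:
        Mm = stability_matrix(
            material, geometry, LoadState(deltaP=dP), env, Mode(n, 0.0)
        ).M
        return float((Mm[0, 0] * Mm[1, 1] - Mm[0, 1] * Mm[1, 0]).real)

    f0, f1 = block(0.0), block(1.0)
    slope = f1 - f0
    if slope == 0.0:
        raise ValueError(f"k=0 block independent of deltaP at n={n}")
    return -f0 / slope


def transversal_buckling_pressure(
    material: ShellMaterial,
    geometry: TubeGeometry,
    env: Environment = FREE,
    n_max: int = 10,
    method: str = "analytic",
) -> CriticalResult:
    """Critical (least-negative) pressure for ovalization at ``k = 0``.

    analytic
        ``deltaP_crit(n) = -C R/(n^2 - 1) - (n^2 - 1) kappa / R^3`` maximized
        over ``|n| in [2, n_max]``; for the free tube this is
        ``-3 kappa / R^3`` at ``|n| = 2``.
    numeric
        Exact root of the k=0 principal block of the stability matrix per n,
        maximized over n.

    Ties on the maximizing n resolve to the smallest |n| (degenerate +/-n
    reported once).  Weak pinning (``C R^4 <= kappa``) keeps the critical
    mode at |n| = 2; strong pinning pushes it to higher |n|.
    """
    if n_max < 2:
        raise ValueError(f"n_max must be >= 2, got {n_max}")
    kappa, R = material.kappa, geometry.R

    best_n, best_dp = None, None
    for n in range(2, n_max + 1):
        if method == "analytic":
            dp = -env.C * R / (n * n - 1.0) - (n * n - 1.0) * kappa / R**3
        elif method == "numeric":
            dp = _transversal_pressure_numeric_single(material, geometry, env, n)
        else:
            raise ValueError(f"unknown method {method!r}")
        if best_dp is None or dp > best_dp:
            best_n, best_dp = n, dp
    return CriticalResult("transversal", float(best_dp), Mode(best_n, 0.0), method)


def plate_buckling_stress(kappa: float, R: float, l_c: float = 1.0) -> float:
    """Buckling stress of a flat square cell plate of side ``a = R``.

    ``sigma = -kappa (l_c pi / R)^2`` with the boundary-condition coefficient
    ``l_c``; pinned borders give ``l_c = 1``.  This is the planar
    ``R -> inf`` limit of the radial diagonal entry of the tube matrix.
    """
    if not (kappa > 0 and R > 0 and l_c > 0):
        raise ValueError("kappa, R and l_c must be positive")
    return -kappa * (l_c * math.pi / R) ** 2


def plate_strip_lc(kappa: float = 1.0, a: float = 1.0, num: int = 400) -> float:
    """Boundary coefficient ``l_c`` from the discretized pinned-strip problem.

    Solves the 1D buckling eigenproblem ``kappa u'''' = -sigma u''`` on
    ``[0, a]`` with pinned ends (deflection and curvature zero) by central
    finite differences: the generalized eigenvalue problem
    ``kappa D2 @ D2 u = P (-D2) u`` with ``P = -sigma``.  The lowest buckling
    load gives ``l_c = k a / pi = sqrt(P/kappa) a / pi``; the discretization
    error is O((a/num)^2).
    """
    if num < 8:
        raise ValueError("need at least 8 grid intervals")
    h = a / num
    main = np.full(num - 1, -2.0) / h**2
    off = np.full(num - 2, 1.0) / h**2
    D2 = np.diag(main) + np.diag(off, 1) + np.diag(off, -1)
    # pinned ends: u = 0 and u'' = 0, so the ghost values satisfy
    # u[-1] = -u[1] and D4 = D2 @ D2 on the interior nodes
    K = kappa * (D2 @ D2)
    G = -D2
    eigvals = linalg.eigh(K, G, eigvals_only=True)
    P = float(np.min(eigvals[eigvals > 0]))
    return math.sqrt(P / kappa) * a / math.pi
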