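"""Normalized stability domain and developmental-trajectory staging.

In the dimensionless coordinates ``(p, sigma)`` (normalized pressure and
axial stress) the three boundaries of the cylindrical phase, for an
incompressible membrane (``nu2d ~ 1``) with normalized bending rigidity
``gamma`` and aspect ratio ``R/L``, are straight lines:

* corrugation:  ``sigma = -[p (1 + 2 gamma)/2 + 2 gamma]``
* Euler:        ``sigma = -(1/2) (2 pi R / L)^2``
* transversal:  ``p = -3 gamma^2``

The corrugation intercept ``-2 gamma`` is the normalized form of the
classical axially-loaded-shell threshold ``-2 sqrt(kappa E2d)/R`` and is
what the stability-matrix determinant yields; renderings of this line that
quote ``-gamma`` at the axis are off by a factor 2.

A developmental trajectory — the vessel's path through ``(p, sigma)`` as
pressure rises and growth-mismatch compression accumulates — is staged
against the corrugation boundary:

    I   expansion, before the first boundary crossing;
    II  corrugated, from the crossing to the maximum of p;
    III from the p maximum until the trajectory re-enters stability;
    IV  after re-entry (shape restored).

``scenario_trajectories`` provides smooth synthetic stand-ins for the
wild-type loop and for reduced-flow / no-flow mutants, whose lower blood
pressure scales p down and makes the trajectory steeper, so it crosses the
corrugation boundary earlier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhasePoint",
    "Trajectory",
    "boundary_lines",
    "classify_state",
    "stage_trajectory",
    "scenario_trajectories",
]

from .elasticity import DimensionlessState

BOUNDARIES = ("corrugation", "euler", "transversal")
ENVIRONMENTS = ("free", "pinned")
STAGES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class PhasePoint:
    """A normalized state plus the context needed to classify it."""

    state: DimensionlessState
    aspect: float = 1.0 / 50.0
    environment: str = "free"

    def __post_init__(self) -> None:
        if not (0.0 < self.aspect < 1.0):
            raise ValueError(f"aspect R/L must lie in (0, 1), got {self.aspect}")
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"environment must be one of {ENVIRONMENTS}")


@dataclass
class Trajectory:
    """A time-ordered path in ``(p, sigma)`` with optional stage labels."""

    times: np.ndarray
    p: np.ndarray
    sigma: np.ndarray
    radius: np.ndarray | None = None
    aspect: float = 1.0 / 50.0
    environment: str = "pinned"
    stages: list[str] | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.times) == len(self.p) == len(self.sigma)):
            raise ValueError("times, p and sigma must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times, "p": self.p, "sigma": self.sigma}
        if self.radius is not None:
            data["radius"] = self.radius
        if self.stages is not None:
            data["stage"] = self.stages
        return pd.DataFrame(data)


def corrugation_sigma(p, gamma: float):
    """Corrugation boundary ``sigma_corr(p) = -[p (1 + 2 gamma)/2 + 2 gamma]``.

    Slope and intercept are the incompressible, small-gamma normalization of
    the dimensional threshold
    ``sigma = -dP R/2 (1 + 2 nu' gamma) - 2 sqrt(kappa E2d)/R``.
    """
    return -(np.asarray(p, dtype=float) * (1.0 + 2.0 * gamma) / 2.0 + 2.0 * gamma)


def euler_sigma(aspect: float) -> float:
    """Euler boundary ``sigma_buck = -(1/2) (2 pi R/L)^2`` (p independent)."""
    return -0.5 * (2.0 * math.pi * aspect) ** 2


def transversal_p(gamma: float) -> float:
    """Transversal boundary ``p_trans = -3 gamma^2`` (sigma independent)."""
    return -3.0 * gamma * gamma


def boundary_lines(
    gamma: float,
    aspect: float = 1.0 / 50.0,
    p_range: tuple[float, float] = (-0.02, 0.1),
    num: int = 201,
) -> pd.DataFrame:
    """Tabulate the three stability-boundary curves over a p range.

    Returns a DataFrame with columns ``p``, ``sigma_corrugation``,
    ``sigma_euler`` (constant) and ``p_transversal`` (constant).
    """
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    if not np.all(np.isfinite(p_range)) or p_range[1] <= p_range[0]:
        raise ValueError(f"invalid p_range {p_range}")
    p = np.linspace(p_range[0], p_range[1], num)
    return pd.DataFrame(
        {
            "p": p,
            "sigma_corrugation": corrugation_sigma(p, gamma),
            "sigma_euler": np.full_like(p, euler_sigma(aspect)),
            "p_transversal": np.full_like(p, transversal_p(gamma)),
        }
    )


def classify_state(point: PhasePoint, gamma: float | None = None) -> dict:
    """Classify a normalized state against the three boundaries.

    Returns ``{"label": ..., "violated": set, "margins": dict}``.  The label
    is ``"cylindrical"`` when no inequality fails; otherwise the violated
    boundary with the largest normalized margin
    ``(threshold - value)/|threshold|``.  For a pinned tube the Euler mode is
    suppressed by the surroundings: it is excluded from the label (still
    reported in ``violated`` with an ``euler_suppressed`` flag).
    """
    if gamma is None:
        gamma = point.state.gamma
    p, sigma = point.state.p, point.state.sigma

    thresholds = {
        "corrugation": float(corrugation_sigma(p, gamma)),
        "euler": euler_sigma(point.aspect),
        "transversal": transversal_p(gamma),
    }
    values = {"corrugation": sigma, "euler": sigma, "transversal": p}

    violated = {name for name in BOUNDARIES if values[name] < thresholds[name]}
    margins = {
        name: (thresholds[name] - values[name]) / abs(thresholds[name])
        for name in violated
        if thresholds[name] != 0.0
    }

    labelable = set(violated)
    flags = set()
    if point.environment == "pinned" and "euler" in labelable:
        labelable.discard("euler")
        flags.add("euler_suppressed")

    if not labelable:
        label = "cylindrical" if not violated else "cylindrical_pinned"
    else:
        label = max(labelable, key=lambda name: margins.get(name, 0.0))
    return {"label": label, "violated": violated, "margins": margins, "flags": flags}


def _crossing_time(times, excess, i):
    """Linear-in-time interpolation of a sign change between samples i, i+1."""
    e0, e1 = excess[i], excess[i + 1]
    if e1 == e0:
        return float(times[i])
    w = -e0 / (e1 - e0)
    return float(times[i] + w * (times[i + 1] - times[i]))


def stage_trajectory(traj: Trajectory, gamma: float) -> Trajectory:
    """Label a trajectory with developmental stages I-IV.

    Stage boundaries: the first crossing of the corrugation line (I -> II),
    the maximum of p (II -> III) and the re-crossing back into stability
    (III -> IV).  Crossings are detected as sign changes of
    ``sigma - sigma_corr(p)`` with linear interpolation in time; the p
    maximum is the discrete argmax.  Missing crossings truncate the stage
    set; pathological inputs (never crossing, or more than two crossings)
    are flagged in ``traj.flags`` without guessing.
    """
    if len(traj.times) < 4:
        raise ValueError("need at least 4 samples to stage a trajectory")
    excess = traj.sigma - corrugation_sigma(traj.p, gamma)
    if excess[0] < 0:
        raise ValueError("trajectory must start in the stable (cylindrical) region")

    sign_changes = [
        i for i in range(len(excess) - 1) if excess[i] >= 0 > excess[i + 1] or excess[i] < 0 <= excess[i + 1]
    ]
    flags = list(traj.flags)
    if not sign_changes:
        flags.append("no_crossing")
        stages = ["I"] * len(traj.times)
        return Trajectory(
            times=traj.times, p=traj.p, sigma=traj.sigma, radius=traj.radius,
            aspect=traj.aspect, environment=traj.environment, stages=stages, flags=flags,
        )
    if len(sign_changes) > 2:
        flags.append("multiple_crossings")

    enter = sign_changes[0]
    t_enter = _crossing_time(traj.times, excess, enter)
    exits = [i for i in sign_changes[1:] if excess[i] < 0 <= excess[i + 1]]
    t_exit = _crossing_time(traj.times, excess, exits[0]) if exits else None

    unstable = slice(enter + 1, (exits[0] + 1) if exits else len(traj.times))
    i_pmax = int(np.argmax(traj.p[unstable])) + unstable.start
    t_pmax = float(traj.times[i_pmax])

    stages = []
    for t in traj.times:
        if t <= t_enter:
            stages.append("I")
        elif t <= t_pmax:
            stages.append("II")
        elif t_exit is None or t <= t_exit:
            stages.append("III")
        else:
            stages.append("IV")
    return Trajectory(
        times=traj.times, p=traj.p, sigma=traj.sigma, radius=traj.radius,
        aspect=traj.aspect, environment=traj.environment, stages=stages, flags=flags,
    )


#: Scenario flow factors: fraction of the wild-type blood pressure.
SCENARIO_FLOW = {"wildtype": 1.0, "reduced_flow": 0.5, "no_flow": 0.02}

#: Wild-type loop amplitudes (dimensionless); chosen so the baseline enters
#: and exits the corrugated region of a gamma = 1/50 tube, emulating the
#: observed expansion (radius ~12 -> ~16 um) and recovery over 25-65 hpf.
P_MAX_WT = 0.06
SIGMA_MAX_WT = 0.08
R0_UM = 12.0
T_START_HPF = 25.0
T_END_HPF = 65.0


def scenario_trajectories(
    kind: str = "wildtype",
    seed: int = 0,
    num: int = 81,
    gamma: float = 1.0 / 50.0,
    aspect: float = 1.0 / 50.0,
    noise_sd: float = 0.0,
) -> Trajectory:
    """Synthetic developmental trajectory for a flow scenario.

    This is an explicit parametric stand-in (not a fit to measurements):
    over t in [0, 1] (mapped to 25-65 hpf) the baseline takes

        p(t)     = f * P_MAX_WT * sin(pi t)
        sigma(t) = -SIGMA_MAX_WT * sin(pi t)^2

    with flow factor ``f`` = 1 (wildtype), 0.5 (reduced_flow) or ~0
    (no_flow, silent-heart-like).  Mutants therefore trace steeper paths in
    ``(p, sigma)`` and cross the corrugation boundary earlier.  The observed
    radius emulates the ~12 -> ~16 um dilation.  Optional Gaussian jitter on
    sigma (std ``noise_sd``) uses the explicit seed; with the default
    ``noise_sd = 0`` the output is deterministic.
    """
    if kind not in SCENARIO_FLOW:
        raise ValueError(f"kind must be one of {sorted(SCENARIO_FLOW)}, got {kind!r}")
    t = np.linspace(0.0, 1.0, num)
    s = np.sin(math.pi * t)
    flow = SCENARIO_FLOW[kind]
    p = flow * P_MAX_WT * s
    sigma = -SIGMA_MAX_WT * s * s
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma = sigma + rng.normal(0.0, noise_sd, size=sigma.shape)
    radius = R0_UM * (1.0 + flow * s / 3.0)
    times = T_START_HPF + (T_END_HPF - T_START_HPF) * t
    return Trajectory(
        times=times, p=p, sigma=sigma, radius=radius, aspect=aspect,
        environment="pinned",
    )
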