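"""Lotka-Volterra dynamics of radiation-sensitive and radiation-resistant tumour
cells co-cultured with natural killer (NK) cells.

The state is (S, R, N): radiation-sensitive tumour cells, radiation-resistant
tumour cells, and NK cells, all in units of 10^5 cells.  Time is measured in
hours and every rate is per hour.  The two tumour populations follow logistic
growth with inter-type competition (coefficients ``alpha_SR`` — the effect of R
on S — and ``alpha_RS``) and are killed by NK cells at per-capita rates
``lambda_SN`` and ``lambda_RN``; an excess of ``lambda_RN`` over ``lambda_SN``
means NK killing preferentially removes the radiation-resistant type, the
signature of an evolutionary double bind.  NK cells grow logistically with no
feedback from the tumour populations, so their trajectory has a closed form::

    dS/dt = r_S * S * (1 - (S + alpha_SR * R) / K_S) - lambda_SN * S * N
    dR/dt = r_R * R * (1 - (R + alpha_RS * S) / K_R) - lambda_RN * R * N
    dN/dt = r_N * N * (1 - N / K_N)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "RATE_BOUNDS",
    "CAPACITY_BOUNDS",
    "INTERACTION_BOUNDS",
    "PARAM_NAMES",
    "Condition",
    "ParameterSet",
    "PopulationState",
    "Trajectory",
    "IntegrationError",
    "lv_rates",
    "logistic_closed_form",
    "simulate",
    "simulate_wells",
    "rt_growth_modifier",
    "delta_from_rates",
    "validate_for_condition",
]

#: Growth rates r_S, r_R, r_N live in [0, 1] per hour.
RATE_BOUNDS = (0.0, 1.0)
#: Carrying capacities in units of 10^5 cells; (0, 10] covers 0 to 10^6 cells.
CAPACITY_BOUNDS = (0.0, 10.0)
#: Competition coefficients and NK kill rates.
INTERACTION_BOUNDS = (-15.0, 15.0)

PARAM_NAMES = (
    "r_S", "r_R", "r_N",
    "K_S", "K_R", "K_N",
    "alpha_SR", "alpha_RS",
    "lambda_SN", "lambda_RN",
)

_RATE_NAMES = ("r_S", "r_R", "r_N")
_CAPACITY_NAMES = ("K_S", "K_R", "K_N")
_INTERACTION_NAMES = ("alpha_SR", "alpha_RS", "lambda_SN", "lambda_RN")


class Condition(str, Enum):
    """Treatment arm of a co-culture well."""

    UT = "UT"        #: untreated
    RT = "RT"        #: radiation only
    NK = "NK"        #: NK cells only
    RTNK = "RTNK"    #: radiation followed by NK cells

    @property
    def has_nk(self) -> bool:
        return self in (Condition.NK, Condition.RTNK)


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a trajectory."""


@dataclass(frozen=True)
class ParameterSet:
    """Full-model parameters with per-parameter fixed/free flags.

    ``fixed`` names the parameters held constant during fitting; it has no
    effect on the dynamics themselves.
    """

    r_S: float
    r_R: float
    r_N: float
    K_S: float
    K_R: float
    K_N: float
    alpha_SR: float
    alpha_RS: float
    lambda_SN: float
    lambda_RN: float
    fixed: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in _RATE_NAMES:
            v = getattr(self, name)
            if not (RATE_BOUNDS[0] <= v <= RATE_BOUNDS[1]):
                raise ValueError(f"{name}={v} outside rate bounds {RATE_BOUNDS}")
        for name in _CAPACITY_NAMES:
            v = getattr(self, name)
            if not (CAPACITY_BOUNDS[0] < v <= CAPACITY_BOUNDS[1]):
                raise ValueError(
                    f"{name}={v} outside capacity bounds (0, {CAPACITY_BOUNDS[1]}]"
                )
        for name in _INTERACTION_NAMES:
            v = getattr(self, name)
            if not (INTERACTION_BOUNDS[0] <= v <= INTERACTION_BOUNDS[1]):
                raise ValueError(
                    f"{name}={v} outside interaction bounds {INTERACTION_BOUNDS}"
                )
        unknown = set(self.fixed) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown fixed parameter names: {sorted(unknown)}")
        object.__setattr__(self, "fixed", frozenset(self.fixed))

    def with_values(self, **updates: float) -> "ParameterSet":
        return replace(self, **updates)

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in PARAM_NAMES}
        d["fixed"] = sorted(self.fixed)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        kwargs = {name: float(d[name]) for name in PARAM_NAMES}
        return cls(**kwargs, fixed=frozenset(d.get("fixed", ())))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ParameterSet":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class PopulationState:
    """Abundances (S, R, N) in units of 10^5 cells; all nonnegative."""

    S: float
    R: float
    N: float = 0.0

    def __post_init__(self) -> None:
        for name in ("S", "R", "N"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative abundance {name}={getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.R, self.N], dtype=float)


@dataclass
class Trajectory:
    """Abundances on a strictly increasing time grid (hours)."""

    times: np.ndarray
    S: np.ndarray
    R: np.ndarray
    N: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("S", "R", "N"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} has shape {arr.shape}, times {self.times.shape}")
            if np.any(arr < 0):
                raise ValueError(f"negative abundances in channel {name}")
            setattr(self, name, arr)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def states(self) -> list[PopulationState]:
        return [PopulationState(s, r, n) for s, r, n in zip(self.S, self.R, self.N)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.times, "S": self.S, "R": self.R, "N": self.N}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        missing = {"time_h", "S", "R", "N"} - set(df.columns)
        if missing:
            raise ValueError(f"trajectory CSV missing columns {sorted(missing)}")
        return cls(df["time_h"].to_numpy(), df["S"].to_numpy(),
                   df["R"].to_numpy(), df["N"].to_numpy())


def validate_for_condition(params: ParameterSet, condition: Condition) -> None:
    """No-NK arms (UT, RT) must carry zero NK kill rates and zero NK growth."""
    if not condition.has_nk:
        if params.lambda_SN != 0 or params.lambda_RN != 0 or params.r_N != 0:
            raise ValueError(
                f"condition {condition.value} requires lambda_SN = lambda_RN = r_N = 0"
            )


def lv_rates(state: PopulationState, params: ParameterSet) -> tuple[float, float, float]:
    """Instantaneous rates (dS/dt, dR/dt, dN/dt) at ``state``."""
    S, R, N = state.S, state.R, state.N
    dS = params.r_S * S * (1.0 - (S + params.alpha_SR * R) / params.K_S) \
        - params.lambda_SN * S * N
    dR = params.r_R * R * (1.0 - (R + params.alpha_RS * S) / params.K_R) \
        - params.lambda_RN * R * N
    dN = params.r_N * N * (1.0 - N / params.K_N)
    return dS, dR, dN


def logistic_closed_form(r: float, K: float, N0: float, t):
    """Logistic growth N(t) = K N0 e^{rt} / (K + N0 (e^{rt} - 1)).

    Evaluated in the overflow-safe form K N0 / (N0 + (K - N0) e^{-rt});
    ``t`` may be a scalar or array (hours).
    """
    if K <= 0:
        raise ValueError(f"carrying capacity must be positive, got {K}")
    if N0 < 0:
        raise ValueError(f"initial abundance must be nonnegative, got {N0}")
    t = np.asarray(t, dtype=float)
    out = K * N0 / (N0 + (K - N0) * np.exp(-r * t))
    return out if out.ndim else float(out)


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D grid with at least two points")
    if times[0] != 0:
        raise ValueError("time grid must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


def simulate(
    params: ParameterSet,
    init: PopulationState,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the full three-species system on ``times``.

    Uses an adaptive explicit Runge-Kutta scheme; values driven marginally
    negative by solver error (below ``atol``) are clipped to zero.
    """
    times = _check_times(times)

    def rhs(t, y):
        S, R, N = y
        return [
            params.r_S * S * (1.0 - (S + params.alpha_SR * R) / params.K_S)
            - params.lambda_SN * S * N,
            params.r_R * R * (1.0 - (R + params.alpha_RS * S) / params.K_R)
            - params.lambda_RN * R * N,
            params.r_N * N * (1.0 - N / params.K_N),
        ]

    sol = solve_ivp(
        rhs, (times[0], times[-1]), init.as_array(),
        t_eval=times, method="RK45", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    y = np.clip(sol.y, 0.0, None)
    return Trajectory(times, y[0], y[1], y[2])


def simulate_wells(
    params: ParameterSet,
    s0: Sequence[float],
    r0: Sequence[float],
    n0: float,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate many wells sharing one parameter set in a single solve.

    Because NK cells receive no feedback from the tumour populations their
    trajectory is the logistic closed form; only (S, R) are integrated, stacked
    across wells.  Returns arrays ``S``, ``R`` of shape (n_wells, n_times) and
    ``N`` of shape (n_times,).
    """
    times = _check_times(times)
    s0 = np.asarray(s0, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    if s0.shape != r0.shape or s0.ndim != 1:
        raise ValueError("s0 and r0 must be 1-D arrays of equal length")
    if np.any(s0 < 0) or np.any(r0 < 0) or n0 < 0:
        raise ValueError("initial abundances must be nonnegative")
    n_wells = s0.size
    r_S, r_R = params.r_S, params.r_R
    K_S, K_R = params.K_S, params.K_R
    a_SR, a_RS = params.alpha_SR, params.alpha_RS
    l_SN, l_RN = params.lambda_SN, params.lambda_RN
    r_N, K_N = params.r_N, params.K_N

    def rhs(t, y):
        S = y[:n_wells]
        R = y[n_wells:]
        N = K_N * n0 / (n0 + (K_N - n0) * np.exp(-r_N * t)) if n0 > 0 else 0.0
        dS = r_S * S * (1.0 - (S + a_SR * R) / K_S) - l_SN * S * N
        dR = r_R * R * (1.0 - (R + a_RS * S) / K_R) - l_RN * R * N
        return np.concatenate([dS, dR])

    y0 = np.concatenate([s0, r0])
    sol = solve_ivp(
        rhs, (times[0], times[-1]), y0,
        t_eval=times, method="RK45", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    y = np.clip(sol.y, 0.0, None)
    N = logistic_closed_form(r_N, K_N, n0, times)
    N = np.broadcast_to(np.asarray(N, dtype=float), times.shape).copy()
    return y[:n_wells], y[n_wells:], N


def rt_growth_modifier(r_S: float, delta: float) -> float:
    """Growth rate of sensitive cells under radiation: r_S' = r_S (1 - delta)."""
    return r_S * (1.0 - delta)


def delta_from_rates(r_S: float, r_S_treated: float) -> float:
    """Radiation effect inferred from rates: delta = 1 - r_S' / r_S."""
    if r_S == 0:
        raise ValueError("untreated growth rate must be nonzero")
    return 1.0 - r_S_treated / r_S
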