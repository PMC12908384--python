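"""Staged bounded least-squares inference of the co-culture model.

A "fitting batch" is one replicate: the S and R counts for all seven seeding
fractions, fit to the model simultaneously.  Fitting is staged to deal with
the identifiability of carrying capacities under treatment:

* stage 1 — the untreated arm is fit per replicate with r_S, r_R, K_S, K_R,
  alpha_SR, alpha_RS free (NK kill rates and NK growth zeroed, K_N fixed at 1);
* stage 2 — every treated arm is fit per replicate with K_S and K_R fixed at
  the untreated across-replicate means.  Radiation-only frees growth rates and
  competition coefficients; NK-containing arms additionally free r_N,
  lambda_SN, and lambda_RN.

Growth rates are bounded in [0, 1] per hour, competition and kill coefficients
in [-15, 15], carrying capacities in (0, 10] (units of 10^5 cells).  Each fit
runs a trust-region-reflective bounded least squares from a data-driven
heuristic start (log-linear early slope of the monoculture wells for rates,
their plateau for capacities) plus multiplicatively jittered restarts; the
best of the multistart is reported.  Residuals are unweighted with both
fluorescence channels weighted equally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import json
import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import linregress

from .model_core import (
    CAPACITY_BOUNDS,
    INTERACTION_BOUNDS,
    PARAM_NAMES,
    RATE_BOUNDS,
    Condition,
    ParameterSet,
    simulate_wells,
)
from .synthetic_data import ExperimentDesign, TimeSeriesDataset, default_design

__all__ = [
    "FitConfig",
    "FitResult",
    "FitSummary",
    "FitError",
    "StagingError",
    "STAGE_FREE_PARAMS",
    "residuals",
    "fit_replicate",
    "staged_fit",
    "summarize",
    "holdout_validate",
]

logger = logging.getLogger(__name__)

#: Parameters freed at each stage, per treatment arm.
STAGE_FREE_PARAMS = {
    Condition.UT: ("r_S", "r_R", "K_S", "K_R", "alpha_SR", "alpha_RS"),
    Condition.RT: ("r_S", "r_R", "alpha_SR", "alpha_RS"),
    Condition.NK: ("r_S", "r_R", "r_N", "alpha_SR", "alpha_RS",
                   "lambda_SN", "lambda_RN"),
    Condition.RTNK: ("r_S", "r_R", "r_N", "alpha_SR", "alpha_RS",
                     "lambda_SN", "lambda_RN"),
}

_RATE_NAMES = {"r_S", "r_R", "r_N"}
_CAPACITY_NAMES = {"K_S", "K_R", "K_N"}


class FitError(RuntimeError):
    """No multistart converged to a usable optimum."""


class StagingError(ValueError):
    """The dataset cannot support the staged procedure (e.g. no untreated arm)."""


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings shared across stages."""

    rate_bounds: tuple = RATE_BOUNDS
    interaction_bounds: tuple = INTERACTION_BOUNDS
    capacity_bounds: tuple = (1e-3, CAPACITY_BOUNDS[1])
    n_multistart: int = 8
    start_jitter: tuple = (0.5, 2.0)
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int | None = None
    solver_rtol: float = 1e-8
    solver_atol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rate_bounds", "interaction_bounds", "capacity_bounds",
                     "start_jitter"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be well-ordered, got ({lo}, {hi})")
        if self.n_multistart < 1:
            raise ValueError("n_multistart must be at least 1")

    def bounds_for(self, name: str) -> tuple[float, float]:
        if name in _RATE_NAMES:
            return self.rate_bounds
        if name in _CAPACITY_NAMES:
            return self.capacity_bounds
        return self.interaction_bounds


@dataclass
class FitResult:
    """One replicate's bounded least-squares estimate."""

    condition: Condition
    replicate: int
    params: ParameterSet
    loss: float                      # sum of squared residuals
    converged: bool
    at_bounds: dict = field(default_factory=dict)
    multistart_losses: tuple = ()

    def to_dict(self) -> dict:
        return {
            "condition": self.condition.value,
            "replicate": int(self.replicate),
            "params": self.params.to_dict(),
            "loss": float(self.loss),
            "converged": bool(self.converged),
            "at_bounds": {k: bool(v) for k, v in self.at_bounds.items()},
            "multistart_losses": [float(v) for v in self.multistart_losses],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            condition=Condition(d["condition"]),
            replicate=int(d["replicate"]),
            params=ParameterSet.from_dict(d["params"]),
            loss=float(d["loss"]),
            converged=bool(d["converged"]),
            at_bounds=dict(d.get("at_bounds", {})),
            multistart_losses=tuple(d.get("multistart_losses", ())),
        )


@dataclass
class FitSummary:
    """Across-replicate mean and standard error per parameter, per arm.

    ``table`` has one row per (condition, parameter) with columns mean, sem,
    n, fixed; ``replicate_values`` keeps the per-replicate estimates so that
    downstream diagnostics can summarise derived quantities per replicate
    instead of from the means alone.
    """

    table: pd.DataFrame
    replicate_values: dict = field(default_factory=dict)

    def value(self, condition: Condition | str, parameter: str,
              stat: str = "mean") -> float:
        cond = Condition(condition).value
        row = self.table[(self.table.condition == cond)
                         & (self.table.parameter == parameter)]
        if row.empty:
            raise KeyError(f"no summary entry for ({cond}, {parameter})")
        return float(row.iloc[0][stat])

    @property
    def conditions(self) -> list[Condition]:
        return [Condition(c) for c in self.table.condition.unique()]

    def mean_params(self, condition: Condition | str) -> ParameterSet:
        cond = Condition(condition)
        sub = self.table[self.table.condition == cond.value]
        values = {r.parameter: r["mean"] for _, r in sub.iterrows()}
        fixed = frozenset(r.parameter for _, r in sub.iterrows() if r.fixed)
        return ParameterSet(**{n: float(values[n]) for n in PARAM_NAMES}, fixed=fixed)

    def to_frame(self) -> pd.DataFrame:
        """Wide layout mirroring the published table: one row per arm."""
        rows = {}
        for cond in self.table.condition.unique():
            sub = self.table[self.table.condition == cond]
            row = {}
            for _, r in sub.iterrows():
                if r["fixed"]:
                    row[r["parameter"]] = f"{r['mean']:g} (fixed)"
                else:
                    row[r["parameter"]] = (
                        f"{r['mean']:.3g} ({r['mean'] - r['sem']:.3g} to "
                        f"{r['mean'] + r['sem']:.3g})"
                    )
            rows[cond] = row
        return pd.DataFrame.from_dict(rows, orient="index")[list(PARAM_NAMES)]

    def to_json(self, path=None) -> str:
        doc = {
            "summary": self.table.to_dict(orient="records"),
            "replicate_values": self.replicate_values,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            from pathlib import Path
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "FitSummary":
        from pathlib import Path
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        return cls(
            table=pd.DataFrame(doc["summary"]),
            replicate_values=doc.get("replicate_values", {}),
        )


def _replicate_arrays(
    replicate_data: TimeSeriesDataset,
    condition: Condition,
    design: ExperimentDesign,
):
    """Pivot one replicate's slice into aligned model/observation arrays."""
    df = replicate_data.data
    df = df[df.condition == condition.value]
    if df.empty:
        raise ValueError(f"slice contains no records for {condition.value}")
    reps = df.replicate.unique()
    if len(reps) != 1:
        raise ValueError(f"slice must cover exactly one replicate, got {list(reps)}")
    fractions = np.sort(df.f.unique())
    times = np.sort(df.time_h.unique())
    if times[0] != 0:
        raise ValueError("time grid must start at 0")
    obs_S = np.empty((fractions.size, times.size))
    obs_R = np.empty_like(obs_S)
    for i, f in enumerate(fractions):
        well = df[df.f == f].sort_values("time_h")
        if len(well) != times.size or not np.array_equal(well.time_h.to_numpy(), times):
            raise ValueError(f"time grid mismatch for fraction f={f}")
        obs_S[i] = well.count_S.to_numpy()
        obs_R[i] = well.count_R.to_numpy()
    inits = [design.initial_state(f, condition) for f in fractions]
    s0 = np.array([i[0] for i in inits])
    r0 = np.array([i[1] for i in inits])
    n0 = inits[0][2]
    return fractions, times, obs_S, obs_R, s0, r0, n0


def residuals(
    params: ParameterSet,
    replicate_data: TimeSeriesDataset,
    design: ExperimentDesign | None = None,
    condition: Condition | str | None = None,
) -> np.ndarray:
    """Model-minus-observation residuals for one replicate.

    Concatenated over all fractions and both observed channels; initial
    conditions are derived from the design and each well's seeding fraction.
    """
    design = design or default_design()
    if condition is None:
        conds = replicate_data.conditions
        if len(conds) != 1:
            raise ValueError("slice covers multiple conditions; pass `condition`")
        condition = conds[0]
    condition = Condition(condition)
    _, times, obs_S, obs_R, s0, r0, n0 = _replicate_arrays(
        replicate_data, condition, design
    )
    S, R, _ = simulate_wells(params, s0, r0, n0, times)
    return np.concatenate([(S - obs_S).ravel(), (R - obs_R).ravel()])


def _heuristic_start(
    name: str,
    fractions: np.ndarray,
    times: np.ndarray,
    obs_S: np.ndarray,
    obs_R: np.ndarray,
    config: FitConfig,
) -> float:
    """Data-driven initial guess for one free parameter.

    Monoculture wells (f = 0 pure sensitive, f = 1 pure resistant) give a
    log-linear early-growth slope for the rates and the observed plateau for
    the carrying capacities; interaction terms start at generic magnitudes.
    """
    def early_slope(y: np.ndarray) -> float:
        k = min(6, y.size)
        mask = y[:k] > 0
        if mask.sum() < 2:
            return 0.03
        return float(linregress(times[:k][mask], np.log(y[:k][mask])).slope)

    def channel(which: str) -> np.ndarray:
        # the purest available well for the requested channel
        if which == "S":
            idx = int(np.argmin(fractions))
            return obs_S[idx]
        idx = int(np.argmax(fractions))
        return obs_R[idx]

    if name == "r_S":
        guess = early_slope(channel("S"))
    elif name == "r_R":
        guess = early_slope(channel("R"))
    elif name == "r_N":
        guess = 0.02
    elif name == "K_S":
        guess = float(np.max(channel("S")))
    elif name == "K_R":
        guess = float(np.max(channel("R")))
    elif name == "K_N":
        guess = 1.0
    elif name in ("alpha_SR", "alpha_RS"):
        guess = 1.0
    else:  # lambda_SN, lambda_RN
        guess = 0.05
    lo, hi = config.bounds_for(name)
    margin = 1e-6 * (hi - lo)
    return float(np.clip(guess, lo + margin, hi - margin))


def fit_replicate(
    replicate_data: TimeSeriesDataset,
    condition: Condition | str,
    config: FitConfig | None = None,
    fixed: Mapping[str, float] | None = None,
    design: ExperimentDesign | None = None,
    replicate: int | None = None,
) -> FitResult:
    """Bounded least-squares fit of one replicate's free parameters.

    ``fixed`` must specify every parameter the staging rules freeze for this
    arm; all remaining parameters are free.  The best of ``n_multistart``
    jittered starts is returned; the run is deterministic given
    ``config.seed``.
    """
    config = config or FitConfig()
    condition = Condition(condition)
    design = design or default_design()
    if replicate is not None:
        replicate_data = replicate_data.subset(replicate=replicate)
    fixed = dict(fixed) if fixed else {}
    free = tuple(n for n in PARAM_NAMES if n not in fixed)
    missing = set(STAGE_FREE_PARAMS[condition]) ^ set(free)
    if missing:
        raise ValueError(
            f"fixed parameters for {condition.value} leave free set {sorted(free)}; "
            f"staging expects {sorted(STAGE_FREE_PARAMS[condition])}"
        )

    fractions, times, obs_S, obs_R, s0, r0, n0 = _replicate_arrays(
        replicate_data, condition, design
    )
    rep_id = int(replicate_data.data.replicate.iloc[0])

    lb = np.array([config.bounds_for(n)[0] for n in free])
    ub = np.array([config.bounds_for(n)[1] for n in free])
    base = dict(fixed)

    def resid_vec(x: np.ndarray) -> np.ndarray:
        values = base | dict(zip(free, x))
        p = ParameterSet(**values, fixed=frozenset(fixed))
        S, R, _ = simulate_wells(
            p, s0, r0, n0, times,
            rtol=config.solver_rtol, atol=config.solver_atol,
        )
        return np.concatenate([(S - obs_S).ravel(), (R - obs_R).ravel()])

    x_heur = np.array([
        _heuristic_start(n, fractions, times, obs_S, obs_R, config) for n in free
    ])
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(config.seed), list(Condition).index(condition), rep_id]
        )
    )
    starts = [x_heur]
    lo_j, hi_j = config.start_jitter
    for _ in range(config.n_multistart - 1):
        jitter = np.exp(rng.uniform(np.log(lo_j), np.log(hi_j), size=x_heur.size))
        starts.append(np.clip(x_heur * jitter, lb + 1e-9, ub - 1e-9))

    best = None
    losses = []
    for x0 in starts:
        try:
            res = least_squares(
                resid_vec, x0, bounds=(lb, ub), method="trf",
                ftol=config.ftol, xtol=config.xtol, gtol=config.gtol,
                max_nfev=config.max_nfev, x_scale="jac",
            )
        except Exception as exc:  # noqa: BLE001 - one start failing is tolerable
            logger.debug("multistart failed for %s rep %s: %s",
                         condition.value, rep_id, exc)
            continue
        loss = float(2.0 * res.cost)
        losses.append(loss)
        if best is None or loss < best[0]:
            best = (loss, res)
    if best is None:
        raise FitError(
            f"all {config.n_multistart} starts failed for {condition.value} "
            f"replicate {rep_id}"
        )
    loss, res = best
    values = base | dict(zip(free, res.x))
    params = ParameterSet(**values, fixed=frozenset(fixed))
    tol = 1e-8
    at_bounds = {
        n: bool(abs(x - lo) < tol or abs(x - hi) < tol)
        for n, x, lo, hi in zip(free, res.x, lb, ub)
    }
    return FitResult(
        condition=condition,
        replicate=rep_id,
        params=params,
        loss=loss,
        converged=bool(res.status > 0),
        at_bounds=at_bounds,
        multistart_losses=tuple(losses),
    )


def _fixed_for(condition: Condition, K_S: float | None = None,
               K_R: float | None = None) -> dict:
    """Staging-frozen parameters for one arm."""
    fixed: dict[str, float] = {"K_N": 1.0}
    if not condition.has_nk:
        fixed.update({"lambda_SN": 0.0, "lambda_RN": 0.0, "r_N": 0.0})
    if condition is not Condition.UT:
        if K_S is None or K_R is None:
            raise StagingError("treated arms need untreated carrying-capacity means")
        fixed.update({"K_S": K_S, "K_R": K_R})
    return fixed


def staged_fit(
    dataset: TimeSeriesDataset,
    config: FitConfig | None = None,
    design: ExperimentDesign | None = None,
) -> dict:
    """Run the two-stage procedure over every arm present in ``dataset``.

    Returns a mapping Condition -> list of per-replicate :class:`FitResult`.
    """
    config = config or FitConfig()
    design = design or _design_from_provenance(dataset)
    conditions = dataset.conditions
    if Condition.UT not in conditions:
        raise StagingError("staged fitting requires the untreated arm")

    results: dict[Condition, list[FitResult]] = {}
    ut_fixed = _fixed_for(Condition.UT)
    ut_results = [
        fit_replicate(dataset.subset(Condition.UT, rep), Condition.UT,
                      config, ut_fixed, design)
        for rep in dataset.subset(Condition.UT).replicates
    ]
    results[Condition.UT] = ut_results
    converged = [r for r in ut_results if r.converged]
    if not converged:
        raise FitError("no untreated replicate converged; cannot fix capacities")
    K_S = float(np.mean([r.params.K_S for r in converged]))
    K_R = float(np.mean([r.params.K_R for r in converged]))
    logger.info("stage 1 complete: K_S=%.4g, K_R=%.4g from %d replicates",
                K_S, K_R, len(converged))

    for cond in (Condition.RT, Condition.NK, Condition.RTNK):
        if cond not in conditions:
            continue
        fixed = _fixed_for(cond, K_S, K_R)
        results[cond] = [
            fit_replicate(dataset.subset(cond, rep), cond, config, fixed, design)
            for rep in dataset.subset(cond).replicates
        ]
    return results


def _design_from_provenance(dataset: TimeSeriesDataset) -> ExperimentDesign:
    d = dataset.provenance.get("design")
    return ExperimentDesign.from_dict(d) if d else default_design()


def summarize(results: Mapping[Condition, Sequence[FitResult]]) -> FitSummary:
    """Across-replicate mean and SEM (sample sd / sqrt(n)) per parameter.

    Only converged replicates enter the summary; fixed parameters are reported
    with zero SEM and a fixed flag.
    """
    if not results:
        raise ValueError("empty results: nothing to summarize")
    rows = []
    replicate_values: dict[str, dict[str, list[float]]] = {}
    for cond, fits in results.items():
        cond = Condition(cond)
        kept = [r for r in fits if r.converged]
        dropped = len(fits) - len(kept)
        if dropped:
            logger.warning("%s: dropping %d nonconverged replicate(s) from summary",
                           cond.value, dropped)
        if not kept:
            raise ValueError(f"no converged replicates for {cond.value}")
        fixed_names = kept[0].params.fixed
        replicate_values[cond.value] = {
            name: [float(getattr(r.params, name)) for r in kept]
            for name in PARAM_NAMES
        }
        for name in PARAM_NAMES:
            vals = np.array(replicate_values[cond.value][name])
            is_fixed = name in fixed_names
            sem = 0.0
            if not is_fixed and vals.size > 1:
                sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size))
            rows.append({
                "condition": cond.value,
                "parameter": name,
                "mean": float(np.mean(vals)),
                "sem": sem,
                "n": int(vals.size),
                "fixed": bool(is_fixed),
            })
    return FitSummary(table=pd.DataFrame(rows), replicate_values=replicate_values)


def holdout_validate(
    dataset: TimeSeriesDataset,
    split: float | Iterable[int],
    config: FitConfig | None = None,
    design: ExperimentDesign | None = None,
) -> dict:
    """Train/validation split over replicates.

    ``split`` is either the fraction of replicates used for training (the
    first ``round(split * n)`` replicate ids) or an explicit set of training
    replicate ids.  The staged fit runs on the training replicates; the
    across-replicate mean parameters are then scored (sum of squared
    residuals) on each held-out replicate.
    """
    config = config or FitConfig()
    design = design or _design_from_provenance(dataset)
    reps = dataset.replicates
    if isinstance(split, float):
        if not 0.0 < split < 1.0:
            raise ValueError("fractional split must lie strictly in (0, 1)")
        n_train = int(round(split * len(reps)))
        train_ids = reps[:n_train]
    else:
        train_ids = sorted(set(int(r) for r in split))
    val_ids = [r for r in reps if r not in train_ids]
    if not train_ids or not val_ids:
        raise ValueError(
            f"degenerate split: {len(train_ids)} training / {len(val_ids)} "
            "validation replicates"
        )

    train_mask = dataset.data.replicate.isin(train_ids)
    train_ds = TimeSeriesDataset(dataset.data[train_mask].copy(),
                                 provenance=dataset.provenance)
    results = staged_fit(train_ds, config, design)
    summary = summarize(results)

    report = {}
    for cond, fits in results.items():
        mean_params = summary.mean_params(cond)
        val_losses = []
        for rep in val_ids:
            sl = dataset.subset(cond, rep)
            r = residuals(mean_params, sl, design, cond)
            val_losses.append(float(np.sum(r ** 2)))
        report[cond.value] = {
            "train_loss": float(np.mean([r.loss for r in fits if r.converged])),
            "validation_loss": float(np.mean(val_losses)),
            "n_train": len(train_ids),
            "n_validation": len(val_ids),
        }
    return report
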