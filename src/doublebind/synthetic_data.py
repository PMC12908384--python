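"""In-silico replicates of the co-culture competition experiment.

Emulates the live-imaging design used to parameterise the model: wells seeded
with 2000 tumour cells at seven initial resistant fractions
f = [0, 0.1, 0.25, 0.5, 0.75, 0.9, 1], imaged every 6 hours for 150 hours,
12 replicates, four treatment arms, NK cells added at a 5:1 effector:target
ratio in NK-containing arms.  Observed counts are the simulated S and R
channels (the two fluorescent labels); N is never observed.  Counts are stored
in units of 10^5 cells, matching the fitted carrying-capacity scale.

Observation noise defaults to multiplicative lognormal with a 10% coefficient
of variation, applied independently per observation: imaging counts carry
roughly proportional error and must stay nonnegative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model_core import Condition, ParameterSet, simulate_wells, validate_for_condition

__all__ = [
    "CELL_UNIT",
    "ExperimentDesign",
    "NoiseModel",
    "TimeSeriesDataset",
    "default_design",
    "generate_dataset",
    "write_csv",
    "read_csv",
]

#: Abundance unit: counts are stored as multiples of 10^5 cells.
CELL_UNIT = 1e5

_CSV_COLUMNS = ["condition", "replicate", "f", "time_h", "count_S", "count_R"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Co-culture plate layout and sampling schedule."""

    fractions: tuple = (0.0, 0.1, 0.25, 0.50, 0.75, 0.9, 1.0)
    n_replicates: int = 12
    sample_interval: float = 6.0    # hours
    horizon: float = 150.0          # hours
    tumor_seed: float = 2000.0      # cells per well
    et_ratio: float = 5.0           # NK effector:target ratio
    conditions: tuple = (Condition.UT, Condition.RT, Condition.NK, Condition.RTNK)

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        if any(not 0.0 <= f <= 1.0 for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if list(fr) != sorted(set(fr)):
            raise ValueError("fractions must be sorted and unique")
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(
            self, "conditions", tuple(Condition(c) for c in self.conditions)
        )
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.horizon < self.sample_interval:
            raise ValueError("horizon must cover at least one sampling interval")
        if self.tumor_seed <= 0:
            raise ValueError("tumor_seed must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")

    @property
    def times(self) -> np.ndarray:
        n = int(np.floor(self.horizon / self.sample_interval)) + 1
        return self.sample_interval * np.arange(n, dtype=float)

    def initial_state(self, f: float, condition: Condition) -> tuple[float, float, float]:
        """Seeding abundances (S0, R0, N0) in units of 10^5 cells."""
        s0 = self.tumor_seed * (1.0 - f) / CELL_UNIT
        r0 = self.tumor_seed * f / CELL_UNIT
        n0 = self.et_ratio * self.tumor_seed / CELL_UNIT if Condition(condition).has_nk else 0.0
        return s0, r0, n0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fractions"] = list(self.fractions)
        d["conditions"] = [c.value for c in self.conditions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        d = dict(d)
        d["fractions"] = tuple(d.get("fractions", cls.fractions))
        d["conditions"] = tuple(Condition(c) for c in d.get("conditions", cls.conditions))
        return cls(**d)


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise law applied to simulated counts.

    ``lognormal_multiplicative`` multiplies each observation by a unit-mean
    lognormal factor with coefficient of variation ``cv``; ``none`` returns the
    simulation exactly.
    """

    law: str = "lognormal_multiplicative"
    cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.law not in ("none", "lognormal_multiplicative"):
            raise ValueError(f"unknown noise law {self.law!r}")
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")

    def apply(self, counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.law == "none" or self.cv == 0:
            return np.asarray(counts, dtype=float)
        sigma2 = np.log1p(self.cv ** 2)          # unit mean, CV exactly cv
        factors = rng.lognormal(
            mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=np.shape(counts)
        )
        return np.asarray(counts, dtype=float) * factors

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TimeSeriesDataset:
    """Tidy per-well counts plus provenance.

    ``data`` has columns condition, replicate, f, time_h, count_S, count_R with
    counts in units of 10^5 cells; ``provenance`` records the generating truth,
    design, and noise settings when the dataset is synthetic.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(_CSV_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        self.data = self.data[_CSV_COLUMNS].reset_index(drop=True)
        bad = self.data[(self.data.count_S < 0) | (self.data.count_R < 0)]
        if len(bad):
            raise ValueError(f"negative counts at row {bad.index[0]}")
        grids = {
            key: tuple(grp.time_h.to_numpy())
            for key, grp in self.data.groupby(["condition", "replicate", "f"], sort=False)
        }
        if len(set(grids.values())) > 1:
            raise ValueError("ragged time grids: wells do not share a sampling grid")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def conditions(self) -> list[Condition]:
        return [Condition(c) for c in self.data.condition.unique()]

    @property
    def replicates(self) -> list[int]:
        return sorted(self.data.replicate.unique())

    def subset(
        self,
        condition: Condition | str | None = None,
        replicate: int | None = None,
    ) -> "TimeSeriesDataset":
        df = self.data
        if condition is not None:
            df = df[df.condition == Condition(condition).value]
        if replicate is not None:
            df = df[df.replicate == replicate]
        if df.empty:
            raise ValueError(
                f"no records for condition={condition}, replicate={replicate}"
            )
        return TimeSeriesDataset(df.copy(), provenance=self.provenance)


def default_design() -> ExperimentDesign:
    """The co-culture layout used throughout: seven seeding fractions,
    12 replicates, 6-hour sampling over 150 hours, 2000 tumour cells per well,
    5:1 NK effector:target ratio."""
    return ExperimentDesign()


def generate_dataset(
    truth: Mapping[Condition, ParameterSet],
    design: ExperimentDesign | None = None,
    noise: NoiseModel | None = None,
) -> TimeSeriesDataset:
    """Simulate the full plate under ``truth`` and perturb per ``noise``.

    The noiseless trajectories are shared across replicates (one batched solve
    per condition); replicates differ only through observation noise.
    """
    design = design or default_design()
    noise = noise or NoiseModel()
    truth = {Condition(c): p for c, p in truth.items()}
    for cond in design.conditions:
        if cond not in truth:
            raise ValueError(f"truth has no ParameterSet for condition {cond.value}")
        validate_for_condition(truth[cond], cond)

    times = design.times
    rng = np.random.default_rng(noise.seed)
    frames = []
    for cond in design.conditions:
        inits = [design.initial_state(f, cond) for f in design.fractions]
        s0 = [i[0] for i in inits]
        r0 = [i[1] for i in inits]
        n0 = inits[0][2]
        S, R, _ = simulate_wells(truth[cond], s0, r0, n0, times)
        for rep in range(1, design.n_replicates + 1):
            obs_S = noise.apply(S, rng)
            obs_R = noise.apply(R, rng)
            for i, f in enumerate(design.fractions):
                frames.append(pd.DataFrame({
                    "condition": cond.value,
                    "replicate": rep,
                    "f": f,
                    "time_h": times,
                    "count_S": obs_S[i],
                    "count_R": obs_R[i],
                }))
    data = pd.concat(frames, ignore_index=True)
    provenance = {
        "truth": {c.value: p.to_dict() for c, p in truth.items()},
        "design": design.to_dict(),
        "noise": noise.to_dict(),
    }
    return TimeSeriesDataset(data, provenance=provenance)


def write_csv(dataset: TimeSeriesDataset, path: str | Path) -> None:
    """Write the tidy CSV plus a ``<stem>.provenance.json`` sidecar."""
    path = Path(path)
    dataset.data.to_csv(path, index=False)
    sidecar = path.with_suffix(".provenance.json")
    sidecar.write_text(json.dumps(dataset.provenance, indent=2, sort_keys=True) + "\n")


def read_csv(path: str | Path) -> TimeSeriesDataset:
    """Read a dataset written by :func:`write_csv` (sidecar optional)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as parse error
        raise ValueError(f"could not parse {path}: {exc}") from exc
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    provenance: dict = {}
    sidecar = path.with_suffix(".provenance.json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())
    return TimeSeriesDataset(df, provenance=provenance)
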