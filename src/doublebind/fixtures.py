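"""Packaged ground-truth parameter sets for the four treatment arms.

These are the published across-replicate mean estimates for the untreated,
radiation-only, NK-only, and radiation-plus-NK co-culture arms, with the
parameters that the staged fitting procedure holds fixed flagged as such
(NK carrying capacity always; tumour carrying capacities in the treated arms;
NK kill rates and NK growth rate zeroed in the no-NK arms).  They serve both
as the default truth for the synthetic-data generator and as the reference
point for self-consistency recovery runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib.resources import files

from .model_core import Condition, ParameterSet

__all__ = ["Table1Fixture", "load_table1_fixture", "FixtureError"]


class FixtureError(RuntimeError):
    """The packaged fixture failed its integrity check."""


@dataclass(frozen=True)
class Table1Fixture:
    """Mean parameter estimates per treatment arm."""

    conditions: dict

    def __getitem__(self, condition: Condition | str) -> ParameterSet:
        return self.conditions[Condition(condition)]

    def __contains__(self, condition) -> bool:
        return Condition(condition) in self.conditions

    def __len__(self) -> int:
        return len(self.conditions)

    def items(self):
        return self.conditions.items()

    def as_truth(self) -> dict:
        """Mapping usable directly by the synthetic-data generator."""
        return dict(self.conditions)


def _canonical_payload(conditions: dict) -> str:
    return json.dumps(conditions, sort_keys=True, separators=(",", ":"))


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged parameter table, verifying its checksum."""
    raw = files("doublebind").joinpath("data/table1.json").read_text()
    doc = json.loads(raw)
    digest = hashlib.sha256(
        _canonical_payload(doc["conditions"]).encode()
    ).hexdigest()
    if digest != doc.get("sha256"):
        raise FixtureError(
            f"fixture checksum mismatch: expected {doc.get('sha256')}, got {digest}"
        )
    conditions = {
        Condition(name): ParameterSet.from_dict(entry)
        for name, entry in doc["conditions"].items()
    }
    return Table1Fixture(conditions=conditions)
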