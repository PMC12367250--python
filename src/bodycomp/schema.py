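"""Label schemas for the abdominal and thigh compartment maps.

The abdominal schema carries seven foreground compartments (vertebral bone,
psoas muscle, core muscle, superficial/deep subcutaneous adipose tissue,
intra- and retroperitoneal adipose tissue) plus merge rules producing the
derived SAT and VAT compartments.  The thigh schema carries femur, vessel,
SAT and muscle.  Background is always label 0 and never part of a schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, Mapping


@dataclass(frozen=True)
class LabelSchema:
    """Region identity, label ids and derived-compartment merge rules."""

    region: str
    label_ids: Mapping[int, str]
    merge_rules: Mapping[str, FrozenSet[int]] = field(default_factory=dict)
    muscle_for_imat: str = ""
    circumference_label: str = ""

    def __post_init__(self) -> None:
        if self.region not in ("abdomen", "thigh"):
            raise ValueError(f"unknown region {self.region!r}")
        ids = list(self.label_ids)
        if any(i <= 0 for i in ids):
            raise ValueError("label ids must be positive (0 is background)")
        if len(set(ids)) != len(ids):
            raise ValueError("label ids must be unique")
        for name, members in self.merge_rules.items():
            if not set(members) <= set(ids):
                raise ValueError(f"merge rule {name} references unknown ids")

    @property
    def names(self) -> Dict[str, int]:
        return {name: i for i, name in self.label_ids.items()}

    def id_of(self, name: str) -> int:
        return self.names[name]

    def ids_of(self, compartment: str) -> FrozenSet[int]:
        """Label-id set for a raw or derived compartment name."""
        if compartment in self.merge_rules:
            return self.merge_rules[compartment]
        return frozenset({self.id_of(compartment)})

    def compartments(self) -> Dict[str, FrozenSet[int]]:
        """All raw labels followed by derived (merged) compartments."""
        out = {name: frozenset({i}) for i, name in self.label_ids.items()}
        out.update({k: frozenset(v) for k, v in self.merge_rules.items()})
        return out


def _load_builtin() -> dict:
    text = resources.files("bodycomp.data").joinpath("schemas.json").read_text()
    return json.loads(text)


def get_schema(region: str) -> LabelSchema:
    """Load a built-in schema ('abdomen' or 'thigh') from the versioned JSON."""
    spec = _load_builtin()["schemas"]
    if region not in spec:
        raise ValueError(f"no built-in schema for region {region!r}")
    entry = spec[region]
    label_ids = {int(k): v for k, v in entry["labels"].items()}
    names = {v: int(k) for k, v in entry["labels"].items()}
    merge = {
        name: frozenset(names[m] for m in members)
        for name, members in entry.get("merge_rules", {}).items()
    }
    return LabelSchema(
        region=region,
        label_ids=label_ids,
        merge_rules=merge,
        muscle_for_imat=entry.get("muscle_for_imat", ""),
        circumference_label=entry.get("circumference_label", ""),
    )


ABDOMEN = get_schema("abdomen")
THIGH = get_schema("thigh")
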