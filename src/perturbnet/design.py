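"""Experimental design: perturbation conditions and their enumeration.

A condition assigns a relative dose to every drug: 0 (absent), 1 (low) or
2 (high, i.e. twice the low dose).  The canonical screen applies every drug
alone at low and at high dose and every unordered drug pair at low doses,
optionally preceded by a vehicle (DMSO) control.  Nine drugs therefore give
9 + 9 + 36 = 54 drug conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

CONTROL_LABEL = "DMSO"


@dataclass(frozen=True)
class PerturbationCondition:
    """Relative drug doses for one experimental condition."""

    label: str
    doses: tuple[tuple[str, float], ...]  # (drug, relative dose), dose > 0

    @classmethod
    def from_doses(cls, label: str, doses: dict[str, float]) -> "PerturbationCondition":
        clean = {k: float(v) for k, v in doses.items() if v != 0}
        if any(v < 0 for v in clean.values()):
            raise ValueError(f"negative dose in condition {label!r}")
        return cls(label=label, doses=tuple(sorted(clean.items())))

    @property
    def dose_map(self) -> dict[str, float]:
        return dict(self.doses)

    @property
    def is_control(self) -> bool:
        return not self.doses

    def dose_vector(self, drug_names: list[str]) -> np.ndarray:
        d = self.dose_map
        unknown = set(d) - set(drug_names)
        if unknown:
            raise ValueError(f"condition {self.label!r} doses unknown drugs {sorted(unknown)}")
        return np.array([d.get(name, 0.0) for name in drug_names], dtype=float)


@dataclass
class DesignSpec:
    """Specification of the single + pairwise perturbation design."""

    drug_names: list[str]
    include_control: bool = True
    low_dose_value: float = 1.0
    high_dose_value: float = 2.0

    def __post_init__(self) -> None:
        if len(self.drug_names) < 1:
            raise ValueError("at least one drug name required")
        if len(set(self.drug_names)) != len(self.drug_names):
            raise ValueError("drug names must be unique")


def generate_experimental_design(spec: DesignSpec) -> list[PerturbationCondition]:
    """Enumerate conditions: [control,] singles low, singles high, pairs low.

    Order is deterministic: drugs in input order, pairs in lexicographic
    position order.  Condition count is
    ``[1 +] 2 n + n (n - 1) / 2`` for ``n`` drugs.
    """
    conds: list[PerturbationCondition] = []
    if spec.include_control:
        conds.append(PerturbationCondition.from_doses(CONTROL_LABEL, {}))
    for name in spec.drug_names:
        conds.append(
            PerturbationCondition.from_doses(f"{name}_low", {name: spec.low_dose_value})
        )
    for name in spec.drug_names:
        conds.append(
            PerturbationCondition.from_doses(f"{name}_high", {name: spec.high_dose_value})
        )
    for a, b in combinations(spec.drug_names, 2):
        conds.append(
            PerturbationCondition.from_doses(
                f"{a}+{b}", {a: spec.low_dose_value, b: spec.low_dose_value}
            )
        )
    return conds


def dose_matrix(
    conditions: list[PerturbationCondition], drug_names: list[str]
) -> np.ndarray:
    """Relative dose matrix, shape (n_drug, n_condition)."""
    return np.column_stack([c.dose_vector(drug_names) for c in conditions])


def n_single_conditions(cond: PerturbationCondition) -> int:
    return len(cond.doses)


def write_design_tsv(
    conditions: list[PerturbationCondition], drug_names: list[str], path: str | Path
) -> None:
    """Long-format design table: one row per (condition, drug) with dose > 0;
    control conditions get a single row with empty drug."""
    rows = []
    for c in conditions:
        if c.is_control:
            rows.append({"condition": c.label, "drug": "", "dose": 0.0})
        for drug, dose in c.doses:
            rows.append({"condition": c.label, "drug": drug, "dose": dose})
    from .io_utils import atomic_write_text

    df = pd.DataFrame(rows, columns=["condition", "drug", "dose"])
    atomic_write_text(Path(path), df.to_csv(sep="\t", index=False))


def read_design_tsv(path: str | Path) -> list[PerturbationCondition]:
    df = pd.read_csv(path, sep="\t", dtype={"condition": str, "drug": str})
    required = {"condition", "drug", "dose"}
    if not required.issubset(df.columns):
        raise ValueError(f"design table must have columns {sorted(required)}")
    conds = []
    for label, grp in df.groupby("condition", sort=False):
        doses = {
            str(r.drug): float(r.dose)
            for r in grp.itertuples()
            if isinstance(r.drug, str) and r.drug and r.dose != 0
        }
        conds.append(PerturbationCondition.from_doses(str(label), doses))
    return conds
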