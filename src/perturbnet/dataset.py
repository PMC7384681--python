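"""The log2-control-normalized response tensor consumed by inference.

A :class:`ResponseDataset` holds one value per (node, condition, time point)
triple together with a measured-mask: the phenotype readouts use a sparser
time grid than the molecular (RPPA) measurements, and individual samples can
drop out during normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import PerturbationCondition
from .io_utils import atomic_write_text

TSV_COLUMNS = ["node", "condition", "time_h", "value", "measured"]


@dataclass
class ResponseDataset:
    """node x condition x time tensor of log2-control-normalized responses.

    ``nodes`` lists molecular nodes first, then ``n_phen`` phenotypic nodes.
    ``values`` has shape (n_node, n_condition, n_time); entries where ``mask``
    is False are not measurements (stored as NaN).
    ``design``, when present, carries the relative drug doses per condition
    and is required for model fitting.
    """

    nodes: list[str]
    n_phen: int
    conditions: list[str]
    times: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    design: list[PerturbationCondition] | None = None
    control_label: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = (len(self.nodes), len(self.conditions), len(self.times))
        if self.values.shape != shape or self.mask.shape != shape:
            raise ValueError(
                f"values/mask must have shape {shape}, got "
                f"{self.values.shape}/{self.mask.shape}"
            )
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node names must be unique")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time points must be strictly increasing")
        if not (0 <= self.n_phen <= len(self.nodes)):
            raise ValueError("n_phen out of range")
        if self.design is not None:
            labels = [c.label for c in self.design]
            if labels != list(self.conditions):
                raise ValueError("design condition labels must match dataset conditions")

    # -- accessors ---------------------------------------------------------
    @property
    def n_molec(self) -> int:
        return len(self.nodes) - self.n_phen

    @property
    def molecular_nodes(self) -> list[str]:
        return self.nodes[: self.n_molec]

    @property
    def phenotype_nodes(self) -> list[str]:
        return self.nodes[self.n_molec:]

    @property
    def n_measured(self) -> int:
        return int(self.mask.sum())

    def points_per_node(self) -> int:
        """Design bookkeeping: (condition, time) grid size per node."""
        return len(self.conditions) * len(self.times)

    def condition_index(self, label: str) -> int:
        try:
            return self.conditions.index(label)
        except ValueError:
            raise KeyError(f"condition {label!r} not in dataset") from None

    def subset_conditions(self, labels: list[str]) -> "ResponseDataset":
        idx = [self.condition_index(lab) for lab in labels]
        return ResponseDataset(
            nodes=list(self.nodes),
            n_phen=self.n_phen,
            conditions=list(labels),
            times=self.times.copy(),
            values=self.values[:, idx, :].copy(),
            mask=self.mask[:, idx, :].copy(),
            design=[self.design[i] for i in idx] if self.design is not None else None,
            control_label=self.control_label if self.control_label in labels else None,
        )

    # -- tidy-frame conversion ----------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        n, c, t = np.nonzero(np.ones_like(self.mask))
        df = pd.DataFrame(
            {
                "node": np.asarray(self.nodes, dtype=object)[n],
                "condition": np.asarray(self.conditions, dtype=object)[c],
                "time_h": self.times[t],
                "value": self.values[n, c, t],
                "measured": self.mask[n, c, t].astype(int),
                "node_type": np.where(
                    n < self.n_molec, "molecular", "phenotypic"
                ),
            }
        )
        return df[df["measured"] == 1].reset_index(drop=True).astype({"measured": int})

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        n_phen: int | None = None,
        phenotype_nodes: list[str] | None = None,
        design: list[PerturbationCondition] | None = None,
        control_label: str | None = None,
    ) -> "ResponseDataset":
        required = {"node", "condition", "time_h", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("empty dataset")
        bad = df[pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()]
        if len(bad):
            raise ValueError(f"non-numeric value at row(s) {bad.index[:5].tolist()}")
        dup = df.duplicated(subset=["node", "condition", "time_h"])
        if dup.any():
            rows = df.index[dup][:5].tolist()
            raise ValueError(f"duplicate (node, condition, time_h) at row(s) {rows}")

        if phenotype_nodes is None and "node_type" in df.columns:
            phenotype_nodes = list(
                pd.unique(df.loc[df["node_type"] == "phenotypic", "node"])
            )
        all_nodes = list(pd.unique(df["node"]))
        if phenotype_nodes:
            molec = [x for x in all_nodes if x not in set(phenotype_nodes)]
            nodes = molec + [x for x in phenotype_nodes if x in set(all_nodes)]
        else:
            nodes = all_nodes
            phenotype_nodes = []
        if n_phen is None:
            n_phen = len([x for x in phenotype_nodes if x in set(all_nodes)])

        conditions = [c.label for c in design] if design is not None else list(
            pd.unique(df["condition"])
        )
        times = np.array(sorted(df["time_h"].astype(float).unique()))
        ni = {x: i for i, x in enumerate(nodes)}
        ci = {x: i for i, x in enumerate(conditions)}
        ti = {x: i for i, x in enumerate(times)}
        shape = (len(nodes), len(conditions), len(times))
        values = np.full(shape, np.nan)
        mask = np.zeros(shape, dtype=bool)
        unknown = set(df["condition"].unique()) - set(conditions)
        if unknown:
            raise ValueError(f"conditions not in design: {sorted(unknown)}")
        rows_n = df["node"].map(ni).to_numpy()
        rows_c = df["condition"].map(ci).to_numpy()
        rows_t = df["time_h"].astype(float).map(ti).to_numpy()
        vals = df["value"].astype(float).to_numpy()
        meas = (
            df["measured"].astype(int).to_numpy().astype(bool)
            if "measured" in df.columns
            else np.ones(len(df), dtype=bool)
        )
        values[rows_n, rows_c, rows_t] = np.where(meas, vals, np.nan)
        mask[rows_n, rows_c, rows_t] = meas
        return cls(
            nodes=nodes,
            n_phen=n_phen,
            conditions=conditions,
            times=times,
            values=values,
            mask=mask,
            design=design,
            control_label=control_label,
        )

    # -- file I/O ------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        text = self.to_frame().to_csv(sep="\t", index=False, float_format="%.17g")
        atomic_write_text(Path(path), text)

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        design: list[PerturbationCondition] | None = None,
        control_label: str | None = None,
    ) -> "ResponseDataset":
        try:
            df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        except pd.errors.EmptyDataError:
            raise ValueError(f"empty dataset file: {path}") from None
        return cls.from_frame(df, design=design, control_label=control_label)


def read_response_dataset(
    path: str | Path,
    design_path: str | Path | None = None,
    control_label: str | None = None,
) -> ResponseDataset:
    """Read a tidy TSV response table, optionally attaching a design table."""
    design = None
    if design_path is not None:
        from .design import read_design_tsv

        design = read_design_tsv(design_path)
    return ResponseDataset.read_tsv(path, design=design, control_label=control_label)
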