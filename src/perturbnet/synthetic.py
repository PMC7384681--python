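"""Synthetic study generator: ground-truth networks, designs, noisy response
datasets and raw dilution-series spot tables.

The defaults emulate the structure of the melanoma perturbation study the
model targets: ~9 drugs applied singly at low/high dose and pairwise at low
dose (54 drug conditions plus a DMSO control), 124 molecular plus 2
phenotypic nodes, 8 time points from 10 minutes to 67 hours, and
multiplicative log-normal measurement noise (additive Gaussian on the log2
scale on which all modeling happens).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model as _model
from .dataset import ResponseDataset
from .design import (
    DesignSpec,
    PerturbationCondition,
    generate_experimental_design,
)
from .params import ModelParameters

#: the study's molecular measurement grid (hours): 10, 27 and 72 minutes,
#: then 3, 9, 24, 48 and 67 hours.
MOLECULAR_TIME_GRID = (10 / 60, 27 / 60, 72 / 60, 3.0, 9.0, 24.0, 48.0, 67.0)
#: phenotype readouts use the sparser grid 1, 3, 9, 24, 48, 67 hours.
PHENOTYPE_TIME_GRID = (1.0, 3.0, 9.0, 24.0, 48.0, 67.0)

PHENOTYPE_NAMES = ("cell_growth", "apoptosis")


@dataclass
class GroundTruthSpec:
    """Recipe for a random ground-truth network.

    edge_density is the probability that an off-diagonal molecular→molecular
    interaction is non-zero; every drug hits ``drug_target_count`` molecular
    targets with mixed signs; non-zero weights have magnitude
    ``weight_scale * U(0.5, 1.5)`` so that (at the default scale 1) they sit
    comfortably above the inference crop thresholds.
    """

    n_molec: int = 124
    n_phen: int = 2
    n_drug: int = 9
    edge_density: float = 0.05
    drug_target_count: int = 2
    weight_scale: float = 1.0
    phen_in_degree: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.edge_density <= 1.0):
            raise ValueError("edge_density must be in [0, 1]")
        if min(self.n_molec, self.n_drug, self.drug_target_count) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_phen < 1:
            raise ValueError("at least one phenotypic node required")
        if self.drug_target_count > self.n_molec:
            raise ValueError("more drug targets than molecular nodes")


def generate_ground_truth(spec: GroundTruthSpec) -> ModelParameters:
    """Draw a reproducible random network satisfying the model's structure."""
    rng = np.random.default_rng(spec.seed)
    n_mol, n_ph = spec.n_molec, spec.n_phen
    n = n_mol + n_ph
    node_names = [f"node{i:03d}" for i in range(n_mol)] + list(
        PHENOTYPE_NAMES[:n_ph]
        if n_ph <= len(PHENOTYPE_NAMES)
        else [f"phen{i}" for i in range(n_ph)]
    )
    drug_names = [f"drug{l}" for l in range(spec.n_drug)]

    # decay/range parameters log-uniform in [0.2, 2]: a numerically tame
    # regime in which nodes relax within minutes to hours.
    eps = np.exp(rng.uniform(np.log(0.2), np.log(2.0), size=n))
    alpha = np.exp(rng.uniform(np.log(0.2), np.log(2.0), size=n))

    def weights(shape):
        mag = spec.weight_scale * rng.uniform(0.5, 1.5, size=shape)
        sign = rng.choice([-1.0, 1.0], size=shape)
        return mag * sign

    W = np.zeros((n, n))
    mol_edges = rng.random((n_mol, n_mol)) < spec.edge_density
    np.fill_diagonal(mol_edges, False)
    W[:n_mol, :n_mol] = np.where(mol_edges, weights((n_mol, n_mol)), 0.0)
    # phenotypes: a fixed number of incoming molecular edges, no outgoing.
    for p in range(n_ph):
        k = min(spec.phen_in_degree, n_mol)
        src = rng.choice(n_mol, size=k, replace=False)
        W[n_mol + p, src] = weights(k)

    D = np.zeros((n, spec.n_drug))
    for l in range(spec.n_drug):
        tgt = rng.choice(n_mol, size=spec.drug_target_count, replace=False)
        D[tgt, l] = weights(spec.drug_target_count)

    delta = rng.uniform(0.5, 1.5, size=spec.n_drug)
    return ModelParameters(
        node_names=node_names,
        n_phen=n_ph,
        drug_names=drug_names,
        eps=eps,
        alpha=alpha,
        W=W,
        D=D,
        delta=delta,
    )


def simulate_dataset(
    params: ModelParameters,
    design: list[PerturbationCondition],
    time_points_h: np.ndarray | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    phenotype_times_h: np.ndarray | None = None,
    step_h: float = _model.DEFAULT_STEP_H,
) -> ResponseDataset:
    """Simulate noiseless trajectories on the measurement grid and add
    independent Gaussian noise on the log2 scale.

    Phenotype nodes are masked to the (sparser) phenotype time grid, matching
    the study's imaging schedule.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    times = np.asarray(
        MOLECULAR_TIME_GRID if time_points_h is None else time_points_h, dtype=float
    )
    if np.any(np.diff(times) <= 0) or np.any(times < 0):
        raise ValueError("time points must be non-negative and strictly increasing")
    phen_times = np.asarray(
        PHENOTYPE_TIME_GRID if phenotype_times_h is None else phenotype_times_h,
        dtype=float,
    )
    clean = _model.simulate_conditions(params, design, times, step_h=step_h)
    rng = np.random.default_rng(seed)
    noisy = clean + (rng.standard_normal(clean.shape) * noise_sd if noise_sd else 0.0)
    mask = np.ones_like(noisy, dtype=bool)
    phen_rows = slice(params.n_molec, params.n_meas)
    phen_mask = np.isclose(times[None, :], phen_times[:, None]).any(axis=0)
    mask[phen_rows, :, ~phen_mask] = False
    noisy[~mask] = np.nan
    control = [c.label for c in design if c.is_control]
    return ResponseDataset(
        nodes=list(params.node_names),
        n_phen=params.n_phen,
        conditions=[c.label for c in design],
        times=times,
        values=noisy,
        mask=mask,
        design=list(design),
        control_label=control[0] if control else None,
    )


#: dilution fractions of the per-sample loading used for the 4-spot series.
DILUTION_FRACTIONS = (0.25, 0.5, 0.75, 1.0)


def generate_raw_spot_table(
    dataset: ResponseDataset,
    mean_loading: float = 0.2,
    outlier_rate: float = 0.0,
    seed: int = 0,
    loading_cv: float = 0.15,
    base_scale: float = 1000.0,
) -> pd.DataFrame:
    """Emit a raw dilution-series spot table whose normalization round-trips
    to the dataset's molecular log2 values.

    Each (antibody, sample) gets four spot intensities exactly linear in the
    dilution fractions of the *actual* per-sample loading, while the recorded
    loading concentration is the nominal ``mean_loading`` — so uneven loading
    shows up as a per-sample intensity factor, which is what double-median
    normalization removes.  With probability ``outlier_rate`` one spot is
    replaced by a gross outlier (flagged later via Cook's distance).
    """
    if mean_loading <= 0:
        raise ValueError("mean_loading must be positive")
    if not (0.0 <= outlier_rate <= 1.0):
        raise ValueError("outlier_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    antibodies = dataset.molecular_nodes
    base = base_scale * np.exp(rng.uniform(-0.5, 0.5, size=len(antibodies)))
    rows = []
    fracs = np.array(DILUTION_FRACTIONS)
    for ci, cond in enumerate(dataset.conditions):
        for ti, t in enumerate(dataset.times):
            loading = mean_loading * np.exp(loading_cv * rng.standard_normal())
            for ai, ab in enumerate(antibodies):
                if not dataset.mask[ai, ci, ti]:
                    continue
                x = dataset.values[ai, ci, ti]
                # signal per unit concentration; actual loading differs from
                # the recorded nominal value -> per-sample factor.
                slope = base[ai] * (2.0 ** x) / mean_loading
                spots = slope * fracs * loading
                if outlier_rate and rng.random() < outlier_rate:
                    m = rng.integers(0, 4)
                    spots = spots.copy()
                    spots[m] *= rng.choice([0.05, 8.0])
                for si in range(4):
                    rows.append(
                        (ab, cond, t, 0, si, fracs[si], spots[si], mean_loading)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "antibody",
            "condition",
            "time_h",
            "replicate",
            "spot_index",
            "dilution_fraction",
            "intensity",
            "loading_conc",
        ],
    )


def demo_design(n_drug: int = 9, include_control: bool = True) -> list[PerturbationCondition]:
    """Convenience: the canonical single+pairwise design for ``n_drug`` drugs."""
    return generate_experimental_design(
        DesignSpec(
            drug_names=[f"drug{l}" for l in range(n_drug)],
            include_control=include_control,
        )
    )
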