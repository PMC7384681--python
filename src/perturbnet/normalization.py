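"""RPPA normalization chain: dilution-series fits, spotting-error removal,
loading correction, control normalization, dataset merging and phenotype
count normalization.

The chain converts raw 4-spot dilution-series fluorescence readings
(Referenced Net spot Fluorescence Intensity, RNFI) into the
log2-control-normalized response tensor used for network inference:

1. per (antibody, sample): flag spotting errors by Cook's distance, fit a
   straight line of intensity versus concentration, and evaluate it at
   0.625 x the reference concentration (the Referenced sample Fluorescence
   Intensity, RFI);
2. log2-transform and correct uneven protein loading by double-median
   normalization (or by per-sample protein factors where those were
   measured);
3. collapse replicates by the median and subtract the DMSO control
   time course from every condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ResponseDataset
from .design import PerturbationCondition
from .synthetic import DILUTION_FRACTIONS, PHENOTYPE_TIME_GRID

#: Cook's distance above which a spot counts as a spotting error.
COOKS_CUTOFF = 0.8
#: reference total-protein concentration per spot (mg/ml).
REFERENCE_CONC = 0.2
#: the dilution fit is evaluated at this fraction of the reference
#: concentration (the mean of the four dilution fractions).
RFI_EVAL_FRACTION = 0.625


@dataclass
class LinearFit:
    """Straight-line fit of spot intensity on concentration."""

    beta0: float
    beta1: float
    used_mask: np.ndarray  # which spots entered the (re)fit


def dilution_pseudoinverse(c_i: float) -> np.ndarray:
    """Closed-form least-squares weights for the 4-spot dilution design.

    Row 0 (intercept): (1, 0.5, 0, -0.5); row 1 (slope):
    (-6/5, -2/5, 2/5, 6/5) / c_i — spots ordered by ascending concentration
    (0.25, 0.5, 0.75, 1) x c_i.
    """
    if c_i <= 0:
        raise ValueError("loading concentration must be positive")
    return np.array(
        [
            [1.0, 0.5, 0.0, -0.5],
            [-1.2 / c_i, -0.4 / c_i, 0.4 / c_i, 1.2 / c_i],
        ]
    )


def fit_dilution_series(
    spots: np.ndarray, c_i: float, used_mask: np.ndarray | None = None
) -> LinearFit:
    """OLS fit of the 4-spot series; uses the closed-form pseudoinverse when
    all four spots are used, a generic solve on the surviving subset after
    outlier removal."""
    spots = np.asarray(spots, dtype=float)
    if spots.shape != (4,):
        raise ValueError("exactly 4 spot intensities expected")
    if not np.all(np.isfinite(spots)):
        raise ValueError("non-finite spot intensity")
    if used_mask is None:
        used_mask = np.ones(4, dtype=bool)
    used_mask = np.asarray(used_mask, dtype=bool)
    if used_mask.sum() < 2:
        raise ValueError("at least 2 spots required for a line fit")
    if used_mask.all():
        beta = dilution_pseudoinverse(c_i) @ spots
    else:
        conc = np.array(DILUTION_FRACTIONS) * c_i
        A = np.column_stack([np.ones(used_mask.sum()), conc[used_mask]])
        beta, *_ = np.linalg.lstsq(A, spots[used_mask], rcond=None)
    return LinearFit(beta0=float(beta[0]), beta1=float(beta[1]), used_mask=used_mask)


def cooks_distances(spots: np.ndarray, c_i: float) -> np.ndarray:
    """Cook's distance of each spot under the simple linear regression of
    intensity on concentration (hat-matrix form)."""
    spots = np.asarray(spots, dtype=float)
    conc = np.array(DILUTION_FRACTIONS) * c_i
    n, p = 4, 2
    A = np.column_stack([np.ones(n), conc])
    H = A @ np.linalg.inv(A.T @ A) @ A.T
    h = np.diag(H)
    resid = spots - H @ spots
    rss = float(resid @ resid)
    if rss <= 1e-20 * max(1.0, float(spots @ spots)):  # numerically collinear
        return np.zeros(n)
    s2 = rss / (n - p)
    return (resid**2 / (p * s2)) * (h / (1.0 - h) ** 2)


def detect_outlier_spots(
    spots: np.ndarray, c_i: float, cutoff: float = COOKS_CUTOFF
) -> np.ndarray | None:
    """Mask of spots flagged as spotting errors (Cook's distance > cutoff).

    Returns None when more than 2 spots are flagged: the sample is unusable
    (fewer than 2 points would remain) and propagates as a missing value.
    The cutoff is applied once; there is no iterative refitting.
    """
    flagged = cooks_distances(spots, c_i) > cutoff
    if flagged.sum() > 2:
        return None
    return flagged


def compute_rfi(fit: LinearFit, c_bar: float = REFERENCE_CONC) -> float:
    """Referenced sample Fluorescence Intensity: the fitted line evaluated at
    0.625 x the reference concentration."""
    return fit.beta0 + fit.beta1 * RFI_EVAL_FRACTION * c_bar


def sample_rfi(
    spots: np.ndarray,
    c_i: float,
    cutoff: float = COOKS_CUTOFF,
    c_bar: float = REFERENCE_CONC,
) -> float:
    """Outlier-aware RFI for one 4-spot series; NaN when unusable."""
    flagged = detect_outlier_spots(spots, c_i, cutoff)
    if flagged is None:
        return float("nan")
    fit = fit_dilution_series(spots, c_i, used_mask=~flagged)
    return compute_rfi(fit, c_bar)


# ---------------------------------------------------------------------------
# loading normalization
# ---------------------------------------------------------------------------

def double_median_normalize(log2_matrix: pd.DataFrame, divide: bool = False) -> pd.DataFrame:
    """Loading correction: subtract the per-antibody median (rows), then the
    per-sample median of the antibody-centered values (columns).

    After the operation every sample's median over antibodies is exactly 0,
    and a matrix that is already row- and column-median-centered passes
    through unchanged.  ``divide=True`` preserves
    a variant that divides by (i.e. subtracts on the log scale via) the
    second median as well — identical here because the data are already
    log2; the flag exists for symmetry with linear-scale conventions.
    """
    m = log2_matrix.astype(float)
    if m.isna().all(axis=1).any():
        bad = m.index[m.isna().all(axis=1)].tolist()
        raise ValueError(f"antibody with no finite values: {bad}")
    if m.isna().all(axis=0).any():
        bad = m.columns[m.isna().all(axis=0)].tolist()
        raise ValueError(f"sample with no finite values: {bad}")
    centered = m.sub(m.median(axis=1), axis=0)
    out = centered.sub(centered.median(axis=0), axis=1)
    return out


def protein_factor_normalize(
    matrix: pd.DataFrame, factors: pd.Series
) -> pd.DataFrame:
    """Divide each sample's raw (linear-scale) values by its median-centered
    protein loading factor.  Factors are re-centered so their median is 1."""
    factors = factors.astype(float).reindex(matrix.columns)
    if factors.isna().any():
        missing = matrix.columns[factors.isna()].tolist()
        raise ValueError(f"missing protein factor for sample(s) {missing}")
    if (factors <= 0).any():
        raise ValueError("protein factors must be positive")
    centered = factors / factors.median()
    return matrix.div(centered, axis=1)


# ---------------------------------------------------------------------------
# full chain from a raw spot table
# ---------------------------------------------------------------------------

SAMPLE_KEYS = ["condition", "time_h", "replicate"]


def spot_table_to_rfi(
    raw: pd.DataFrame,
    cooks_cutoff: float = COOKS_CUTOFF,
    reference_conc: float = REFERENCE_CONC,
) -> pd.DataFrame:
    """Collapse each (antibody, sample) 4-spot series to one RFI value.

    Returns a tidy frame (antibody, condition, time_h, replicate, rfi).
    """
    required = {"antibody", "intensity", "dilution_fraction", "loading_conc", *SAMPLE_KEYS}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw spot table missing columns {sorted(missing)}")
    rows = []
    for key, grp in raw.groupby(["antibody", *SAMPLE_KEYS], sort=False):
        grp = grp.sort_values("dilution_fraction")
        if len(grp) != 4:
            raise ValueError(f"expected 4 spots for {key}, got {len(grp)}")
        rfi = sample_rfi(
            grp["intensity"].to_numpy(),
            float(grp["loading_conc"].iloc[0]),
            cutoff=cooks_cutoff,
            c_bar=reference_conc,
        )
        rows.append((*key, rfi))
    return pd.DataFrame(rows, columns=["antibody", *SAMPLE_KEYS, "rfi"])


def control_normalize(dataset: ResponseDataset, control_label: str) -> ResponseDataset:
    """Subtract the control condition's time course per node (log2 scale).

    The control column becomes identically zero."""
    try:
        ctrl = dataset.condition_index(control_label)
    except KeyError:
        raise ValueError(f"control condition {control_label!r} not in dataset") from None
    ctrl_vals = dataset.values[:, ctrl, :]
    ctrl_mask = dataset.mask[:, ctrl, :]
    needed = dataset.mask.any(axis=(0, 1))
    missing_t = dataset.times[needed & ~ctrl_mask.all(axis=0)]
    if len(missing_t):
        raise ValueError(
            f"control {control_label!r} missing at time point(s) "
            f"{np.round(missing_t, 4).tolist()}"
        )
    values = dataset.values - ctrl_vals[:, None, :]
    values[:, ctrl, :] = np.where(ctrl_mask, 0.0, np.nan)
    return ResponseDataset(
        nodes=list(dataset.nodes),
        n_phen=dataset.n_phen,
        conditions=list(dataset.conditions),
        times=dataset.times.copy(),
        values=values,
        mask=dataset.mask.copy(),
        design=dataset.design,
        control_label=control_label,
    )


def normalize_raw_spot_table(
    raw: pd.DataFrame,
    control_label: str,
    cooks_cutoff: float = COOKS_CUTOFF,
    reference_conc: float = REFERENCE_CONC,
    design: list[PerturbationCondition] | None = None,
    protein_factors: pd.Series | None = None,
) -> ResponseDataset:
    """Full molecular chain: spots -> RFI -> log2 -> loading normalization ->
    replicate medians -> DMSO subtraction."""
    rfi = spot_table_to_rfi(raw, cooks_cutoff, reference_conc)
    rfi["sample"] = list(zip(rfi["condition"], rfi["time_h"], rfi["replicate"]))
    wide = rfi.pivot(index="antibody", columns="sample", values="rfi")
    wide = wide.where(wide > 0)  # non-positive fitted intensities are unusable
    if protein_factors is not None:
        wide = protein_factor_normalize(wide, protein_factors)
    log2m = np.log2(wide)
    norm = double_median_normalize(log2m)
    # collapse replicates by median
    cols = pd.MultiIndex.from_tuples(norm.columns, names=SAMPLE_KEYS)
    norm.columns = cols
    collapsed = norm.T.groupby(level=["condition", "time_h"]).median().T
    long = collapsed.stack(["condition", "time_h"], future_stack=True).rename("value").reset_index()
    long["measured"] = long["value"].notna().astype(int)
    long = long.rename(columns={"antibody": "node"})
    ds = ResponseDataset.from_frame(
        long.dropna(subset=["value"]),
        n_phen=0,
        design=design,
        control_label=control_label,
    )
    return control_normalize(ds, control_label)


# ---------------------------------------------------------------------------
# dataset merge and phenotype normalization
# ---------------------------------------------------------------------------

def merge_datasets(
    ds1: ResponseDataset,
    ds2: ResponseDataset,
    rule: str = "mean",
) -> ResponseDataset:
    """Union two antibody panels measured on the same (condition, time) design.

    Antibodies present in both panels (inter-platform controls) are resolved
    by the configured rule: ``"mean"`` averages the two datasets' values,
    ``"first"``/``"second"`` keep one panel's values.
    """
    if list(ds1.conditions) != list(ds2.conditions) or not np.array_equal(
        ds1.times, ds2.times
    ):
        raise ValueError("datasets must share the (condition, time) design")
    if ds1.n_phen or ds2.n_phen:
        raise ValueError("merge operates on molecular (antibody) panels only")
    shared = [n for n in ds1.nodes if n in set(ds2.nodes)]
    nodes = list(ds1.nodes) + [n for n in ds2.nodes if n not in set(ds1.nodes)]
    i2 = {n: i for i, n in enumerate(ds2.nodes)}
    shape = (len(nodes), len(ds1.conditions), len(ds1.times))
    values = np.full(shape, np.nan)
    mask = np.zeros(shape, dtype=bool)
    for i, n in enumerate(nodes):
        have1, have2 = n in set(ds1.nodes), n in i2
        if have1 and have2:
            v1, m1 = ds1.values[ds1.nodes.index(n)], ds1.mask[ds1.nodes.index(n)]
            v2, m2 = ds2.values[i2[n]], ds2.mask[i2[n]]
            if rule == "mean":
                both = m1 & m2
                v = np.where(both, (v1 + v2) / 2.0, np.where(m1, v1, v2))
            elif rule == "first":
                v = np.where(m1, v1, v2)
            elif rule == "second":
                v = np.where(m2, v2, v1)
            else:
                raise ValueError(f"unknown merge rule {rule!r}")
            values[i], mask[i] = v, m1 | m2
        elif have1:
            j = ds1.nodes.index(n)
            values[i], mask[i] = ds1.values[j], ds1.mask[j]
        else:
            values[i], mask[i] = ds2.values[i2[n]], ds2.mask[i2[n]]
    values[~mask] = np.nan
    return ResponseDataset(
        nodes=nodes,
        n_phen=0,
        conditions=list(ds1.conditions),
        times=ds1.times.copy(),
        values=values,
        mask=mask,
        design=ds1.design or ds2.design,
        control_label=ds1.control_label or ds2.control_label,
    )


def normalize_phenotype(
    counts: pd.DataFrame,
    control_label: str,
    phenotype_times_h: np.ndarray | None = None,
) -> pd.DataFrame:
    """log2 ratio of cell/apoptosis counts to the DMSO control, sub-sampled
    to the phenotype time grid.

    ``counts`` columns: phenotype, condition, time_h, count [, replicate].
    Returns a tidy frame (node, condition, time_h, value) ready to append to
    the molecular dataset.
    """
    required = {"phenotype", "condition", "time_h", "count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"phenotype counts missing columns {sorted(missing)}")
    if (counts["count"] <= 0).any():
        raise ValueError("counts must be strictly positive")
    grid = np.asarray(
        PHENOTYPE_TIME_GRID if phenotype_times_h is None else phenotype_times_h,
        dtype=float,
    )
    df = counts.copy()
    df = df[np.isclose(df["time_h"].to_numpy()[:, None], grid[None, :]).any(axis=1)]
    df["log2count"] = np.log2(df["count"].astype(float))
    if "replicate" in df.columns:
        df = (
            df.groupby(["phenotype", "condition", "time_h"], sort=False)["log2count"]
            .median()
            .reset_index()
        )
    ctrl = df[df["condition"] == control_label].set_index(["phenotype", "time_h"])[
        "log2count"
    ]
    if ctrl.empty:
        raise ValueError(f"control condition {control_label!r} absent from counts")
    key = pd.MultiIndex.from_frame(df[["phenotype", "time_h"]])
    ref = ctrl.reindex(key)
    if ref.isna().any():
        missing_t = sorted(set(key[ref.isna().to_numpy()].get_level_values("time_h")))
        raise ValueError(f"control missing at time point(s) {missing_t}")
    out = pd.DataFrame(
        {
            "node": df["phenotype"].to_numpy(),
            "condition": df["condition"].to_numpy(),
            "time_h": df["time_h"].to_numpy(),
            "value": df["log2count"].to_numpy() - ref.to_numpy(),
        }
    )
    return out.reset_index(drop=True)
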