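"""Regularization-strength selection: train/validation/test split, BIC and
the lambda-grid scan.

The training set holds the control and all single-drug conditions (low and
high dose); the pairwise-combination conditions are partitioned into
validation and test halves such that every drug occurs equally often on each
side.  The regularization strength is chosen as the argmin of the BIC on the
training fits (with the validation RSS reported as a cross-check; both
criteria agreed on the study data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ResponseDataset
from .inference import FitConfig, FitResult, fit_batch, masked_rss


@dataclass
class DatasetSplit:
    """Condition labels of the train / validation / test partition."""

    train: list[str]
    validation: list[str]
    test: list[str]
    balanced: bool  # True when the per-drug balance is exact


def _pair_drugs(cond) -> list[str]:
    return [d for d, _ in cond.doses]


def split_dataset(
    dataset: ResponseDataset, seed: int = 0, max_tries: int = 10_000
) -> DatasetSplit:
    """Randomized search for a per-drug-balanced bisection of the pairwise
    conditions; deterministic in ``seed``.  Falls back to the best-balanced
    partition seen when exact balance is impossible (flagged)."""
    if dataset.design is None:
        raise ValueError("dataset has no attached experimental design")
    singles, pairs = [], []
    for c in dataset.design:
        k = len(c.doses)
        if k <= 1:
            singles.append(c.label)
        elif k == 2:
            pairs.append(c)
        else:
            raise ValueError(f"condition {c.label!r} doses more than two drugs")
    if not pairs:
        raise ValueError("design has no pairwise-combination conditions")
    drugs = sorted({d for c in pairs for d in _pair_drugs(c)})
    di = {d: i for i, d in enumerate(drugs)}
    occ = np.zeros((len(pairs), len(drugs)), dtype=int)
    for p, c in enumerate(pairs):
        for d in _pair_drugs(c):
            occ[p, di[d]] = 1
    rng = np.random.default_rng(seed)
    n = len(pairs)
    half = n // 2

    def imbalance_of(val_idx: np.ndarray) -> int:
        diff = occ[val_idx].sum(axis=0) - occ[~val_idx].sum(axis=0)
        return int(np.abs(diff).sum())

    # randomized restarts with greedy swap repair: plain rejection sampling
    # essentially never hits exact balance for realistic pair counts.
    best_idx, best_imbalance = None, np.inf
    n_restarts = max(1, max_tries // 200)
    for _ in range(n_restarts):
        perm = rng.permutation(n)
        val_idx = np.zeros(n, dtype=bool)
        val_idx[perm[:half]] = True
        imb = imbalance_of(val_idx)
        improved = True
        while imb > 0 and improved:
            improved = False
            for i in np.nonzero(val_idx)[0]:
                for j in np.nonzero(~val_idx)[0]:
                    val_idx[i], val_idx[j] = False, True
                    new_imb = imbalance_of(val_idx)
                    if new_imb < imb:
                        imb = new_imb
                        improved = True
                        break
                    val_idx[i], val_idx[j] = True, False
                if improved:
                    break
        if imb < best_imbalance:
            best_imbalance, best_idx = imb, val_idx.copy()
        if imb == 0:
            break
    val = [pairs[i].label for i in range(n) if best_idx[i]]
    tst = [pairs[i].label for i in range(n) if not best_idx[i]]
    return DatasetSplit(
        train=singles, validation=val, test=tst, balanced=best_imbalance == 0
    )


def bic(rss: float, k: int, n: int) -> float:
    """Simplified Bayesian information criterion ``n ln(RSS/n) + k ln(n)``
    (Gaussian errors, constants dropped)."""
    if rss <= 0:
        raise ValueError("rss must be positive")
    if n <= 0 or k < 0:
        raise ValueError("need n > 0 and k >= 0")
    return float(n * np.log(rss / n) + k * np.log(n))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN (undefined) for zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.sum(xc * yc) / (sx * sy))


@dataclass
class EvaluationMetrics:
    """Held-out predictive performance of a model ensemble."""

    rss_per_point: float
    pearson_r: float
    rss_per_point_phenotype: float
    pearson_r_phenotype: float
    n_points: int


def evaluate(
    models: list,
    dataset: ResponseDataset,
    condition_labels: list[str] | None = None,
    time_subset: np.ndarray | None = None,
    step_h: float = 0.05,
) -> EvaluationMetrics:
    """Mean per-model RSS per data point and Pearson r between prediction and
    measurement, overall and for phenotype nodes only, optionally restricted
    to a condition subset and/or a time window."""
    from .inference import FitResult as _FR
    from .model import simulate_conditions

    if not models:
        raise ValueError("at least one model required")
    params_list = [m.params if isinstance(m, _FR) else m for m in models]
    ds = (
        dataset.subset_conditions(condition_labels)
        if condition_labels is not None
        else dataset
    )
    tmask = np.ones(len(ds.times), dtype=bool)
    if time_subset is not None:
        tmask = np.isclose(ds.times[:, None], np.asarray(time_subset)[None, :]).any(axis=1)
    mask = ds.mask & tmask[None, None, :]
    n_points = int(mask.sum())
    phen_mask = mask.copy()
    phen_mask[: ds.n_molec] = False

    preds = np.stack(
        [
            simulate_conditions(p, ds.design, ds.times, step_h=step_h)
            for p in params_list
        ]
    )
    rss_all = [masked_rss(pred, ds.values, mask) for pred in preds]
    rss_ph = [masked_rss(pred, ds.values, phen_mask) for pred in preds]
    mean_pred = preds.mean(axis=0)
    r_all = pearson(mean_pred[mask], ds.values[mask])
    r_ph = (
        pearson(mean_pred[phen_mask], ds.values[phen_mask])
        if phen_mask.any()
        else float("nan")
    )
    n_ph = max(int(phen_mask.sum()), 1)
    return EvaluationMetrics(
        rss_per_point=float(np.mean(rss_all) / max(n_points, 1)),
        pearson_r=r_all,
        rss_per_point_phenotype=float(np.mean(rss_ph) / n_ph),
        pearson_r_phenotype=r_ph,
        n_points=n_points,
    )


@dataclass
class SelectionReport:
    """Per-lambda summaries of the grid scan and the selected value."""

    lambda_grid: list[float]
    mean_bic: list[float]
    std_bic: list[float]
    mean_train_rss: list[float]
    mean_validation_rss: list[float]
    mean_validation_pearson: list[float]
    mean_n_nonzero_w: list[float]
    lambda_star: float
    criterion: str
    split: DatasetSplit
    fits: dict[float, list[FitResult]] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "lambda_grid": self.lambda_grid,
            "mean_bic": self.mean_bic,
            "std_bic": self.std_bic,
            "mean_train_rss": self.mean_train_rss,
            "mean_validation_rss": self.mean_validation_rss,
            "mean_validation_pearson": self.mean_validation_pearson,
            "mean_n_nonzero_w": self.mean_n_nonzero_w,
            "lambda_star": self.lambda_star,
            "criterion": self.criterion,
            "train_conditions": self.split.train,
            "validation_conditions": self.split.validation,
            "test_conditions": self.split.test,
            "balanced_split": self.split.balanced,
        }


def select_lambda(
    dataset: ResponseDataset,
    lambda_grid: np.ndarray | list[float] | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    config: FitConfig | None = None,
    criterion: str = "bic",
    split: DatasetSplit | None = None,
) -> SelectionReport:
    """Scan the lambda grid: ``n_restarts`` training fits per value, BIC on
    the training set, RSS and Pearson r on the validation set; the selected
    lambda minimizes the chosen criterion, ties broken toward the larger
    (sparser) value."""
    grid = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0] if lambda_grid is None else list(
        map(float, lambda_grid)
    )
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    if criterion not in {"bic", "validation_rss"}:
        raise ValueError("criterion must be 'bic' or 'validation_rss'")
    cfg = config or FitConfig()
    if split is None:
        split = split_dataset(dataset, seed=seed)
    train_ds = dataset.subset_conditions(split.train)
    val_ds = dataset.subset_conditions(split.validation)
    n_train = train_ds.n_measured

    # all (lambda, restart) fits go through one batched optimization
    lambdas = np.repeat(grid, n_restarts)
    seeds = [seed + 1000 * gi + r for gi in range(len(grid)) for r in range(n_restarts)]
    all_fits = fit_batch(train_ds, lambdas, seeds, cfg)

    report_rows = {lam: [] for lam in grid}
    for lam, res in zip(lambdas, all_fits):
        report_rows[float(lam)].append(res)

    mean_bic, std_bic, mean_rss, mean_vrss, mean_vr, mean_nnz = (
        [], [], [], [], [], []
    )
    usable_grid = []
    fits_by_lambda = {}
    for lam in grid:
        ok = [r for r in report_rows[lam] if not r.failed]
        if not ok:
            import warnings

            warnings.warn(f"all fits failed at lambda={lam}; value excluded")
            continue
        usable_grid.append(lam)
        fits_by_lambda[lam] = ok
        bics = [bic(r.rss_train, r.params.n_nonzero_params(), n_train) for r in ok]
        vm = evaluate_per_fit(ok, val_ds)
        mean_bic.append(float(np.mean(bics)))
        std_bic.append(float(np.std(bics)))
        mean_rss.append(float(np.mean([r.rss_train for r in ok])))
        mean_vrss.append(float(np.mean(vm[0])))
        mean_vr.append(float(np.nanmean(vm[1])))
        mean_nnz.append(float(np.mean([r.n_nonzero_w for r in ok])))
    if not usable_grid:
        raise RuntimeError("every lambda value failed")
    score = mean_bic if criterion == "bic" else mean_vrss
    best = max(
        range(len(usable_grid)),
        key=lambda i: (-score[i], usable_grid[i]),
    )
    return SelectionReport(
        lambda_grid=usable_grid,
        mean_bic=mean_bic,
        std_bic=std_bic,
        mean_train_rss=mean_rss,
        mean_validation_rss=mean_vrss,
        mean_validation_pearson=mean_vr,
        mean_n_nonzero_w=mean_nnz,
        lambda_star=usable_grid[best],
        criterion=criterion,
        split=split,
        fits=fits_by_lambda,
    )


def evaluate_per_fit(
    fits: list[FitResult], dataset: ResponseDataset, step_h: float = 0.2
) -> tuple[list[float], list[float]]:
    """Per-fit validation RSS (per data point) and Pearson r."""
    from .model import simulate_conditions

    rss_list, r_list = [], []
    for r in fits:
        pred = simulate_conditions(r.params, dataset.design, dataset.times, step_h=step_h)
        rss_list.append(
            masked_rss(pred, dataset.values, dataset.mask) / max(dataset.n_measured, 1)
        )
        r_list.append(pearson(pred[dataset.mask], dataset.values[dataset.mask]))
    return rss_list, r_list
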