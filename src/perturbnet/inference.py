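"""Network inference: L1-regularized least squares on simulated trajectories.

The loss for one model is

    RSS(Theta) + lambda * sum_{i, j != i} |w_ij|

with RSS summed over the measured (node, condition, time) entries only.
Minimization is first-order (Adam with adaptive moments) on all free
parameters Theta = (eps, alpha, W, D, delta); positivity of eps, alpha and
delta is enforced by optimizing their logarithms.  Sparsity comes from
per-step cropping: after every update (past a short burn-in) interaction
parameters with |w_ij| < 0.01 and drug effects with |d_il| < 0.05 are set to
exactly zero.  A run that ends with an entirely zero W has failed and is
discarded.

Gradients are exact for the discretized trajectories: a reverse-mode
(discrete-adjoint) sweep through the fixed-step RK2 integrator, computed in
closed form and batched over ensemble members (see :mod:`perturbnet._ode`).
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, replace

import numpy as np

from . import _ode
from .dataset import ResponseDataset
from .design import dose_matrix
from .params import ModelParameters

CROP_W = 0.01
CROP_D = 0.05


@dataclass
class FitConfig:
    """Optimization settings.

    ``step_h`` is the RK2 step used inside the fit (coarser than the
    simulation default: the loss is defined on — and differentiated through —
    this discretization, so a modest step costs accuracy only through the
    trajectory bias, which is far below the measurement noise for tame
    networks).
    """

    lambda_: float = 0.0
    learning_rate: float = 0.01
    max_iterations: int = 10_000
    max_walltime_s: float | None = None
    crop_w: float = CROP_W
    crop_d: float = CROP_D
    crop_burn_in: int = 100
    seed: int = 0
    init_scale: float = 0.1
    step_h: float = 0.2
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda must be non-negative")
        if self.crop_w <= 0 or self.crop_d <= 0:
            raise ValueError("crop thresholds must be positive")


@dataclass
class FitResult:
    """One fitted network model plus its training diagnostics."""

    params: ModelParameters
    rss_train: float
    penalty: float
    n_nonzero_w: int
    converged: bool
    failed: bool
    seed: int
    lambda_: float
    n_iterations: int

    @property
    def total_loss(self) -> float:
        return self.rss_train + self.penalty


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def masked_rss(pred: np.ndarray, values: np.ndarray, mask: np.ndarray) -> float:
    """Residual sum of squares over measured entries only."""
    r = np.where(mask, pred - np.where(mask, values, 0.0), 0.0)
    return float(np.sum(r * r))


def l1_penalty(params: ModelParameters, lambda_: float) -> float:
    return float(lambda_ * np.sum(np.abs(params.W)))


def loss(
    params: ModelParameters,
    dataset: ResponseDataset,
    lambda_: float,
    step_h: float = 0.2,
) -> tuple[float, float, float]:
    """(rss, penalty, total) of a parameter set on a dataset."""
    from .model import simulate_conditions

    _check_dataset(dataset, params.node_names)
    pred = simulate_conditions(params, dataset.design, dataset.times, step_h=step_h)
    rss = masked_rss(pred, dataset.values, dataset.mask)
    pen = l1_penalty(params, lambda_)
    return rss, pen, rss + pen


def _check_dataset(dataset: ResponseDataset, node_names: list[str]) -> None:
    if dataset.design is None:
        raise ValueError("dataset has no attached experimental design")
    if list(dataset.nodes) != list(node_names):
        raise ValueError("dataset nodes do not match model nodes")


# ---------------------------------------------------------------------------
# batched fitting
# ---------------------------------------------------------------------------

class _Batch:
    """Free parameters for M models, with structural masks and Adam state."""

    def __init__(
        self, M: int, n_meas: int, n_phen: int, n_drug: int, rng_seeds: list[int],
        init_scale: float,
    ):
        self.M, self.N, self.L = M, n_meas, n_drug
        self.n_phen = n_phen
        self.wmask = ModelParameters.interaction_mask(n_meas, n_phen)
        self.dmask = ModelParameters.drug_mask(n_meas, n_phen, n_drug)
        W = np.zeros((M, n_meas, n_meas))
        D = np.zeros((M, n_meas, n_drug))
        for m, s in enumerate(rng_seeds):
            rng = np.random.default_rng(s)
            W[m][self.wmask] = rng.normal(0.0, init_scale, size=self.wmask.sum())
            D[m][self.dmask] = rng.normal(0.0, init_scale, size=self.dmask.sum())
        self.W, self.D = W, D
        self.rho_eps = np.zeros((M, n_meas))     # eps = exp(rho) -> init 1
        self.rho_alpha = np.zeros((M, n_meas))
        self.rho_delta = np.full((M, n_drug), np.log(0.5))
        self._adam = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in self.arrays().items()}
        self._t = 0

    def arrays(self) -> dict[str, np.ndarray]:
        return {
            "W": self.W,
            "D": self.D,
            "rho_eps": self.rho_eps,
            "rho_alpha": self.rho_alpha,
            "rho_delta": self.rho_delta,
        }

    @property
    def eps(self) -> np.ndarray:
        return np.exp(self.rho_eps)

    @property
    def alpha(self) -> np.ndarray:
        return np.exp(self.rho_alpha)

    @property
    def delta(self) -> np.ndarray:
        return np.exp(self.rho_delta)

    def adam_step(self, grads: dict[str, np.ndarray], cfg: FitConfig) -> None:
        self._t += 1
        b1, b2, eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps
        corr1 = 1.0 - b1**self._t
        corr2 = 1.0 - b2**self._t
        for k, v in self.arrays().items():
            g = grads[k]
            m, s = self._adam[k]
            m *= b1
            m += (1 - b1) * g
            s *= b2
            s += (1 - b2) * g * g
            v -= cfg.learning_rate * (m / corr1) / (np.sqrt(s / corr2) + eps)
        # structural zeros must survive the update
        self.W[:, ~self.wmask] = 0.0
        self.D[:, ~self.dmask] = 0.0

    def crop(self, cfg: FitConfig) -> None:
        self.W[np.abs(self.W) < cfg.crop_w] = 0.0
        self.D[np.abs(self.D) < cfg.crop_d] = 0.0

    def to_params(
        self, m: int, node_names: list[str], drug_names: list[str]
    ) -> ModelParameters:
        return ModelParameters(
            node_names=list(node_names),
            n_phen=self.n_phen,
            drug_names=list(drug_names),
            eps=self.eps[m],
            alpha=self.alpha[m],
            W=self.W[m].copy(),
            D=self.D[m].copy(),
            delta=self.delta[m],
        )


def _batch_loss_and_grads(
    batch: _Batch,
    doses: np.ndarray,
    values: np.ndarray,
    mask: np.ndarray,
    grid: _ode.TimeGrid,
    lambdas: np.ndarray,
):
    """Per-model (rss, penalty) and gradients of the total loss."""
    eps, alpha, delta = batch.eps, batch.alpha, batch.delta
    B, A = _ode.drive_matrix(batch.D, delta, doses)
    X_out, cache = _ode.rk2_forward(
        eps, alpha, batch.W, B, None, grid, store=True, check=False
    )
    R = np.where(mask[None], X_out - np.where(mask, values, 0.0)[None], 0.0)
    rss = np.einsum("mnct,mnct->m", R, R)
    pen = lambdas * np.abs(batch.W).sum(axis=(1, 2))
    d_eps, d_alpha, dW, dB = _ode.rk2_backward(
        eps, alpha, batch.W, B, None, grid, cache, 2.0 * R
    )
    dD, d_delta = _ode.drive_backward(batch.D, delta, doses, A, dB)
    dW += lambdas[:, None, None] * np.sign(batch.W)
    dW[:, ~batch.wmask] = 0.0
    dD[:, ~batch.dmask] = 0.0
    grads = {
        "W": dW,
        "D": dD,
        "rho_eps": d_eps * eps,
        "rho_alpha": d_alpha * alpha,
        "rho_delta": d_delta * delta,
    }
    return rss, pen, grads


def fit_batch(
    dataset: ResponseDataset,
    lambdas: np.ndarray,
    seeds: list[int],
    config: FitConfig,
) -> list[FitResult]:
    """Fit several models simultaneously (shared data, per-model lambda/seed).

    Ensemble members are independent optimizations; batching them through the
    same vectorized integrator sweep is purely a speed device.
    """
    _check_dataset(dataset, dataset.nodes)
    lambdas = np.asarray(lambdas, dtype=float)
    M = len(seeds)
    if lambdas.shape != (M,):
        raise ValueError("one lambda per seed required")
    n_phen = dataset.n_phen
    drug_names = sorted({d for c in dataset.design for d, _ in c.doses})
    if not drug_names:
        raise ValueError("design has no perturbed conditions")
    doses = dose_matrix(dataset.design, drug_names)
    grid = _ode.build_grid(dataset.times, config.step_h)
    if dataset.mask.any(axis=(1, 2)).sum() != len(dataset.nodes):
        raise ValueError("every node needs at least one measured entry")

    batch = _Batch(M, len(dataset.nodes), n_phen, len(drug_names), seeds,
                   config.init_scale)
    values, mask = dataset.values, dataset.mask
    t_start = _time.monotonic()
    n_iter = 0
    rss = np.full(M, np.inf)
    pen = np.zeros(M)
    diverged = np.zeros(M, dtype=bool)
    for n_iter in range(1, config.max_iterations + 1):
        try:
            rss_i, pen_i, grads = _batch_loss_and_grads(
                batch, doses, values, mask, grid, lambdas
            )
        except FloatingPointError:
            diverged[:] = ~np.isfinite(batch.W).all(axis=(1, 2))
            break
        bad = ~np.isfinite(rss_i)
        if bad.any():
            diverged |= bad
            for k in grads:
                grads[k][bad] = 0.0
        rss, pen = np.where(bad, rss, rss_i), pen_i
        batch.adam_step(grads, config)
        if n_iter > config.crop_burn_in:
            batch.crop(config)
        if (
            config.max_walltime_s is not None
            and _time.monotonic() - t_start > config.max_walltime_s
        ):
            break

    # final evaluation at the cropped parameters
    try:
        rss_f, pen_f, _ = _batch_loss_and_grads(
            batch, doses, values, mask, grid, lambdas
        )
        ok = np.isfinite(rss_f)
        rss = np.where(ok, rss_f, rss)
        pen = np.where(ok, pen_f, pen)
        diverged |= ~ok
    except FloatingPointError:
        diverged[:] = True

    results = []
    for m, seed in enumerate(seeds):
        params = batch.to_params(m, dataset.nodes, drug_names)
        nz = params.n_nonzero_w()
        failed = bool(diverged[m] or nz == 0)
        results.append(
            FitResult(
                params=params,
                rss_train=float(rss[m]),
                penalty=float(pen[m]),
                n_nonzero_w=nz,
                converged=not failed and n_iter >= config.max_iterations,
                failed=failed,
                seed=seed,
                lambda_=float(lambdas[m]),
                n_iterations=n_iter,
            )
        )
    return results


def fit(dataset: ResponseDataset, config: FitConfig) -> FitResult:
    """Single gradient-descent run; never raises on divergence — a divergent
    or all-zero-W run comes back with ``failed=True``."""
    return fit_batch(
        dataset, np.array([config.lambda_]), [config.seed], config
    )[0]


def fit_ensemble(
    dataset: ResponseDataset,
    lambda_: float,
    n_models: int,
    base_seed: int = 0,
    config: FitConfig | None = None,
    retry_factor: int = 3,
) -> list[FitResult]:
    """``n_models`` independent fits with distinct seeds; failed runs (all
    w_ij = 0 or divergent) are discarded and replaced up to a retry cap."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    cfg = replace(config or FitConfig(), lambda_=lambda_)
    max_fits = retry_factor * n_models
    results: list[FitResult] = []
    next_seed = base_seed
    attempted = 0
    while len(results) < n_models and attempted < max_fits:
        want = min(n_models - len(results), max_fits - attempted)
        seeds = [next_seed + i for i in range(want)]
        next_seed += want
        attempted += want
        out = fit_batch(dataset, np.full(want, lambda_), seeds, cfg)
        results.extend(r for r in out if not r.failed)
    if len(results) < n_models:
        raise RuntimeError(
            f"only {len(results)}/{n_models} fits succeeded after "
            f"{attempted} attempts (failure rate "
            f"{1 - len(results) / attempted:.0%})"
        )
    return results[:n_models]
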