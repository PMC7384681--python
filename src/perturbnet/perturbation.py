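"""In-silico perturbation engine: step-concentration inhibition of molecular
nodes, Hill/EC50 dose-response fits, exhaustive single + pairwise combination
screening over a model ensemble, and target ranking.

An in-silico inhibitor of node *i* is a constant ``-c_i`` added inside the
tanh argument of node *i*'s equation for all t >= 0 (a perfectly specific
step inhibitor).  The phenotype change at the 72 h horizon, as a function of
the inhibitor concentration, is summarized by the Hill curve

    x(c) = E1 * (1 - 1 / (1 + (c / ec50)^n)),    x(0) = 0,

whose parameters (asymptotic effect E1, half-effect concentration EC50 and
Hill coefficient n) are estimated per node from the ensemble-mean response.
Pairwise screens dose each node at its own fitted EC50.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import least_squares

from .design import PerturbationCondition
from .model import simulate_conditions
from .params import ModelParameters

HORIZON_H = 72.0
SCREEN_STEP_H = 0.05
#: |E1| below this is reported as "no effect" (2% of a one-unit log2 change).
NO_EFFECT_E1 = 0.02
DEFAULT_DOSE_GRID = tuple(np.geomspace(0.01, 100.0, 12))

_NO_DRUGS = PerturbationCondition.from_doses("none", {})


@dataclass
class InhibitionSpec:
    """Step-inhibitor concentrations per targeted molecular node."""

    targets: dict[str, float]
    horizon_h: float = HORIZON_H

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.targets.values()):
            raise ValueError("inhibitor concentrations must be non-negative")


def _pert_matrix(
    params: ModelParameters, target_sets: list[dict[str, float]]
) -> np.ndarray:
    """Constant tanh-argument input (N, C): -c on targeted molecular rows."""
    idx = {n: i for i, n in enumerate(params.molecular_names)}
    P = np.zeros((params.n_meas, len(target_sets)))
    for c, targets in enumerate(target_sets):
        for node, conc in targets.items():
            if node not in idx:
                raise ValueError(
                    f"{node!r} is not a molecular node (phenotypes cannot be "
                    "directly inhibited)"
                )
            P[idx[node], c] = -float(conc)
    return P


def simulate_inhibition(
    params: ModelParameters,
    spec: InhibitionSpec,
    step_h: float = SCREEN_STEP_H,
) -> dict[str, float]:
    """Phenotype changes (log2 vs unperturbed control) at the horizon under
    the given step inhibition; no drugs are applied unless also specified."""
    P = _pert_matrix(params, [spec.targets])
    x = simulate_conditions(
        params, [_NO_DRUGS], np.array([spec.horizon_h]), step_h=step_h,
        pert_input=P,
    )[:, 0, 0]
    return {name: float(x[params.n_molec + i]) for i, name in enumerate(params.phenotype_names)}


def _batch_phenotype_response(
    ensemble: list[ModelParameters],
    target_sets: list[dict[str, float]],
    horizon_h: float = HORIZON_H,
    step_h: float = SCREEN_STEP_H,
) -> np.ndarray:
    """Ensemble phenotype responses, shape (n_models, n_phen, n_sets).

    All target sets are integrated as one batched condition axis per model;
    models are stacked when their shapes agree.
    """
    from . import _ode

    ref = ensemble[0]
    same = all(
        p.node_names == ref.node_names and p.n_phen == ref.n_phen for p in ensemble
    )
    if not same:
        raise ValueError("ensemble members must share the node set")
    P = _pert_matrix(ref, target_sets)
    M, N, C = len(ensemble), ref.n_meas, len(target_sets)
    eps = np.stack([p.eps for p in ensemble])
    alpha = np.stack([p.alpha for p in ensemble])
    W = np.stack([p.W for p in ensemble])
    B = np.zeros((M, N, C))
    grid = _ode.build_grid(np.array([horizon_h]), step_h)
    X_out, _ = _ode.rk2_forward(eps, alpha, W, B, P[None, :, :], grid)
    return X_out[:, ref.n_molec:, :, 0]


@dataclass
class HillFit:
    """Fitted Hill dose-response parameters for one node and phenotype."""

    e1: float
    ec50: float
    hill_n: float
    residual: float
    no_effect: bool

    def curve(self, c: np.ndarray) -> np.ndarray:
        return hill_curve(np.asarray(c, dtype=float), self.e1, self.ec50, self.hill_n)


def hill_curve(c: np.ndarray, e1: float, ec50: float, n: float) -> np.ndarray:
    """``E1 (1 - 1/(1 + (c/ec50)^n))`` with the zero-dose response pinned to 0."""
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, c / ec50, 0.0)
        return e1 * (1.0 - 1.0 / (1.0 + ratio**n))


def fit_hill(
    doses: np.ndarray,
    responses: np.ndarray,
    n_bounds: tuple[float, float] = (0.2, 8.0),
    no_effect_threshold: float = NO_EFFECT_E1,
) -> HillFit:
    """Nonlinear least-squares Hill fit with E2 = 0, bounded Hill slope and
    multi-start initial guesses; flat curves come back flagged ``no_effect``
    with an undefined (NaN) EC50."""
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(doses) < 4 or len(doses) != len(responses):
        raise ValueError("need >= 4 (dose, response) pairs")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    e1_guess = responses[np.argmax(np.abs(responses))]
    if abs(e1_guess) < no_effect_threshold:
        return HillFit(
            e1=float(e1_guess), ec50=float("nan"), hill_n=float("nan"),
            residual=float(np.sum(responses**2)), no_effect=True,
        )
    lo, hi = doses.min(), doses.max()
    span = hi / lo
    bounds = (
        [-np.inf, lo / span, n_bounds[0]],
        [np.inf, hi * span, n_bounds[1]],
    )

    def resid(theta):
        return hill_curve(doses, *theta) - responses

    best = None
    for ec0 in (np.sqrt(lo * hi), lo * span**0.25, hi / span**0.25):
        for n0 in (1.0, 2.0):
            x0 = [float(e1_guess), float(ec0), n0]
            sol = least_squares(
                resid, x0, bounds=bounds, xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
            if best is None or sol.cost < best.cost:
                best = sol
    e1, ec50, n = best.x
    return HillFit(
        e1=float(e1),
        ec50=float(ec50),
        hill_n=float(n),
        residual=float(2 * best.cost),
        no_effect=bool(abs(e1) < no_effect_threshold),
    )


@dataclass
class DoseResponse:
    """Ensemble-mean dose-response curves of one inhibited node."""

    node: str
    doses: np.ndarray
    mean_response: dict[str, np.ndarray]  # phenotype -> curve
    fits: dict[str, HillFit]              # phenotype -> Hill fit


def dose_response(
    ensemble: list[ModelParameters],
    node: str,
    dose_grid: np.ndarray | None = None,
    horizon_h: float = HORIZON_H,
    step_h: float = SCREEN_STEP_H,
) -> DoseResponse:
    """Simulate the node's inhibition over a dose grid, average the phenotype
    responses over the ensemble and fit a Hill curve per phenotype."""
    doses = np.asarray(DEFAULT_DOSE_GRID if dose_grid is None else dose_grid, dtype=float)
    if len(doses) < 6 or doses.max() / doses.min() < 10:
        raise ValueError("dose grid must span >= 1 decade with >= 6 points")
    resp = _batch_phenotype_response(
        ensemble, [{node: d} for d in doses], horizon_h, step_h
    ).mean(axis=0)  # (n_phen, n_dose)
    phen = ensemble[0].phenotype_names
    mean_response = {p: resp[i] for i, p in enumerate(phen)}
    fits = {p: fit_hill(doses, resp[i]) for i, p in enumerate(phen)}
    return DoseResponse(node=node, doses=doses, mean_response=mean_response, fits=fits)


def estimate_ec50_map(
    ensemble: list[ModelParameters],
    phenotype: str,
    dose_grid: np.ndarray | None = None,
    nodes: list[str] | None = None,
    horizon_h: float = HORIZON_H,
    step_h: float = SCREEN_STEP_H,
) -> tuple[dict[str, float], dict[str, HillFit]]:
    """EC50 per molecular node for one phenotype (NaN where no effect).

    All (node, dose) inhibitions are simulated in one batched sweep.
    """
    ref = ensemble[0]
    nodes = list(ref.molecular_names) if nodes is None else nodes
    doses = np.asarray(DEFAULT_DOSE_GRID if dose_grid is None else dose_grid, dtype=float)
    sets = [{n: d} for n in nodes for d in doses]
    resp = _batch_phenotype_response(ensemble, sets, horizon_h, step_h).mean(axis=0)
    p_idx = ref.phenotype_names.index(phenotype)
    curves = resp[p_idx].reshape(len(nodes), len(doses))
    fits = {n: fit_hill(doses, curves[i]) for i, n in enumerate(nodes)}
    ec50 = {n: f.ec50 for n, f in fits.items()}
    return ec50, fits


@dataclass
class ScreenResult:
    """Ensemble-mean phenotype change for every single and pairwise
    inhibition, as a symmetric matrix (diagonal = single-node)."""

    phenotype: str
    nodes: list[str]
    matrix: np.ndarray  # (N, N)
    doses: dict[str, float]
    n_models: int

    @property
    def n_pair_conditions(self) -> int:
        """Ordered pair count N (N - 1) — both orientations reported."""
        n = len(self.nodes)
        return n * (n - 1)

    @property
    def n_simulated_responses(self) -> int:
        """Pair conditions times ensemble size, per phenotype."""
        return self.n_pair_conditions * self.n_models


def screen_counts(n_nodes: int, n_models: int) -> dict[str, int]:
    """Pure bookkeeping of the combination screen's size."""
    pairs = n_nodes * (n_nodes - 1)
    return {
        "pair_conditions": pairs,
        "single_conditions": n_nodes,
        "responses_per_phenotype": pairs * n_models,
    }


def combinatorial_screen(
    ensemble: list[ModelParameters],
    ec50_map: dict[str, float],
    phenotype: str,
    fallback_dose: float | None = None,
    horizon_h: float = HORIZON_H,
    step_h: float = SCREEN_STEP_H,
    nodes: list[str] | None = None,
) -> ScreenResult:
    """Simulate every unordered pair (and every single node) with each node
    dosed at its own EC50; entries are ensemble means of the phenotype change
    at the horizon.  The matrix is symmetric because the dosing rule does not
    depend on pair order."""
    ref = ensemble[0]
    nodes = list(ref.molecular_names) if nodes is None else list(nodes)
    doses = {}
    missing = []
    for n in nodes:
        d = ec50_map.get(n, float("nan"))
        if not np.isfinite(d) or d <= 0:
            if fallback_dose is None:
                missing.append(n)
            else:
                d = fallback_dose
        doses[n] = d
    if missing:
        raise ValueError(f"no EC50 and no fallback dose for node(s) {missing}")
    singles = [{n: doses[n]} for n in nodes]
    pairs = list(combinations(range(len(nodes)), 2))
    pair_sets = [
        {nodes[i]: doses[nodes[i]], nodes[j]: doses[nodes[j]]} for i, j in pairs
    ]
    resp = _batch_phenotype_response(ensemble, singles + pair_sets, horizon_h, step_h)
    p_idx = ref.phenotype_names.index(phenotype)
    mean = resp[:, p_idx, :].mean(axis=0)
    N = len(nodes)
    mat = np.zeros((N, N))
    np.fill_diagonal(mat, mean[:N])
    for k, (i, j) in enumerate(pairs):
        mat[i, j] = mat[j, i] = mean[N + k]
    return ScreenResult(
        phenotype=phenotype, nodes=nodes, matrix=mat, doses=doses,
        n_models=len(ensemble),
    )


@dataclass
class RankedCombination:
    node_a: str
    node_b: str
    effect: float


def rank_targets(
    screen: ScreenResult,
    direction: str = "auto",
    top_unique: int = 20,
    include_singles: bool = False,
) -> list[RankedCombination]:
    """Walk the combination ranking (best predicted effect first) until
    ``top_unique`` distinct nodes have been collected.

    ``direction='min'`` ranks most-negative first (cell growth reduction),
    ``'max'`` most-positive first (apoptosis increase); ``'auto'`` picks from
    the screen's phenotype name.  Ties break lexicographically on the node
    pair.
    """
    if direction == "auto":
        direction = "max" if "apopt" in screen.phenotype.lower() else "min"
    if direction not in {"min", "max"}:
        raise ValueError("direction must be 'min', 'max' or 'auto'")
    sign = 1.0 if direction == "min" else -1.0
    combos = []
    N = len(screen.nodes)
    for i in range(N):
        rng_j = range(i, N) if include_singles else range(i + 1, N)
        for j in rng_j:
            combos.append(
                (
                    sign * screen.matrix[i, j],
                    screen.nodes[i],
                    screen.nodes[j],
                )
            )
    combos.sort(key=lambda t: (t[0], t[1], t[2]))
    seen: set[str] = set()
    out = []
    for val, a, b in combos:
        out.append(RankedCombination(node_a=a, node_b=b, effect=sign * val))
        seen.update((a, b))
        if len(seen) >= top_unique:
            break
    return out
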