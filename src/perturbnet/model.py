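"""Simulation of the coupled molecular/phenotypic/drug-node system.

Public entry points operate on a single :class:`~perturbnet.params.ModelParameters`
and one or more perturbation conditions; the batched numerics live in
:mod:`perturbnet._ode`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _ode
from .design import PerturbationCondition, dose_matrix
from .params import ModelParameters

#: default fixed RK2 step (hours); small enough that trajectories of tame
#: networks (decay rates up to ~2/h) agree with an adaptive reference
#: integrator to well below 1e-3 absolute.
DEFAULT_STEP_H = 0.01


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


def drug_input(
    delta: float | np.ndarray, c: float | np.ndarray, t: float | np.ndarray
) -> np.ndarray:
    """Closed-form drug-node value ``tanh(delta c) (1 - exp(-10 t))``.

    The drug node relaxes with fixed rate 10/h toward the saturated level
    ``tanh(delta c)``; the rate is a modeling constant, never fitted.
    """
    return np.tanh(np.asarray(delta, dtype=float) * np.asarray(c, dtype=float)) * (
        _ode.drug_gate(t)
    )


@dataclass
class Trajectory:
    """Simulated node and drug-node time courses for one condition."""

    times: np.ndarray
    node_names: list[str]
    values: np.ndarray       # (N, T) log2 ratio to control
    drug_names: list[str]
    drug_values: np.ndarray  # (L, T)


def _prepare_inputs(
    params: ModelParameters,
    conditions: list[PerturbationCondition],
    pert_input: np.ndarray | None = None,
):
    doses = dose_matrix(conditions, params.drug_names)
    B, _ = _ode.drive_matrix(
        params.D[None, :, :], params.delta[None, :], doses
    )
    P = None
    if pert_input is not None:
        P = np.asarray(pert_input, dtype=float)[None, :, :]
    return doses, B, P


def simulate_conditions(
    params: ModelParameters,
    conditions: list[PerturbationCondition],
    t_grid: np.ndarray,
    step_h: float = DEFAULT_STEP_H,
    pert_input: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate several conditions at once; returns values (N, C, T).

    ``pert_input``, when given (shape (N, C)), is a constant term added
    inside the tanh of each node — the in-silico step-inhibitor mechanism
    (a negative entry inhibits the node).
    """
    grid = _ode.build_grid(np.asarray(t_grid, dtype=float), step_h)
    doses, B, P = _prepare_inputs(params, conditions, pert_input)
    try:
        X_out, _ = _ode.rk2_forward(
            params.eps[None, :], params.alpha[None, :], params.W[None, :, :],
            B, P, grid,
        )
    except FloatingPointError as exc:
        raise IntegrationError(str(exc)) from None
    if not np.all(np.isfinite(X_out)):
        bad = np.nonzero(~np.isfinite(X_out))[1]
        raise IntegrationError(
            f"non-finite trajectory for node {params.node_names[bad[0]]}"
        )
    return X_out[0]


def simulate(
    params: ModelParameters,
    condition: PerturbationCondition,
    t_grid: np.ndarray,
    step_h: float = DEFAULT_STEP_H,
) -> Trajectory:
    """Integrate one condition and return node + drug-node trajectories."""
    t_grid = np.asarray(t_grid, dtype=float)
    values = simulate_conditions(params, [condition], t_grid, step_h)[:, 0, :]
    c = condition.dose_vector(params.drug_names)
    drug_values = drug_input(
        params.delta[:, None], c[:, None], t_grid[None, :]
    )
    return Trajectory(
        times=t_grid,
        node_names=list(params.node_names),
        values=values,
        drug_names=list(params.drug_names),
        drug_values=drug_values,
    )


def steady_state(
    params: ModelParameters,
    condition: PerturbationCondition,
    horizon_h: float = 72.0,
    step_h: float = DEFAULT_STEP_H,
    residual_tol: float = 1e-3,
    pert_input: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """State at a long horizon plus the fixed-point residual.

    Returns ``(x, residual, converged)`` where
    ``residual_i = |eps_i tanh(z_i) - alpha_i x_i|`` evaluated at the horizon;
    ``converged`` is False when any residual exceeds ``residual_tol``
    (the system may still be drifting or oscillating).
    """
    x = simulate_conditions(
        params, [condition], np.array([horizon_h]), step_h, pert_input
    )[:, 0, 0]
    c = condition.dose_vector(params.drug_names)
    u = drug_input(params.delta, c, horizon_h)
    z = params.W @ x + params.D @ u
    if pert_input is not None:
        z = z + np.asarray(pert_input, dtype=float)[:, 0]
    residual = np.abs(params.eps * np.tanh(z) - params.alpha * x)
    return x, residual, bool(np.all(residual <= residual_tol))


def trajectory_to_frame(traj: Trajectory):
    """Tidy frame (node, time_h, value) for a :class:`Trajectory`."""
    import pandas as pd

    n, t = np.meshgrid(
        np.arange(len(traj.node_names)), np.arange(len(traj.times)), indexing="ij"
    )
    return pd.DataFrame(
        {
            "node": np.asarray(traj.node_names, dtype=object)[n.ravel()],
            "time_h": traj.times[t.ravel()],
            "value": traj.values[n.ravel(), t.ravel()],
        }
    )
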