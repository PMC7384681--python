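"""Parameter container for the coupled molecular/phenotypic/drug-node model.

The network couples three kinds of nodes:

* molecular nodes (protein and phospho-protein levels, log2 ratio to control),
* phenotypic nodes (cell growth and apoptosis readouts, log2 ratio to control),
* drug nodes (dimensionless perturbation inputs with a fixed fast rate).

Molecular node dynamics::

    dx_i/dt = eps_i * tanh( sum_j w_ij x_j + sum_l d_il u_l(t) ) - alpha_i x_i

Phenotypic nodes follow the same law but receive only molecular inputs (no
drug term) and emit no edges.  Drug nodes have the closed-form solution
``u_l(t) = tanh(delta_l c_l) (1 - exp(-10 t))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class ModelParameters:
    """All inferred quantities of one network model.

    Attributes
    ----------
    node_names
        Measured node names, molecular nodes first, then ``n_phen``
        phenotypic nodes.
    n_phen
        Number of phenotypic nodes (trailing entries of ``node_names``).
    drug_names
        Drug (perturbation input) names.
    eps
        Dynamic-range prefactors ``eps_i > 0`` (log2-units/h), shape (N,).
    alpha
        Decay rates ``alpha_i > 0`` (1/h), shape (N,).
    W
        Interaction matrix ``w_ij`` (effect of node j on node i), shape
        (N, N).  Zero diagonal; phenotype columns are identically zero
        (phenotypes emit no edges).
    D
        Drug-effect matrix ``d_il``, shape (N, L); phenotype rows are zero.
    delta
        Effective drug impacts ``delta_l >= 0``, shape (L,).
    """

    node_names: list[str]
    n_phen: int
    drug_names: list[str]
    eps: np.ndarray
    alpha: np.ndarray
    W: np.ndarray
    D: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.eps = np.asarray(self.eps, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.validate()

    # -- basic shape accessors -------------------------------------------
    @property
    def n_meas(self) -> int:
        return len(self.node_names)

    @property
    def n_molec(self) -> int:
        return self.n_meas - self.n_phen

    @property
    def n_drug(self) -> int:
        return len(self.drug_names)

    @property
    def molecular_names(self) -> list[str]:
        return self.node_names[: self.n_molec]

    @property
    def phenotype_names(self) -> list[str]:
        return self.node_names[self.n_molec:]

    # -- structural masks -------------------------------------------------
    @staticmethod
    def interaction_mask(n_meas: int, n_phen: int) -> np.ndarray:
        """Boolean mask of structurally allowed W entries.

        Allowed: off-diagonal entries whose source (column) is molecular.
        Phenotype nodes never act as sources; self-interactions are excluded.
        """
        n_molec = n_meas - n_phen
        mask = np.zeros((n_meas, n_meas), dtype=bool)
        mask[:, :n_molec] = True
        np.fill_diagonal(mask, False)
        return mask

    @staticmethod
    def drug_mask(n_meas: int, n_phen: int, n_drug: int) -> np.ndarray:
        """Boolean mask of allowed D entries: molecular rows only."""
        n_molec = n_meas - n_phen
        mask = np.zeros((n_meas, n_drug), dtype=bool)
        mask[:n_molec, :] = True
        return mask

    def validate(self) -> None:
        n, p, m = self.n_meas, self.n_phen, self.n_drug
        if not (0 <= p <= n):
            raise ValueError(f"n_phen={p} out of range for {n} nodes")
        if self.eps.shape != (n,) or self.alpha.shape != (n,):
            raise ValueError("eps/alpha must have one entry per measured node")
        if self.W.shape != (n, n):
            raise ValueError(f"W must be {(n, n)}, got {self.W.shape}")
        if self.D.shape != (n, m):
            raise ValueError(f"D must be {(n, m)}, got {self.D.shape}")
        if self.delta.shape != (m,):
            raise ValueError("delta must have one entry per drug")
        if np.any(self.eps <= 0) or np.any(self.alpha <= 0):
            raise ValueError("eps and alpha must be strictly positive")
        if np.any(self.delta < 0):
            raise ValueError("delta must be non-negative")
        wmask = self.interaction_mask(n, p)
        if np.any(self.W[~wmask] != 0):
            raise ValueError(
                "W has entries outside the allowed structure "
                "(diagonal or phenotype source columns)"
            )
        dmask = self.drug_mask(n, p, m)
        if np.any(self.D[~dmask] != 0):
            raise ValueError("D has non-zero entries in phenotype rows")

    # -- bookkeeping -------------------------------------------------------
    def n_nonzero_w(self) -> int:
        return int(np.count_nonzero(self.W))

    def n_nonzero_params(self) -> int:
        """Count of non-zero model parameters (k in the BIC).

        Non-zero entries of W and D plus all eps, alpha, delta (the latter
        are never cropped, so they always count).
        """
        return (
            int(np.count_nonzero(self.W))
            + int(np.count_nonzero(self.D))
            + 2 * self.n_meas
            + self.n_drug
        )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "node_names": list(self.node_names),
            "n_phen": int(self.n_phen),
            "drug_names": list(self.drug_names),
            "eps": self.eps.tolist(),
            "alpha": self.alpha.tolist(),
            "W": self.W.tolist(),
            "D": self.D.tolist(),
            "delta": self.delta.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(
            node_names=list(d["node_names"]),
            n_phen=int(d["n_phen"]),
            drug_names=list(d["drug_names"]),
            eps=np.array(d["eps"], dtype=float),
            alpha=np.array(d["alpha"], dtype=float),
            W=np.array(d["W"], dtype=float),
            D=np.array(d["D"], dtype=float),
            delta=np.array(d["delta"], dtype=float),
        )

    def to_json(self, path: str | Path) -> None:
        from .io_utils import atomic_write_text

        atomic_write_text(Path(path), json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
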