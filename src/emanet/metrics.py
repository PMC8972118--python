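"""Node centrality and overall connectivity of a temporal network.

Out-strength of node j sums the absolute weights of edges leaving j
(column j of the coefficient matrix, self-loop excluded); in-strength sums
the absolute weights of edges entering j (row j). Absolute values are used
because temporal networks carry negative edges and signed sums would let
them cancel; a ``signed`` flag gives the literal signed reading. Strengths
use *all* edges, significant or not. Overall connectivity is the sum of
absolute weights of the full matrix, self-loops included by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CentralityTable", "strength_centrality", "global_connectivity"]


@dataclass
class CentralityTable:
    """Per-node in-/out-strength, raw and standardized (z across nodes)."""

    table: pd.DataFrame  # node, in_strength, out_strength, *_z

    def __getitem__(self, col):
        return self.table[col]

    def as_vector(self) -> np.ndarray:
        """Stacked (in_strengths..., out_strengths...) in node order —
        the 2k-vector the permutation test compares between groups."""
        return np.concatenate(
            [self.table["in_strength"].to_numpy(), self.table["out_strength"].to_numpy()]
        )


def _coef_matrix(network) -> tuple[np.ndarray, tuple]:
    if hasattr(network, "B"):
        return np.asarray(network.B, dtype=float), tuple(network.node_labels)
    B = np.asarray(network, dtype=float)
    return B, tuple(f"v{i+1}" for i in range(B.shape[0]))


def strength_centrality(
    network, include_self: bool = False, signed: bool = False
) -> CentralityTable:
    """In-/out-strength per node from all edges of the network.

    ``network`` is a TemporalNetwork or a bare (outcome x predictor)
    coefficient matrix. Standardized columns are z-scores across nodes
    (sample SD); when the SD is zero they are set to zero.
    """
    B, labels = _coef_matrix(network)
    W = B if signed else np.abs(B)
    k = W.shape[0]
    off = ~np.eye(k, dtype=bool) if not include_self else np.ones((k, k), dtype=bool)
    Wm = np.where(off, W, 0.0)
    in_strength = Wm.sum(axis=1)  # row j: edges entering outcome j
    out_strength = Wm.sum(axis=0)  # column j: edges leaving predictor j

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1) if k > 1 else 0.0
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    return CentralityTable(
        pd.DataFrame(
            {
                "node": list(labels),
                "in_strength": in_strength,
                "out_strength": out_strength,
                "in_strength_z": z(in_strength),
                "out_strength_z": z(out_strength),
            }
        )
    )


def global_connectivity(network, include_self: bool = True) -> float:
    """Sum of absolute edge weights over the whole network."""
    B, _ = _coef_matrix(network)
    if include_self:
        return float(np.abs(B).sum())
    k = B.shape[0]
    return float(np.abs(B[~np.eye(k, dtype=bool)]).sum())
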