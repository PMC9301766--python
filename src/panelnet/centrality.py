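"""Expected-influence centrality for directed panel networks.

Out-expected-influence (out-EI) of a node is the signed sum of its outgoing
edge weights — how much the node predicts the rest of the network at the next
wave.  In-EI is the signed sum of incoming weights — how predictable the node
is.  Sums are signed, not absolute: a negative edge reduces influence.
Autoregressive self-loops are excluded by default ("cross-lagged" expected
influence); a flag includes them.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CLPNetwork

__all__ = ["CentralityTable", "expected_influence", "rank_centrality"]


@dataclass
class CentralityTable:
    labels: list[str]
    out_ei: np.ndarray
    in_ei: np.ndarray
    out_ei_z: np.ndarray
    in_ei_z: np.ndarray
    include_autoregressive: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.labels,
                "out_ei": self.out_ei,
                "in_ei": self.in_ei,
                "out_ei_z": self.out_ei_z,
                "in_ei_z": self.in_ei_z,
            }
        )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def expected_influence(
    network: CLPNetwork, include_autoregressive: bool = False
) -> CentralityTable:
    """Raw and standardized out-EI/in-EI per node.

    out_ei[i] = sum_{j != i} B[i, j]; in_ei[j] = sum_{i != j} B[i, j];
    the diagonal is added to both when ``include_autoregressive``.
    """
    if network.p < 2:
        raise ValueError("need at least 2 nodes")
    M = network.B.copy()
    diag = np.diag(M).copy()
    np.fill_diagonal(M, 0.0)
    out_ei = M.sum(axis=1)
    in_ei = M.sum(axis=0)
    if include_autoregressive:
        out_ei = out_ei + diag
        in_ei = in_ei + diag
    return CentralityTable(
        labels=list(network.labels),
        out_ei=out_ei,
        in_ei=in_ei,
        out_ei_z=_zscore(out_ei),
        in_ei_z=_zscore(in_ei),
        include_autoregressive=include_autoregressive,
    )


def rank_centrality(table: CentralityTable, which: str = "in_ei") -> list[str]:
    """Node labels sorted by descending centrality, ties lexicographic."""
    if which not in ("in_ei", "out_ei"):
        raise ValueError("which must be 'in_ei' or 'out_ei'")
    values = table.in_ei if which == "in_ei" else table.out_ei
    order = sorted(zip(table.labels, values), key=lambda t: (-t[1], t[0]))
    return [lab for lab, _ in order]
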