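"""Redundancy screening of items by weighted topological overlap (wTO).

Two items that correlate strongly with each other *and* share the same
neighbourhood of correlations are near-duplicates measuring one construct;
keeping both would split an edge's variance across two nodes.  The screen
computes wTO on the absolute wave-1 correlation matrix, flags pairs with
unusually high overlap, and within each connected component of flagged pairs
retains the hub item (highest mean absolute correlation to all other items).

The exact variant in use (unsigned soft-threshold wTO, quantile flagging with
an absolute floor, hub retention) is a reconstruction of a standard
redundancy-reduction procedure; every piece is configurable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import PanelDataset

__all__ = ["WTOResult", "weighted_topological_overlap", "reduce_items"]


@dataclass
class WTOResult:
    labels: list[str]
    adjacency: np.ndarray
    wto: np.ndarray
    flagged_pairs: list[tuple[str, str, float]]
    kept: list[str]
    dropped: dict[str, str]  # label -> reason
    threshold: float
    excluded: list[str] = field(default_factory=list)  # constant columns


def weighted_topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """wTO matrix of a nonnegative symmetric adjacency with zero diagonal.

    omega_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i = sum_{u != i} a_iu.  For adjacency entries in [0, 1] the result
    is in [0, 1]; a complete unit-weight graph gives omega = 1 everywhere.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if A.min() < 0 or A.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1] "
                         "(use absolute correlations)")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    # (A @ A)_ij sums a_iu a_uj over all u; the u=i and u=j terms vanish
    # because the diagonal is zero.
    numerator = A @ A + A
    k = A.sum(axis=1)
    denominator = np.minimum.outer(k, k) + 1.0 - A
    omega = numerator / denominator
    np.fill_diagonal(omega, 0.0)
    return omega


def _components(q: int, edges: list[tuple[int, int]]) -> list[list[int]]:
    """Connected components of the flagged-pair graph (union-find)."""
    parent = list(range(q))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for x in range(q):
        groups.setdefault(find(x), []).append(x)
    return [g for g in groups.values() if len(g) > 1]


def reduce_items(
    data: PanelDataset,
    threshold_quantile: float = 0.95,
    correlation_kind: str = "spearman",
    min_overlap: float = 0.20,
) -> tuple[WTOResult, PanelDataset]:
    """Collapse redundant items before network estimation.

    The adjacency is the absolute pairwise-complete correlation of the
    wave-1 item scores (baseline, the fuller sample in a two-wave design).
    A pair is flagged when its wTO exceeds both the ``threshold_quantile``
    quantile of off-diagonal wTO values and the absolute floor
    ``min_overlap`` (without the floor, some fraction of pairs would always
    be flagged even among independent items).  Within each connected
    component of flagged pairs, the item with the highest mean absolute
    correlation to all other items is retained; ties break lexicographically
    by label.
    """
    if data.p < 3:
        raise ValueError("need at least 3 items")
    if not 0 < threshold_quantile <= 1:
        raise ValueError("threshold_quantile must be in (0, 1]")
    if correlation_kind not in ("spearman", "pearson"):
        raise ValueError("correlation_kind must be spearman or pearson")

    labels = data.item_labels
    frame = pd.DataFrame(data.X1, columns=labels)
    excluded = [
        lab for lab in labels
        if frame[lab].dropna().nunique() <= 1
    ]
    if excluded:
        warnings.warn(
            f"constant item column(s) excluded from correlation: {excluded}"
        )
    active = [lab for lab in labels if lab not in excluded]
    corr = frame[active].corr(method=correlation_kind, min_periods=2)
    A = np.abs(corr.to_numpy())
    A = np.nan_to_num(A, nan=0.0)
    A = np.clip((A + A.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(A, 0.0)

    omega = weighted_topological_overlap(A)
    q = len(active)
    iu = np.triu_indices(q, k=1)
    off_values = omega[iu]
    if threshold_quantile >= 1.0:
        threshold = np.inf  # nothing can strictly exceed the maximum
    else:
        threshold = max(float(np.quantile(off_values, threshold_quantile)),
                        min_overlap)

    flagged_idx = [
        (i, j)
        for i, j in zip(*iu)
        if omega[i, j] > threshold
    ]
    flagged_pairs = [
        (active[i], active[j], float(omega[i, j])) for i, j in flagged_idx
    ]

    mean_abs_corr = A.sum(axis=1) / max(q - 1, 1)
    # round so exact-duplicate columns tie despite summation-order noise
    hub_score = np.round(mean_abs_corr, 10)
    dropped: dict[str, str] = {}
    for comp in _components(q, flagged_idx):
        # hub retention: global mean |corr| argmax, lexicographic tie-break
        hub = min(comp, key=lambda i: (-hub_score[i], active[i]))
        for i in comp:
            if i != hub:
                dropped[active[i]] = (
                    f"redundant with {active[hub]} "
                    f"(wTO component, mean |r| {mean_abs_corr[i]:.3f})"
                )
    kept = [lab for lab in labels if lab not in dropped]

    result = WTOResult(
        labels=active,
        adjacency=A,
        wto=omega,
        flagged_pairs=flagged_pairs,
        kept=kept,
        dropped=dropped,
        threshold=float(threshold) if np.isfinite(threshold) else float("nan"),
        excluded=excluded,
    )
    return result, data.select_items(kept)
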