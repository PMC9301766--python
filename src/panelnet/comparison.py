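"""Sensitivity comparison between a main network and a control network.

A control network is the same model refit on a subsample (e.g. with the
largest diagnostic group excluded).  Similarity is summarized by the Pearson
correlation of the vectorized coefficient matrices, asymmetric edge
replication fractions (each network's own nonzero edge set as denominator —
which is why the two fractions generally differ), correlations of the two
centrality vectors, and whether the most central node coincides.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .centrality import expected_influence, rank_centrality
from .clpn import FitConfig, fit_clpn
from .data_model import CLPNetwork, PanelDataset

__all__ = ["ComparisonReport", "compare_networks", "subgroup_refit"]


@dataclass
class ComparisonReport:
    edge_correlation: float          # NaN when a network has zero variance
    replication_a_in_b: float
    replication_b_in_a: float
    in_ei_correlation: float
    out_ei_correlation: float
    top_nodes_match: dict[str, bool]
    degenerate: bool = False         # edge correlation undefined

    def to_dict(self) -> dict:
        return {
            "edge_correlation": self.edge_correlation,
            "replication_a_in_b": self.replication_a_in_b,
            "replication_b_in_a": self.replication_b_in_a,
            "in_ei_correlation": self.in_ei_correlation,
            "out_ei_correlation": self.out_ei_correlation,
            "top_nodes_match": dict(self.top_nodes_match),
            "degenerate": self.degenerate,
        }


def _safe_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    if x.std() == 0 or y.std() == 0:
        return float("nan"), True
    return float(np.corrcoef(x, y)[0, 1]), False


def compare_networks(
    A: CLPNetwork, B: CLPNetwork, include_zeros: bool = True
) -> ComparisonReport:
    """Similarity report between two networks on the same node set.

    ``edge_correlation`` is the Pearson correlation of the full vectorized
    coefficient matrices (autoregressive + cross-lagged); with
    ``include_zeros=False`` only cells nonzero in either network enter.
    ``replication_a_in_b`` is the fraction of A's nonzero directed edges that
    are also nonzero in B (and symmetrically for b_in_a).
    """
    if list(A.labels) != list(B.labels):
        raise ValueError("networks must share node labels and order")
    a = A.B.ravel()
    b = B.B.ravel()
    if include_zeros:
        r, degenerate = _safe_corr(a, b)
    else:
        mask = (a != 0) | (b != 0)
        r, degenerate = _safe_corr(a[mask], b[mask]) if mask.any() else (float("nan"), True)

    nz_a = a != 0
    nz_b = b != 0
    rep_ab = float((nz_a & nz_b).sum() / nz_a.sum()) if nz_a.any() else float("nan")
    rep_ba = float((nz_a & nz_b).sum() / nz_b.sum()) if nz_b.any() else float("nan")

    cent_a = expected_influence(A)
    cent_b = expected_influence(B)
    in_r, _ = _safe_corr(cent_a.in_ei, cent_b.in_ei)
    out_r, _ = _safe_corr(cent_a.out_ei, cent_b.out_ei)
    top_match = {
        which: rank_centrality(cent_a, which)[0] == rank_centrality(cent_b, which)[0]
        for which in ("in_ei", "out_ei")
    }
    return ComparisonReport(
        edge_correlation=r,
        replication_a_in_b=rep_ab,
        replication_b_in_a=rep_ba,
        in_ei_correlation=in_r,
        out_ei_correlation=out_r,
        top_nodes_match=top_match,
        degenerate=degenerate,
    )


def subgroup_refit(
    data: PanelDataset,
    exclude: Callable[[pd.Series], bool] | tuple[str, object],
    config: FitConfig | None = None,
) -> tuple[CLPNetwork, ComparisonReport]:
    """Refit the network on a covariate-defined subsample and compare.

    ``exclude`` is either a predicate over covariate rows or a
    ``(covariate_name, value)`` pair; rows where it holds are removed, the
    network is refit from scratch (fresh penalty selection) and compared to
    the full-sample network — A is the main network, B the control, so
    ``replication_a_in_b`` reads "fraction of main edges replicated in the
    control network".
    """
    config = config or FitConfig()
    if isinstance(exclude, tuple):
        name, value = exclude
        drop_mask = (data.covariates[name] == value).to_numpy()
    else:
        drop_mask = data.covariates.apply(exclude, axis=1).to_numpy(dtype=bool)
    keep_idx = np.flatnonzero(~drop_mask)
    if keep_idx.size == 0:
        raise ValueError("exclusion predicate removed every participant")
    c_expanded = data.expand_covariates()[0].shape[1]
    if keep_idx.size < data.p + c_expanded + 10:
        raise ValueError(
            f"retained subsample of {keep_idx.size} is too small "
            f"(need >= p + c' + 10 = {data.p + c_expanded + 10})"
        )
    main = fit_clpn(data, config)
    control = fit_clpn(data.take(keep_idx), config)
    return control, compare_networks(main, control)
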