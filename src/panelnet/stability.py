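"""Bootstrap stability diagnostics for estimated networks.

Three resampling schemes, all refitting the network per resample:

* nonparametric bootstrap of participants -> percentile confidence intervals
  for edge weights and pairwise edge-difference tests;
* the same bootstrap applied to centralities -> node-pair difference tests;
* case-dropping bootstrap -> correlation between full-sample and subsample
  centralities as a function of the dropped proportion, summarized by the
  correlation-stability (CS) coefficient: the largest dropped proportion at
  which at least 95% of subsample correlations stay >= 0.7.

By convention a CS coefficient below 0.25 marks a centrality as
uninterpretable and above 0.5 as good.  Intervals are plain percentile
intervals at alpha = 0.05; difference tests are unadjusted for multiplicity.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seeds import substream
from .centrality import expected_influence
from .clpn import FitConfig, fit_clpn
from .data_model import CLPNetwork, PanelDataset

__all__ = [
    "EdgeBootstrapResult",
    "StabilityReport",
    "edge_bootstrap",
    "case_dropping_bootstrap",
    "cs_coefficient",
    "classify_stability",
    "centrality_difference_test",
]

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))


@dataclass
class EdgeBootstrapResult:
    labels: list[str]
    full_B: np.ndarray
    boot_B: np.ndarray            # n_boot x p x p
    ci_lower: np.ndarray          # p x p
    ci_upper: np.ndarray
    diff_edges: list[tuple[int, int]]   # edges entering the difference test
    diff_significant: np.ndarray  # m x m boolean
    n_boot: int
    seed: int
    n_redrawn: int = 0


@dataclass
class StabilityReport:
    edge: EdgeBootstrapResult | None
    correlations_by_drop: dict[str, dict[float, np.ndarray]]
    cs: dict[str, float]
    cs_class: dict[str, str]
    centrality_diff: dict[str, np.ndarray] | None
    drop_proportions: tuple[float, ...]
    n_boot: int
    seed: int


def _refit(
    data: PanelDataset,
    idx: np.ndarray,
    config: FitConfig,
    fixed_lambdas: np.ndarray | None,
) -> CLPNetwork:
    return fit_clpn(data.take(idx), config, fixed_lambdas=fixed_lambdas)


def edge_bootstrap(
    data: PanelDataset,
    config: FitConfig | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    freeze_lambda: bool = False,
) -> EdgeBootstrapResult:
    """Participant bootstrap: edge-weight CIs and edge-difference tests.

    Participants are resampled with replacement and the network refit per
    resample; the penalty is re-selected inside every resample unless
    ``freeze_lambda`` reuses the full-sample per-node penalties (faster,
    slightly anti-conservative).  Per-edge 2.5%/97.5% percentile bounds are
    reported; a pair of edges differs significantly when the percentile
    interval of their bootstrapped difference excludes zero.  Difference
    tests cover the edges that are nonzero in the full-sample network.
    """
    config = config or FitConfig()
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if n_boot < 1000:
        warnings.warn(f"n_boot={n_boot} < 1000: intervals will be noisy")
    rng = substream(seed, "edge-bootstrap")
    full = fit_clpn(data, config)
    lam = full.lambdas if freeze_lambda else None
    p = full.p
    n = data.n

    boot = np.empty((n_boot, p, p))
    n_redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            boot[b] = _refit(data, idx, config, lam).B
        except Exception:  # degenerate resample: redraw, keep count
            n_redrawn += 1
            if n_redrawn > 10 * n_boot:
                raise RuntimeError("too many failed bootstrap resamples")
            continue
        b += 1

    ci_lower = np.quantile(boot, 0.025, axis=0)
    ci_upper = np.quantile(boot, 0.975, axis=0)

    edges = [(i, j) for i in range(p) for j in range(p) if full.B[i, j] != 0.0]
    m = len(edges)
    if m:
        vals = np.stack([boot[:, i, j] for i, j in edges], axis=1)  # n_boot x m
        diffs = vals[:, :, None] - vals[:, None, :]
        lo = np.quantile(diffs, 0.025, axis=0)
        hi = np.quantile(diffs, 0.975, axis=0)
        significant = (lo > 0) | (hi < 0)
        np.fill_diagonal(significant, False)
    else:
        significant = np.zeros((0, 0), dtype=bool)

    return EdgeBootstrapResult(
        labels=list(full.labels),
        full_B=full.B,
        boot_B=boot,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        diff_edges=edges,
        diff_significant=significant,
        n_boot=n_boot,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def case_dropping_bootstrap(
    data: PanelDataset,
    config: FitConfig | None = None,
    centralities: Sequence[str] = ("out_ei", "in_ei"),
    drop_proportions: Sequence[float] = DEFAULT_DROP_GRID,
    n_boot: int = 250,
    seed: int = 0,
    freeze_lambda: bool = False,
) -> dict[str, dict[float, np.ndarray]]:
    """Case-dropping bootstrap of centrality stability.

    For each proportion pi, draw ``n_boot`` subsamples retaining
    ``ceil((1 - pi) n)`` participants without replacement, refit, and record
    the Pearson correlation between full-sample and subsample centralities.
    Proportions whose subsample would be smaller than p + 2 are skipped.
    """
    config = config or FitConfig()
    for pi in drop_proportions:
        if not 0 < pi < 0.9:
            raise ValueError("drop proportions must lie in (0, 0.9)")
    rng = substream(seed, "case-dropping")
    full = fit_clpn(data, config)
    lam = full.lambdas if freeze_lambda else None
    full_cent = expected_influence(full)
    full_vals = {"out_ei": full_cent.out_ei, "in_ei": full_cent.in_ei}
    n, p = data.n, data.p

    out: dict[str, dict[float, np.ndarray]] = {c: {} for c in centralities}
    for pi in drop_proportions:
        keep = int(np.ceil((1 - pi) * n))
        if keep < p + 2:
            warnings.warn(f"drop proportion {pi}: subsample {keep} < p + 2, skipped")
            continue
        cors = {c: np.empty(n_boot) for c in centralities}
        for b in range(n_boot):
            idx = rng.choice(n, size=keep, replace=False)
            net = _refit(data, idx, config, lam)
            cent = expected_influence(net)
            sub_vals = {"out_ei": cent.out_ei, "in_ei": cent.in_ei}
            for c in centralities:
                x, y = full_vals[c], sub_vals[c]
                if x.std() == 0 or y.std() == 0:
                    cors[c][b] = np.nan
                else:
                    cors[c][b] = np.corrcoef(x, y)[0, 1]
        for c in centralities:
            out[c][float(pi)] = cors[c]
    return out


def cs_coefficient(
    correlations_by_drop: dict[float, np.ndarray],
    threshold_r: float = 0.7,
    confidence: float = 0.95,
) -> float:
    """Correlation-stability coefficient for one centrality.

    The largest tested dropped proportion pi such that at least
    ``confidence`` of the bootstrap correlations at pi are >= ``threshold_r``;
    0 if none qualifies.  NaN correlations (degenerate subsample
    centralities) count as failures.
    """
    if not correlations_by_drop:
        raise ValueError("correlations_by_drop is empty")
    cs = 0.0
    for pi in sorted(correlations_by_drop):
        r = np.asarray(correlations_by_drop[pi], dtype=float)
        ok = np.mean(np.where(np.isnan(r), -np.inf, r) >= threshold_r)
        if ok >= confidence:
            cs = float(pi)
    return cs


def classify_stability(cs: float) -> str:
    """Interpretation rule: < 0.25 uninterpretable, [0.25, 0.5] acceptable,
    > 0.5 good."""
    if cs < 0:
        raise ValueError("cs must be >= 0")
    if cs < 0.25:
        return "uninterpretable"
    if cs <= 0.5:
        return "acceptable"
    return "good"


def centrality_difference_test(
    data: PanelDataset,
    config: FitConfig | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    freeze_lambda: bool = False,
) -> dict[str, np.ndarray]:
    """Bootstrap node-pair difference tests for out-EI and in-EI.

    A pair of nodes differs significantly on a centrality when the
    percentile interval of the bootstrapped difference excludes zero.  The
    returned boolean matrices are symmetric with a False diagonal.
    """
    config = config or FitConfig()
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = substream(seed, "centrality-diff")
    full = fit_clpn(data, config)
    lam = full.lambdas if freeze_lambda else None
    n, p = data.n, full.p

    outs = np.empty((n_boot, p))
    ins = np.empty((n_boot, p))
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            cent = expected_influence(_refit(data, idx, config, lam))
        except Exception:
            continue
        outs[b] = cent.out_ei
        ins[b] = cent.in_ei
        b += 1

    result = {}
    for name, mat in (("out_ei", outs), ("in_ei", ins)):
        diffs = mat[:, :, None] - mat[:, None, :]
        lo = np.quantile(diffs, 0.025, axis=0)
        hi = np.quantile(diffs, 0.975, axis=0)
        sig = (lo > 0) | (hi < 0)
        sig = sig | sig.T  # symmetric by construction of the two tails
        np.fill_diagonal(sig, False)
        result[name] = sig
    return result


def stability_report(
    data: PanelDataset,
    config: FitConfig | None = None,
    n_boot_edges: int = 1000,
    n_boot_drop: int = 250,
    drop_proportions: Sequence[float] = DEFAULT_DROP_GRID,
    seed: int = 0,
    freeze_lambda: bool = False,
    include_edge_bootstrap: bool = True,
    include_centrality_diff: bool = True,
) -> StabilityReport:
    """Run the full stability battery and bundle the results."""
    config = config or FitConfig()
    edge = (
        edge_bootstrap(data, config, n_boot_edges, seed, freeze_lambda)
        if include_edge_bootstrap
        else None
    )
    drops = case_dropping_bootstrap(
        data, config, ("out_ei", "in_ei"), drop_proportions,
        n_boot_drop, seed, freeze_lambda,
    )
    cs = {c: cs_coefficient(drops[c]) for c in drops}
    cent_diff = (
        centrality_difference_test(data, config, n_boot_edges, seed, freeze_lambda)
        if include_centrality_diff
        else None
    )
    return StabilityReport(
        edge=edge,
        correlations_by_drop=drops,
        cs=cs,
        cs_class={c: classify_stability(v) for c, v in cs.items()},
        centrality_diff=cent_diff,
        drop_proportions=tuple(float(x) for x in drop_proportions),
        n_boot=n_boot_edges,
        seed=seed,
    )
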