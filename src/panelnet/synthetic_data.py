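"""Two-wave panel simulator with known ground truth.

The generator emulates the statistical structure of a transdiagnostic
clinical panel study: ~15 ordinal symptom items on heterogeneous scales
(0-3, 0-4, 0-8), ~222 participants, a sparse directed cross-lagged structure
with predominantly positive edges and a strong autoregressive diagonal,
covariate effects (age, gender, diagnostic category, treatment) and a small
amount of row-sparse MCAR missingness.

Model: wave-1 scores are multivariate normal with a single-factor-plus-noise
correlation structure (all pairwise correlations positive, emulating symptom
co-occurrence); latent wave-2 scores follow ``X2 = X1 B + C G + eps``; ordinal
items are produced by per-wave quantile discretization of the latent columns.
This linear-Gaussian latent model with post-hoc discretization matches what
node-wise linear LASSO regressions can recover, keeping the recorded truth
directly comparable to the estimate.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from ._seeds import substream
from .data_model import (
    CovariateSpec,
    GeneratorTruth,
    ItemSpec,
    PanelDataset,
)

__all__ = [
    "ScenarioConfig",
    "study_items",
    "study_covariates",
    "study_scenario",
    "draw_truth",
    "simulate_panel",
    "simulate_scenario",
    "inject_redundant_items",
]


def study_items() -> list[ItemSpec]:
    """The 15 symptom nodes of the study design.

    Five depression items (0-3), six social-anxiety / anxiety items (0-4) and
    four attenuated-psychosis items (0-8); the sleep node merges three source
    items (onset, middle and early-morning insomnia).
    """
    ids = lambda *xs: tuple(xs)
    return [
        ItemSpec("Sad", "IDS-SR", ids("IDS-5"), 0, 3),
        ItemSpec("Int", "IDS-SR", ids("IDS-19"), 0, 3),
        ItemSpec("Self", "IDS-SR", ids("IDS-16"), 0, 3),
        ItemSpec("Sui", "IDS-SR", ids("IDS-18"), 0, 3),
        ItemSpec("Sleep", "IDS-SR", ids("IDS-1", "IDS-2", "IDS-3"), 0, 3, True),
        ItemSpec("AnxT", "HRSA", ids("HRSA-1"), 0, 4),
        ItemSpec("SocT", "SIAS", ids("SIAS-14"), 0, 4),
        ItemSpec("DifCo", "SIAS", ids("SIAS-10"), 0, 4),
        ItemSpec("Talk", "SIAS", ids("SIAS-6"), 0, 4),
        ItemSpec("Dis", "SIAS", ids("SIAS-16"), 0, 4),
        ItemSpec("EyCon", "SIAS", ids("SIAS-5"), 0, 4),
        ItemSpec("AbSal", "Dimensions", ids("DIM-R2"), 0, 8),
        ItemSpec("PerAn", "Dimensions", ids("DIM-R1"), 0, 8),
        ItemSpec("Perplx", "Dimensions", ids("DIM-R3"), 0, 8),
        ItemSpec("Threat", "Dimensions", ids("DIM-R4"), 0, 8),
    ]


def study_covariates() -> dict:
    """Covariate layout of the study: age, gender, two treatment flags and a
    7-level diagnostic category with misophonia as the largest group."""
    return {
        "continuous": ["age"],
        "binary": ["gender", "treat_t1", "treat_t2"],
        "categorical": {
            "diagnosis": {
                "misophonia": 0.396,
                "depressive": 0.15,
                "anxiety": 0.14,
                "psychotic": 0.12,
                "ocd": 0.09,
                "bipolar": 0.05,
                "other": 0.054,
            }
        },
    }


@dataclass
class ScenarioConfig:
    """Parameters of one simulated study scenario.

    Defaults emulate the study conditions: n=222 participants, p=15 items,
    off-diagonal density 79/210 (79 nonzero cross-lagged edges among 210
    ordered pairs), 92.4% positive edges, autoregressive effects in
    (0.2, 0.6), cross-lagged magnitudes in (0.05, 0.35), residual sd 0.6 and
    a cell-level MCAR rate of 0.0035 — which leaves roughly 10% of rows (22
    of 222) with at least one missing item score across the 2p item cells.
    """

    n: int = 222
    p: int = 15
    covariates: dict = field(default_factory=study_covariates)
    density: float = 79 / 210
    positive_edge_fraction: float = 0.924
    auto_range: tuple[float, float] = (0.2, 0.6)
    cross_range: tuple[float, float] = (0.05, 0.35)
    sigma: float = 0.6
    covariate_effect_sd: float = 0.12
    ordinalize: bool = True
    items: list[ItemSpec] | None = None
    missing_rate: float = 0.0035
    missing_mechanism: str = "MCAR"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.density <= 1:
            raise ValueError("density must be in [0, 1]")
        if not 0 <= self.positive_edge_fraction <= 1:
            raise ValueError("positive_edge_fraction must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ValueError("missing_mechanism must be MCAR or MAR")
        for name, rng_ in (("auto_range", self.auto_range),
                           ("cross_range", self.cross_range)):
            lo, hi = rng_
            if not (0 < lo < hi < 1):
                raise ValueError(f"{name} must be an interval inside (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.items is not None and len(self.items) != self.p:
            raise ValueError("items list must have length p")

    def resolved_items(self) -> list[ItemSpec]:
        if self.items is not None:
            return list(self.items)
        base = study_items()
        if self.p == len(base):
            return base
        # generic items cycling through the study's three scale ranges
        scales = [(0, 3), (0, 4), (0, 8)]
        return [
            ItemSpec(f"V{k + 1}", "synthetic", (f"V{k + 1}",), *scales[k % 3])
            for k in range(self.p)
        ]

    def n_expanded_covariates(self) -> int:
        c = len(self.covariates.get("continuous", []))
        c += len(self.covariates.get("binary", []))
        for levels in self.covariates.get("categorical", {}).values():
            c += len(levels) - 1
        return c


def study_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """The default study-scale scenario (n=222, p=15)."""
    return replace(ScenarioConfig(seed=seed), **overrides)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def draw_truth(config: ScenarioConfig) -> GeneratorTruth:
    """Draw a ground-truth network and noise model for a scenario.

    The diagonal of ``B_true`` is uniform on ``auto_range``.  Exactly
    ``round(density * p * (p-1))`` off-diagonal entries are nonzero, with
    magnitudes uniform on ``cross_range`` and signs positive with probability
    ``positive_edge_fraction``.  The wave-1 covariance is a single common
    factor plus unique noise, normalized to unit variances.
    """
    rng = substream(config.seed, "truth")
    p = config.p
    B = np.zeros((p, p))
    B[np.diag_indices(p)] = rng.uniform(*config.auto_range, size=p)

    off = [(i, j) for i in range(p) for j in range(p) if i != j]
    n_edges = int(round(config.density * len(off)))
    if n_edges > 0:
        chosen = rng.choice(len(off), size=n_edges, replace=False)
        mags = rng.uniform(*config.cross_range, size=n_edges)
        signs = np.where(
            rng.random(n_edges) < config.positive_edge_fraction, 1.0, -1.0
        )
        for k, idx in enumerate(chosen):
            i, j = off[idx]
            B[i, j] = mags[k] * signs[k]

    loadings = rng.uniform(0.4, 0.8, size=p)
    cov = np.outer(loadings, loadings)
    np.fill_diagonal(cov, 1.0)

    c = config.n_expanded_covariates()
    G = rng.normal(0.0, config.covariate_effect_sd, size=(c, p))

    return GeneratorTruth(
        B_true=B,
        G_true=G,
        sigma=config.sigma,
        baseline_cov=cov,
        positive_edge_fraction=config.positive_edge_fraction,
        density=config.density,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

def _draw_covariates(config: ScenarioConfig, rng: np.random.Generator):
    """Raw covariate table plus the expanded design used in the truth model.

    Categorical columns are reference-coded against their highest-probability
    level so the expansion is deterministic in the layout, not the sample.
    """
    n = config.n
    layout = config.covariates
    raw: dict[str, object] = {}
    design_cols: list[np.ndarray] = []
    specs: list[CovariateSpec] = []

    for name in layout.get("continuous", []):
        col = rng.normal(0.0, 1.0, size=n)
        raw[name] = col
        design_cols.append(col)
        specs.append(CovariateSpec(name, "continuous"))
    for name in layout.get("binary", []):
        col = rng.integers(0, 2, size=n).astype(float)
        raw[name] = col
        design_cols.append(col)
        specs.append(CovariateSpec(name, "binary"))
    for name, level_probs in layout.get("categorical", {}).items():
        levels = list(level_probs)
        probs = np.array([level_probs[l] for l in levels], dtype=float)
        probs = probs / probs.sum()
        draws = rng.choice(len(levels), size=n, p=probs)
        raw[name] = np.array([levels[d] for d in draws], dtype=object)
        reference = levels[int(np.argmax(probs))]
        for lev in levels:
            if lev == reference:
                continue
            design_cols.append((np.array([levels[d] for d in draws]) == lev).astype(float))
        specs.append(CovariateSpec(name, "categorical", tuple(levels)))

    C = np.column_stack(design_cols) if design_cols else np.zeros((n, 0))
    return pd.DataFrame(raw), specs, C


def _ordinalize_column(latent: np.ndarray, spec: ItemSpec) -> np.ndarray:
    """Map a latent column onto the item's integer scale by quantile bins.

    Thresholds are the equal-probability quantiles of the column itself, so
    both waves get matching marginal level distributions.
    """
    L = spec.n_levels
    qs = np.quantile(latent, np.linspace(0, 1, L + 1)[1:-1])
    return spec.scale_min + np.searchsorted(qs, latent, side="right").astype(float)


def _inject_missing(
    X1: np.ndarray,
    X2: np.ndarray,
    config: ScenarioConfig,
    age: np.ndarray | None,
    rng: np.random.Generator,
) -> None:
    """Set item cells to NaN in place, MCAR or MAR (keyed to observed age)."""
    rate = config.missing_rate
    if rate == 0:
        return
    n, p = X1.shape
    if config.missing_mechanism == "MCAR":
        prob = np.full(n, rate)
    else:
        if age is None:
            raise ValueError("MAR mechanism requires a continuous age covariate")
        slope = 1.5

        def mean_rate(a):
            return expit(a + slope * age).mean() - rate

        offset = brentq(mean_rate, logit(max(rate, 1e-9)) - 10, 10)
        prob = expit(offset + slope * age)
    for X in (X1, X2):
        mask = rng.random((n, p)) < prob[:, None]
        X[mask] = np.nan


def simulate_panel(
    truth: GeneratorTruth, config: ScenarioConfig
) -> PanelDataset:
    """Simulate one two-wave panel from a drawn truth.

    ``X1 ~ MVN(0, baseline_cov)``; latent ``X2 = X1 B + C G + eps`` with
    i.i.d. normal residuals of sd ``sigma``; optional per-wave quantile
    ordinalization; missingness injected last.
    """
    if truth.p != config.p:
        raise ValueError("truth and config dimensions disagree")
    rng = substream(config.seed, "panel")
    n, p = config.n, config.p
    items = config.resolved_items()

    X1 = rng.multivariate_normal(np.zeros(p), truth.baseline_cov, size=n,
                                 method="cholesky")
    covariates, cov_specs, C = _draw_covariates(config, rng)
    if C.shape[1] != truth.G_true.shape[0]:
        raise ValueError("covariate layout does not match truth G dimensions")
    eps = rng.normal(0.0, truth.sigma, size=(n, p))
    X2 = X1 @ truth.B_true + C @ truth.G_true + eps

    if config.ordinalize:
        for k, spec in enumerate(items):
            X1[:, k] = _ordinalize_column(X1[:, k], spec)
            X2[:, k] = _ordinalize_column(X2[:, k], spec)

    age = covariates["age"].to_numpy(dtype=float) if "age" in covariates else None
    _inject_missing(X1, X2, config, age, rng)

    return PanelDataset(
        subjects=[f"S{i + 1:04d}" for i in range(n)],
        items=items,
        X1=X1,
        X2=X2,
        covariates=covariates,
        covariate_specs=cov_specs,
    )


def simulate_scenario(config: ScenarioConfig) -> tuple[PanelDataset, GeneratorTruth]:
    """Draw a truth and simulate one panel from it."""
    truth = draw_truth(config)
    return simulate_panel(truth, config), truth


def inject_redundant_items(
    data: PanelDataset, k: int, noise_sd: float, seed: int = 0
) -> tuple[PanelDataset, dict[str, str]]:
    """Append k near-duplicate items as fixtures for redundancy screening.

    Each duplicate copies a randomly chosen parent column at both waves plus
    N(0, noise_sd) noise and is labelled ``<parent>_dup<i>``.  Returns the
    augmented dataset and a duplicate -> parent label mapping.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = substream(seed, "redundant-items")
    parents = rng.choice(data.p, size=k, replace=k > data.p)
    new_items = list(data.items)
    X1_cols = [data.X1]
    X2_cols = [data.X2]
    mapping: dict[str, str] = {}
    for i, parent in enumerate(parents, start=1):
        parent_spec = data.items[parent]
        label = f"{parent_spec.label}_dup{i}"
        new_items.append(
            ItemSpec(
                label=label,
                instrument=parent_spec.instrument,
                item_ids=parent_spec.item_ids,
                scale_min=parent_spec.scale_min,
                scale_max=parent_spec.scale_max,
                combined=parent_spec.combined,
            )
        )
        mapping[label] = parent_spec.label
        n = data.n
        X1_cols.append((data.X1[:, parent] + rng.normal(0, noise_sd, n))[:, None]
                       if noise_sd > 0 else data.X1[:, [parent]].copy())
        X2_cols.append((data.X2[:, parent] + rng.normal(0, noise_sd, n))[:, None]
                       if noise_sd > 0 else data.X2[:, [parent]].copy())
    return (
        PanelDataset(
            subjects=list(data.subjects),
            items=new_items,
            X1=np.concatenate(X1_cols, axis=1),
            X2=np.concatenate(X2_cols, axis=1),
            covariates=data.covariates,
            covariate_specs=list(data.covariate_specs),
        ),
        mapping,
    )
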