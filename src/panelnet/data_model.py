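"""Core containers for two-wave panel symptom data and estimated networks.

A :class:`PanelDataset` holds the same set of ordinal symptom items measured at
two time points (wide format, one row per participant) together with
covariates.  A :class:`CLPNetwork` holds the directed coefficient matrix of a
cross-lagged panel network: ``B[i, j]`` is the effect of item ``i`` at wave 1
on item ``j`` at wave 2, so the diagonal carries autoregressive effects and
off-diagonal entries carry cross-lagged edges.  Missing scores are encoded as
NaN in memory and as empty cells in CSV; no sentinel value is ever a valid
score.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ItemSpec",
    "CovariateSpec",
    "PanelDataset",
    "CLPNetwork",
    "GeneratorTruth",
    "combine_items",
    "combine_item_specs",
    "validate_panel",
    "save_item_specs",
    "load_item_specs",
]


@dataclass(frozen=True)
class ItemSpec:
    """One symptom node: short label, source instrument and ordinal scale."""

    label: str
    instrument: str = ""
    item_ids: tuple[str, ...] = ()
    scale_min: int = 0
    scale_max: int = 4
    combined: bool = False

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValueError(
                f"item {self.label!r}: scale_min must be < scale_max "
                f"(got {self.scale_min} >= {self.scale_max})"
            )
        object.__setattr__(self, "item_ids", tuple(self.item_ids))

    @property
    def n_levels(self) -> int:
        return self.scale_max - self.scale_min + 1


@dataclass(frozen=True)
class CovariateSpec:
    """Covariate column: name and kind (continuous, binary or categorical)."""

    name: str
    kind: str = "continuous"
    levels: tuple[str, ...] = ()

    _KINDS = ("continuous", "binary", "categorical")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        object.__setattr__(self, "levels", tuple(self.levels))


@dataclass
class PanelDataset:
    """Two-wave panel: item scores at both waves plus covariates.

    ``X1`` and ``X2`` are ``n x p`` float arrays sharing item order; NaN marks
    a missing score.  ``covariates`` is a DataFrame with one column per
    :class:`CovariateSpec` (categoricals stored as strings).
    """

    subjects: list[str]
    items: list[ItemSpec]
    X1: np.ndarray
    X2: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    covariate_specs: list[CovariateSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X1 = np.asarray(self.X1, dtype=float)
        self.X2 = np.asarray(self.X2, dtype=float)
        n, p = self.X1.shape
        if self.X2.shape != (n, p):
            raise ValueError(
                f"X1 {self.X1.shape} and X2 {self.X2.shape} must share dimensions"
            )
        if len(self.items) != p:
            raise ValueError(f"{len(self.items)} item specs for {p} columns")
        if len(self.subjects) != n:
            raise ValueError(f"{len(self.subjects)} subject ids for {n} rows")
        if len(self.covariates) not in (0, n):
            raise ValueError("covariate table row count does not match X1")

    # -- basic geometry -----------------------------------------------------
    @property
    def n(self) -> int:
        return self.X1.shape[0]

    @property
    def p(self) -> int:
        return self.X1.shape[1]

    @property
    def item_labels(self) -> list[str]:
        return [it.label for it in self.items]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean n x (2p + c) mask over [X1 | X2 | covariates]."""
        blocks = [np.isnan(self.X1), np.isnan(self.X2)]
        if len(self.covariates.columns):
            blocks.append(self.covariates.isna().to_numpy())
        return np.concatenate(blocks, axis=1)

    def item_matrix(self) -> np.ndarray:
        """The n x 2p matrix [X1 | X2] of item scores."""
        return np.concatenate([self.X1, self.X2], axis=1)

    def take(self, indices: Sequence[int]) -> "PanelDataset":
        """Row subset (used by bootstrap resampling and subgroup refits)."""
        idx = np.asarray(indices, dtype=int)
        cov = (
            self.covariates.iloc[idx].reset_index(drop=True)
            if len(self.covariates.columns)
            else self.covariates
        )
        return PanelDataset(
            subjects=[self.subjects[i] for i in idx],
            items=list(self.items),
            X1=self.X1[idx],
            X2=self.X2[idx],
            covariates=cov,
            covariate_specs=list(self.covariate_specs),
        )

    def select_items(self, labels: Sequence[str]) -> "PanelDataset":
        """Column subset keeping the given item labels (both waves)."""
        order = {it.label: k for k, it in enumerate(self.items)}
        idx = [order[lab] for lab in labels]
        return PanelDataset(
            subjects=list(self.subjects),
            items=[self.items[k] for k in idx],
            X1=self.X1[:, idx],
            X2=self.X2[:, idx],
            covariates=self.covariates,
            covariate_specs=list(self.covariate_specs),
        )

    # -- covariate expansion ------------------------------------------------
    def expand_covariates(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Expand covariates into a numeric design block.

        Continuous columns pass through; binary columns are mapped to {0, 1};
        categorical columns are reference-coded with the most frequent level
        as reference (ties broken lexicographically).  Returns
        ``(C, names, kinds)`` where kinds are per expanded column.
        """
        cols: list[np.ndarray] = []
        names: list[str] = []
        kinds: list[str] = []
        for spec in self.covariate_specs:
            s = self.covariates[spec.name]
            if spec.kind == "continuous":
                cols.append(s.to_numpy(dtype=float))
                names.append(spec.name)
                kinds.append("continuous")
            elif spec.kind == "binary":
                vals = sorted(v for v in s.dropna().unique())
                if len(vals) > 2:
                    raise ValueError(
                        f"binary covariate {spec.name!r} has {len(vals)} levels"
                    )
                hi = vals[-1] if vals else 1
                col = np.where(s.isna(), np.nan, (s == hi).astype(float))
                cols.append(col.astype(float))
                names.append(spec.name)
                kinds.append("binary")
            else:  # categorical -> reference-coded indicators
                counts = s.value_counts()
                if counts.empty:
                    continue
                top = counts.max()
                reference = sorted(l for l in counts.index if counts[l] == top)[0]
                levels = sorted(l for l in counts.index if l != reference)
                for lev in levels:
                    col = np.where(s.isna(), np.nan, (s == lev).astype(float))
                    cols.append(col.astype(float))
                    names.append(f"{spec.name}={lev}")
                    kinds.append("binary")
        if not cols:
            return np.zeros((self.n, 0)), [], []
        return np.column_stack(cols), names, kinds

    # -- CSV round trip -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {"subject": self.subjects}
        for k, it in enumerate(self.items):
            data[f"{it.label}_t1"] = self.X1[:, k]
        for k, it in enumerate(self.items):
            data[f"{it.label}_t2"] = self.X2[:, k]
        frame = pd.DataFrame(data)
        for spec in self.covariate_specs:
            frame[spec.name] = self.covariates[spec.name].to_numpy()
        return frame

    def to_csv(self, path: str | Path) -> None:
        """Write the panel as CSV (empty cell = missing)."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        items: Sequence[ItemSpec],
        covariate_specs: Sequence[CovariateSpec] = (),
    ) -> "PanelDataset":
        frame = pd.read_csv(path)
        subjects = (
            frame["subject"].astype(str).tolist()
            if "subject" in frame.columns
            else [str(i) for i in range(len(frame))]
        )
        X1 = np.column_stack(
            [frame[f"{it.label}_t1"].to_numpy(dtype=float) for it in items]
        )
        X2 = np.column_stack(
            [frame[f"{it.label}_t2"].to_numpy(dtype=float) for it in items]
        )
        cov_cols: dict[str, object] = {}
        for spec in covariate_specs:
            col = frame[spec.name]
            cov_cols[spec.name] = (
                col if spec.kind == "categorical" else col.astype(float)
            )
        return cls(
            subjects=subjects,
            items=list(items),
            X1=X1,
            X2=X2,
            covariates=pd.DataFrame(cov_cols),
            covariate_specs=list(covariate_specs),
        )


@dataclass
class CLPNetwork:
    """Estimated cross-lagged panel network.

    ``B[i, j]`` is the standardized coefficient of item ``i`` at wave 1
    predicting item ``j`` at wave 2 (row = source, column = target; diagonal =
    autoregressive).  Coefficients set to zero by the penalty are exact zeros.
    ``G`` holds covariate coefficients (expanded columns x p).
    """

    labels: list[str]
    B: np.ndarray
    G: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    covariate_names: list[str] = field(default_factory=list)
    intercepts: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lambdas: np.ndarray = field(default_factory=lambda: np.zeros(0))
    standardization: dict = field(default_factory=dict)
    n: int = 0
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        p = len(self.labels)
        if self.B.shape != (p, p):
            raise ValueError(f"B must be {p}x{p}, got {self.B.shape}")
        if self.G.size == 0:
            self.G = np.zeros((0, p))
        if self.intercepts.size == 0:
            self.intercepts = np.zeros(p)
        if self.lambdas.size == 0:
            self.lambdas = np.zeros(p)

    @property
    def p(self) -> int:
        return len(self.labels)

    def cross_lagged(self) -> np.ndarray:
        """Off-diagonal (cross-lagged) part of B, diagonal zeroed."""
        out = self.B.copy()
        np.fill_diagonal(out, 0.0)
        return out

    def autoregressive(self) -> np.ndarray:
        return np.diag(self.B).copy()

    def edge_list(self, include_covariates: bool = False) -> pd.DataFrame:
        """Nonzero edges as (source, target, weight, type) rows."""
        rows = []
        for i, src in enumerate(self.labels):
            for j, tgt in enumerate(self.labels):
                w = self.B[i, j]
                if w != 0.0:
                    kind = "autoregressive" if i == j else "cross-lagged"
                    rows.append((src, tgt, w, kind))
        if include_covariates:
            for i, src in enumerate(self.covariate_names):
                for j, tgt in enumerate(self.labels):
                    w = self.G[i, j]
                    if w != 0.0:
                        rows.append((src, tgt, w, "covariate"))
        return pd.DataFrame(rows, columns=["source", "target", "weight", "type"])


@dataclass
class GeneratorTruth:
    """Ground truth of a simulated scenario, kept for recovery tests."""

    B_true: np.ndarray
    G_true: np.ndarray
    sigma: float
    baseline_cov: np.ndarray
    positive_edge_fraction: float
    density: float
    seed: int

    def __post_init__(self) -> None:
        self.B_true = np.asarray(self.B_true, dtype=float)
        self.baseline_cov = np.asarray(self.baseline_cov, dtype=float)
        C = self.baseline_cov
        if not np.allclose(C, C.T):
            raise ValueError("baseline_cov must be symmetric")
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ValueError("baseline_cov must be positive definite")

    @property
    def p(self) -> int:
        return self.B_true.shape[0]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def combine_items(
    raw_items: Sequence[np.ndarray], method: str = "mean"
) -> np.ndarray:
    """Merge k >= 2 item columns element-wise over observed values.

    Missing entries are ignored; the result is missing only where every input
    is missing.  ``method`` is ``"mean"`` (default) or ``"sum"``.
    """
    if len(raw_items) < 2:
        raise ValueError("combine_items requires at least two columns")
    cols = [np.asarray(c, dtype=float).ravel() for c in raw_items]
    length = cols[0].shape[0]
    if any(c.shape[0] != length for c in cols):
        raise ValueError("combine_items: columns have mismatched lengths")
    if method not in ("mean", "sum"):
        raise ValueError(f"unknown combination method {method!r}")
    stack = np.column_stack(cols)
    all_missing = np.isnan(stack).all(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        out = np.nanmean(stack, axis=1) if method == "mean" else np.nansum(stack, axis=1)
    out[all_missing] = np.nan
    return out


def combine_item_specs(
    specs: Sequence[ItemSpec], label: str, method: str = "mean"
) -> ItemSpec:
    """ItemSpec for a merged node, recording every source item id."""
    ids: list[str] = []
    for s in specs:
        ids.extend(s.item_ids if s.item_ids else (s.label,))
    lo = min(s.scale_min for s in specs)
    hi = (
        max(s.scale_max for s in specs)
        if method == "mean"
        else sum(s.scale_max for s in specs)
    )
    return ItemSpec(
        label=label,
        instrument=specs[0].instrument,
        item_ids=tuple(ids),
        scale_min=lo,
        scale_max=hi,
        combined=True,
    )


def validate_panel(data: PanelDataset) -> list[str]:
    """Report invariant violations; an empty list means the panel is clean.

    Checks: duplicate labels, out-of-range observed scores, all-missing
    columns and non-varying columns.  Report-only — never raises.
    """
    report: list[str] = []
    labels = data.item_labels
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            report.append(f"duplicate item label: {lab}")
        seen.add(lab)
    for wave, X in (("t1", data.X1), ("t2", data.X2)):
        for k, it in enumerate(data.items):
            col = X[:, k]
            obs = col[~np.isnan(col)]
            name = f"{it.label}_{wave}"
            if obs.size == 0:
                report.append(f"all-missing column: {name}")
                continue
            bad = ((obs < it.scale_min) | (obs > it.scale_max)).sum()
            if bad:
                report.append(
                    f"out-of-range scores in {name}: {bad} value(s) outside "
                    f"[{it.scale_min}, {it.scale_max}]"
                )
            if obs.size > 1 and np.ptp(obs) == 0:
                report.append(f"non-varying column: {name}")
    return report


# ---------------------------------------------------------------------------
# item metadata sidecar
# ---------------------------------------------------------------------------

def save_item_specs(
    items: Sequence[ItemSpec],
    path: str | Path,
    covariate_specs: Sequence[CovariateSpec] = (),
) -> None:
    doc = {
        "items": [
            {
                "label": it.label,
                "instrument": it.instrument,
                "item_ids": list(it.item_ids),
                "scale_min": it.scale_min,
                "scale_max": it.scale_max,
                "combined": it.combined,
            }
            for it in items
        ],
        "covariates": [
            {"name": c.name, "kind": c.kind, "levels": list(c.levels)}
            for c in covariate_specs
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_item_specs(
    path: str | Path,
) -> tuple[list[ItemSpec], list[CovariateSpec]]:
    doc = yaml.safe_load(Path(path).read_text())
    items = [
        ItemSpec(
            label=d["label"],
            instrument=d.get("instrument", ""),
            item_ids=tuple(d.get("item_ids", ())),
            scale_min=int(d.get("scale_min", 0)),
            scale_max=int(d.get("scale_max", 4)),
            combined=bool(d.get("combined", False)),
        )
        for d in doc.get("items", [])
    ]
    covs = [
        CovariateSpec(
            name=d["name"], kind=d.get("kind", "continuous"),
            levels=tuple(d.get("levels", ())),
        )
        for d in doc.get("covariates", [])
    ]
    return items, covs
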