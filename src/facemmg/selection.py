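"""Feature relevance testing and Benjamini-Yekutieli (BY) selection.

Each feature column gets a p-value from a one-vs-rest two-sided
rank-sum (Mann-Whitney U) test per class, aggregated as the minimum
over classes with a Bonferroni factor for the class count.  The BY
step-up rule controls the false discovery rate under arbitrary
dependence: sort p-values ascending and retain the k* smallest, where
k* is the largest k with P(k) <= k * alpha / (m * c(m)) and
c(m) = sum_{i=1..m} 1/i (c(m) = 1 in the independent variant, which
reduces BY to Benjamini-Hochberg).

Selection runs per volunteer; the per-subject retained masks are then
consolidated into the top-k feature definitions by cross-subject
retention count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .features import FEATURE_NAMES

__all__ = [
    "SelectionConfig", "SelectionResult", "feature_pvalue",
    "feature_pvalues", "benjamini_yekutieli", "by_correction_constant",
    "top_common_features", "select_per_subject",
]


@dataclass(frozen=True)
class SelectionConfig:
    alpha: float = 0.05
    dependency_mode: str = "arbitrary"   # or "independent"
    k_top: int = 16

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.dependency_mode not in ("arbitrary", "independent"):
            raise ValueError(
                f"unknown dependency mode {self.dependency_mode!r}")


def feature_pvalue(column: np.ndarray, labels: Sequence) -> float:
    """Relevance p-value of one feature column against class labels.

    Minimum over classes of the two-sided rank-sum p of class-vs-rest,
    Bonferroni-multiplied by the class count and capped at 1.  A
    constant column is never relevant (p = 1).
    """
    col = np.asarray(column, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(col)):
        raise ValueError("feature column contains non-finite values")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if np.ptp(col) == 0.0:
        return 1.0
    pmin = 1.0
    for c in classes:
        a = col[labels == c]
        b = col[labels != c]
        p = sp_stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        pmin = min(pmin, float(p))
    return min(1.0, pmin * classes.size)


def feature_pvalues(values: pd.DataFrame, labels: Sequence) -> pd.Series:
    """Per-column relevance p-values of a feature matrix.

    Non-finite cells (NaN sentinels) are replaced by the column median
    before testing, mirroring the imputation the classifier sees.
    """
    out = {}
    for name in values.columns:
        col = values[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            med = np.nanmedian(col)
            col = np.where(np.isnan(col), med if np.isfinite(med) else 0.0, col)
        out[name] = feature_pvalue(col, labels)
    return pd.Series(out)


def by_correction_constant(m: int, dependency_mode: str = "arbitrary") -> float:
    """c(m): 1 if independent, the harmonic number H_m under arbitrary dependence."""
    if dependency_mode == "independent":
        return 1.0
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def benjamini_yekutieli(
    pvalues: Sequence[float],
    alpha: float = 0.05,
    dependency_mode: str = "arbitrary",
) -> np.ndarray:
    """BY step-up retained mask, aligned with the input order.

    Retains the k* smallest p-values, with k* the largest k such that
    P(k) <= k * alpha / (m * c(m)).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    m = p.size
    cm = by_correction_constant(m, dependency_mode)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ks = np.arange(1, m + 1)
    ok = sorted_p <= ks * alpha / (m * cm)
    mask = np.zeros(m, dtype=bool)
    if ok.any():
        k_star = int(np.max(ks[ok]))
        mask[order[:k_star]] = True
    return mask


@dataclass
class SelectionResult:
    """Outcome of BY selection on one feature matrix."""

    pvalues: pd.Series
    mask: pd.Series
    alpha: float
    dependency_mode: str
    k_star: int = field(init=False)

    def __post_init__(self) -> None:
        self.k_star = int(self.mask.sum())

    @property
    def retained(self) -> list[str]:
        return list(self.mask.index[self.mask])

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "dependency_mode": self.dependency_mode,
            "k_star": self.k_star,
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "retained": self.retained,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def select_per_subject(
    values: pd.DataFrame,
    labels: pd.DataFrame,
    config: SelectionConfig = SelectionConfig(),
) -> dict[int, SelectionResult]:
    """Run relevance testing + BY per volunteer."""
    results: dict[int, SelectionResult] = {}
    for subj in sorted(labels["subject_id"].unique()):
        idx = labels.index[labels["subject_id"] == subj]
        pv = feature_pvalues(values.loc[idx], labels.loc[idx, "gesture"])
        mask = benjamini_yekutieli(pv.to_numpy(), config.alpha,
                                   config.dependency_mode)
        results[int(subj)] = SelectionResult(
            pvalues=pv, mask=pd.Series(mask, index=pv.index),
            alpha=config.alpha, dependency_mode=config.dependency_mode)
    return results


def _definition_of(column: str) -> str:
    # Columns are named "<pair label>__<feature definition>".
    return column.split("__", 1)[1]


def top_common_features(
    per_subject: Mapping[int, SelectionResult] | Mapping[int, pd.Series],
    k_top: int = 16,
) -> list[str]:
    """Consolidate per-subject retention into the top-k feature definitions.

    A definition (feature name, aggregated over DMA pairs) scores one
    point per subject that retains it on any pair.  Ties break by the
    smaller mean p-value across subjects and pairs, then by canonical
    feature order.
    """
    if not per_subject:
        raise ValueError("need at least one subject mask")
    counts: dict[str, int] = {f: 0 for f in FEATURE_NAMES}
    psums: dict[str, list[float]] = {f: [] for f in FEATURE_NAMES}
    for subj, res in per_subject.items():
        mask = res.mask if isinstance(res, SelectionResult) else res
        pvals = res.pvalues if isinstance(res, SelectionResult) else None
        retained_defs = {_definition_of(c) for c in mask.index[mask]}
        for f in retained_defs:
            counts[f] += 1
        if pvals is not None:
            for c, p in pvals.items():
                psums[_definition_of(c)].append(float(p))
    mean_p = {f: (np.mean(v) if v else 1.0) for f, v in psums.items()}
    order = sorted(
        FEATURE_NAMES,
        key=lambda f: (-counts[f], mean_p[f], FEATURE_NAMES.index(f)))
    if k_top > len(order):
        warnings.warn(
            f"k_top={k_top} exceeds {len(order)} available definitions; "
            "returning all")
        k_top = len(order)
    return order[:k_top]
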