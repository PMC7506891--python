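"""The 16 retained time-series features and the event feature matrix.

Each calibrated DMA channel of an event is reduced to 16 scalar
features (quantiles, FFT magnitudes, linear-trend statistics, chunked
energy ratios, autocorrelation, the c3 nonlinearity statistic, a
Langevin-drift fixed point, and change statistics).  With 11 DMA pairs
this yields a 176-column matrix per event set; a 6-pair subset yields
96 columns.  Columns are standardized (zero mean, unit variance) with
statistics fitted on training rows only; NaN cells (the Langevin
feature's no-real-root sentinel) are imputed with training medians.

Conventions: population (1/n) variance for the autocorrelation and
r-sigma features; events are mean-removed and zero-padded to a fixed
512-sample window so FFT bin indices address consistent frequencies
(bin k maps to k * 200 / 512 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .calibration import SITES, CalibrationTable, DMAPair, caldma, matching_factor

__all__ = [
    "FIXED_LENGTH", "FEATURE_NAMES", "prepare", "feature_vector",
    "quantile", "abs_fft_coefficient", "linear_trend",
    "energy_ratio_by_chunks", "autocorrelation", "c3", "count_below_mean",
    "agg_linear_trend_min_rvalue", "max_langevin_fixed_point",
    "ratio_beyond_r_sigma", "mean_abs_change_quantiles",
    "FeatureMatrix", "Standardizer", "build_feature_matrix",
]

#: Fixed analysis window (samples) after mean removal and zero padding.
FIXED_LENGTH = 512


def prepare(x: np.ndarray, length: int = FIXED_LENGTH) -> np.ndarray:
    """Mean-remove and zero-pad (or truncate) a channel to a fixed length."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    if x.size >= length:
        return x[:length]
    return np.pad(x, (0, length - x.size))


# ------------------------------------------------------- scalar features

def quantile(x: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile; q=0 is the min, q=1 the max."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("quantile of empty input")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile level must be in [0, 1], got {q}")
    return float(np.quantile(x, q))


def abs_fft_coefficient(x: np.ndarray, k: int) -> float:
    """Magnitude of the k-th DFT coefficient (no normalization)."""
    x = np.asarray(x, dtype=float)
    if not 0 <= k <= x.size // 2:
        raise ValueError(f"FFT coefficient {k} out of range for n={x.size}")
    return float(np.abs(np.fft.rfft(x)[k]))


def linear_trend(x: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of x on the sample index: (slope, p_value, stderr, r_value).

    p is the two-sided t-test of zero slope.  A constant series adopts
    the total conventions slope=0, p=1, stderr=0, r=0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("linear trend needs at least 3 samples")
    if np.ptp(x) == 0.0:
        return 0.0, 1.0, 0.0, 0.0
    t = np.arange(x.size, dtype=float)
    res = sp_stats.linregress(t, x)
    return (float(res.slope), float(res.pvalue), float(res.stderr),
            float(res.rvalue))


def energy_ratio_by_chunks(x: np.ndarray, n_segments: int = 10,
                           focus: int = 1) -> float:
    """Energy of segment ``focus`` (1-based) over total energy.

    The series is split into ``n_segments`` consecutive chunks (sizes
    differ by at most one when the length is not divisible).  Ratios
    over all segments sum to 1.
    """
    x = np.asarray(x, dtype=float)
    if not 1 <= focus <= n_segments:
        raise ValueError(f"segment focus {focus} outside 1..{n_segments}")
    total = float(np.sum(x * x))
    if total == 0.0:
        raise ValueError("energy ratio undefined for an all-zero signal")
    seg = np.array_split(x, n_segments)[focus - 1]
    return float(np.sum(seg * seg)) / total


def autocorrelation(x: np.ndarray, lag: int = 2) -> float:
    """Autocorrelation at ``lag`` with full-series mean and 1/n variance."""
    x = np.asarray(x, dtype=float)
    if x.size <= lag:
        raise ValueError(f"need more than lag={lag} samples, got {x.size}")
    mu = x.mean()
    var = x.var()  # population convention
    if var == 0.0:
        return 0.0
    c = np.sum((x[:-lag] - mu) * (x[lag:] - mu))
    return float(c / ((x.size - lag) * var))


def c3(x: np.ndarray, lag: int = 3) -> float:
    """Nonlinearity statistic: mean of x_{i+2lag}^2 * x_{i+lag} * x_i."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= 2 * lag:
        raise ValueError(f"need more than 2*lag={2 * lag} samples, got {n}")
    m = n - 2 * lag
    return float(np.mean(x[2 * lag:2 * lag + m] ** 2
                         * x[lag:lag + m] * x[:m]))


def count_below_mean(x: np.ndarray) -> int:
    """Number of samples strictly below the series mean."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("count_below_mean of empty input")
    return int(np.sum(x < x.mean()))


def agg_linear_trend_min_rvalue(x: np.ndarray, chunk_len: int = 10,
                                mode: str = "aggregate") -> float:
    """Linear-trend r-value over chunk minima (default reading).

    ``mode="aggregate"``: partition into consecutive chunks of
    ``chunk_len`` (remainder dropped), aggregate each chunk by its
    minimum, fit one trend over the aggregated sequence and return its
    r-value.  ``mode="per_chunk"``: fit a trend per chunk and return
    the minimum r-value (the alternative reading of the same name).
    """
    x = np.asarray(x, dtype=float)
    n_chunks = x.size // chunk_len
    if n_chunks < 2:
        raise ValueError(
            f"need at least 2 full chunks of {chunk_len}, got {x.size} samples")
    chunks = x[:n_chunks * chunk_len].reshape(n_chunks, chunk_len)
    if mode == "aggregate":
        mins = chunks.min(axis=1)
        return linear_trend(mins)[3]
    if mode == "per_chunk":
        return min(linear_trend(chunk)[3] for chunk in chunks)
    raise ValueError(f"unknown mode {mode!r}")


def max_langevin_fixed_point(x: np.ndarray, poly_order: int = 3,
                             n_quantiles: int = 30) -> float:
    """Largest fixed point of the reconstructed Langevin drift.

    Friedrich reconstruction: bin the states x_i (i < n-1) into
    ``n_quantiles`` quantile bins, record each bin's mean state and
    mean one-step increment, least-squares fit a degree-``poly_order``
    polynomial to increment-vs-state, and return its largest real root
    (where the drift vanishes).  Only roots inside the sampled state
    range count: the reconstruction is unconstrained
    outside the data support, where a cubic fitted to, e.g., a linear
    drift can sprout spurious far roots.  NaN when the fit is
    degenerate or no real root lies in range.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * n_quantiles:
        raise ValueError(
            f"need at least {2 * n_quantiles} samples, got {x.size}")
    if np.ptp(x) == 0.0:
        return float("nan")
    states = x[:-1]
    increments = np.diff(x)
    edges = np.unique(np.quantile(states, np.linspace(0.0, 1.0, n_quantiles + 1)))
    if edges.size < 3:
        return float("nan")
    which = np.clip(np.searchsorted(edges, states, side="right") - 1,
                    0, edges.size - 2)
    xs, ys = [], []
    for b in range(edges.size - 1):
        mask = which == b
        if mask.any():
            xs.append(states[mask].mean())
            ys.append(increments[mask].mean())
    if len(xs) < poly_order + 1:
        return float("nan")
    coef = np.polyfit(np.asarray(xs), np.asarray(ys), deg=poly_order)
    if not np.all(np.isfinite(coef)) or np.allclose(coef, 0.0):
        return float("nan")
    roots = np.roots(coef)
    real = roots[np.abs(roots.imag) < 1e-8].real
    real = real[(real >= x.min()) & (real <= x.max())]
    if real.size == 0:
        return float("nan")
    return float(real.max())


def ratio_beyond_r_sigma(x: np.ndarray, r: float = 1.5) -> float:
    """Fraction of samples farther than r population-std from the mean."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("ratio_beyond_r_sigma of empty input")
    sd = x.std()  # population convention
    if sd == 0.0:
        return 0.0
    return float(np.mean(np.abs(x - x.mean()) > r * sd))


def mean_abs_change_quantiles(x: np.ndarray, qL: float = 0.0,
                              qH: float = 1.0) -> float:
    """Mean absolute one-step change inside the [qL, qH] quantile corridor.

    A difference is counted only when both endpoints lie inside the
    corridor; at the default full corridor this is the plain mean
    absolute change.  Returns 0 when no consecutive pair qualifies.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("mean_abs_change_quantiles needs >= 2 samples")
    lo, hi = np.quantile(x, qL), np.quantile(x, qH)
    inside = (x >= lo) & (x <= hi)
    both = inside[:-1] & inside[1:]
    if not both.any():
        return 0.0
    return float(np.mean(np.abs(np.diff(x))[both]))


# ---------------------------------------------------------- the catalogue

#: The retained feature catalogue, in canonical order.
FEATURE_DEFS: list[tuple[str, Callable[[np.ndarray], float]]] = [
    ("quantile_q80", lambda x: quantile(x, 0.8)),
    ("quantile_q10", lambda x: quantile(x, 0.1)),
    ("abs_fft_coeff_94", lambda x: abs_fft_coefficient(x, 94)),
    ("abs_fft_coeff_38", lambda x: abs_fft_coefficient(x, 38)),
    ("abs_fft_coeff_20", lambda x: abs_fft_coefficient(x, 20)),
    ("linear_trend_pvalue", lambda x: linear_trend(x)[1]),
    ("linear_trend_stderr", lambda x: linear_trend(x)[2]),
    ("energy_ratio_seg1", lambda x: energy_ratio_by_chunks(x, 10, 1)),
    ("energy_ratio_seg8", lambda x: energy_ratio_by_chunks(x, 10, 8)),
    ("autocorr_lag2", lambda x: autocorrelation(x, 2)),
    ("c3_lag3", lambda x: c3(x, 3)),
    ("count_below_mean", lambda x: float(count_below_mean(x))),
    ("agg_trend_min_rvalue", lambda x: agg_linear_trend_min_rvalue(x, 10)),
    ("langevin_max_fixed_point",
     lambda x: max_langevin_fixed_point(x, 3, 30)),
    ("ratio_beyond_1p5_sigma", lambda x: ratio_beyond_r_sigma(x, 1.5)),
    ("mean_abs_change", lambda x: mean_abs_change_quantiles(x, 0.0, 1.0)),
]

FEATURE_NAMES: tuple[str, ...] = tuple(name for name, _ in FEATURE_DEFS)


def feature_vector(x: np.ndarray) -> np.ndarray:
    """All 16 features of one prepared channel, in canonical order."""
    return np.array([fn(x) for _, fn in FEATURE_DEFS])


# ------------------------------------------------------ matrix construction

@dataclass
class Standardizer:
    """Training-only imputation (column median) and standardization."""

    medians: np.ndarray | None = None
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        med = np.nanmedian(X, axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        Xi = np.where(np.isnan(X), med, X)
        self.medians = med
        self.means = Xi.mean(axis=0)
        sds = Xi.std(axis=0)
        self.sds = np.where(sds > 0, sds, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.medians is None:
            raise ValueError("Standardizer is not fitted")
        X = np.asarray(X, dtype=float)
        Xi = np.where(np.isnan(X), self.medians, X)
        return (Xi - self.means) / self.sds


@dataclass
class FeatureMatrix:
    """Events x (pairs x 16 features) values with event labels."""

    values: pd.DataFrame            # index event_id, columns pair__feature
    labels: pd.DataFrame            # index event_id: subject, session, gesture, repetition
    pairs: list[DMAPair] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def standardized(self, train_index: Sequence[str]) -> tuple[np.ndarray, np.ndarray, "Standardizer"]:
        """(train X, all X) standardized with training-row statistics."""
        std = Standardizer().fit(self.values.loc[train_index].to_numpy())
        return (std.transform(self.values.loc[train_index].to_numpy()),
                std.transform(self.values.to_numpy()), std)

    def to_csv(self, path) -> None:
        self.values.join(self.labels).to_csv(path, index_label="event_id")


def column_name(pair: DMAPair, feature: str) -> str:
    return f"{pair.label}__{feature}"


def build_feature_matrix(
    dataset,
    pairs: Sequence[DMAPair],
    tables: Mapping[tuple[int, int], CalibrationTable] | CalibrationTable,
    policy: str = "max",
    area: str = "Area1",
) -> FeatureMatrix:
    """Featurize every event over every calibrated DMA pair.

    ``tables`` is either one :class:`CalibrationTable` for the whole
    dataset or a mapping keyed by (subject_id, session_id).  Matching
    factors follow ``policy`` over ``area``.  NaN cells are left in
    place; imputation happens at standardization time from training
    rows only.
    """
    if not dataset.events:
        raise ValueError("dataset has no events")
    per_session_mf: dict[tuple[int, int], list[float]] = {}

    def mfs_for(subj: int, sess: int) -> list[float]:
        key = (subj, sess)
        if key not in per_session_mf:
            table = tables[key] if isinstance(tables, Mapping) else tables
            per_session_mf[key] = [
                matching_factor(table, p, area=area, policy=policy)
                for p in pairs]
        return per_session_mf[key]

    columns = [column_name(p, f) for p in pairs for f in FEATURE_NAMES]
    rows, index, labels = [], [], []
    for ev in dataset.events:
        mfs = mfs_for(ev.subject_id, ev.session_id)
        feats = np.empty(len(pairs) * len(FEATURE_NAMES))
        for j, (pair, mf) in enumerate(zip(pairs, mfs)):
            x = caldma(ev.channel(pair.x_site), ev.channel(pair.y_site), mf)
            feats[j * len(FEATURE_NAMES):(j + 1) * len(FEATURE_NAMES)] = (
                feature_vector(prepare(x)))
        rows.append(feats)
        index.append(ev.event_id)
        labels.append((ev.subject_id, ev.session_id, ev.gesture, ev.repetition))

    values = pd.DataFrame(np.vstack(rows), index=index, columns=columns)
    labels_df = pd.DataFrame(
        labels, index=index,
        columns=["subject_id", "session_id", "gesture", "repetition"])
    return FeatureMatrix(values=values, labels=labels_df, pairs=list(pairs))
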