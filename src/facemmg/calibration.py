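"""Microphone calibration and calibrated DMA differencing.

Hand-built stethoscope-microphones have unequal gains (observed spread
up to a factor ~4 in the low band).  Each microphone is swept with
discrete square-wave tones; the peak-to-peak ADC response ``A = V * G``
per tone is aggregated into a per-microphone, per-band table from which
a matching factor ``MF = A_y / A_x`` is derived.  The calibrated
differential channel is then ``caldma = MF * Mx - My``, which cancels
common-mode sound despite the gain mismatch.

The spectrum is partitioned into three bands: Area1 (21-751 Hz, where
muscle sound lives), Area2 (1001-1751 Hz) and Area3 (2001-2501 Hz).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SWEEP_FREQS", "AREAS", "SITES", "TABLE1_SCALE",
    "CalibrationError", "CalibrationEntry", "CalibrationTable", "DMAPair",
    "area_of", "sweep_response", "build_table", "matching_factor",
    "caldma", "enumerate_pairs",
]

#: Discrete sweep tone frequencies (Hz).
SWEEP_FREQS: tuple[int, ...] = (21, 41, 61, 81, 101, 501, 751,
                                1001, 1251, 1501, 1751, 2001, 2251, 2501)

#: Spectral areas: inclusive (low, high) bounds in Hz.
AREAS: dict[str, tuple[int, int]] = {
    "Area1": (21, 751),
    "Area2": (1001, 1751),
    "Area3": (2001, 2501),
}

#: Canonical sensor sites on the face (matching a glasses frame outline).
SITES: tuple[str, ...] = (
    "temple_L", "temple_R",
    "eyebrow_L", "eyebrow_R",
    "cheek_L", "cheek_R",
)

#: Display scaling used when tables are rendered as A = V*G / 1000.
TABLE1_SCALE = 1000.0

ADC_MAX = 4095

Policy = Literal["min", "max", "mean", "unity"]


class CalibrationError(ValueError):
    """Raised for malformed sweeps, missing table cells, or bad pairs."""


@dataclass(frozen=True)
class CalibrationEntry:
    """Peak-to-peak ADC response of one microphone at one sweep tone."""

    mic_id: str
    freq_hz: float
    a_pp: float  # peak-to-peak response in raw ADC counts

    def __post_init__(self) -> None:
        if not 0 <= self.a_pp <= ADC_MAX:
            raise CalibrationError(
                f"peak-to-peak response {self.a_pp} outside [0, {ADC_MAX}]")


def area_of(freq_hz: float) -> str | None:
    """Spectral area containing ``freq_hz``, or None for gap frequencies."""
    for name, (lo, hi) in AREAS.items():
        if lo <= freq_hz <= hi:
            return name
    return None


def sweep_response(
    recording: np.ndarray,
    tone_schedule: Sequence[tuple[float, float, float]] | Sequence[dict],
    fs: float,
    mic_id: str = "mic",
    guard_frac: float = 0.1,
) -> list[CalibrationEntry]:
    """Peak-to-peak response per scheduled tone of a sweep recording.

    Parameters
    ----------
    recording : array of ADC-coded samples for a single microphone.
    tone_schedule : sequence of (freq_hz, start_s, dur_s) triples or of
        dicts with keys ``freq_hz``, ``start_s``, ``dur_s``.
    fs : sampling rate of the recording, Hz.
    guard_frac : leading fraction of each segment discarded as a
        settling guard before taking max - min.
    """
    x = np.asarray(recording)
    if x.ndim != 1 or x.size == 0:
        raise CalibrationError("recording must be a non-empty 1-D array")
    entries = []
    for tone in tone_schedule:
        if isinstance(tone, dict):
            freq, start, dur = tone["freq_hz"], tone["start_s"], tone["dur_s"]
        else:
            freq, start, dur = tone
        i0 = int(round(start * fs))
        i1 = int(round((start + dur) * fs))
        if i0 < 0 or i1 > x.size or i1 <= i0:
            raise CalibrationError(
                f"tone at {freq} Hz: segment [{i0}, {i1}) outside recording "
                f"of length {x.size}")
        seg = x[i0:i1]
        seg = seg[int(round(guard_frac * seg.size)):]
        if seg.size == 0:
            raise CalibrationError(f"tone at {freq} Hz: empty segment after guard")
        entries.append(CalibrationEntry(
            mic_id=mic_id, freq_hz=float(freq),
            a_pp=float(seg.max() - seg.min())))
    return entries


@dataclass
class CalibrationTable:
    """Per-microphone, per-area min/max/mean of the peak-to-peak response.

    Values are kept in raw ADC counts; the /1000 display convention is
    applied only on request (``scale="table1_scale"``).
    """

    data: pd.DataFrame = field(repr=False)  # index (mic_id, area), cols min/max/mean

    def stat(self, mic_id: str, area: str = "Area1",
             statistic: str = "max") -> float:
        try:
            return float(self.data.loc[(mic_id, area), statistic])
        except KeyError as exc:
            raise CalibrationError(
                f"no calibration cell for mic {mic_id!r} in {area!r}") from exc

    def mics(self) -> list[str]:
        return sorted(self.data.index.get_level_values("mic_id").unique())

    def to_frame(self, scale: str | None = None) -> pd.DataFrame:
        out = self.data.copy()
        if scale == "table1_scale":
            out = out / TABLE1_SCALE
        return out

    def to_csv(self, path: str | Path) -> None:
        df = self.data.reset_index()
        df.to_csv(path, index=False)
        sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
        sidecar.write_text(json.dumps(
            {"units": "adc_counts", "display_scale": TABLE1_SCALE,
             "areas": AREAS}, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationTable":
        df = pd.read_csv(path)
        return cls(df.set_index(["mic_id", "area"])[["min", "max", "mean"]])


def build_table(entries: Iterable[CalibrationEntry]) -> CalibrationTable:
    """Aggregate sweep entries into a :class:`CalibrationTable`.

    Frequencies in the gaps between areas (752-1000 and 1752-2000 Hz)
    are excluded.  A microphone with no entries in some area raises a
    :class:`CalibrationError` naming the mic and area.
    """
    rows = [(e.mic_id, area_of(e.freq_hz), e.a_pp) for e in entries]
    rows = [r for r in rows if r[1] is not None]
    if not rows:
        raise CalibrationError("no calibration entries fall inside any area")
    df = pd.DataFrame(rows, columns=["mic_id", "area", "a_pp"])
    agg = (df.groupby(["mic_id", "area"])["a_pp"]
             .agg(["min", "max", "mean"]).sort_index())
    for mic in df["mic_id"].unique():
        for area in AREAS:
            if (mic, area) not in agg.index:
                raise CalibrationError(
                    f"mic {mic!r} has no sweep entries in {area!r}")
    return CalibrationTable(agg)


_CATEGORY_ORDER = ("horizontal", "temple-cheek", "eyebrow-cheek")


@dataclass(frozen=True)
class DMAPair:
    """Ordered microphone pair forming one calibrated differential channel.

    ``x_site`` is the minuend channel (multiplied by MF), ``y_site`` the
    subtrahend.  Within a category x is the site listed first in the
    canonical order (left before right, temple/eyebrow before cheek).
    """

    x_site: str
    y_site: str
    category: str

    def __post_init__(self) -> None:
        if self.x_site == self.y_site:
            raise CalibrationError("a DMA pair needs two distinct sites")
        if self.category not in _CATEGORY_ORDER:
            raise CalibrationError(f"unknown pair category {self.category!r}")

    @property
    def label(self) -> str:
        return f"{self.x_site}-{self.y_site}"


def matching_factor(
    table: CalibrationTable,
    pair: DMAPair,
    area: str = "Area1",
    policy: Policy = "max",
) -> float:
    """Matching factor ``MF = stat(A_y) / stat(A_x)`` for a pair.

    ``policy`` selects the area statistic (min/max/mean) or ``unity``
    for MF = 1 (no gain compensation).  The reported headline results
    use the max statistic over Area1.
    """
    if policy == "unity":
        return 1.0
    if policy not in ("min", "max", "mean"):
        raise CalibrationError(f"unknown matching policy {policy!r}")
    ax = table.stat(pair.x_site, area, policy)
    ay = table.stat(pair.y_site, area, policy)
    if ax == 0:
        raise CalibrationError(
            f"zero response for mic {pair.x_site!r} in {area!r}; "
            "matching factor undefined")
    return ay / ax


def caldma(mx: np.ndarray, my: np.ndarray, mf: float) -> np.ndarray:
    """Calibrated first-order differential channel ``MF * Mx - My``.

    Each channel's sample mean (the ADC mid-scale DC bias) is removed
    first so the MF scaling does not shift the baseline.
    """
    mx = np.asarray(mx, dtype=float)
    my = np.asarray(my, dtype=float)
    if mx.shape != my.shape:
        raise CalibrationError(
            f"channel length mismatch: {mx.shape} vs {my.shape}")
    return mf * (mx - mx.mean()) - (my - my.mean())


def enumerate_pairs(
    dma_set: str = "all",
    sites: Sequence[str] = SITES,
) -> list[DMAPair]:
    """Canonical DMA pairs for a sensor layout.

    ``all`` yields the 11 pairs in three categories: 3 horizontal
    (temple-temple, eyebrow-eyebrow, cheek-cheek), 4 temple x cheek and
    4 eyebrow x cheek.  ``temples_cheeks`` / ``eyebrows_cheeks`` yield
    the 6 pairs among their respective 4 sites.  Temple-eyebrow pairs
    are never emitted.  Output order is deterministic (category, then
    canonical site order).
    """
    missing = [s for s in SITES if s not in sites]
    if missing:
        raise CalibrationError(f"sensor layout missing sites: {missing}")

    horizontal = [
        DMAPair("temple_L", "temple_R", "horizontal"),
        DMAPair("eyebrow_L", "eyebrow_R", "horizontal"),
        DMAPair("cheek_L", "cheek_R", "horizontal"),
    ]
    temple_cheek = [
        DMAPair(t, c, "temple-cheek")
        for t in ("temple_L", "temple_R") for c in ("cheek_L", "cheek_R")
    ]
    eyebrow_cheek = [
        DMAPair(e, c, "eyebrow-cheek")
        for e in ("eyebrow_L", "eyebrow_R") for c in ("cheek_L", "cheek_R")
    ]

    if dma_set == "all":
        return horizontal + temple_cheek + eyebrow_cheek
    if dma_set == "temples_cheeks":
        keep = {"temple_L", "temple_R", "cheek_L", "cheek_R"}
        horiz = [p for p in horizontal
                 if p.x_site in keep and p.y_site in keep]
        return horiz + temple_cheek
    if dma_set == "eyebrows_cheeks":
        keep = {"eyebrow_L", "eyebrow_R", "cheek_L", "cheek_R"}
        horiz = [p for p in horizontal
                 if p.x_site in keep and p.y_site in keep]
        return horiz + eyebrow_cheek
    raise CalibrationError(f"unknown DMA set {dma_set!r}")
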