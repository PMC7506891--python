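"""Synthetic acoustic-mechanomyography (A-MMG) session generator.

Muscle contraction emits low-frequency sound (2-200 Hz, power mostly
below 50 Hz).  Six stethoscope-microphones on the face (temples,
eyebrows, cheeks) record it through 12-bit ADCs at 200 Hz with a
mid-scale DC bias.  This module emulates that recording protocol so
the downstream pipeline (calibration, features, selection, classifier)
is testable end to end:

* each of 11 gesture classes is an activation pattern over 8 facial
  muscle source regions;
* each source emits band-limited noise under a trapezoidal
  start-hold-release envelope;
* sound propagates to each microphone with distance attenuation;
* channels share common-mode ambient noise, carry independent sensor
  noise, and are scaled by per-microphone gains (spread up to ~x4)
  with per-session drift; sensors are re-placed each session
  (positional jitter);
* samples are biased to mid-scale, clipped to [0, 4095] and rounded.

Default protocol dimensions: 8 subjects x 3 sessions x 11 classes x
10 repetitions = 2640 events of 2-3 s each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sp_signal

from .calibration import (SITES, SWEEP_FREQS, CalibrationTable, area_of,
                          build_table, sweep_response)

__all__ = [
    "GESTURES", "REGIONS", "GeneratorConfig", "SubjectProfile",
    "SessionContext", "EventRecord", "Dataset", "difficulty_presets",
    "source_signal", "generate_event", "generate_protocol",
    "generate_sweep", "calibration_tables",
    "ADC_BITS", "ADC_MAX", "DC_BIAS", "VCC", "adc_precision_mv", "sqnr_db",
]

# ---------------------------------------------------------------- ADC model

ADC_BITS = 12
ADC_MAX = 2 ** ADC_BITS - 1  # 4095
DC_BIAS = 2048               # VCC/2 mid-scale bias
VCC = 3.3                    # volts


def adc_precision_mv(vcc: float = VCC, bits: int = ADC_BITS) -> float:
    """LSB size of the ADC in millivolts (3.3 V / 2^12 ~ 0.805 mV)."""
    return vcc / (2 ** bits) * 1000.0


def sqnr_db(bits: int = ADC_BITS) -> float:
    """Dynamic range of an ideal ADC, 20 log10(2^bits) (~72 dB at 12 bits)."""
    return 20.0 * math.log10(2.0 ** bits)


def quantize(x: np.ndarray) -> np.ndarray:
    """Round to integer counts and clip to the 12-bit rails."""
    return np.clip(np.rint(x), 0, ADC_MAX).astype(np.int32)


# ------------------------------------------------------- geometry & classes

#: Face-plane sensor coordinates in cm (x lateral, y vertical).  Chosen so
#: head-to-head pair distances fall in the 4-13 cm range of the hardware.
SITE_POS: dict[str, tuple[float, float]] = {
    "temple_L": (-6.0, 6.0),
    "temple_R": (6.0, 6.0),
    "eyebrow_L": (-3.0, 7.0),
    "eyebrow_R": (3.0, 7.0),
    "cheek_L": (-4.5, -1.5),
    "cheek_R": (4.5, -1.5),
}

#: Muscle source regions driving the gesture dictionary.
REGIONS: tuple[str, ...] = (
    "frontalis_L", "frontalis_R",
    "orb_oculi_L", "orb_oculi_R",
    "zygomaticus_L", "zygomaticus_R",
    "orb_oris", "masseter",
)

REGION_POS: dict[str, tuple[float, float]] = {
    "frontalis_L": (-3.0, 8.5),
    "frontalis_R": (3.0, 8.5),
    "orb_oculi_L": (-4.0, 5.0),
    "orb_oculi_R": (4.0, 5.0),
    "zygomaticus_L": (-4.5, 0.5),
    "zygomaticus_R": (4.5, 0.5),
    "orb_oris": (0.0, -3.5),
    "masseter": (5.0, -4.5),  # jaw angle, lateral to the mouth
}

#: Gesture dictionary: 10 facial actions plus the neutral null class.
GESTURES: tuple[str, ...] = (
    "happy", "angry", "surprise", "sad", "upset", "disgust",
    "kiss", "blink", "tongue_out", "take_pill", "neutral",
)

# Per-class activation over REGIONS (face-valid assignments; this is
# configuration, not measurement).  The sad/upset/disgust triad is
# deliberately close in pattern space: those expressions recruit
# overlapping brow/mouth musculature and are the hardest to separate.
_N = 0.01
ACTIVATIONS_OVERLAPPED: dict[str, tuple[float, ...]] = {
    #            frnL  frnR  oclL  oclR  zygL  zygR  oris  mass
    "happy":     (0.00, 0.00, 0.30, 0.30, 0.90, 0.90, 0.20, 0.00),
    "angry":     (0.80, 0.80, 0.20, 0.20, 0.00, 0.00, 0.20, 0.80),
    "surprise":  (1.00, 1.00, 0.40, 0.40, 0.00, 0.00, 0.40, 0.10),
    "sad":       (0.45, 0.45, 0.20, 0.20, 0.10, 0.10, 0.35, 0.10),
    "upset":     (0.50, 0.50, 0.25, 0.25, 0.10, 0.10, 0.30, 0.20),
    "disgust":   (0.40, 0.40, 0.30, 0.30, 0.15, 0.15, 0.30, 0.10),
    "kiss":      (0.00, 0.00, 0.10, 0.10, 0.20, 0.20, 1.00, 0.10),
    "blink":     (0.00, 0.00, 0.90, 0.90, 0.00, 0.00, 0.00, 0.00),
    "tongue_out": (0.00, 0.00, 0.20, 0.20, 0.10, 0.10, 0.80, 0.40),
    "take_pill": (0.00, 0.00, 0.10, 0.10, 0.00, 0.00, 0.30, 1.00),
    "neutral":   (_N,) * 8,
}

# Patterns for the easy regime: each class keeps its face-valid primary
# region, and secondary activations were chosen (once, by maximising the
# minimum pairwise distance between the classes' expected DMA-channel
# energy signatures under the propagation model) so that no pattern is a
# scaled copy or subset of another.
ACTIVATIONS_SEPARABLE: dict[str, tuple[float, ...]] = {
    #            frnL  frnR  oclL  oclR  zygL  zygR  oris  mass
    "happy":     (_N,   _N,  0.30, 0.30, 1.00, 1.00, _N,   _N),
    "angry":     (1.00, 1.00, _N,   _N,  0.80, 0.80, _N,   _N),
    "surprise":  (1.00, 1.00, _N,   _N,  _N,   _N,  0.50,  _N),
    "sad":       (0.70, 0.70, _N,   _N,  _N,   _N,  _N,   0.80),
    "upset":     (_N,   _N,  0.90, 0.90, 0.80, 0.80, _N,   _N),
    "disgust":   (_N,   _N,  _N,   _N,  0.50, 0.50, 0.90,  _N),
    "kiss":      (_N,   _N,  _N,   _N,  _N,   _N,  1.00,  _N),
    "blink":     (_N,   _N,  1.00, 1.00, _N,   _N,  _N,   _N),
    "tongue_out": (0.50, 0.50, _N,  _N,  _N,   _N,  0.70,  _N),
    "take_pill": (_N,   _N,  _N,   _N,  _N,   _N,  _N,   1.00),
    "neutral":   (_N,) * 8,
}


# ------------------------------------------------------------ configuration

@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic protocol.

    Amplitudes are in ADC counts; distances in cm.  Defaults reproduce
    the recording conditions the pipeline assumes: 200 Hz sampling,
    2-3 s events, microphone gain spread bounded by a factor ~4,
    per-session re-placement jitter, 20% common-mode ambient noise.
    """

    name: str = "paper-like"
    activations: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(ACTIVATIONS_OVERLAPPED))
    fs: int = 200
    duration_range: tuple[float, float] = (2.0, 3.0)
    source_amp: float = 150.0          # per-region source std, counts
    lambda_att: float = 3.0            # propagation attenuation length, cm
    ambient_frac: float = 0.20         # common-mode amplitude vs source_amp
    sensor_noise_sd: float = 2.0       # independent electronic noise, counts
    gain_range: tuple[float, float] = (0.5, 1.8)  # per-mic gain spread (<= x4)
    gain_drift_sd: float = 0.05        # per-session multiplicative drift
    placement_jitter_sd: float = 0.5   # per-session sensor offset, cm
    expressiveness_sd: float = 0.2     # per-subject amplitude scale spread
    region_offset_sd: float = 0.05     # per-subject activation perturbation
    envelope_frac: float = 0.15        # rise/release fraction of the event
    bandpass_hz: tuple[float, float] = (2.0, 45.0)

    def activation_matrix(self) -> np.ndarray:
        return np.array([self.activations[g] for g in GESTURES])


def difficulty_presets(name: str) -> GeneratorConfig:
    """Named generator configurations.

    ``separable``: disjoint activation patterns, low noise and jitter —
    an end-to-end pipeline should recognise gestures almost perfectly.
    ``paper-like``: overlapping sad/upset/disgust patterns, full noise
    and placement jitter — the weak-class structure of real sessions.
    ``hard``: paper-like patterns with heavy subject heterogeneity.
    """
    if name == "separable":
        return GeneratorConfig(
            name="separable",
            activations=dict(ACTIVATIONS_SEPARABLE),
            ambient_frac=0.05, sensor_noise_sd=1.0,
            gain_drift_sd=0.005, placement_jitter_sd=0.1,
            expressiveness_sd=0.02, region_offset_sd=0.01)
    if name == "paper-like":
        return GeneratorConfig(name="paper-like")
    if name == "hard":
        return GeneratorConfig(
            name="hard",
            ambient_frac=0.30, placement_jitter_sd=0.8,
            expressiveness_sd=0.5, region_offset_sd=0.10)
    raise ValueError(f"unknown difficulty preset {name!r}")


# ------------------------------------------------------------- domain types

@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject physiology: expressiveness, mic gains, pattern offsets."""

    subject_id: int
    expressiveness: float
    mic_gains: np.ndarray            # shape (6,), positive
    region_offsets: np.ndarray       # shape (n_classes, 8), relative perturbation

    def __post_init__(self) -> None:
        g = np.asarray(self.mic_gains, dtype=float)
        if g.shape != (len(SITES),) or np.any(g <= 0):
            raise ValueError("mic_gains must be 6 positive multipliers")
        if g.max() / g.min() > 4.1:
            raise ValueError("mic gain spread exceeds the x4.1 hardware bound")


@dataclass(frozen=True)
class SessionContext:
    """Per-session placement jitter and gain drift (sensors re-placed)."""

    session_id: int
    placement_jitter: Mapping[str, tuple[float, float]]  # cm offsets per site
    gain_drift: np.ndarray                               # shape (6,)
    rng_seed: int


@dataclass(frozen=True)
class EventRecord:
    """One labelled 6-channel ADC gesture recording."""

    samples: np.ndarray   # int array, shape (6, T), counts in [0, 4095]
    fs: int
    subject_id: int
    session_id: int
    gesture: str
    repetition: int
    event_id: str

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    def channel(self, site: str) -> np.ndarray:
        return self.samples[SITES.index(site)]


@dataclass
class Dataset:
    """A generated protocol: events plus the profiles that produced them."""

    events: list[EventRecord]
    profiles: dict[int, SubjectProfile]
    sessions: dict[tuple[int, int], SessionContext]
    config: GeneratorConfig
    seed: int

    def effective_gains(self, subject_id: int, session_id: int) -> np.ndarray:
        """True per-channel gains of a session: subject gains x drift."""
        return (self.profiles[subject_id].mic_gains
                * self.sessions[(subject_id, session_id)].gain_drift)

    def subject_ids(self) -> list[int]:
        return sorted(self.profiles)

    def session_ids(self) -> list[int]:
        return sorted({s for (_, s) in self.sessions})


# ------------------------------------------------------------- signal model

def _event_rng(seed: int, subject: int, session: int, index: int) -> np.random.Generator:
    # Splittable counter scheme: every event stream is reproducible in
    # isolation from (global seed, subject, session, event index).
    return np.random.default_rng(
        np.random.SeedSequence((seed, 2, subject, session, index)))


def source_signal(
    duration_s: float,
    fs: int = 200,
    rng: np.random.Generator | None = None,
    bandpass_hz: tuple[float, float] = (2.0, 45.0),
    envelope_frac: float = 0.15,
) -> np.ndarray:
    """Band-limited muscle-sound burst under a start-hold-release envelope.

    Gaussian noise band-passed to ``bandpass_hz`` (so >= 70% of power
    lies below 50 Hz at fs = 200), scaled to unit standard deviation,
    then shaped by a trapezoid that is zero at both ends (the gesture
    starts and ends at rest).
    """
    if rng is None:
        rng = np.random.default_rng()
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    sos = sp_signal.butter(4, bandpass_hz, btype="bandpass", fs=fs, output="sos")
    x = sp_signal.sosfiltfilt(sos, white)
    sd = x.std()
    if sd > 0:
        x = x / sd
    t = np.arange(n, dtype=float)
    ramp = max(1.0, envelope_frac * n)
    env = np.minimum(1.0, np.minimum(t / ramp, (n - 1 - t) / ramp))
    env = np.clip(env, 0.0, 1.0)
    return x * env


def _prop_gain(region: str, site: str,
               jitter: Mapping[str, tuple[float, float]] | None,
               lambda_att: float) -> float:
    rx, ry = REGION_POS[region]
    sx, sy = SITE_POS[site]
    if jitter is not None:
        dx, dy = jitter.get(site, (0.0, 0.0))
        sx, sy = sx + dx, sy + dy
    dist = math.hypot(rx - sx, ry - sy)
    return 1.0 / (1.0 + dist / lambda_att)


def generate_event(
    gesture: str,
    subject: SubjectProfile,
    session: SessionContext,
    config: GeneratorConfig,
    rng: np.random.Generator,
    repetition: int = 0,
    event_id: str = "event",
    duration_s: float | None = None,
) -> EventRecord:
    """Synthesize one 6-channel ADC recording of a gesture event."""
    act = np.asarray(config.activations[gesture], dtype=float)
    if act.shape != (len(REGIONS),):
        raise ValueError(
            f"activation vector for {gesture!r} must have {len(REGIONS)} "
            f"entries, got {act.shape}")
    gi = GESTURES.index(gesture)
    # per-subject perturbation is relative: unused regions stay silent
    act = np.clip(act * (1.0 + subject.region_offsets[gi]), 0.0, None)

    if duration_s is None:
        duration_s = rng.uniform(*config.duration_range)
    n = int(round(duration_s * config.fs))

    sources = np.stack([
        source_signal(duration_s, config.fs, rng, config.bandpass_hz,
                      config.envelope_frac)
        for _ in REGIONS
    ])
    # Ambient room noise: identical on every channel, no gesture envelope.
    ambient = config.ambient_frac * config.source_amp * _ambient_noise(
        n, config.fs, rng, config.bandpass_hz)

    gains = subject.mic_gains * session.gain_drift
    prop = np.array([
        [_prop_gain(r, s, session.placement_jitter, config.lambda_att)
         for r in REGIONS]
        for s in SITES
    ])  # (6, 8)
    weights = prop * (act * subject.expressiveness * config.source_amp)
    clean = weights @ sources                           # (6, n)
    noise = rng.normal(0.0, config.sensor_noise_sd, size=(len(SITES), n))
    raw = (clean + ambient[None, :] + noise) * gains[:, None] + DC_BIAS
    return EventRecord(
        samples=quantize(raw), fs=config.fs,
        subject_id=subject.subject_id, session_id=session.session_id,
        gesture=gesture, repetition=repetition, event_id=event_id)


def _ambient_noise(n: int, fs: int, rng: np.random.Generator,
                   bandpass_hz: tuple[float, float]) -> np.ndarray:
    sos = sp_signal.butter(4, bandpass_hz, btype="bandpass", fs=fs, output="sos")
    x = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _make_profile(subject_id: int, seed: int,
                  config: GeneratorConfig) -> SubjectProfile:
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0, subject_id)))
    lo, hi = config.gain_range
    gains = rng.uniform(lo, hi, size=len(SITES))
    expr = float(np.clip(rng.normal(1.0, config.expressiveness_sd), 0.3, None))
    offsets = rng.normal(0.0, config.region_offset_sd,
                         size=(len(GESTURES), len(REGIONS)))
    return SubjectProfile(subject_id=subject_id, expressiveness=expr,
                          mic_gains=gains, region_offsets=offsets)


def _make_session(subject_id: int, session_id: int, seed: int,
                  config: GeneratorConfig) -> SessionContext:
    ss = np.random.SeedSequence((seed, 1, subject_id, session_id))
    rng = np.random.default_rng(ss)
    jitter = {
        site: tuple(rng.normal(0.0, config.placement_jitter_sd, size=2))
        for site in SITES
    }
    drift = np.clip(rng.normal(1.0, config.gain_drift_sd, size=len(SITES)),
                    0.5, 2.0)
    return SessionContext(session_id=session_id, placement_jitter=jitter,
                          gain_drift=drift,
                          rng_seed=int(ss.generate_state(1)[0] % (2 ** 31)))


def generate_protocol(
    n_subjects: int = 8,
    n_sessions: int = 3,
    reps: int = 10,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> Dataset:
    """Emulate the full recording protocol.

    Each (subject, session) block contains ``reps`` repetitions of each
    of the 11 classes in randomized order.  Defaults yield 2640 events,
    240 per class, 330 per block.  Byte-identical output for the same
    seed.
    """
    if min(n_subjects, n_sessions, reps) < 1:
        raise ValueError("protocol dimensions must be positive")
    if config is None:
        config = difficulty_presets("paper-like")

    profiles = {s: _make_profile(s, seed, config)
                for s in range(1, n_subjects + 1)}
    sessions: dict[tuple[int, int], SessionContext] = {}
    events: list[EventRecord] = []
    for subj in range(1, n_subjects + 1):
        for sess in range(1, n_sessions + 1):
            ctx = _make_session(subj, sess, seed, config)
            sessions[(subj, sess)] = ctx
            order_rng = np.random.default_rng(
                np.random.SeedSequence((seed, 3, subj, sess)))
            labels = [(g, r) for g in GESTURES for r in range(1, reps + 1)]
            order_rng.shuffle(labels)
            for idx, (gesture, rep) in enumerate(labels):
                rng = _event_rng(seed, subj, sess, idx)
                eid = f"s{subj:02d}_ss{sess}_e{idx:03d}"
                events.append(generate_event(
                    gesture, profiles[subj], ctx, config, rng,
                    repetition=rep, event_id=eid))
    return Dataset(events=events, profiles=profiles, sessions=sessions,
                   config=config, seed=seed)


# ------------------------------------------------------- calibration sweeps

def _mic_response_shape(freq_hz: float) -> float:
    # Stylised stethoscope-microphone frequency response: strongest in
    # the low band, weaker in the middle and high bands (flat within
    # each band so the Area1 max ratio recovers the gain ratio exactly).
    area = area_of(freq_hz)
    if area == "Area1":
        return 1.0
    if area == "Area2":
        return 0.45
    if area == "Area3":
        return 0.25
    return 0.6


def default_schedule(dur_s: float = 1.0,
                     freqs: Sequence[float] = SWEEP_FREQS) -> list[dict]:
    """Tone schedule covering the sweep list, ``dur_s`` seconds per tone."""
    return [{"freq_hz": float(f), "start_s": i * dur_s, "dur_s": dur_s}
            for i, f in enumerate(freqs)]


def generate_sweep(
    gains: Sequence[float],
    schedule: Sequence[dict] | None = None,
    fs: int = 4000,
    base_amp: float = 350.0,
) -> tuple[dict[str, np.ndarray], list[dict], int]:
    """Synthetic per-microphone calibration sweep recordings.

    Square-wave tones at the scheduled frequencies, with amplitude
    ``base_amp * gain * response_shape(freq)`` counts about mid-scale,
    quantized to the 12-bit ADC.  Returns (recordings keyed by site,
    schedule, fs).
    """
    if schedule is None:
        schedule = default_schedule()
    total_s = max(t["start_s"] + t["dur_s"] for t in schedule)
    n = int(round(total_s * fs))
    t = np.arange(n) / fs
    recordings: dict[str, np.ndarray] = {}
    for site, gain in zip(SITES, gains):
        wave = np.zeros(n)
        for tone in schedule:
            i0 = int(round(tone["start_s"] * fs))
            i1 = int(round((tone["start_s"] + tone["dur_s"]) * fs))
            amp = base_amp * gain * _mic_response_shape(tone["freq_hz"])
            seg_t = t[i0:i1] - t[i0]
            wave[i0:i1] = amp * np.sign(
                np.sin(2 * np.pi * tone["freq_hz"] * seg_t) + 1e-12)
        recordings[site] = quantize(wave + DC_BIAS)
    return recordings, list(schedule), fs


def calibration_tables(dataset: Dataset) -> dict[tuple[int, int], CalibrationTable]:
    """Per-(subject, session) calibration tables from synthetic sweeps.

    Runs the same sweep -> peak-to-peak -> table path the hardware
    calibration uses, against each session's effective gains.
    """
    tables: dict[tuple[int, int], CalibrationTable] = {}
    for (subj, sess) in dataset.sessions:
        gains = dataset.effective_gains(subj, sess)
        recs, schedule, fs = generate_sweep(gains)
        entries = []
        for site, rec in recs.items():
            entries.extend(sweep_response(rec, schedule, fs, mic_id=site))
        tables[(subj, sess)] = build_table(entries)
    return tables
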