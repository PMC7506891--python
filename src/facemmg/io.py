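"""Session file formats, run configuration, and the end-to-end pipeline.

Canonical interchange is human-inspectable CSV/JSON: one long-format
CSV per recording session (columns event_id, sample_idx, mic1..mic6)
plus a ``sessions.json`` manifest carrying labels and provenance.
Optional per-event WAV export recenters counts to signed 16-bit PCM
(lossy in DC offset, by design).

``run_all`` chains simulate -> calibrate -> featurize -> select ->
train/evaluate, embedding a config hash in every artifact so a run is
reproducible from (config, seed) alone.  Stages whose output files
already exist are not rewritten; deleting an artifact and re-running
regenerates it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from . import __version__
from .calibration import SITES, CalibrationTable
from .classify import GridSpec, run_experiment
from .features import build_feature_matrix
from .selection import SelectionConfig, select_per_subject, top_common_features
from .synth import (ADC_MAX, DC_BIAS, Dataset, EventRecord,
                    calibration_tables, difficulty_presets, generate_protocol)

__all__ = [
    "SchemaError", "RunConfig", "write_dataset", "read_dataset",
    "write_session", "read_session", "export_wav", "config_hash", "run_all",
]

log = logging.getLogger("facemmg")

MIC_COLUMNS = tuple(f"mic{i + 1}" for i in range(len(SITES)))


class SchemaError(ValueError):
    """Raised when a session file violates the on-disk schema."""


# ------------------------------------------------------------- session files

def write_session(path: str | Path, events: list[EventRecord]) -> None:
    """Write one session's events as a long-format CSV."""
    frames = []
    for ev in events:
        df = pd.DataFrame(ev.samples.T, columns=list(MIC_COLUMNS))
        df.insert(0, "sample_idx", np.arange(ev.samples.shape[1]))
        df.insert(0, "event_id", ev.event_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_session(path: str | Path, manifest: Mapping[str, dict],
                 fs: int = 200) -> list[EventRecord]:
    """Read one session CSV back into :class:`EventRecord` objects.

    Validates the schema strictly: required columns, integer counts in
    [0, 4095] (violations are reported with their row number), and a
    manifest entry for every event exactly once.
    """
    df = pd.read_csv(path)
    required = ["event_id", "sample_idx", *MIC_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    mics = df[list(MIC_COLUMNS)]
    bad = ~((mics >= 0) & (mics <= ADC_MAX)) | mics.isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0][0])
        raise SchemaError(
            f"{path}: sample out of ADC range [0, {ADC_MAX}] at data row "
            f"{row} (file line {row + 2})")
    if (mics.to_numpy() != np.rint(mics.to_numpy())).any():
        raise SchemaError(f"{path}: non-integer ADC counts")
    events = []
    for eid, g in df.groupby("event_id", sort=False):
        if eid not in manifest:
            raise SchemaError(f"{path}: event {eid!r} missing from manifest")
        meta = manifest[eid]
        g = g.sort_values("sample_idx")
        if not np.array_equal(g["sample_idx"].to_numpy(),
                              np.arange(len(g))):
            raise SchemaError(f"{path}: event {eid!r} has gaps or duplicate "
                              "sample indices")
        events.append(EventRecord(
            samples=g[list(MIC_COLUMNS)].to_numpy(dtype=np.int32).T,
            fs=int(meta.get("fs", fs)),
            subject_id=int(meta["subject_id"]),
            session_id=int(meta["session_id"]),
            gesture=str(meta["gesture"]),
            repetition=int(meta["repetition"]),
            event_id=str(eid)))
    seen = {ev.event_id for ev in events}
    dup = df["event_id"].nunique() != len(seen)
    if dup:
        raise SchemaError(f"{path}: duplicate event ids")
    return events


def write_dataset(dataset: Dataset, outdir: str | Path,
                  extra_meta: dict | None = None) -> Path:
    """Write a generated dataset: per-session CSVs plus sessions.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_session: dict[tuple[int, int], list[EventRecord]] = {}
    for ev in dataset.events:
        by_session.setdefault((ev.subject_id, ev.session_id), []).append(ev)
    manifest_events = {}
    files = {}
    for (subj, sess), events in sorted(by_session.items()):
        fname = f"session_s{subj:02d}_{sess}.csv"
        write_session(outdir / fname, events)
        files[fname] = {"subject_id": subj, "session_id": sess}
        for ev in events:
            manifest_events[ev.event_id] = {
                "subject_id": ev.subject_id, "session_id": ev.session_id,
                "gesture": ev.gesture, "repetition": ev.repetition,
                "fs": ev.fs, "duration_s": round(ev.duration, 6),
            }
    manifest = {
        "generator_version": __version__,
        "seed": dataset.seed,
        "preset": dataset.config.name,
        "fs": dataset.config.fs,
        "files": files,
        "events": manifest_events,
    }
    if extra_meta:
        manifest.update(extra_meta)
    with open(outdir / "sessions.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir / "sessions.json"


@dataclass
class LoadedDataset:
    """Events re-read from disk (generator internals are not recoverable)."""

    events: list[EventRecord]
    manifest: dict


def read_dataset(datadir: str | Path) -> LoadedDataset:
    """Read back a dataset directory written by :func:`write_dataset`."""
    datadir = Path(datadir)
    with open(datadir / "sessions.json") as fh:
        manifest = json.load(fh)
    events: list[EventRecord] = []
    for fname in sorted(manifest["files"]):
        events.extend(read_session(datadir / fname, manifest["events"],
                                   fs=manifest.get("fs", 200)))
    listed = set(manifest["events"])
    loaded = {ev.event_id for ev in events}
    if listed != loaded:
        raise SchemaError(
            f"manifest/file mismatch: {len(listed ^ loaded)} orphan events")
    return LoadedDataset(events=events, manifest=manifest)


def export_wav(event: EventRecord, outdir: str | Path) -> list[Path]:
    """Export one event as six mono 16-bit PCM WAV files at the event fs.

    Counts are recentered to signed integers (the mid-scale DC bias is
    removed), so the export is lossy in DC offset.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, site in enumerate(SITES):
        p = outdir / f"{event.event_id}_{site}.wav"
        wavfile.write(p, event.fs,
                      (event.samples[i].astype(np.int32) - DC_BIAS)
                      .astype(np.int16))
        paths.append(p)
    return paths


# ---------------------------------------------------------------- run config

@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run (plus a seed)."""

    preset: str = "paper-like"
    n_subjects: int = 8
    n_sessions: int = 3
    reps: int = 10
    seed: int = 0
    alpha: float = 0.05
    dependency_mode: str = "arbitrary"
    dma_set: str = "all"
    mode: str = "independent"
    subject_id: int | None = None
    policy: str = "max"
    decomposition: str = "ovo"
    grid_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def grid(self) -> GridSpec:
        kwargs = dict(self.grid_overrides)
        kwargs.setdefault("include_gaussian", self.mode == "independent")
        return GridSpec(**kwargs)


def config_hash(config: RunConfig | dict) -> str:
    payload = config.to_dict() if isinstance(config, RunConfig) else config
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ------------------------------------------------------------------ pipeline

def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def _tables_to_csv(tables: Mapping[tuple[int, int], CalibrationTable],
                   path: Path) -> None:
    frames = []
    for (subj, sess), table in sorted(tables.items()):
        df = table.data.reset_index()
        df.insert(0, "session_id", sess)
        df.insert(0, "subject_id", subj)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run the whole pipeline and write its artifact bundle.

    Stages: simulate, calibrate, featurize, select, evaluate.  Each
    stage logs its timing and event counts; every artifact embeds the
    config hash.  Existing artifacts are left in place; missing ones
    are regenerated (the dataset itself is deterministic in the seed,
    so recomputation is exact).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    provenance = {"config": config.to_dict(), "config_hash": chash,
                  "version": __version__}

    def stage(name):
        t0 = time.time()
        log.info("stage %s started", name)
        return t0

    # -- simulate
    t0 = stage("simulate")
    dataset = generate_protocol(
        config.n_subjects, config.n_sessions, config.reps, config.seed,
        difficulty_presets(config.preset))
    datadir = outdir / "data"
    if not (datadir / "sessions.json").exists():
        write_dataset(dataset, datadir, extra_meta={"config_hash": chash})
    log.info("simulate: %d events in %.1fs", len(dataset.events),
             time.time() - t0)

    # -- calibrate
    t0 = stage("calibrate")
    tables = calibration_tables(dataset)
    cal_path = outdir / "caltables.csv"
    if not cal_path.exists():
        _tables_to_csv(tables, cal_path)
    log.info("calibrate: %d tables in %.1fs", len(tables), time.time() - t0)

    # -- featurize (also feeds selection)
    t0 = stage("featurize")
    from .calibration import enumerate_pairs
    pairs = enumerate_pairs(config.dma_set)
    fm = build_feature_matrix(dataset, pairs, tables, policy=config.policy)
    feat_path = outdir / "features.csv"
    if not feat_path.exists():
        fm.to_csv(feat_path)
    log.info("featurize: %d x %d in %.1fs", *fm.values.shape, time.time() - t0)

    # -- select (per-volunteer BY + consolidation; reported, the final
    #    pipeline applies the full 16-feature catalogue to every pair)
    t0 = stage("select")
    sel_cfg = SelectionConfig(alpha=config.alpha,
                              dependency_mode=config.dependency_mode)
    per_subject = select_per_subject(fm.values, fm.labels, sel_cfg)
    consolidated = top_common_features(per_subject, sel_cfg.k_top)
    sel_path = outdir / "selection.json"
    if not sel_path.exists():
        _write_json(sel_path, {
            "config_hash": chash, "alpha": config.alpha,
            "dependency_mode": config.dependency_mode,
            "per_subject_k_star": {str(s): r.k_star
                                   for s, r in per_subject.items()},
            "top_common_features": consolidated,
        })
    log.info("select: consolidated %d definitions in %.1fs",
             len(consolidated), time.time() - t0)

    # -- train + evaluate
    t0 = stage("evaluate")
    result = run_experiment(
        dataset, dma_set=config.dma_set, mode=config.mode,
        subject_id=config.subject_id, seed=config.seed, grid=config.grid(),
        policy=config.policy, decomposition=config.decomposition,
        feature_matrix=fm)
    report = {
        "config_hash": chash,
        "provenance": provenance,
        "mean_macro": result.mean_macro,
        "mean_per_class_f1": {k: float(v)
                              for k, v in result.mean_per_class_f1.items()},
        "best_params": {str(k): v for k, v in result.best_params.items()},
        "rotations": {str(k): r.to_json_dict()
                      for k, r in result.reports.items()},
    }
    report_path = outdir / "report.json"
    if not report_path.exists():
        _write_json(report_path, report)
        for sess, rep in result.reports.items():
            rep.confusion.to_csv(outdir / f"confusion_session{sess}.csv")
    _write_json(outdir / "provenance.json", provenance)
    log.info("evaluate: macro F1 %.3f in %.1fs", result.mean_macro["f1"],
             time.time() - t0)
    return report
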