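"""File round-tripping and the end-to-end processing pipeline.

All on-disk formats are plain text: RFC 4180 CSV (UTF-8) with times in
seconds from session start at 6 decimal places, labels as uppercase enum
strings, plus JSON/YAML sidecars for metadata and provenance manifests.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import AnnotationTrack
from .classifier import ActivityLabel, Bout, ClassifierConfig, LabelStream
from .signals import (
    AccelSignal,
    EPOCH_COLUMNS,
    InvalidSignalError,
    build_epoch_frame,
    calibrate_supine,
    compute_sma,
    compute_tilt_angles,
    extract_gravity,
    median_filter3,
)

FLOAT_FMT = "%.6f"


# ---------------------------------------------------------------------------
# sensor CSV + sidecar

def write_accel_csv(sig: AccelSignal, path: str | Path, meta_path: str | Path | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame({
        "time_s": sig.times,
        "ax_g": sig.data[:, 0],
        "ay_g": sig.data[:, 1],
        "az_g": sig.data[:, 2],
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    if meta_path is None:
        meta_path = path.with_suffix(".meta.yaml")
    meta = {"site": sig.site, "rate_hz": sig.rate, "start_offset_s": sig.start_offset}
    Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_accel_csv(path: str | Path, meta_path: str | Path | None = None,
                   site: str | None = None, rate: float | None = None) -> AccelSignal:
    path = Path(path)
    meta: dict = {}
    if meta_path is None:
        candidate = path.with_suffix(".meta.yaml")
        meta_path = candidate if candidate.exists() else None
    if meta_path is not None:
        meta = yaml.safe_load(Path(meta_path).read_text()) or {}
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise InvalidSignalError(f"{path}: unreadable CSV ({exc})") from exc
    required = ["time_s", "ax_g", "ay_g", "az_g"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidSignalError(f"{path}: missing columns {missing}")
    bad = df[required].isna().any(axis=1)
    if bad.any():
        raise InvalidSignalError(f"{path}: malformed row at line {int(bad.idxmax()) + 2}")
    t = df["time_s"].to_numpy(dtype=float)
    inferred_rate = rate or meta.get("rate_hz") or (
        1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 20.0
    )
    return AccelSignal(
        df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float),
        rate=float(round(inferred_rate, 6)),
        site=site or meta.get("site", "chest_left"),
        start_offset=float(t[0]) if len(t) else 0.0,
    )


# ---------------------------------------------------------------------------
# epoch frame / labels / bouts / annotations

def write_epoch_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_epoch_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = [c for c in EPOCH_COLUMNS if not c.startswith("mag")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidSignalError(f"{path}: missing epoch columns {missing}")
    return df


def write_labels_csv(stream: LabelStream, path: str | Path) -> None:
    df = pd.DataFrame({
        "epoch_s": stream.times,
        "label": [l.value for l in stream.labels],
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_labels_csv(path: str | Path, source: str = "algorithm") -> LabelStream:
    df = pd.read_csv(path)
    if not {"epoch_s", "label"} <= set(df.columns):
        raise InvalidSignalError(f"{path}: expected columns epoch_s,label")
    times = df["epoch_s"].to_numpy(dtype=float)
    rate = 1.0 / float(np.median(np.diff(times))) if len(times) > 1 else 5.0
    return LabelStream(
        labels=df["label"].to_numpy(),
        rate=float(round(rate, 6)),
        start_s=float(times[0]) - 0.5 / rate if len(times) else 0.0,
        source=source,
    )


def write_bouts_csv(bouts: list[Bout], path: str | Path) -> None:
    df = pd.DataFrame({
        "label": [b.label.value for b in bouts],
        "start_s": [b.start_s for b in bouts],
        "duration_s": [b.duration_s for b in bouts],
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_annotations_csv(track: AnnotationTrack, path: str | Path) -> None:
    df = pd.DataFrame(
        [(s, e, l.value) for s, e, l in track.intervals],
        columns=["start_s", "end_s", "label"],
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_annotations_csv(path: str | Path) -> AnnotationTrack:
    df = pd.read_csv(path)
    if not {"start_s", "end_s", "label"} <= set(df.columns):
        raise InvalidSignalError(f"{path}: expected columns start_s,end_s,label")
    return AnnotationTrack([
        (float(r.start_s), float(r.end_s), ActivityLabel(str(r.label)))
        for r in df.itertuples()
    ])


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def config_manifest(config: ClassifierConfig, extra: dict | None = None) -> dict:
    """Machine-readable provenance: package version + config hash/values."""
    payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()}
    blob = json.dumps(payload, sort_keys=True)
    manifest = {
        "icumotion_version": __version__,
        "classifier_config": payload,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    if extra:
        manifest.update(extra)
    return manifest


def load_config_yaml(path: str | Path) -> ClassifierConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("semi_sit_phi", "cycle_freq_band"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ClassifierConfig(**raw)


# ---------------------------------------------------------------------------
# processing pipeline

def process_sensor(
    sig: AccelSignal,
    calibration_window: tuple[float, float],
    cutoff_hz: float = 0.25,
    rest_activity_threshold: float = 0.03,
):
    """Condition one sensor: median filter, gravity, angles, baseline, SMA.

    Returns (orientation, sma, gravity, offsets).  The calibration window
    must be quiet: its SMA must stay at/below the rest-activity threshold,
    otherwise the supine-rest assumption is violated and an error is raised.
    """
    smoothed = median_filter3(sig)
    gravity = extract_gravity(smoothed, cutoff_hz=cutoff_hz)
    angles = compute_tilt_angles(gravity)
    sma = compute_sma(smoothed, gravity)
    w0, w1 = calibration_window
    in_window = (sma.times >= w0) & (sma.times <= w1)
    if in_window.any() and np.max(sma.values[in_window]) > rest_activity_threshold:
        raise InvalidSignalError(
            f"calibration window ({w0:.1f}, {w1:.1f}) s is not at rest for site "
            f"{sig.site}: peak SMA {np.max(sma.values[in_window]):.3f} g; "
            "supply a quiet supine interval"
        )
    offsets, corrected = calibrate_supine(angles, calibration_window)
    return corrected, sma, gravity, offsets


def process_session(
    chest: AccelSignal,
    thigh: AccelSignal,
    calibration_window: tuple[float, float],
    cutoff_hz: float = 0.25,
    rest_activity_threshold: float = 0.03,
) -> pd.DataFrame:
    """Full raw-to-epoch-frame chain for one chest + thigh session."""
    if not chest.site.startswith("chest") or not thigh.site.startswith("thigh"):
        raise InvalidSignalError(
            f"need exactly one chest and one thigh sensor, got {chest.site}/{thigh.site}"
        )
    c_ang, c_sma, c_grav, _ = process_sensor(
        chest, calibration_window, cutoff_hz, rest_activity_threshold)
    t_ang, t_sma, t_grav, _ = process_sensor(
        thigh, calibration_window, cutoff_hz, rest_activity_threshold)
    return build_epoch_frame((c_ang, c_sma), (t_ang, t_sma), c_grav, t_grav)
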