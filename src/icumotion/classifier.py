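"""Rule-based activity classification from fused chest/thigh epochs.

The decision logic mirrors how clinicians reason about in-bed activity: the
SMA (movement intensity) of both sensors first splits each 0.2 s epoch into
static and dynamic; static epochs are assigned a posture from the chest
inclination (phi), chest roll (theta) and thigh inclination, while dynamic
epochs become walking, bed cycling, or a transition depending on the
duration and posture consistency of the surrounding dynamic run and on
thigh periodicity.

Category conventions follow the clinical merges used during validation:
side lying and semi (reclined-side) lying collapse into single left/right
"side-semi lying" categories, and sitting on the edge of the bed and in a
chair collapse into one sitting category.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signals import EPOCH_RATE, EPOCH_S

logger = logging.getLogger(__name__)


class ActivityLabel(Enum):
    """Activity classes distinguishable by the dual-sensor setup."""

    SUPINE = "SUPINE"
    PRONE = "PRONE"
    SIDE_SEMI_LEFT = "SIDE_SEMI_LEFT"    # side lying + semi lying, left
    SIDE_SEMI_RIGHT = "SIDE_SEMI_RIGHT"  # side lying + semi lying, right
    SEMI_SIT = "SEMI_SIT"                # in bed, bed head raised
    SIT = "SIT"                          # edge of bed or chair
    STAND = "STAND"
    WALK = "WALK"
    CYCLE = "CYCLE"                      # bed-cycle ergometer
    TRANSITION = "TRANSITION"
    UNKNOWN = "UNKNOWN"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


STATIC_LABELS = frozenset({
    ActivityLabel.SUPINE, ActivityLabel.PRONE, ActivityLabel.SIDE_SEMI_LEFT,
    ActivityLabel.SIDE_SEMI_RIGHT, ActivityLabel.SEMI_SIT, ActivityLabel.SIT,
    ActivityLabel.STAND,
})
DYNAMIC_LABELS = frozenset({ActivityLabel.WALK, ActivityLabel.CYCLE, ActivityLabel.TRANSITION})


@dataclass
class ClassifierConfig:
    """Tunable decision boundaries of the classifier.

    The rest-activity threshold (0.03 g) separates static from dynamic
    epochs: an epoch is dynamic only when either sensor's SMA is strictly
    above the threshold.  A preset with 0.04 g is provided as
    :meth:`alternative_threshold` for sensitivity analyses.  Angle
    boundaries are in degrees; they default to posture geometry (45 deg
    trunk inclination separating upright from reclined, 70 deg separating
    reclined from lying) and are meant to be tuned per population.
    """

    rest_activity_threshold: float = 0.03   # g
    upright_phi_max: float = 45.0           # chest phi below -> trunk upright
    horizontal_phi_min: float = 70.0        # chest phi at/above -> lying
    thigh_vertical_max: float = 45.0        # thigh phi below -> leg vertical
    semi_sit_phi: tuple[float, float] = (45.0, 70.0)
    supine_roll_max: float = 45.0           # |chest roll| at/below -> supine
    prone_roll_min: float = 135.0           # |chest roll| at/above -> prone
    cycle_freq_band: tuple[float, float] = (0.2, 2.0)  # Hz, [low, high)
    walk_min_run_s: float = 3.0             # shortest dynamic run called walking
    magnitude_guard_g: float = 0.3          # |gravity magnitude - 1| above -> UNKNOWN
    roll_positive_right: bool = True        # positive theta = toward right side
    # Dynamic-run context knobs
    cycle_window_s: float = 4.0             # context window for periodicity
    cycle_min_cycles: float = 2.0           # revolutions required inside the window
    cycle_min_amp_deg: float = 0.5          # spectral amplitude floor (thigh angle)
    cycle_band_frac: float = 0.5            # peak power / band power required
    min_bout_s: float = 0.0                 # optional label smoothing, off by default

    def __post_init__(self) -> None:
        lo, hi = self.semi_sit_phi
        if not (self.upright_phi_max <= lo < hi <= self.horizontal_phi_min):
            raise ValueError(
                "semi-sit phi band must lie within [upright_phi_max, horizontal_phi_min]"
            )
        if self.rest_activity_threshold <= 0:
            raise ValueError("rest-activity threshold must be positive")
        if not 0 <= self.supine_roll_max < self.prone_roll_min <= 180:
            raise ValueError("roll boundaries must satisfy 0 <= supine < prone <= 180")

    @classmethod
    def alternative_threshold(cls, **kwargs) -> "ClassifierConfig":
        """Preset using the 0.04 g rest-activity threshold."""
        kwargs.setdefault("rest_activity_threshold", 0.04)
        return cls(**kwargs)


@dataclass
class DynamicContext:
    """Context of the dynamic run an epoch belongs to (pass-1 output).

    ``run_s`` is the duration of the longest upright stretch (trunk and
    thigh both near-vertical) of the dynamic run that contains the epoch;
    ``walk_ok`` marks epochs inside such a stretch.  Walking is sustained
    upright movement, whereas a transition changes posture partway through
    its run, so only the upright stretch counts toward the walking-duration
    requirement.
    """

    run_s: float = 0.0          # upright stretch duration within the run
    walk_ok: bool = False       # epoch lies inside the upright stretch
    cycling: bool = False       # sustained thigh periodicity around the epoch


@dataclass
class LabelStream:
    """One activity label per 5 Hz epoch."""

    labels: np.ndarray
    rate: float = EPOCH_RATE
    start_s: float = 0.0
    source: str = "algorithm"

    def __post_init__(self) -> None:
        self.labels = np.asarray(
            [l if isinstance(l, ActivityLabel) else ActivityLabel(str(l)) for l in self.labels],
            dtype=object,
        )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def times(self) -> np.ndarray:
        """Epoch center times on the session clock."""
        return self.start_s + (np.arange(len(self.labels)) + 0.5) / self.rate

    @property
    def duration(self) -> float:
        return len(self.labels) / self.rate


@dataclass
class Bout:
    """Maximal run of consecutive epochs sharing one label."""

    label: ActivityLabel
    start_s: float
    duration_s: float
    epoch_count: int


def _is_static_record(sma_mc: float, sma_t: float, config: ClassifierConfig) -> bool:
    # "<= threshold" is static; strictly above is dynamic.
    return sma_mc <= config.rest_activity_threshold and sma_t <= config.rest_activity_threshold


def _classify_static(phi_mc: float, theta_mc: float, phi_t: float, config: ClassifierConfig) -> ActivityLabel:
    if phi_mc < config.upright_phi_max:
        # Trunk upright: the thigh disambiguates standing from sitting.
        if phi_t < config.thigh_vertical_max:
            return ActivityLabel.STAND
        return ActivityLabel.SIT
    if phi_mc < config.horizontal_phi_min:
        # Trunk reclined: semi-sitting when the legs lie in bed; a reclined
        # trunk over vertical legs is read as (slouched) sitting.
        lo, hi = config.semi_sit_phi
        if lo <= phi_mc < hi:
            if phi_t >= config.thigh_vertical_max:
                return ActivityLabel.SEMI_SIT
            return ActivityLabel.SIT
        return ActivityLabel.UNKNOWN  # configured dead-band
    # Trunk horizontal: lying posture from the chest roll.
    roll = theta_mc if config.roll_positive_right else -theta_mc
    if abs(roll) <= config.supine_roll_max:
        return ActivityLabel.SUPINE
    if abs(roll) >= config.prone_roll_min:
        return ActivityLabel.PRONE
    return ActivityLabel.SIDE_SEMI_RIGHT if roll > 0 else ActivityLabel.SIDE_SEMI_LEFT


def classify_epoch(record, config: ClassifierConfig | None = None,
                   context: DynamicContext | None = None) -> ActivityLabel:
    """Assign an activity label to a single fused epoch record.

    ``record`` is any mapping with keys ``phi_mc``, ``theta_mc``, ``phi_t``,
    ``sma_mc``, ``sma_t`` (and optionally ``mag_mc``/``mag_t`` for the wear
    guard).  ``context`` describes the surrounding dynamic run; without it a
    dynamic epoch can only be a transition.
    """
    config = config or ClassifierConfig()
    context = context or DynamicContext()
    try:
        phi_mc = float(record["phi_mc"])
        theta_mc = float(record["theta_mc"])
        phi_t = float(record["phi_t"])
        sma_mc = float(record["sma_mc"])
        sma_t = float(record["sma_t"])
    except (KeyError, TypeError, ValueError) as exc:
        logger.warning("unreadable epoch record (%s); labeling UNKNOWN", exc)
        return ActivityLabel.UNKNOWN
    values = (phi_mc, theta_mc, phi_t, sma_mc, sma_t)
    if not all(math.isfinite(v) for v in values):
        logger.warning("non-finite epoch features %s; labeling UNKNOWN", values)
        return ActivityLabel.UNKNOWN
    if _is_static_record(sma_mc, sma_t, config):
        # Wear guard applies at rest only: during movement the low-pass
        # gravity estimate legitimately departs from 1 g, but a resting
        # sensor reading far from 1 g indicates non-wear or a unit error.
        for key in ("mag_mc", "mag_t"):
            try:
                mag = float(record[key])
            except (KeyError, IndexError, TypeError):
                continue
            if math.isfinite(mag) and abs(mag - 1.0) > config.magnitude_guard_g:
                return ActivityLabel.UNKNOWN
        return _classify_static(phi_mc, theta_mc, phi_t, config)

    if context.cycling and phi_mc >= config.upright_phi_max:
        return ActivityLabel.CYCLE
    if (
        context.run_s >= config.walk_min_run_s
        and context.walk_ok
        and phi_mc < config.upright_phi_max
        and sma_t > config.rest_activity_threshold
    ):
        return ActivityLabel.WALK
    return ActivityLabel.TRANSITION


def detect_cycling(
    thigh_sma_window: np.ndarray,
    thigh_angle_window: np.ndarray,
    config: ClassifierConfig | None = None,
    rate: float = EPOCH_RATE,
) -> bool:
    """Detect sustained pedaling periodicity in a thigh feature window.

    True when the dominant (non-DC) spectral peak of the linearly detrended
    thigh inclination falls inside ``cycle_freq_band``, completes at least
    ``cycle_min_cycles`` revolutions inside the window, carries at least
    ``cycle_band_frac`` of the band's power, and exceeds a small amplitude
    floor (so sensor noise on a still leg never looks periodic).  Pedaling
    is carried by the angle; the SMA window is accepted only when the angle
    window is unusable (too short or non-finite), because one-shot movement
    bursts also put broadband power into the SMA and would masquerade as
    periodicity.
    """
    config = config or ClassifierConfig()
    angle = np.asarray(thigh_angle_window, dtype=float)
    need = int(config.cycle_window_s * rate)
    if angle.ndim == 1 and len(angle) >= need and np.all(np.isfinite(angle)):
        return _periodic_in_band(angle, rate, config, config.cycle_min_amp_deg)
    sma = np.asarray(thigh_sma_window, dtype=float)
    if sma.ndim == 1 and len(sma) >= need and np.all(np.isfinite(sma)):
        return _periodic_in_band(sma, rate, config, amp_floor=0.01)
    return False


def _periodic_in_band(window: np.ndarray, rate: float, config: ClassifierConfig,
                      amp_floor: float) -> bool:
    n = len(window)
    if not np.all(np.isfinite(window)):
        return False
    x = sps.detrend(window, type="linear")
    if np.allclose(x, 0.0):
        return False
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    power[0] = 0.0  # detrended anyway; never pick DC
    k = int(np.argmax(power))
    f_peak = freqs[k]
    lo, hi = config.cycle_freq_band
    if not (lo <= f_peak < hi):
        return False
    if f_peak * (n / rate) < config.cycle_min_cycles:
        return False
    band = (freqs >= lo) & (freqs < hi)
    band_power = power[band].sum()
    if band_power <= 0 or power[k] < config.cycle_band_frac * band_power:
        return False
    amplitude = 2.0 * np.abs(spec[k]) / n
    return amplitude >= amp_floor


def _dynamic_runs(dynamic: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal dynamic runs (stop exclusive)."""
    runs = []
    n = len(dynamic)
    i = 0
    while i < n:
        if dynamic[i]:
            j = i
            while j < n and dynamic[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def classify_recording(frame: pd.DataFrame, config: ClassifierConfig | None = None) -> LabelStream:
    """Classify a full epoch frame with two passes.

    Pass 1 marks each epoch static/dynamic, finds maximal dynamic runs, and
    evaluates run-level context: run duration, whether the run's postures
    are consistent with walking (trunk and thigh upright throughout most of
    the run), and per-epoch thigh periodicity on a centered sliding window.
    Pass 2 applies :func:`classify_epoch` with that context.
    """
    config = config or ClassifierConfig()
    if frame is None or len(frame) == 0:
        raise ValueError("cannot classify an empty epoch frame")
    n = len(frame)
    sma_mc = frame["sma_mc"].to_numpy(dtype=float)
    sma_t = frame["sma_t"].to_numpy(dtype=float)
    phi_mc = frame["phi_mc"].to_numpy(dtype=float)
    phi_t = frame["phi_t"].to_numpy(dtype=float)
    thr = config.rest_activity_threshold
    dynamic = (sma_mc > thr) | (sma_t > thr)

    # Walking = a sustained upright stretch of a dynamic run.  Transitions
    # change posture partway through, so only maximal sub-runs where trunk
    # and thigh are simultaneously near-vertical count toward the walking
    # duration requirement.
    run_s = np.zeros(n)
    walk_ok = np.zeros(n, dtype=bool)
    upright = (phi_mc < config.upright_phi_max) & (phi_t < config.thigh_vertical_max)
    for start, stop in _dynamic_runs(dynamic):
        for sub_start, sub_stop in _dynamic_runs(upright[start:stop]):
            dur = (sub_stop - sub_start) * EPOCH_S
            lo, hi = start + sub_start, start + sub_stop
            run_s[lo:hi] = dur
            walk_ok[lo:hi] = True

    w = int(round(config.cycle_window_s * EPOCH_RATE))
    cycling = np.zeros(n, dtype=bool)
    if n >= w:
        half = w // 2
        cache: dict[int, bool] = {}
        for i in np.where(dynamic)[0]:
            a = min(max(0, i - half), n - w)
            if a not in cache:
                cache[a] = detect_cycling(sma_t[a:a + w], phi_t[a:a + w], config)
            cycling[i] = cache[a]

    records = frame.to_dict("records")
    labels = [
        classify_epoch(
            rec, config,
            DynamicContext(run_s=run_s[i], walk_ok=bool(walk_ok[i]), cycling=bool(cycling[i])),
        )
        for i, rec in enumerate(records)
    ]
    stream = LabelStream(
        labels=np.array(labels, dtype=object),
        rate=EPOCH_RATE,
        start_s=float(frame["epoch_s"].iloc[0]) - EPOCH_S / 2,
        source="algorithm",
    )
    if config.min_bout_s > 0:
        stream = smooth_short_bouts(stream, config.min_bout_s)
    return stream


def smooth_short_bouts(stream: LabelStream, min_bout_s: float) -> LabelStream:
    """Optionally absorb bouts shorter than ``min_bout_s`` into their predecessor."""
    labels = stream.labels.copy()
    changed = True
    while changed:
        changed = False
        for bout in extract_bouts(LabelStream(labels, stream.rate, stream.start_s, stream.source)):
            if bout.duration_s < min_bout_s:
                i0 = int(round((bout.start_s - stream.start_s) * stream.rate))
                if i0 > 0:
                    labels[i0:i0 + bout.epoch_count] = labels[i0 - 1]
                    changed = True
                    break
    return replace(stream, labels=labels)


def extract_bouts(stream: LabelStream) -> list[Bout]:
    """Run-length encode a label stream into activity bouts.

    Bout counts per label give the activity frequency; bout durations sum to
    the stream duration.  ``bouts_to_stream`` is the exact inverse.
    """
    if len(stream) == 0:
        raise ValueError("cannot extract bouts from an empty stream")
    bouts: list[Bout] = []
    labels = stream.labels
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            count = i - start
            bouts.append(Bout(
                label=labels[start],
                start_s=stream.start_s + start / stream.rate,
                duration_s=count / stream.rate,
                epoch_count=count,
            ))
            start = i
    return bouts


def bouts_to_stream(bouts: list[Bout], rate: float = EPOCH_RATE, source: str = "algorithm") -> LabelStream:
    """Reconstruct the epoch label stream from its bout encoding."""
    if not bouts:
        raise ValueError("no bouts to decode")
    labels = np.concatenate([np.full(b.epoch_count, b.label, dtype=object) for b in bouts])
    return LabelStream(labels=labels, rate=rate, start_s=bouts[0].start_s, source=source)


def duration_totals(stream: LabelStream) -> dict[ActivityLabel, float]:
    """Total seconds per activity label (for ICC-style duration comparisons)."""
    totals: dict[ActivityLabel, float] = {}
    for bout in extract_bouts(stream):
        totals[bout.label] = totals.get(bout.label, 0.0) + bout.duration_s
    return totals


def summarize(stream: LabelStream) -> dict:
    """Per-class frequency (bout count) and total duration, JSON-ready."""
    bouts = extract_bouts(stream)
    summary: dict[str, dict] = {}
    for bout in bouts:
        entry = summary.setdefault(bout.label.value, {"bouts": 0, "total_s": 0.0})
        entry["bouts"] += 1
        entry["total_s"] = round(entry["total_s"] + bout.duration_s, 6)
    return {
        "duration_s": round(stream.duration, 6),
        "epochs": len(stream),
        "classes": summary,
    }
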