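"""Validation machinery: alignment, annotation resampling, %Agr, ICC(A,1).

The sensor stream and the reference annotations live on different clocks
(the sensors start recording before the video).  Alignment uses the first
strong SMA increase, which marks the first transition of the protocol.
Annotations at arbitrary time resolution are resampled to the common 5 Hz
epoch grid by the label covering each epoch's center instant.  Agreement is
quantified per class as the percentage of reference epochs the test stream
labels identically (%Agr, asymmetric: the reference is authoritative) and,
for duration totals, by the intraclass correlation ICC(A,1) — two-way
model, absolute agreement, single measures.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import ActivityLabel, LabelStream
from .signals import EPOCH_RATE, SmaSeries

logger = logging.getLogger(__name__)

#: Default SMA level marking the "strong increase" used for clock alignment.
#: Well above the 0.03 g rest-activity threshold — about halfway up to the
#: plateau of a self-initiated transition burst — so that the detected
#: instant sits on the steep rise of the first transition rather than on
#: the shoulder that the 1 s SMA window smears ahead of it.
ALIGN_THRESHOLD_G = 0.08


class AlignmentError(RuntimeError):
    """Raised when no usable SMA peak / transition exists for alignment."""


@dataclass
class AnnotationTrack:
    """Non-overlapping labeled intervals [start_s, end_s) at any resolution."""

    intervals: list[tuple[float, float, ActivityLabel]]

    def __post_init__(self) -> None:
        cleaned = []
        for start, end, label in self.intervals:
            if end <= start:
                raise ValueError(f"interval ({start}, {end}) has non-positive length")
            if not isinstance(label, ActivityLabel):
                label = ActivityLabel(str(label))
            cleaned.append((float(start), float(end), label))
        cleaned.sort(key=lambda iv: iv[0])
        for (s0, e0, _), (s1, _, _) in zip(cleaned, cleaned[1:]):
            if s1 < e0 - 1e-9:
                raise ValueError("annotation intervals overlap")
        self.intervals = cleaned

    @classmethod
    def from_label_stream(cls, stream: LabelStream) -> "AnnotationTrack":
        from .classifier import extract_bouts

        ivs = [
            (b.start_s, b.start_s + b.duration_s, b.label) for b in extract_bouts(stream)
        ]
        return cls(ivs)

    @property
    def end_s(self) -> float:
        return self.intervals[-1][1]


def align_by_first_peak(
    sma: SmaSeries,
    reference: AnnotationTrack,
    threshold: float = ALIGN_THRESHOLD_G,
) -> float:
    """Clock offset (sensor minus annotation) from the first movement burst.

    Returns the time of the first SMA value exceeding ``threshold`` minus
    the start of the first annotated transition; subtracting the offset from
    sensor timestamps moves them onto the annotation clock.
    """
    above = np.nonzero(sma.values > threshold)[0]
    if len(above) == 0:
        raise AlignmentError(f"no SMA value exceeds {threshold} g; cannot align")
    first_transition = next(
        (iv for iv in reference.intervals if iv[2] is ActivityLabel.TRANSITION), None
    )
    if first_transition is None:
        raise AlignmentError("reference annotations contain no transition interval")
    return float(sma.times[above[0]] - first_transition[0])


def resample_annotations(
    track: AnnotationTrack,
    rate: float = EPOCH_RATE,
    start_s: float = 0.0,
    end_s: float | None = None,
) -> LabelStream:
    """Resample interval annotations onto the epoch grid.

    Each epoch takes the label of the half-open interval [start, end)
    containing the epoch's center instant (deterministic; no ties). Gaps are
    labeled UNKNOWN.
    """
    if end_s is None:
        end_s = track.end_s
    n = int(np.floor((end_s - start_s) * rate + 1e-9))
    centers = start_s + (np.arange(n) + 0.5) / rate
    starts = np.array([iv[0] for iv in track.intervals])
    ends = np.array([iv[1] for iv in track.intervals])
    labels = np.full(n, ActivityLabel.UNKNOWN, dtype=object)
    idx = np.searchsorted(starts, centers, side="right") - 1
    valid = idx >= 0
    covered = valid & (centers < ends[np.clip(idx, 0, None)])
    for i in np.nonzero(covered)[0]:
        labels[i] = track.intervals[idx[i]][2]
    return LabelStream(labels=labels, rate=rate, start_s=start_s, source="rater")


@dataclass
class AgreementReport:
    """Per-class and overall percentage agreement against a reference stream."""

    per_class: dict[ActivityLabel, float]
    overall: float
    confusion: pd.DataFrame       # rows: reference classes, cols: predicted
    epochs_compared: int

    def to_dict(self) -> dict:
        return {
            "overall_pct": round(self.overall, 4),
            "epochs_compared": self.epochs_compared,
            "per_class_pct": {k.value: round(v, 4) for k, v in self.per_class.items()},
            "confusion": {
                ref: {col: int(cnt) for col, cnt in row.items() if cnt}
                for ref, row in self.confusion.to_dict(orient="index").items()
            },
        }


def percent_agreement(reference: LabelStream, test: LabelStream) -> AgreementReport:
    """Percentage of reference epochs the test stream labels identically.

    Per class c present in the reference: 100 * #(ref==c and test==c) /
    #(ref==c).  The measure is asymmetric; ``reference`` plays the role of
    the authoritative rater.  Classes absent from the reference are simply
    not reported.
    """
    if len(reference) != len(test):
        raise ValueError(f"stream lengths differ: {len(reference)} vs {len(test)}")
    if abs(reference.rate - test.rate) > 1e-9:
        raise ValueError("streams have different epoch rates")
    ref = np.array([l.value for l in reference.labels])
    tst = np.array([l.value for l in test.labels])
    confusion = pd.crosstab(pd.Series(ref, name="reference"), pd.Series(tst, name="predicted"))
    per_class: dict[ActivityLabel, float] = {}
    for cls in confusion.index:
        row_total = int(confusion.loc[cls].sum())
        hits = int(confusion.loc[cls, cls]) if cls in confusion.columns else 0
        per_class[ActivityLabel(cls)] = 100.0 * hits / row_total
    overall = 100.0 * float(np.mean(ref == tst))
    return AgreementReport(
        per_class=per_class,
        overall=overall,
        confusion=confusion,
        epochs_compared=len(reference),
    )


@dataclass
class IccResult:
    """Intraclass correlation, two-way model, absolute agreement, single measures."""

    icc: float
    ci95: tuple[float, float]
    model: str = "ICC(A,1)"
    n_subjects: int = 0
    n_raters: int = 0


def icc_a1(ratings, alpha: float = 0.05) -> IccResult:
    """ICC(A,1) of an (n subjects x k raters) rating matrix.

    Computed from the two-way ANOVA mean squares as

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with MSR = between-subjects, MSC = between-raters, MSE = residual mean
    square.  The 95% CI follows the standard F-based construction for
    absolute-agreement single measures.  A matrix with zero total variance
    (all cells equal) is reported as icc = 1 with a degenerate CI.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D (subjects x raters) matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings contain missing/non-finite cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-30:
        logger.warning("zero total variance in ratings; ICC degenerate, reporting 1")
        return IccResult(icc=1.0, ci95=(float("nan"), float("nan")),
                         n_subjects=n, n_raters=k)
    icc = (msr - mse) / denom

    # McGraw & Wong F-based interval for ICC(A,1)
    if mse <= 0 or icc >= 1.0:
        ci = (float("nan"), float("nan")) if mse <= 0 else (icc, 1.0)
        return IccResult(icc=float(min(icc, 1.0)), ci95=ci, n_subjects=n, n_raters=k)
    a = (k * icc) / (n * (1 - icc))
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return IccResult(icc=float(icc), ci95=(float(lower), float(upper)),
                     n_subjects=n, n_raters=k)


def duration_matrix(streams_by_rater: dict[str, list[LabelStream]],
                    labels: list[ActivityLabel] | None = None) -> tuple[np.ndarray, list]:
    """Build the (subjects x raters) duration matrix for one activity set.

    ``streams_by_rater`` maps rater name -> list of label streams (one per
    subject, same order for every rater).  Rows are (subject, label) pairs;
    the cell value is that rater's total duration of the label for the
    subject, in seconds.
    """
    from .classifier import duration_totals

    raters = list(streams_by_rater)
    n_subjects = len(streams_by_rater[raters[0]])
    if any(len(v) != n_subjects for v in streams_by_rater.values()):
        raise ValueError("every rater needs one stream per subject")
    if labels is None:
        present: set[ActivityLabel] = set()
        for streams in streams_by_rater.values():
            for s in streams:
                present.update(duration_totals(s))
        labels = sorted(present, key=lambda l: l.value)
    rows = []
    index = []
    for subj in range(n_subjects):
        totals = {r: duration_totals(streams_by_rater[r][subj]) for r in raters}
        for lab in labels:
            rows.append([totals[r].get(lab, 0.0) for r in raters])
            index.append((subj, lab))
    return np.asarray(rows), index
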