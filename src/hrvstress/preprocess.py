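"""RR-series cleaning, windowing, missing-data scoring, and imputation.

Pipeline order is fixed: delete abnormal beats -> cut windows -> score missing
data -> filter on quality -> impute -> label.  On a gap-free record the
pipeline reproduces the input beat sequence exactly.

Missing-data scoring walks consecutive beat pairs inside a window; a pair
whose time difference exceeds the gap threshold (1.3 s by default, strict)
contributes ``N = floor(gap / meanRR)`` inferred missing beats, where
``meanRR`` is the mean of the up-to-10 observed RR values immediately
preceding the gap.  The window's missing percentage is
``100 * Ntot / (n_observed + Ntot)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from hrvstress.data_io import (
    NON_STRESS,
    STRESS,
    UNLABELED,
    LabeledSegment,
    PipelineConfig,
    RRRecord,
    ValidationError,
)

logger = logging.getLogger("hrvstress")


@dataclass
class RRWindow:
    """A fixed-length analysis segment of one subject's tachogram."""

    subject_id: str
    window_id: str
    start_s: float
    end_s: float
    beat_times: np.ndarray
    rr: np.ndarray
    p_missing: float = float("nan")
    n_missing_total: int = 0
    label: str = UNLABELED
    imputed: bool = False

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)


def remove_abnormal_beats(
    record: RRRecord, rr_min: float = 0.3, rr_max: float = 1.3
) -> tuple[RRRecord, int]:
    """Delete ectopic/abnormal beats: RR strictly above ``rr_max`` or strictly
    below ``rr_min``.

    Timestamps of retained beats are unchanged — deletion creates gaps in the
    beat sequence, it never shifts time.  Returns the cleaned record and the
    deletion count.  A record losing every beat is returned empty with a
    warning, not an exception.
    """
    keep = (record.rr >= rr_min) & (record.rr <= rr_max)
    n_deleted = int((~keep).sum())
    if n_deleted and not keep.any():
        logger.warning(
            "subject %s: all %d beats outside [%g, %g] s — empty record",
            record.subject_id, n_deleted, rr_min, rr_max,
        )
    cleaned = replace(
        record, beat_times=record.beat_times[keep], rr=record.rr[keep]
    )
    return cleaned, n_deleted


def segment_windows(
    record: RRRecord, window_len: float = 300.0, step: float = 60.0
) -> list[RRWindow]:
    """Cut the record into ``[k*step, k*step + window_len)`` windows.

    ``step == window_len`` gives side-by-side windows, ``step == 60`` the
    sliding mode.  The trailing span shorter than one window is dropped; a
    record shorter than one window yields an empty list with a warning.
    """
    duration = record.duration_s
    if duration < window_len:
        logger.warning(
            "subject %s: record (%.1f s) shorter than one %.0f s window",
            record.subject_id, duration, window_len,
        )
        return []
    n_windows = int(math.floor((duration - window_len) / step)) + 1
    windows = []
    for k in range(n_windows):
        start = k * step
        end = start + window_len
        mask = (record.beat_times >= start) & (record.beat_times < end)
        windows.append(
            RRWindow(
                subject_id=record.subject_id,
                window_id=f"{record.subject_id}_w{k:04d}",
                start_s=start,
                end_s=end,
                beat_times=record.beat_times[mask],
                rr=record.rr[mask],
            )
        )
    return windows


def _gap_counts(
    beat_times: np.ndarray, rr: np.ndarray, gap_threshold: float
) -> list[tuple[int, float, int]]:
    """Enumerate over-threshold inter-beat gaps as ``(i, gap, N)`` triples.

    ``i`` is the index of the beat ending the gap; ``N = floor(gap/meanRR)``
    with meanRR the mean of up to 10 observed RR values preceding the gap
    (the window median if none precede it).
    """
    gaps = []
    for i in range(1, beat_times.size):
        gap = beat_times[i] - beat_times[i - 1]
        if gap > gap_threshold:
            prior = rr[max(0, i - 10):i]
            mean_rr = float(prior.mean()) if prior.size else float(np.median(rr))
            gaps.append((i, float(gap), int(math.floor(gap / mean_rr))))
    return gaps


def missing_data_percentage(
    window: RRWindow, gap_threshold: float = 1.3
) -> tuple[float, int]:
    """Score a window's inferred missing-beat percentage.

    Returns ``(p_missing, n_missing_total)`` and stores both on the window.
    A window with fewer than two beats is unusable and scored 100%.
    """
    if window.n_beats < 2:
        logger.warning("window %s: <2 beats, flagged unusable", window.window_id)
        window.p_missing, window.n_missing_total = 100.0, 0
        return 100.0, 0
    n_tot = sum(n for _, _, n in _gap_counts(window.beat_times, window.rr, gap_threshold))
    p = 100.0 * n_tot / (window.n_beats + n_tot)
    window.p_missing, window.n_missing_total = p, n_tot
    return p, n_tot


def filter_windows(
    windows: list[RRWindow], p_max: float = 50.0
) -> tuple[list[RRWindow], pd.DataFrame]:
    """Keep windows with ``p_missing <= p_max`` (inclusive at the boundary).

    Returns the kept windows and a per-window quality report
    (``subject_id, window_id, p_missing, kept``).
    """
    rows, kept = [], []
    for w in windows:
        if math.isnan(w.p_missing):
            raise ValidationError(
                f"window {w.window_id}: p_missing not computed before filtering"
            )
        keep = w.p_missing <= p_max
        rows.append((w.subject_id, w.window_id, w.p_missing, keep))
        if keep:
            kept.append(w)
    report = pd.DataFrame(rows, columns=["subject_id", "window_id", "p_missing", "kept"])
    return kept, report


def impute_missing_beats(
    window: RRWindow, gap_threshold: float = 1.3
) -> RRWindow:
    """Fill over-threshold gaps with beats interpolated by a shape-preserving
    piecewise cubic Hermite polynomial (PCHIP).

    Each gap receives its inferred count ``N`` of beats, evenly spaced inside
    the gap; their RR values are read off a PCHIP interpolant fitted to the
    observed ``(beat time, RR)`` pairs, so imputed values never overshoot the
    local data.  A gap-free window is returned unchanged (identity), which
    also makes imputation idempotent.  Requires at least 4 observed beats.
    """
    if window.n_beats < 4:
        raise ValidationError(
            f"window {window.window_id}: {window.n_beats} beats < 4 required "
            "for cubic Hermite imputation"
        )
    gaps = _gap_counts(window.beat_times, window.rr, gap_threshold)
    gaps = [(i, g, n) for i, g, n in gaps if n > 0]
    if not gaps:
        return window

    interpolant = PchipInterpolator(window.beat_times, window.rr)
    new_t = [window.beat_times]
    for i, gap, n in gaps:
        t0 = window.beat_times[i - 1]
        spacing = gap / (n + 1)
        new_t.append(t0 + spacing * np.arange(1, n + 1))
    t_all = np.concatenate(new_t)
    order = np.argsort(t_all, kind="stable")
    t_all = t_all[order]
    rr_all = np.concatenate([window.rr, interpolant(np.concatenate(new_t[1:]))])[order]

    out = replace(window, beat_times=t_all, rr=rr_all, imputed=True)
    # quality metrics describe the observed window; keep them as scored
    out.p_missing, out.n_missing_total = window.p_missing, window.n_missing_total
    return out


def assign_labels(
    windows: list[RRWindow], segments: list[LabeledSegment]
) -> list[RRWindow]:
    """Label each window with the condition segment that fully contains it.

    Windows straddling a segment boundary, or outside every segment, stay
    unlabeled (and are excluded downstream).  Overlapping segments raise.
    """
    segs = sorted(segments, key=lambda s: s.start_s)
    for a, b in zip(segs, segs[1:]):
        if b.start_s < a.end_s:
            raise ValidationError(
                f"overlapping segments [{a.start_s}, {a.end_s}) / [{b.start_s}, {b.end_s})"
            )
    for w in windows:
        w.label = UNLABELED
        for seg in segs:
            if seg.contains(w.start_s, w.end_s):
                w.label = seg.label
                break
    return windows


def preprocess_record(
    record: RRRecord,
    config: PipelineConfig | None = None,
    mode: str = "sliding",
) -> tuple[list[RRWindow], pd.DataFrame]:
    """Run the full preprocessing chain on one record.

    ``mode`` is ``"sliding"`` (5-min windows on a 1-min slide; lab protocol)
    or ``"adjacent"`` (side-by-side windows; ambulatory protocol).  Returns
    labelled, imputed windows that passed the quality filter, plus the
    quality report covering every cut window.
    """
    config = config or PipelineConfig()
    if mode not in ("sliding", "adjacent"):
        raise ValidationError(f"mode must be 'sliding' or 'adjacent', got {mode!r}")
    step = config.slide_step if mode == "sliding" else config.window_len

    cleaned, _ = remove_abnormal_beats(record, config.rr_min, config.rr_max)
    windows = segment_windows(cleaned, config.window_len, step)
    for w in windows:
        missing_data_percentage(w, config.gap_threshold)
    kept, report = filter_windows(windows, config.p_missing_max)
    out = []
    for w in kept:
        if w.n_beats < 4:
            logger.warning("window %s: too few beats to impute, skipped", w.window_id)
            continue
        out.append(impute_missing_beats(w, config.gap_threshold))
    assign_labels(out, record.segments)
    return out, report
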