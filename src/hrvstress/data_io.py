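"""Canonical record types, CSV interchange formats, and pipeline configuration.

All quantities are in seconds internally; unit conversion happens only at the
file boundary (the CSV dialects below are already in seconds).

File dialects
-------------
RR CSV:      ``subject_id,t_s,rr_s`` — one row per beat; ``t_s`` is the beat
             timestamp from record start and ``rr_s`` the interval ending at
             that beat.
Label CSV:   ``subject_id,start_s,end_s,label`` with half-open ``[start, end)``
             condition segments and ``label`` in ``{stress, non_stress}``.
Feature CSV: ``subject_id,window_id,window_start_s,label`` followed by the 61
             registry features in canonical order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("hrvstress")

STRESS = "stress"
NON_STRESS = "non_stress"
UNLABELED = "unlabeled"
VALID_LABELS = (STRESS, NON_STRESS)


class FormatError(ValueError):
    """Malformed input file (missing column, bad dialect)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


class SchemaError(ValueError):
    """Table columns do not match the expected registry/schema."""


@dataclass(frozen=True)
class LabeledSegment:
    """Half-open ``[start_s, end_s)`` condition segment of one record."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"segment start {self.start_s} must precede end {self.end_s}"
            )
        if self.label not in VALID_LABELS:
            raise ValidationError(
                f"label {self.label!r} not in {VALID_LABELS}"
            )

    def contains(self, start_s: float, end_s: float) -> bool:
        """True iff the half-open interval lies entirely inside this segment."""
        return self.start_s <= start_s and end_s <= self.end_s


@dataclass
class RRRecord:
    """One subject's beat-time / RR-interval series with condition segments.

    ``rr[i]`` is the interval (s) ending at ``beat_times[i]`` (s from record
    start).  Between consecutive beats with no intervening deletion the two
    are redundant (``beat_times[i] - beat_times[i-1] == rr[i]``); after
    abnormal-beat deletion gaps appear and only the timestamps remain
    authoritative.
    """

    subject_id: str
    beat_times: np.ndarray
    rr: np.ndarray
    segments: list[LabeledSegment] = field(default_factory=list)
    source_tag: str = ""
    record_len_s: float | None = None  # nominal recording length; defaults to last beat time

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.beat_times.shape != self.rr.shape:
            raise ValidationError("beat_times and rr must have equal length")
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= 0):
            bad = int(np.argmax(np.diff(self.beat_times) <= 0)) + 1
            raise ValidationError(
                f"beat_times not strictly increasing at index {bad} "
                f"(subject {self.subject_id})"
            )
        if np.any(self.rr <= 0):
            raise ValidationError(f"non-positive RR value (subject {self.subject_id})")

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    @property
    def duration_s(self) -> float:
        """Record span in seconds: the nominal recording length if known,
        else the time of the last beat (records start at 0)."""
        if self.record_len_s is not None:
            return float(self.record_len_s)
        return float(self.beat_times[-1]) if self.beat_times.size else 0.0

    def validate_segments(self) -> None:
        """Raise if condition segments overlap."""
        segs = sorted(self.segments, key=lambda s: s.start_s)
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.end_s:
                raise ValidationError(
                    f"overlapping segments [{a.start_s}, {a.end_s}) and "
                    f"[{b.start_s}, {b.end_s}) for subject {self.subject_id}"
                )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: feature metadata columns, always first and in this order
META_COLUMNS = ("subject_id", "window_id", "window_start_s", "label")


@dataclass(frozen=True)
class PipelineConfig:
    """Every pipeline constant, with the study's defaults.

    rr_min, rr_max : physiological RR bounds (s); beats strictly outside are
        deleted (the 0.3–1.3 s range corresponds to 45–200 bpm).
    window_len, slide_step : analysis window length and slide (s); a step equal
        to the window length gives side-by-side windows, 60 s the sliding mode.
    gap_threshold : inter-beat gap (s) above which beats are counted missing.
    p_missing_max : windows with a higher missing-data percentage are dropped.
    resample_hz : uniform tachogram sampling rate for spectral analysis.
    band edges : VLF/LF/HF spectral band boundaries (Hz).
    human_energy_band : band (Hz) for the "human range energy" spectral
        descriptor (a fixed artifact convention; not an HRV band).
    smote_k : nearest-neighbour count for minority oversampling.
    outlier_scope : "train" applies IQR outlier removal inside each training
        fold only; "all" filters the whole table (sensitivity analysis).
    """

    rr_min: float = 0.3
    rr_max: float = 1.3
    window_len: float = 300.0
    slide_step: float = 60.0
    gap_threshold: float = 1.3
    p_missing_max: float = 50.0
    resample_hz: float = 8.0
    vlf_low: float = 0.003
    vlf_high: float = 0.04
    lf_high: float = 0.15
    hf_high: float = 0.4
    human_energy_low: float = 0.6
    human_energy_high: float = 2.5
    smote_k: int = 5
    outlier_scope: str = "train"
    use_welch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_len <= 0:
            raise ValidationError("window_len must be positive")
        if self.slide_step <= 0:
            raise ValidationError("slide_step must be positive")
        if not 0 < self.rr_min < self.rr_max:
            raise ValidationError("need 0 < rr_min < rr_max")
        if not 0 <= self.p_missing_max <= 100:
            raise ValidationError("p_missing_max must be a percentage in [0, 100]")
        if self.resample_hz <= 2 * self.hf_high:
            raise ValidationError("resample_hz must exceed twice the HF upper edge")
        if not 0 < self.vlf_low < self.vlf_high < self.lf_high < self.hf_high:
            raise ValidationError("spectral band edges must be increasing")
        if self.smote_k < 1:
            raise ValidationError("smote_k must be >= 1")
        if self.outlier_scope not in ("train", "all"):
            raise ValidationError("outlier_scope must be 'train' or 'all'")

    @property
    def bands(self):
        from hrvstress.features import SpectralBands

        return SpectralBands(
            vlf=(self.vlf_low, self.vlf_high),
            lf=(self.vlf_high, self.lf_high),
            hf=(self.lf_high, self.hf_high),
        )


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file; absent keys fall back to the study defaults.

    Raises on unknown keys and on out-of-range values.  ``overrides`` are
    applied after the file (CLI convenience).
    """
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"config {path} must be a mapping")
        values.update(raw)
    values.update(overrides)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**values)


# ---------------------------------------------------------------------------
# RR + label CSV
# ---------------------------------------------------------------------------

def read_rr_csv(path: str | Path, labels_path: str | Path | None = None,
                source_tag: str = "") -> list[RRRecord]:
    """Read an RR CSV (optionally with a companion label CSV) into records.

    Rows are grouped by subject and time-sorted; an empty file (header only)
    yields an empty list.  Non-monotone timestamps *after sorting* (ties)
    raise a :class:`ValidationError` naming the first offending row.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in ("subject_id", "t_s", "rr_s"):
        if col not in df.columns:
            raise FormatError(f"RR CSV {path} is missing column {col!r}")
    segments = read_labels_csv(labels_path) if labels_path is not None else {}

    records = []
    for subject_id, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("t_s", kind="stable")
        t = grp["t_s"].to_numpy(dtype=float)
        dup = np.flatnonzero(np.diff(t) <= 0)
        if dup.size:
            row = grp.index[dup[0] + 1]
            raise ValidationError(
                f"duplicate/non-increasing timestamp for subject {subject_id} "
                f"at input row {row}"
            )
        records.append(
            RRRecord(
                subject_id=str(subject_id),
                beat_times=t,
                rr=grp["rr_s"].to_numpy(dtype=float),
                segments=segments.get(str(subject_id), []),
                source_tag=source_tag,
            )
        )
    return records


def read_labels_csv(path: str | Path) -> dict[str, list[LabeledSegment]]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in ("subject_id", "start_s", "end_s", "label"):
        if col not in df.columns:
            raise FormatError(f"label CSV {path} is missing column {col!r}")
    out: dict[str, list[LabeledSegment]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), []).append(
            LabeledSegment(float(row.start_s), float(row.end_s), str(row.label))
        )
    return out


def write_rr_csv(records: Iterable[RRRecord], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"subject_id": rec.subject_id, "t_s": rec.beat_times, "rr_s": rec.rr}
        )
        for rec in records
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["subject_id", "t_s", "rr_s"])
    )
    df.to_csv(path, index=False, float_format="%.12g")


def write_labels_csv(records: Iterable[RRRecord], path: str | Path) -> None:
    rows = [
        (rec.subject_id, seg.start_s, seg.end_s, seg.label)
        for rec in records
        for seg in rec.segments
    ]
    pd.DataFrame(rows, columns=["subject_id", "start_s", "end_s", "label"]).to_csv(
        path, index=False, float_format="%.12g"
    )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def _check_feature_schema(columns: Sequence[str]) -> None:
    from hrvstress.features import FEATURE_REGISTRY

    expected = list(META_COLUMNS) + FEATURE_REGISTRY.names
    missing = [c for c in expected if c not in columns]
    extra = [c for c in columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"feature table schema mismatch: missing={missing} extra={extra}"
        )


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table in canonical column order (metadata, then the
    61 registry features); round-trips losslessly to 12 significant digits."""
    from hrvstress.features import FEATURE_REGISTRY

    _check_feature_schema(table.columns)
    ordered = table[list(META_COLUMNS) + FEATURE_REGISTRY.names]
    ordered.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    from hrvstress.features import FEATURE_REGISTRY

    df = pd.read_csv(path, dtype={"subject_id": str, "window_id": str})
    _check_feature_schema(df.columns)
    # integral-valued features (beat counts etc.) must read back as floats
    return df.astype({"window_start_s": float, **{n: float for n in FEATURE_REGISTRY.names}})
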