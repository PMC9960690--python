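"""Synthetic labelled RR-interval datasets with stress-dependent dynamics.

The generator encodes the autonomic assumptions the analysis relies on:
under stress, overall variability and vagal (HF, 0.25 Hz) modulation drop
while the LF/HF balance rises.  A beat sequence is built iteratively,
``t[k+1] = t[k] + RR(t[k])`` with

    RR(t) = rr0 * (1 + a_lf sin(2π·0.1·t + φ1) + a_hf sin(2π·0.25·t + φ2)) + ε,
    ε ~ Normal(0, noise_sd · rr0),

oscillators fixed at the LF/HF band centers so simulated power lands
unambiguously in the right bands.  Stress applies per-subject multipliers to
rr0 (slower→faster heart rate), a_hf (vagal withdrawal), a_lf and noise_sd.

Two dataset flavors: a lab protocol (15 min relaxation, 20 min stress,
10 min recovery per subject; sliding 5-min windows downstream) and an
ambulatory corpus (window-aligned stress episodes covering a configurable
~7% of recording time; side-by-side windows downstream, heavier beat-loss
gaps and ectopic beats).  Corruption deletes Poisson-placed spans of beats
(creating over-threshold gaps) and replaces single RR values with a
premature-beat pair (0.25 s, RR − 0.25 s) that the abnormal-beat rule later
removes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from hrvstress.data_io import (
    NON_STRESS,
    STRESS,
    LabeledSegment,
    RRRecord,
    ValidationError,
)

logger = logging.getLogger("hrvstress")

LF_TONE_HZ = 0.1
HF_TONE_HZ = 0.25


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject autonomic parameters and stress-effect multipliers.

    ``rr0`` is the baseline mean RR (s); ``a_lf``/``a_hf`` are relative
    oscillation amplitudes at the LF/HF tones; ``noise_sd`` the relative
    beat-to-beat noise.  Stress multiplies these by the ``stress_*`` factors.
    """

    rr0: float = 0.85
    a_lf: float = 0.03
    a_hf: float = 0.05
    noise_sd: float = 0.02
    stress_rr0_mult: float = 0.85
    stress_ahf_mult: float = 0.4
    stress_alf_mult: float = 1.2
    stress_noise_mult: float = 0.7

    def __post_init__(self) -> None:
        if min(self.a_lf, self.a_hf, self.noise_sd) < 0:
            raise ValidationError("amplitudes and noise_sd must be >= 0")
        if not 0.55 <= self.rr0 <= 1.2:
            raise ValidationError("rr0 must lie in [0.55, 1.2] s")

    def params(self, condition: str) -> tuple[float, float, float, float]:
        """(rr0, a_lf, a_hf, noise_sd) effective under the given condition."""
        if condition == STRESS:
            return (
                self.rr0 * self.stress_rr0_mult,
                self.a_lf * self.stress_alf_mult,
                self.a_hf * self.stress_ahf_mult,
                self.noise_sd * self.stress_noise_mult,
            )
        return self.rr0, self.a_lf, self.a_hf, self.noise_sd


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters for one dataset.

    Lab mode emits one 45-min record per subject (relax 900 s, stress 1200 s,
    recovery 600 s); ambulatory mode emits ``total_hours`` per subject with
    stress episodes aligned to the 300 s side-by-side window grid covering
    about ``stress_fraction`` of the windows.  ``gap_rate``/``ectopic_rate``
    are expected corruption events per 5 minutes.
    """

    protocol: str = "lab"
    n_subjects: int = 68
    relax_s: float = 900.0
    stress_s: float = 1200.0
    recovery_s: float = 600.0
    total_hours: float = 3.0
    stress_fraction: float = 0.07
    gap_rate: float = 0.2
    ectopic_rate: float = 0.5
    rr0_mean: float = 0.85
    rr0_sd: float = 0.07
    base_a_lf: float = 0.03
    base_a_hf: float = 0.05
    base_noise_sd: float = 0.02
    stress_rr0_mult: float = 0.85
    stress_ahf_mult: float = 0.4
    stress_alf_mult: float = 1.2
    stress_noise_mult: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in ("lab", "ambulatory"):
            raise ValidationError("protocol must be 'lab' or 'ambulatory'")
        if not 0 <= self.stress_fraction <= 1:
            raise ValidationError("stress_fraction must lie in [0, 1]")
        if self.stress_fraction in (0.0, 1.0):
            logger.warning(
                "stress_fraction %.0f%%: single-class subjects are likely",
                100 * self.stress_fraction,
            )
        if self.gap_rate < 0 or self.ectopic_rate < 0:
            raise ValidationError("corruption rates must be >= 0")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")

    @staticmethod
    def ambulatory(**kw) -> "SimConfig":
        """Ambulatory defaults: 25 subjects, heavier device-noise corruption."""
        defaults = dict(
            protocol="ambulatory", n_subjects=25, gap_rate=0.6, ectopic_rate=1.5
        )
        defaults.update(kw)
        return SimConfig(**defaults)


def draw_profile(config: SimConfig, rng: np.random.Generator) -> SubjectProfile:
    """Draw one subject's profile: rr0 ~ Normal(0.85, 0.07) clipped to
    [0.55, 1.2] s, amplitudes/noise jittered ±20% around the config base."""
    rr0 = float(np.clip(rng.normal(config.rr0_mean, config.rr0_sd), 0.55, 1.2))
    jitter = lambda base: float(base * rng.uniform(0.8, 1.2))
    return SubjectProfile(
        rr0=rr0,
        a_lf=jitter(config.base_a_lf),
        a_hf=jitter(config.base_a_hf),
        noise_sd=jitter(config.base_noise_sd),
        stress_rr0_mult=config.stress_rr0_mult,
        stress_ahf_mult=config.stress_ahf_mult,
        stress_alf_mult=config.stress_alf_mult,
        stress_noise_mult=config.stress_noise_mult,
    )


def _segment_beats(
    profile: SubjectProfile,
    condition: str,
    duration: float,
    rng: np.random.Generator,
    t_start: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate beats covering ``[t_start, t_start + duration]``.

    Oscillator phases are drawn once per segment.  Emitted RR values are
    clipped strictly inside (0.3, 1.3) s so clean segments pass the
    abnormal-beat filter untouched.
    """
    rr0, a_lf, a_hf, noise_sd = profile.params(condition)
    if rr0 * (1 - a_lf - a_hf) <= 0:
        raise ValidationError("profile implies non-positive RR")
    if duration < 60:
        raise ValidationError("segment duration must be >= 60 s")
    phi1, phi2 = rng.uniform(0, 2 * math.pi, size=2)
    end = t_start + duration
    times, rrs = [], []
    t = t_start
    while True:
        rr = rr0 * (
            1.0
            + a_lf * math.sin(2 * math.pi * LF_TONE_HZ * t + phi1)
            + a_hf * math.sin(2 * math.pi * HF_TONE_HZ * t + phi2)
        ) + rng.normal(0.0, noise_sd * rr0)
        rr = min(max(rr, 0.3 + 1e-6), 1.3 - 1e-6)
        if t + rr > end:
            break
        t += rr
        times.append(t)
        rrs.append(rr)
    return np.asarray(times), np.asarray(rrs)


def simulate_rr_segment(
    profile: SubjectProfile,
    condition: str,
    duration: float,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim",
) -> RRRecord:
    """Simulate one single-condition record of the given duration."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t, rr = _segment_beats(profile, condition, duration, rng)
    segments = (
        [LabeledSegment(0.0, duration, condition)]
        if condition in (STRESS, NON_STRESS)
        else []
    )
    return RRRecord(subject_id=subject_id, beat_times=t, rr=rr, segments=segments)


def corrupt_record(
    record: RRRecord,
    gap_rate: float,
    ectopic_rate: float,
    seed: int | np.random.Generator = 0,
) -> RRRecord:
    """Inject beat-loss gaps and ectopic beats.

    Gaps delete Poisson-placed spans of 2–8 consecutive beats (survivor
    timestamps unchanged), extended if needed so the resulting inter-beat gap
    exceeds 1.3 s.  Ectopics replace one RR value x >= 0.55 s with the
    premature pair (0.25 s, x − 0.25 s), which preprocessing later deletes.
    Rates are expected events per 5 minutes; rate 0 is the identity.
    """
    if gap_rate < 0 or ectopic_rate < 0:
        raise ValidationError("corruption rates must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = record.beat_times.copy()
    rr = record.rr.copy()
    duration = record.duration_s
    n_gaps = int(rng.poisson(gap_rate * duration / 300.0))
    n_ect = int(rng.poisson(ectopic_rate * duration / 300.0))

    for _ in range(n_gaps):
        if t.size < 12:
            logger.warning("record %s too short for more gaps", record.subject_id)
            break
        span = int(rng.integers(2, 9))
        i = int(rng.integers(1, max(2, t.size - span)))
        end = min(i + span, t.size - 1)
        while end < t.size - 1 and t[end] - t[i - 1] <= 1.3:
            end += 1
        keep = np.ones(t.size, dtype=bool)
        keep[i:end] = False
        t, rr = t[keep], rr[keep]

    for _ in range(n_ect):
        candidates = np.flatnonzero(rr >= 0.55)
        if candidates.size == 0:
            logger.warning("record %s has no RR >= 0.55 s for ectopics", record.subject_id)
            break
        i = int(rng.choice(candidates))
        x = rr[i]
        t_new = t[i] - x + 0.25
        t = np.insert(t, i, t_new)
        rr = np.insert(rr, i, 0.25)
        rr[i + 1] = x - 0.25

    return replace(record, beat_times=t, rr=rr)


def simulate_lab_dataset(config: SimConfig) -> list[RRRecord]:
    """Lab protocol: per subject one continuous 45-min record with segments
    relax [0, 900) → non-stress, stress [900, 2100) → stress, recovery
    [2100, 2700) → non-stress, plus the configured corruption."""
    if config.protocol != "lab":
        raise ValidationError("simulate_lab_dataset requires protocol='lab'")
    phases = [
        (config.relax_s, NON_STRESS),
        (config.stress_s, STRESS),
        (config.recovery_s, NON_STRESS),
    ]
    records = []
    for s in range(config.n_subjects):
        rng = np.random.default_rng([config.seed, s])
        profile = draw_profile(config, rng)
        t_parts, rr_parts, segments = [], [], []
        t_cursor = 0.0
        for dur, condition in phases:
            seg_t, seg_rr = _segment_beats(profile, condition, dur, rng, t_cursor)
            t_parts.append(seg_t)
            rr_parts.append(seg_rr)
            segments.append(LabeledSegment(t_cursor, t_cursor + dur, condition))
            t_cursor += dur
        record = RRRecord(
            subject_id=f"lab{s:03d}",
            beat_times=np.concatenate(t_parts),
            rr=np.concatenate(rr_parts),
            segments=segments,
            source_tag="lab",
            record_len_s=t_cursor,
        )
        records.append(
            corrupt_record(record, config.gap_rate, config.ectopic_rate, rng)
        )
    return records


def simulate_ambulatory_dataset(config: SimConfig) -> list[RRRecord]:
    """Ambulatory corpus: long records with rare stress episodes.

    Stress time is allotted per subject as a contiguous run of 300 s blocks
    aligned to the side-by-side window grid (expected count =
    stress_fraction × windows, randomised remainder), so the realized
    window-level class imbalance tracks the configured fraction.
    """
    if config.protocol != "ambulatory":
        raise ValidationError("requires protocol='ambulatory'")
    win = 300.0
    n_win = int(config.total_hours * 3600 / win)
    records = []
    for s in range(config.n_subjects):
        rng = np.random.default_rng([config.seed, s])
        profile = draw_profile(config, rng)
        target = config.stress_fraction * n_win
        k = int(math.floor(target)) + int(rng.random() < (target % 1.0))
        k = min(k, n_win)
        start_block = int(rng.integers(0, n_win - k + 1)) if k < n_win else 0
        blocks = []  # (duration, condition) runs
        if start_block > 0:
            blocks.append((start_block * win, NON_STRESS))
        if k > 0:
            blocks.append((k * win, STRESS))
        if start_block + k < n_win:
            blocks.append(((n_win - start_block - k) * win, NON_STRESS))

        t_parts, rr_parts, segments = [], [], []
        t_cursor = 0.0
        for dur, condition in blocks:
            seg_t, seg_rr = _segment_beats(profile, condition, dur, rng, t_cursor)
            t_parts.append(seg_t)
            rr_parts.append(seg_rr)
            segments.append(LabeledSegment(t_cursor, t_cursor + dur, condition))
            t_cursor += dur
        record = RRRecord(
            subject_id=f"amb{s:03d}",
            beat_times=np.concatenate(t_parts),
            rr=np.concatenate(rr_parts),
            segments=segments,
            source_tag="ambulatory",
            record_len_s=t_cursor,
        )
        records.append(
            corrupt_record(record, config.gap_rate, config.ectopic_rate, rng)
        )
    return records


def shifted_ambulatory_config(
    n_subjects: int = 10, total_hours: float = 1.5, seed: int = 0
) -> SimConfig:
    """Ambulatory variant emulating a different device and milder stressors.

    Relative to the default ambulatory corpus: higher beat-to-beat device
    noise (0.03 vs 0.02), a weaker heart-rate stress response (rr0 ×0.90 vs
    ×0.85) and milder vagal withdrawal (a_hf ×0.5 vs ×0.4).  Used as the
    held-out dataset in the cross-dataset generalizability harness.
    """
    return SimConfig.ambulatory(
        n_subjects=n_subjects,
        total_hours=total_hours,
        base_noise_sd=0.03,
        stress_rr0_mult=0.90,
        stress_ahf_mult=0.5,
        seed=seed,
    )
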