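"""The 61-feature HRV battery computed per analysis window.

Five blocks: 21 time-domain measures (counts, heart-rate summaries,
SDNN/RMSSD/SDSD, NN50/pNN50/NN20/pNN20 and the geometric TINN/triangular
index), 7 frequency-domain band powers from an FFT periodogram of the 8 Hz
resampled tachogram (VLF/LF/HF, total, LF/HF and normalized units), 3
Poincaré descriptors (SD1, SD2, SD1/SD2), 15 statistical descriptors of the
raw in-window RR sequence, and 14 spectral-shape descriptors of the PSD —
plus spectral spread (kept separate from its square, spectral variance),
giving 61 values in a fixed registry order.

Conventions (pinned for reproducibility): SDNN and heart-rate std use sample
(n-1) normalization; Poincaré variances are population variances; NN50/NN20
use strict > 50 ms / > 20 ms; TINN and the triangular index use the standard
7.8125 ms histogram bin; quantiles use linear interpolation (type 7).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.interpolate import PchipInterpolator

from hrvstress.data_io import META_COLUMNS, VALID_LABELS, PipelineConfig, ValidationError
from hrvstress.preprocess import RRWindow

logger = logging.getLogger("hrvstress")

#: NN-interval histogram bin width (s) for TINN / triangular index
HIST_BIN_S = 0.0078125

TIME_FEATURES = [
    "nni_count", "nni_mean", "nni_max", "hr_mean", "hr_min", "hr_max",
    "hr_std", "nni_diff_mean", "nni_diff_min", "nni_diff_max", "sdnn",
    "rmssd", "sdsd", "nn50", "pnn50", "nn20", "pnn20", "tinn_n", "tinn_m",
    "tinn", "tri_index",
]
FREQUENCY_FEATURES = [
    "vlf_power", "lf_power", "hf_power", "total_power", "lf_hf", "lf_nu",
    "hf_nu",
]
NONLINEAR_FEATURES = ["sd1", "sd2", "sd1_sd2"]
STATISTICAL_FEATURES = [
    "abs_energy", "autocorr_lag1", "rr_median", "rr_std", "entropy",
    "rr_iqr", "mean_abs_dev", "mean_abs_diff", "rr_mean", "median_diff",
    "median_abs_dev", "median_abs_diff", "kurtosis", "skewness", "slope",
]
SPECTRAL_SHAPE_FEATURES = [
    "spectral_centroid", "spectral_variance", "bandwidth",
    "spectral_skewness", "spectral_kurtosis", "spectral_entropy",
    "spectral_decrease", "spectral_rolloff_95", "spectral_distribution",
    "median_frequency", "spectral_energy", "human_range_energy",
    "fundamental_frequency", "psd_auc",
]


@dataclass(frozen=True)
class SpectralBands:
    """Contiguous VLF/LF/HF band edges (Hz), half-open ``[low, high)``."""

    vlf: tuple[float, float] = (0.003, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        edges = [*self.vlf, *self.lf, *self.hf]
        if not (edges[0] < edges[1] == edges[2] < edges[3] == edges[4] < edges[5]):
            raise ValidationError("bands must be contiguous, non-overlapping, increasing")


@dataclass(frozen=True)
class FeatureRegistry:
    """Fixed, versioned ordering of the 61 canonical feature names."""

    names: list
    domains: dict

    def __len__(self) -> int:
        return len(self.names)


def _build_registry() -> FeatureRegistry:
    names = (
        TIME_FEATURES + FREQUENCY_FEATURES + NONLINEAR_FEATURES
        + STATISTICAL_FEATURES + SPECTRAL_SHAPE_FEATURES + ["spectral_spread"]
    )
    domains = {}
    for n in TIME_FEATURES:
        domains[n] = "time"
    for n in FREQUENCY_FEATURES:
        domains[n] = "frequency"
    for n in NONLINEAR_FEATURES:
        domains[n] = "nonlinear"
    for n in STATISTICAL_FEATURES:
        domains[n] = "statistical"
    for n in SPECTRAL_SHAPE_FEATURES + ["spectral_spread"]:
        domains[n] = "spectral_shape"
    if len(set(names)) != 61:
        raise AssertionError("feature registry must contain 61 unique names")
    return FeatureRegistry(names=names, domains=domains)


FEATURE_REGISTRY = _build_registry()


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def _tinn_triangular(rr: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares triangular fit to the NN histogram (7.8125 ms bins).

    Returns (tinn_n, tinn_m, tinn, tri_index).  The triangle has vertices
    (N, 0), (X, D[X]), (M, 0) with X the modal bin center; N and M are chosen
    over bin centers to minimise the squared deviation from the histogram.
    The left and right errors are independent, so the search is separable.
    """
    lo = math.floor(rr.min() / HIST_BIN_S) * HIST_BIN_S
    hi = math.ceil(rr.max() / HIST_BIN_S) * HIST_BIN_S
    if hi - lo < HIST_BIN_S / 2:  # constant series: a single degenerate bin
        return float(rr.min()), float(rr.min()), 0.0, 1.0
    edges = np.arange(lo, hi + HIST_BIN_S / 2, HIST_BIN_S)
    counts, edges = np.histogram(rr, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    mode = int(np.argmax(counts))
    peak = counts[mode]

    def side_best(idx_range, left: bool) -> int:
        best, best_err = None, np.inf
        for j in idx_range:
            if left:
                ramp_idx = np.arange(j + 1, mode)
                frac = (centers[ramp_idx] - centers[j]) / (centers[mode] - centers[j])
                err = float((counts[: j + 1] ** 2).sum())
            else:
                ramp_idx = np.arange(mode + 1, j)
                frac = (centers[j] - centers[ramp_idx]) / (centers[j] - centers[mode])
                err = float((counts[j:] ** 2).sum())
            err += float(((counts[ramp_idx] - peak * frac) ** 2).sum())
            if err < best_err:
                best, best_err = j, err
        return best

    n_idx = side_best(range(0, mode), left=True) if mode > 0 else mode
    m_idx = (
        side_best(range(mode + 1, len(centers)), left=False)
        if mode < len(centers) - 1
        else mode
    )
    tinn_n = float(centers[n_idx])
    tinn_m = float(centers[m_idx])
    tri_index = rr.size / float(peak)
    return tinn_n, tinn_m, tinn_m - tinn_n, tri_index


def time_domain_features(window: RRWindow) -> dict:
    """Time-domain block: counts, HR summaries, variability and geometry."""
    rr = window.rr
    if rr.size < 2:
        raise ValidationError(f"window {window.window_id}: <2 beats for time domain")
    hr = 60.0 / rr
    diff = np.diff(rr)
    adiff = np.abs(diff)
    tinn_n, tinn_m, tinn, tri = _tinn_triangular(rr)
    return {
        "nni_count": float(rr.size),
        "nni_mean": float(rr.mean()),
        "nni_max": float(rr.max()),
        "hr_mean": float(hr.mean()),
        "hr_min": float(hr.min()),
        "hr_max": float(hr.max()),
        "hr_std": float(hr.std(ddof=1)),
        "nni_diff_mean": float(adiff.mean()),
        "nni_diff_min": float(adiff.min()),
        "nni_diff_max": float(adiff.max()),
        "sdnn": float(rr.std(ddof=1)),
        "rmssd": float(np.sqrt(np.mean(diff**2))),
        "sdsd": float(diff.std(ddof=1)) if diff.size > 1 else 0.0,
        "nn50": float(np.sum(adiff > 0.05)),
        "pnn50": float(100.0 * np.sum(adiff > 0.05) / adiff.size),
        "nn20": float(np.sum(adiff > 0.02)),
        "pnn20": float(100.0 * np.sum(adiff > 0.02) / adiff.size),
        "tinn_n": tinn_n,
        "tinn_m": tinn_m,
        "tinn": tinn,
        "tri_index": tri,
    }


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

def resample_and_psd(
    window: RRWindow,
    fs: float = 8.0,
    use_welch: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly resample the tachogram and return its one-sided PSD.

    The RR(t) series is interpolated with the shape-preserving cubic (PCHIP)
    onto a uniform grid at ``fs`` over [first beat, last beat], linearly
    detrended, and transformed with a plain FFT periodogram (Welch behind a
    flag).  The PSD is renormalised so that ``sum(psd) * df`` equals the
    variance of the detrended resampled signal (Parseval), units s²/Hz.
    Returns ``(freqs, psd)``.
    """
    if window.n_beats < 4:
        raise ValidationError(f"window {window.window_id}: <4 beats for PSD")
    t0, t1 = window.beat_times[0], window.beat_times[-1]
    if t1 - t0 < 60.0:
        raise ValidationError(
            f"window {window.window_id}: span {t1 - t0:.1f} s < 60 s, "
            "insufficient spectral resolution for LF"
        )
    n = int(math.floor((t1 - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs
    x = PchipInterpolator(window.beat_times, window.rr)(grid)
    x = signal.detrend(x, type="linear")
    if use_welch:
        freqs, psd = signal.welch(x, fs=fs, nperseg=min(n, 1024), detrend=False)
    else:
        freqs, psd = signal.periodogram(x, fs=fs, detrend=False)
    df = freqs[1] - freqs[0]
    var = float(np.var(x))
    total = float(psd.sum() * df)
    if total > 0:
        psd = psd * (var / total)
    return freqs, psd


def frequency_band_features(
    freqs: np.ndarray, psd: np.ndarray, bands: SpectralBands = SpectralBands()
) -> dict:
    """Band powers by rectangular integration with half-open membership."""
    df = freqs[1] - freqs[0]

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs < hi)
        return float(psd[mask].sum() * df)

    vlf = band_power(*bands.vlf)
    lf = band_power(*bands.lf)
    hf = band_power(*bands.hf)
    if hf > 0:
        lf_hf = lf / hf
    else:
        lf_hf = float(np.finfo(np.float64).max) if lf > 0 else 0.0
        logger.warning("HF power is 0: lf_hf set to sentinel")
    denom = lf + hf
    lf_nu = 100.0 * lf / denom if denom > 0 else 0.0
    hf_nu = 100.0 * hf / denom if denom > 0 else 0.0
    return {
        "vlf_power": vlf,
        "lf_power": lf,
        "hf_power": hf,
        "total_power": vlf + lf + hf,
        "lf_hf": lf_hf,
        "lf_nu": lf_nu,
        "hf_nu": hf_nu,
    }


# ---------------------------------------------------------------------------
# Poincaré
# ---------------------------------------------------------------------------

def poincare_features(window: RRWindow) -> dict:
    """Poincaré SD1/SD2 from population variances of RR and its differences."""
    rr = window.rr
    if rr.size < 3:
        raise ValidationError(f"window {window.window_id}: <3 beats for Poincaré")
    diff = np.diff(rr)
    var_d = float(np.var(diff))
    sd1 = math.sqrt(var_d / 2.0)
    sd2_sq = 2.0 * float(np.var(rr)) - var_d / 2.0
    sd2 = math.sqrt(max(sd2_sq, 0.0))
    if sd2 == 0.0:
        logger.warning("window %s: SD2 == 0, ratio guarded to 0", window.window_id)
    return {"sd1": sd1, "sd2": sd2, "sd1_sd2": sd1 / sd2 if sd2 > 0 else 0.0}


# ---------------------------------------------------------------------------
# statistical descriptors
# ---------------------------------------------------------------------------

def statistical_features(window: RRWindow) -> dict:
    """Distributional descriptors of the raw in-window RR sequence.

    Shannon entropy uses a 10-bin histogram of RR values (base 2, empty bins
    skipped); quantile-based features use the linear-interpolation quantile
    convention; zero-variance inputs yield guarded zeros for entropy,
    kurtosis, skewness and slope.
    """
    rr = window.rr
    if rr.size < 2:
        raise ValidationError(f"window {window.window_id}: <2 beats for statistics")
    diff = np.diff(rr)
    counts, _ = np.histogram(rr, bins=10)
    p = counts[counts > 0] / rr.size
    entropy = float(-(p * np.log2(p)).sum())
    std = float(rr.std())
    if std <= 1e-12:  # numerically constant series
        std = 0.0
    if std > 0:
        a, b = rr[:-1], rr[1:]
        if a.std() > 0 and b.std() > 0:
            autocorr = float(np.corrcoef(a, b)[0, 1])
        else:
            autocorr = 0.0
        kurt = float(stats.kurtosis(rr))
        skew = float(stats.skew(rr))
        slope = float(np.polyfit(np.arange(rr.size), rr, 1)[0])
    else:
        autocorr, kurt, skew, slope = 0.0, 0.0, 0.0, 0.0
    q75, q25 = np.quantile(rr, [0.75, 0.25])
    return {
        "abs_energy": float(np.sum(rr**2)),
        "autocorr_lag1": autocorr,
        "rr_median": float(np.median(rr)),
        "rr_std": std,
        "entropy": entropy,
        "rr_iqr": float(q75 - q25),
        "mean_abs_dev": float(np.mean(np.abs(rr - rr.mean()))),
        "mean_abs_diff": float(np.mean(np.abs(diff))),
        "rr_mean": float(rr.mean()),
        "median_diff": float(np.median(diff)),
        "median_abs_dev": float(np.median(np.abs(rr - np.median(rr)))),
        "median_abs_diff": float(np.median(np.abs(diff))),
        "kurtosis": kurt,
        "skewness": skew,
        "slope": slope,
    }


# ---------------------------------------------------------------------------
# spectral shape
# ---------------------------------------------------------------------------

def spectral_shape_features(
    freqs: np.ndarray,
    psd: np.ndarray,
    distribution_edge: float = 0.15,
    human_band: tuple[float, float] = (0.6, 2.5),
) -> dict:
    """Shape descriptors of the PSD treated as a distribution over frequency.

    ``distribution_edge`` sets the cutoff for the cumulative spectral
    distribution; ``human_band`` the band whose power fraction is reported as
    human-range energy.  An all-zero PSD yields all-zero features with a
    warning.
    """
    df = freqs[1] - freqs[0]
    total = float(psd.sum())
    out = {name: 0.0 for name in SPECTRAL_SHAPE_FEATURES + ["spectral_spread"]}
    if total <= 0:
        logger.warning("all-zero PSD: spectral shape features set to 0")
        return out

    pmf = psd / total
    centroid = float((freqs * pmf).sum())
    variance = float(((freqs - centroid) ** 2 * pmf).sum())
    spread = math.sqrt(variance)
    if spread > 0:
        skewness = float(((freqs - centroid) ** 3 * pmf).sum()) / spread**3
        kurt = float(((freqs - centroid) ** 4 * pmf).sum()) / spread**4
    else:
        skewness, kurt = 0.0, 0.0
    nz = pmf[pmf > 0]
    entropy = float(-(nz * np.log2(nz)).sum() / np.log2(pmf.size)) if pmf.size > 1 else 0.0
    if psd.size > 1:
        k = np.arange(1, psd.size)
        denom = float(psd[1:].sum())
        decrease = float(((psd[1:] - psd[0]) / k).sum() / denom) if denom > 0 else 0.0
    else:
        decrease = 0.0
    cum = np.cumsum(psd)
    rolloff = float(freqs[np.searchsorted(cum, 0.95 * total)])
    median_f = float(freqs[np.searchsorted(cum, 0.5 * total)])
    half_max = psd >= psd.max() / 2.0
    bandwidth = float(freqs[half_max][-1] - freqs[half_max][0])
    distribution = float(psd[freqs < distribution_edge].sum() / total)
    human = (freqs >= human_band[0]) & (freqs < human_band[1])
    human_energy = float(psd[human].sum() / total)
    fund_mask = freqs >= 0.003
    fundamental = float(freqs[fund_mask][np.argmax(psd[fund_mask])])

    out.update(
        spectral_centroid=centroid,
        spectral_variance=variance,
        spectral_spread=spread,
        bandwidth=bandwidth,
        spectral_skewness=skewness,
        spectral_kurtosis=kurt,
        spectral_entropy=entropy,
        spectral_decrease=decrease,
        spectral_rolloff_95=rolloff,
        spectral_distribution=distribution,
        median_frequency=median_f,
        spectral_energy=float(psd.sum() * df),
        human_range_energy=human_energy,
        fundamental_frequency=fundamental,
        psd_auc=float(np.trapezoid(psd, freqs)),
    )
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def extract_feature_vector(
    window: RRWindow,
    config: PipelineConfig | None = None,
    registry: FeatureRegistry = FEATURE_REGISTRY,
) -> dict:
    """Assemble the full 61-value feature vector for one window.

    Returns a dict of metadata plus the registry features; raises on any
    sub-computation failure (callers decide whether to skip the window).
    """
    config = config or PipelineConfig()
    freqs, psd = resample_and_psd(window, fs=config.resample_hz, use_welch=config.use_welch)
    values = {}
    values.update(time_domain_features(window))
    values.update(frequency_band_features(freqs, psd, config.bands))
    values.update(poincare_features(window))
    values.update(statistical_features(window))
    values.update(
        spectral_shape_features(
            freqs,
            psd,
            distribution_edge=config.lf_high,
            human_band=(config.human_energy_low, config.human_energy_high),
        )
    )
    vec = {name: values[name] for name in registry.names}
    bad = [k for k, v in vec.items() if not np.isfinite(v)]
    if bad:
        raise ValidationError(f"window {window.window_id}: non-finite features {bad}")
    return {
        "subject_id": window.subject_id,
        "window_id": window.window_id,
        "window_start_s": window.start_s,
        "label": window.label,
        **vec,
    }


def extract_feature_table(
    windows,
    config: PipelineConfig | None = None,
    registry: FeatureRegistry = FEATURE_REGISTRY,
) -> pd.DataFrame:
    """Extract feature vectors for every labelled window.

    Unlabeled windows and windows failing a feature precondition are skipped
    (logged, and listed in ``table.attrs['skipped']``), never zero-filled.
    """
    rows, skipped = [], []
    for w in windows:
        if w.label not in VALID_LABELS:
            skipped.append((w.window_id, "unlabeled"))
            continue
        try:
            rows.append(extract_feature_vector(w, config, registry))
        except ValidationError as exc:
            logger.warning("skipping window %s: %s", w.window_id, exc)
            skipped.append((w.window_id, str(exc)))
    table = pd.DataFrame(rows, columns=list(META_COLUMNS) + registry.names)
    table.attrs["skipped"] = skipped
    return table
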