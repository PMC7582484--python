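"""Per-epoch gait-quality characteristics.

Implements, on 10-s trunk-acceleration epochs:

* sample entropy (gait regularity; VT and ML),
* the logarithmic rate of divergence per stride (local dynamic stability /
  maximal Lyapunov exponent, Rosenstein-style; VT, ML, AP),
* root mean square of ML acceleration,
* index of harmonicity of ML (spectral power at the stride frequency over
  the power in the fundamental plus its first five harmonics),
* spectral amplitude at the dominant period of AP,
* autocorrelation at the dominant period of VT,
* walking speed as stride frequency x stride length, with stride length
  from leg length and vertical trunk excursion under the compass-gait
  (inverted-pendulum) model: step length = 2*sqrt(2*l*h - h^2),
* a gait-quality composite: a weighted sum of the four z-scored spectral /
  amplitude measures, oriented so that higher = better gait.

Frequency conventions: the dominant VT/AP oscillation is at *step*
frequency; ML is at *stride* frequency; stride = 2 steps. Estimators whose
preconditions fail return ``numpy.nan`` as the undefined-marker, which
downstream medians skip (never zero-fill).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate as spi
from scipy import signal as sps
from scipy.spatial.distance import cdist

from .recording import G, AccelRecording
from .segmentation import Epoch

__all__ = [
    "FeatureConfig",
    "sample_entropy",
    "log_divergence_per_stride",
    "dominant_frequency",
    "stride_frequency",
    "stride_length",
    "vertical_excursion",
    "rms",
    "index_of_harmonicity",
    "dominant_amplitude",
    "autocorr_at_dominant_period",
    "composite_score",
    "compute_epoch_features",
    "COMPOSITE_COMPONENTS",
    "DEFAULT_ORIENTATION",
]

#: components of the gait-quality composite, in canonical order
COMPOSITE_COMPONENTS = (
    "rms_ml",
    "index_harmonicity_ml",
    "dominant_amplitude_ap",
    "autocorr_dominant_vt",
)

#: sign conventions orienting each component so that larger oriented value =
#: better (more regular / less precarious) gait: more ML sway is worse, a
#: more harmonic and more autocorrelated pattern is better.
DEFAULT_ORIENTATION = {
    "rms_ml": -1.0,
    "index_harmonicity_ml": 1.0,
    "dominant_amplitude_ap": 1.0,
    "autocorr_dominant_vt": 1.0,
}


@dataclass
class FeatureConfig:
    """Every tunable estimator parameter, with field-typical defaults.

    Sample entropy uses template length ``sampen_m`` and tolerance
    ``sampen_r`` x SD(signal). The divergence estimator delay-embeds with
    dimension ``embed_dim`` and delay ``embed_delay`` samples, excludes
    neighbours closer in time than one stride, follows divergence for
    ``fit_stride_fraction`` of a stride and fits a least-squares line to the
    mean log-divergence curve. Spectral peaks are searched in ``freq_band``
    (Hz, interpreted as the step-frequency band for VT/AP).
    """

    sampen_m: int = 5
    sampen_r: float = 0.3
    embed_dim: int = 5
    embed_delay: int = 10
    fit_stride_fraction: float = 0.5
    min_neighbor_pairs: int = 20
    freq_band: tuple = (1.2, 4.0)
    peak_snr_min: float = 12.0
    n_harmonics: int = 5
    harmonic_bw: float = 0.15  # Hz, half-width of each harmonic band
    nfft: int = 1 << 14
    composite_weights: dict = field(
        default_factory=lambda: {c: 0.25 for c in COMPOSITE_COMPONENTS}
    )
    composite_orientation: dict = field(
        default_factory=lambda: dict(DEFAULT_ORIENTATION)
    )


# ---------------------------------------------------------------------------
# regularity


def sample_entropy(x: np.ndarray, m: int = 5, r_factor: float = 0.3) -> float:
    """Sample entropy SampEn(m, r_factor*SD) of a 1-D signal.

    Counts ordered template pairs (i != j, i, j <= n-m-1) whose Chebyshev
    distance is within tolerance at length ``m`` (count B) and ``m+1``
    (count A), excluding self-matches, and returns -ln(A/B). Returns 0 for a
    constant signal with positive tolerance and NaN whenever A or B is zero
    (the undefined-marker), never a division error.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("sample entropy needs at least 100 samples")
    if r_factor <= 0:
        return math.nan
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0  # all templates match at both lengths: -ln(1)
    r = r_factor * sd

    n_tpl = n - m  # same template count basis at both lengths
    idx = np.arange(n_tpl)[:, None] + np.arange(m + 1)[None, :]
    tpl = x[idx]  # (n_tpl, m+1)
    d_m = cdist(tpl[:, :m], tpl[:, :m], metric="chebyshev")
    d_m1 = cdist(tpl, tpl, metric="chebyshev")
    np.fill_diagonal(d_m, np.inf)
    np.fill_diagonal(d_m1, np.inf)
    B = int(np.count_nonzero(d_m <= r))
    A = int(np.count_nonzero(d_m1 <= r))
    if A == 0 or B == 0:
        return math.nan
    return -math.log(A / B) + 0.0  # + 0.0 normalizes -ln(1) to +0.0


# ---------------------------------------------------------------------------
# local dynamic stability


def _embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    n = len(x) - (dim - 1) * delay
    if n <= 0:
        raise ValueError("signal too short for the requested embedding")
    idx = np.arange(n)[:, None] + np.arange(dim)[None, :] * delay
    return x[idx]


def log_divergence_per_stride(
    x: np.ndarray,
    stride_time: float,
    sampling_rate: float,
    config: FeatureConfig | None = None,
) -> float:
    """Logarithmic rate of divergence per stride (Rosenstein estimate).

    Delay-embeds the signal, pairs every point with its nearest neighbour
    at temporal separation > 1 stride, averages the log of the pairwise
    distance while both trajectories are followed forward for
    ``fit_stride_fraction`` of a stride, and converts the least-squares
    slope of that curve from per-sample to per-stride units. NaN when too
    few valid neighbour pairs exist.
    """
    cfg = config or FeatureConfig()
    x = np.asarray(x, dtype=float)
    if stride_time <= 0 or not np.isfinite(stride_time):
        return math.nan
    if len(x) < sampling_rate * 10 - 1:
        raise ValueError("divergence estimation needs at least 10 s of signal")

    emb = _embed(x, cfg.embed_dim, cfg.embed_delay)
    n = len(emb)
    min_sep = int(round(stride_time * sampling_rate))
    K = int(round(cfg.fit_stride_fraction * stride_time * sampling_rate))
    usable = n - K
    if usable <= min_sep + 1 or K < 2:
        return math.nan

    d0 = cdist(emb[:usable], emb[:usable])
    ii, jj = np.indices((usable, usable), sparse=True)
    d0[np.abs(ii - jj) <= min_sep] = np.inf
    nn = np.argmin(d0, axis=1)
    valid = np.isfinite(d0[np.arange(usable), nn])
    if int(valid.sum()) < cfg.min_neighbor_pairs:
        return math.nan
    i_idx = np.flatnonzero(valid)
    j_idx = nn[i_idx]

    curve = np.empty(K + 1)
    for k in range(K + 1):
        diff = emb[i_idx + k] - emb[j_idx + k]
        dist = np.sqrt(np.sum(diff * diff, axis=1))
        curve[k] = np.mean(np.log(np.maximum(dist, 1e-12)))

    k = np.arange(K + 1, dtype=float)
    slope = float(np.polyfit(k, curve, 1)[0])  # nats per sample
    return slope * sampling_rate * stride_time


# ---------------------------------------------------------------------------
# spectral measures


def _amplitude_spectrum(x: np.ndarray, fs: float, nfft: int) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed zero-padded amplitude spectrum scaled so a pure sine of
    amplitude A reads ~A at its frequency."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    w = np.hanning(len(x))
    spec = np.abs(np.fft.rfft(x * w, n=max(nfft, len(x))))
    freqs = np.fft.rfftfreq(max(nfft, len(x)), d=1.0 / fs)
    return freqs, 2.0 * spec / w.sum()


def dominant_frequency(
    x: np.ndarray, fs: float, config: FeatureConfig | None = None
) -> float:
    """Frequency of the dominant spectral peak inside the locomotion band.

    NaN (undefined) when no peak stands above the in-band noise floor by
    the configured factor — e.g. for rest noise.
    """
    cfg = config or FeatureConfig()
    freqs, amp = _amplitude_spectrum(x, fs, cfg.nfft)
    band = (freqs >= cfg.freq_band[0]) & (freqs <= cfg.freq_band[1])
    if not np.any(band):
        return math.nan
    p = amp[band] ** 2
    peak = float(np.max(p))
    floor = float(np.median(p))
    if floor <= 0 or peak < cfg.peak_snr_min * floor:
        return math.nan
    return float(freqs[band][np.argmax(p)])


def stride_frequency(
    vt: np.ndarray, fs: float, config: FeatureConfig | None = None
) -> float:
    """Stride frequency in Hz: half the VT dominant (step) frequency."""
    f_step = dominant_frequency(vt, fs, config)
    return f_step / 2.0 if np.isfinite(f_step) else math.nan


def stride_length(h: float, l: float) -> float:
    """Compass-gait stride length from vertical excursion h and leg length l.

    step = 2*sqrt(2*l*h - h^2); stride = 2*step. Requires 0 <= h < l.
    """
    if not np.isfinite(h) or not np.isfinite(l):
        return math.nan
    if h < 0 or l <= 0:
        raise ValueError("vertical excursion and leg length must be nonnegative/positive")
    if h >= l:
        raise ValueError(f"vertical excursion h={h:g} m must be smaller than leg length l={l:g} m")
    step = 2.0 * math.sqrt(2.0 * l * h - h * h)
    return 2.0 * step


def vertical_excursion(
    vt: np.ndarray, step_frequency: float, fs: float
) -> float:
    """Mean per-step peak-to-trough vertical trunk displacement, in m.

    The VT channel (g) is mean-removed, converted to m/s^2 and
    double-integrated; drift is controlled by linear detrending after each
    integration plus a per-stride-window linear detrend before the
    per-step peak-to-trough is measured. Edge strides are discarded. NaN
    when the step frequency is undefined.
    """
    if not np.isfinite(step_frequency) or step_frequency <= 0:
        return math.nan
    a = (np.asarray(vt, dtype=float) - np.mean(vt)) * G
    dt = 1.0 / fs
    v = spi.cumulative_trapezoid(a, dx=dt, initial=0.0)
    v = sps.detrend(v)
    z = spi.cumulative_trapezoid(v, dx=dt, initial=0.0)
    z = sps.detrend(z)

    step_n = int(round(fs / step_frequency))
    stride_n = 2 * step_n
    n_strides = len(z) // stride_n
    if n_strides < 3:
        return math.nan
    excursions = []
    for s in range(1, n_strides - 1):  # drop edge strides
        w = sps.detrend(z[s * stride_n : (s + 1) * stride_n])
        for st in range(2):
            seg = w[st * step_n : (st + 1) * step_n]
            excursions.append(float(np.max(seg) - np.min(seg)))
    return float(np.mean(excursions))


def rms(x: np.ndarray) -> float:
    """Root mean square of the mean-removed signal."""
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def index_of_harmonicity(
    ml: np.ndarray,
    stride_freq: float,
    fs: float,
    config: FeatureConfig | None = None,
) -> float:
    """Fraction of ML power at the stride (fundamental) frequency relative
    to the fundamental plus its first ``n_harmonics`` harmonics; in [0, 1].
    """
    cfg = config or FeatureConfig()
    if not np.isfinite(stride_freq) or stride_freq <= 0:
        return math.nan
    freqs, psd = sps.periodogram(
        np.asarray(ml, dtype=float) - np.mean(ml),
        fs=fs,
        window="hann",
        nfft=max(cfg.nfft, len(ml)),
    )
    powers = []
    for k in range(1, cfg.n_harmonics + 2):
        f_k = k * stride_freq
        band = np.abs(freqs - f_k) <= cfg.harmonic_bw
        powers.append(float(psd[band].sum()) if np.any(band) else 0.0)
    total = sum(powers)
    if total <= 0:
        return math.nan
    return powers[0] / total


def dominant_amplitude(
    ap: np.ndarray, fs: float, config: FeatureConfig | None = None
) -> float:
    """Acceleration amplitude (g) at the dominant period of the AP signal."""
    cfg = config or FeatureConfig()
    f_dom = dominant_frequency(ap, fs, cfg)
    if not np.isfinite(f_dom):
        return math.nan
    freqs, amp = _amplitude_spectrum(ap, fs, cfg.nfft)
    return float(amp[np.argmin(np.abs(freqs - f_dom))])


def autocorr_at_dominant_period(
    vt: np.ndarray, fs: float, config: FeatureConfig | None = None,
    dominant_freq: float | None = None,
) -> float:
    """Biased-normalized autocorrelation of VT at lag = dominant period.

    r(k) = sum_i (x_i - mean)(x_{i+k} - mean) / sum_i (x_i - mean)^2, with
    k = round(fs / dominant frequency); lies in [-1, 1]. NaN when the
    dominant frequency is undefined.
    """
    f_dom = dominant_frequency(vt, fs, config) if dominant_freq is None else dominant_freq
    if not np.isfinite(f_dom) or f_dom <= 0:
        return math.nan
    x = np.asarray(vt, dtype=float)
    x = x - x.mean()
    k = int(round(fs / f_dom))
    if k <= 0 or k >= len(x):
        return math.nan
    denom = float(np.dot(x, x))
    if denom == 0:
        return math.nan
    return float(np.dot(x[:-k], x[k:]) / denom)


# ---------------------------------------------------------------------------
# composite


def composite_score(
    components: dict,
    weights: dict | None = None,
    normalization: dict | None = None,
    orientation: dict | None = None,
) -> float:
    """Gait-quality composite for one subject/epoch.

    Each of the four components is z-scored against ``normalization``
    (``{name: (mean, sd)}``, e.g. cohort statistics or an external reference
    population), sign-oriented so that a higher oriented value means better
    gait, then combined as a weighted sum. NaN if any required component is
    undefined.
    """
    weights = weights or {c: 0.25 for c in COMPOSITE_COMPONENTS}
    orientation = orientation or DEFAULT_ORIENTATION
    if normalization is None:
        raise ValueError("composite_score requires a normalization (mean, sd) per component")
    out = 0.0
    for name in COMPOSITE_COMPONENTS:
        v = components.get(name, math.nan)
        if v is None or not np.isfinite(v):
            return math.nan
        mean, sd = normalization[name]
        if sd <= 0:
            return math.nan
        out += weights.get(name, 0.0) * orientation.get(name, 1.0) * (v - mean) / sd
    return out


def cohort_normalization(values: "pd.DataFrame") -> dict:
    """Cohort-internal (mean, sd) normalization for the composite components."""
    import pandas as pd  # local import keeps module load light

    assert isinstance(values, pd.DataFrame)
    return {
        c: (float(values[c].mean()), float(values[c].std(ddof=0)))
        for c in COMPOSITE_COMPONENTS
    }


# ---------------------------------------------------------------------------
# per-epoch driver


def compute_epoch_features(
    rec: AccelRecording,
    epoch: Epoch,
    leg_length: float | None = None,
    config: FeatureConfig | None = None,
) -> dict:
    """All gait characteristics for one 10-s epoch of a recording.

    Returns a plain dict (one row of the per-epoch feature table). Walking
    speed is stride_frequency x stride_length exactly; it is NaN when the
    leg length is unknown or any of its inputs is undefined.
    """
    cfg = config or FeatureConfig()
    fs = rec.sampling_rate
    seg = rec.samples[epoch.start_sample : epoch.end_sample]
    vt, ml, ap = seg[:, 0], seg[:, 1], seg[:, 2]

    f_step = dominant_frequency(vt, fs, cfg)
    f_stride = f_step / 2.0 if np.isfinite(f_step) else math.nan
    stride_time = 1.0 / f_stride if np.isfinite(f_stride) and f_stride > 0 else math.nan

    h = vertical_excursion(vt, f_step, fs)
    if leg_length is not None and np.isfinite(h) and 0 <= h < leg_length:
        s_len = stride_length(h, leg_length)
    else:
        s_len = math.nan
    speed = f_stride * s_len if np.isfinite(f_stride) and np.isfinite(s_len) else math.nan

    row = {
        "sample_entropy_vt": sample_entropy(vt, cfg.sampen_m, cfg.sampen_r),
        "sample_entropy_ml": sample_entropy(ml, cfg.sampen_m, cfg.sampen_r),
        "log_divergence_vt": log_divergence_per_stride(vt, stride_time, fs, cfg),
        "log_divergence_ml": log_divergence_per_stride(ml, stride_time, fs, cfg),
        "log_divergence_ap": log_divergence_per_stride(ap, stride_time, fs, cfg),
        "rms_ml": rms(ml),
        "index_harmonicity_ml": index_of_harmonicity(ml, f_stride, fs, cfg),
        "dominant_amplitude_ap": dominant_amplitude(ap, fs, cfg),
        "autocorr_dominant_vt": autocorr_at_dominant_period(vt, fs, cfg, dominant_freq=f_step),
        "stride_frequency": f_stride,
        "vertical_excursion": h,
        "stride_length": s_len,
        "walking_speed": speed,
    }
    return row
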