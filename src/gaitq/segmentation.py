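"""Orientation calibration, wear-period exclusion, locomotion detection and
epoching.

Locomotion detection replaces the sensor manufacturer's proprietary
classifier with a transparent two-criterion detector: a sliding 2-s window
is flagged as walking when (a) the fraction of VT power inside the
locomotion band (0.5–3 Hz) exceeds a threshold and (b) the VT standard
deviation exceeds an activity threshold. Flagged windows are merged, short
gaps bridged, and only bouts of at least 10 s survive. All thresholds are
configuration, not constants. Indices are 0-based and intervals half-open
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from .recording import AccelRecording

__all__ = [
    "LocomotionEpisode",
    "Epoch",
    "DetectorConfig",
    "calibrate_orientation",
    "exclude_initial_hours",
    "detect_locomotion",
    "split_epochs",
    "time_spent_walking",
]


@dataclass(frozen=True)
class LocomotionEpisode:
    """A detected walking bout: half-open sample range, >= 10 s long."""

    start_sample: int
    end_sample: int
    sampling_rate: float
    min_duration: float = 10.0

    def __post_init__(self) -> None:
        if self.end_sample <= self.start_sample:
            raise ValueError("episode must be non-empty")
        if self.duration < self.min_duration - 1e-9:
            raise ValueError(
                f"episode of {self.duration:.2f} s is shorter than the "
                f"{self.min_duration:g} s minimum"
            )

    @property
    def duration(self) -> float:
        return (self.end_sample - self.start_sample) / self.sampling_rate


@dataclass(frozen=True)
class Epoch:
    """A fixed 10-s analysis window inside one episode."""

    episode_id: int
    start_sample: int
    n_samples: int

    @property
    def end_sample(self) -> int:
        return self.start_sample + self.n_samples


def calibrate_orientation(rec: AccelRecording) -> tuple[AccelRecording, np.ndarray]:
    """Rotate axes so the quasi-static gravity vector sits on VT at +1 g.

    The gravity direction is the mean of the < 0.1 Hz low-passed signal. If
    its magnitude falls outside [0.8, 1.2] g the sensor was presumably not
    worn or not in g units, and an error is raised. Returns the rotated
    recording and the 3x3 rotation matrix applied.
    """
    if rec.duration < 60.0:
        raise ValueError("orientation calibration needs at least 60 s of signal")
    sos = sps.butter(2, 0.1, btype="low", fs=rec.sampling_rate, output="sos")
    slow = sps.sosfiltfilt(sos, rec.samples, axis=0)
    g_vec = slow.mean(axis=0)
    g_mag = float(np.linalg.norm(g_vec))
    if not 0.8 <= g_mag <= 1.2:
        raise ValueError(
            f"mean acceleration magnitude {g_mag:.3f} g outside [0.8, 1.2] g; "
            "sensor not worn or miscalibrated"
        )
    rot, _ = Rotation.align_vectors([[1.0, 0.0, 0.0]], [g_vec])
    R = rot.as_matrix()
    out = AccelRecording(
        sampling_rate=rec.sampling_rate,
        samples=rec.samples @ R.T,
        subject_id=rec.subject_id,
        start_time=rec.start_time,
        gaps=list(rec.gaps),
    )
    return out, R


def exclude_initial_hours(rec: AccelRecording, hours: float = 6.0) -> AccelRecording:
    """Drop the first ``hours`` of the recording (transportation guard)."""
    if hours < 0:
        raise ValueError("hours must be >= 0")
    n_drop = int(round(hours * 3600.0 * rec.sampling_rate))
    if n_drop >= rec.n_samples:
        raise ValueError(
            f"recording of {rec.duration / 3600:.2f} h is not longer than the "
            f"{hours:g} h exclusion window"
        )
    return rec.slice(n_drop, rec.n_samples)


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds of the band-power + activity locomotion detector."""

    window_s: float = 2.0
    hop_s: float = 0.5
    band: tuple = (0.5, 3.0)
    band_fraction_min: float = 0.5
    vt_std_min: float = 0.08  # g
    merge_gap_s: float = 1.0
    min_duration_s: float = 10.0
    #: shaved off each flank of a merged interval; windows flag on partial
    #: overlap with a bout, so raw flags overhang the true bout by roughly
    #: one window length
    edge_trim_s: float = 2.0


def _window_flags(vt: np.ndarray, fs: float, cfg: DetectorConfig) -> tuple[np.ndarray, int, int]:
    win = int(round(cfg.window_s * fs))
    hop = int(round(cfg.hop_s * fs))
    n_win = max(0, (len(vt) - win) // hop + 1)
    if n_win == 0:
        return np.zeros(0, dtype=bool), win, hop
    idx = np.arange(n_win)[:, None] * hop + np.arange(win)[None, :]
    segs = vt[idx]
    segs = segs - segs.mean(axis=1, keepdims=True)
    std = segs.std(axis=1)
    spec = np.abs(np.fft.rfft(segs, axis=1)) ** 2
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    total = spec[:, 1:].sum(axis=1)  # exclude DC
    in_band = (freqs >= cfg.band[0]) & (freqs <= cfg.band[1])
    band_p = spec[:, in_band].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, band_p / total, 0.0)
    return (frac >= cfg.band_fraction_min) & (std >= cfg.vt_std_min), win, hop


def detect_locomotion(
    rec: AccelRecording, config: DetectorConfig | None = None
) -> list[LocomotionEpisode]:
    """Detect walking bouts of at least ``min_duration_s`` seconds.

    Returns disjoint, sorted episodes; an empty list is a valid result.
    """
    cfg = config or DetectorConfig()
    fs = rec.sampling_rate
    flags, win, hop = _window_flags(rec.vt, fs, cfg)
    if flags.size == 0:
        return []

    # merge flagged windows into sample intervals, bridging short gaps
    intervals = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            intervals.append((start * hop, (i - 1) * hop + win))
            start = None
    if start is not None:
        intervals.append((start * hop, (len(flags) - 1) * hop + win))

    merged = []
    max_gap = int(round(cfg.merge_gap_s * fs))
    for s, e in intervals:
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    trim = int(round(cfg.edge_trim_s * fs))
    min_len = cfg.min_duration_s * fs
    out = []
    for s, e in merged:
        s, e = s + trim, min(e, rec.n_samples) - trim
        if e - s >= min_len:
            out.append(LocomotionEpisode(s, e, fs, cfg.min_duration_s))
    return out


def split_epochs(
    episode: LocomotionEpisode, rec: AccelRecording, episode_id: int = 0,
    epoch_s: float = 10.0,
) -> list[Epoch]:
    """Cut an episode into consecutive non-overlapping 10-s epochs.

    The trailing remainder shorter than one epoch is discarded.
    """
    n = int(round(epoch_s * rec.sampling_rate))
    n_epochs = (episode.end_sample - episode.start_sample) // n
    return [
        Epoch(episode_id, episode.start_sample + k * n, n) for k in range(n_epochs)
    ]


def time_spent_walking(episodes: list[LocomotionEpisode], n_days: float) -> float:
    """Average daily walking exposure in minutes per day."""
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    total_s = sum(ep.duration for ep in episodes)
    return total_s / 60.0 / n_days
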