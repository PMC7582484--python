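"""Core container for tri-axial trunk acceleration time series.

Axis convention is fixed throughout the package: column 0 = vertical (VT),
column 1 = mediolateral (ML), column 2 = anteroposterior (AP), all in units
of g. Timestamps are seconds from the start of the recording; the calendar
start time is metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

#: acceleration of gravity, m/s^2 per g
G = 9.80665

#: sensor measurement range in g; samples are clipped to this on generation
#: and validated against it on read
SENSOR_RANGE_G = 6.0

AXES = ("vt", "ml", "ap")


@dataclass
class AccelRecording:
    """A contiguous tri-axial trunk acceleration recording.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz). The nominal wear protocol samples at 100 Hz.
    samples : ndarray, shape (n, 3)
        Acceleration in g, columns ordered VT, ML, AP.
    subject_id : str
        Identifier joining the recording to clinical data.
    start_time : str
        ISO-8601 calendar time of sample 0.
    gaps : list of (int, float)
        (row index, gap seconds) for tolerated acquisition gaps, if any.
    """

    sampling_rate: float
    samples: np.ndarray
    subject_id: str = ""
    start_time: str = "2000-01-01T00:00:00"
    gaps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3) for VT, ML, AP")
        amax = np.nanmax(np.abs(self.samples)) if self.samples.size else 0.0
        if amax > SENSOR_RANGE_G + 1e-9:
            raise ValueError(
                f"samples exceed the ±{SENSOR_RANGE_G:g} g sensor range "
                f"(max |a| = {amax:.3f} g); clip before constructing"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Seconds from recording start for each sample."""
        return np.arange(self.n_samples) / self.sampling_rate

    @property
    def vt(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def ml(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def ap(self) -> np.ndarray:
        return self.samples[:, 2]

    def slice(self, start_sample: int, end_sample: int) -> "AccelRecording":
        """Half-open sample-index slice, preserving metadata.

        ``start_time`` is shifted by the dropped leading samples.
        """
        if not 0 <= start_sample <= end_sample <= self.n_samples:
            raise ValueError("invalid slice bounds")
        shift = timedelta(seconds=start_sample / self.sampling_rate)
        t0 = datetime.fromisoformat(self.start_time) + shift
        return AccelRecording(
            sampling_rate=self.sampling_rate,
            samples=self.samples[start_sample:end_sample],
            subject_id=self.subject_id,
            start_time=t0.isoformat(),
        )
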