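"""Raw accelerometer handling and stride detection.

The sensor is a thigh-worn tri-axial accelerometer sampling at 20 Hz with a
±4 g range. During walking the thigh swings once per stride, so the
band-passed acceleration is periodic at the stride frequency; strides are
recovered as prominent peaks of the dominant oscillation axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Physiologically plausible stride-frequency band (Hz). Strides implying a
#: frequency outside this band are discarded, not imputed.
STRIDE_FREQ_MIN_HZ = 0.4
STRIDE_FREQ_MAX_HZ = 1.6

#: Band-pass corners for gait content (Hz).
BAND_HZ = (0.3, 3.0)

#: Minimum separation between successive stride peaks (s).
MIN_PEAK_DISTANCE_S = 0.55

#: Signal discarded at each bout boundary before peak search (s), to avoid
#: zero-phase filter transients.
EDGE_EXCLUSION_S = 0.5


@dataclass
class AccelerometerRecording:
    """Uniformly sampled tri-axial thigh acceleration for one participant.

    ``samples`` is an (n, 3) array of (ax, ay, az) in units of g; ``start_s``
    is the timeline offset of the first sample.
    """

    participant_id: str
    sampling_rate: float
    samples: np.ndarray
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32).reshape(-1, 3)
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.n_samples) / self.sampling_rate

    def slice(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples covering [start_s, end_s] on the recording timeline."""
        i0 = int(np.ceil((start_s - self.start_s) * self.sampling_rate))
        i1 = int(np.floor((end_s - self.start_s) * self.sampling_rate)) + 1
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        return self.samples[i0:i1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "time_s": self.times,
                "ax_g": self.samples[:, 0],
                "ay_g": self.samples[:, 1],
                "az_g": self.samples[:, 2],
            }
        )
        df.to_csv(path, index=False, float_format="%.4f")

    @classmethod
    def from_csv(cls, path: str | Path, participant_id: str | None = None,
                 sampling_rate: float | None = None) -> "AccelerometerRecording":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if sampling_rate is None:
            if len(t) < 2:
                raise ValueError("cannot infer sampling rate from < 2 samples")
            sampling_rate = 1.0 / float(np.median(np.diff(t)))
        pid = participant_id or Path(path).stem
        samples = df[["ax_g", "ay_g", "az_g"]].to_numpy()
        return cls(pid, sampling_rate, samples, start_s=float(t[0]) if len(t) else 0.0)


@dataclass
class StrideSequence:
    """Stride events of one stepping bout.

    ``events`` are event times in seconds, strictly increasing. Consecutive
    differences are stride times; their reciprocals stride frequencies.
    ``n_discarded`` counts detected peaks removed by the plausibility gate.
    """

    events: np.ndarray
    n_discarded: int = 0

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.size > 1 and np.any(np.diff(self.events) <= 0):
            raise ValueError("stride events must be strictly increasing")

    def __len__(self) -> int:
        return int(self.events.size)

    @property
    def stride_times(self) -> np.ndarray:
        return np.diff(self.events)

    @property
    def stride_frequencies(self) -> np.ndarray:
        return 1.0 / np.diff(self.events)

    @property
    def mean_frequency(self) -> float:
        """Mean stride frequency over the bout as strides per unit time,
        (n_events - 1) / span. Unlike the average of per-stride reciprocal
        intervals this is not inflated by interval timing noise."""
        if self.events.size < 2:
            return float("nan")
        return float((self.events.size - 1)
                     / (self.events[-1] - self.events[0]))

    @property
    def is_empty(self) -> bool:
        return self.events.size < 2


def stride_metrics(strides: StrideSequence) -> tuple[np.ndarray, np.ndarray]:
    """Stride times and frequencies from an event sequence.

    stride_time_i = t_{i+1} - t_i and f_i = 1 / stride_time_i. Fewer than two
    events yield empty arrays.
    """
    if len(strides) < 2:
        return np.empty(0), np.empty(0)
    st = strides.stride_times
    return st, 1.0 / st


def plausible_frequencies(strides: StrideSequence,
                          lo: float = STRIDE_FREQ_MIN_HZ,
                          hi: float = STRIDE_FREQ_MAX_HZ) -> np.ndarray:
    """Stride frequencies within the physiological band [lo, hi] Hz."""
    _, f = stride_metrics(strides)
    return f[(f >= lo) & (f <= hi)]


def bandpass(x: np.ndarray, fs: float, band: tuple[float, float] = BAND_HZ,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0."""
    nyq = fs / 2.0
    hi = min(band[1], 0.95 * nyq)
    sos = sps.butter(order, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def principal_axis_signal(samples: np.ndarray, fs: float) -> np.ndarray:
    """Project the band-passed tri-axial signal onto its axis of maximal
    variance; the sign is fixed so the skewness is non-negative, making peak
    polarity deterministic."""
    filt = bandpass(samples.astype(float), fs)
    cov = np.cov(filt.T)
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    proj = filt @ axis
    centered = proj - proj.mean()
    if np.mean(centered**3) < 0:
        proj = -proj
    return proj


def detect_strides(recording: AccelerometerRecording,
                   bout: tuple[float, float]) -> StrideSequence:
    """Detect stride events within a stepping bout.

    Peak-picking on the band-passed principal-axis signal: minimum peak
    distance 0.55 s, prominence adaptive to the signal SD, with the first
    and last 0.5 s excluded. Peaks implying stride frequencies outside
    [0.4, 1.6] Hz are discarded (too-fast intervals drop the later peak;
    too-slow intervals are counted but the events are kept, since a long
    interval is a pause rather than a false event).

    Returns an empty sequence (not an error) when fewer than two plausible
    events are found.
    """
    start_s, end_s = bout
    if end_s - start_s < 2.0:
        raise ValueError("bout must be at least 2 s long")
    if start_s < recording.start_s - 1e-9 or \
            end_s > recording.start_s + recording.duration_s + 1e-9:
        raise ValueError("bout lies outside the recording")

    seg = recording.slice(start_s, end_s)
    if seg.shape[0] < int(2 * recording.sampling_rate):
        return StrideSequence(np.empty(0))

    fs = recording.sampling_rate
    proj = principal_axis_signal(seg, fs)
    sd = float(np.std(proj))
    if sd < 1e-6:
        return StrideSequence(np.empty(0))

    distance = max(1, int(round(MIN_PEAK_DISTANCE_S * fs)))
    peaks, _ = sps.find_peaks(proj, distance=distance, prominence=0.5 * sd)

    edge = int(round(EDGE_EXCLUSION_S * fs))
    peaks = peaks[(peaks >= edge) & (peaks < len(proj) - edge)]
    if peaks.size < 2:
        return StrideSequence(np.empty(0))

    t0 = max(start_s, recording.start_s)
    times = t0 + peaks / fs

    # debounce: drop later peak of any implausibly fast pair
    min_dt = 1.0 / STRIDE_FREQ_MAX_HZ
    keep = [0]
    dropped = 0
    for i in range(1, len(times)):
        if times[i] - times[keep[-1]] >= min_dt:
            keep.append(i)
        else:
            dropped += 1
    times = times[keep]

    slow = int(np.sum(np.diff(times) > 1.0 / STRIDE_FREQ_MIN_HZ))
    if dropped or slow:
        logger.debug(
            "bout [%.1f, %.1f]: discarded %d fast peaks, %d slow intervals",
            start_s, end_s, dropped, slow,
        )
    if times.size < 2:
        return StrideSequence(np.empty(0), n_discarded=dropped + slow)
    return StrideSequence(times, n_discarded=dropped + slow)
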