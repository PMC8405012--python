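"""RR-interval sequences and combined-interval (RRnI / RRnI_m) construction.

The combined sequences are windowed sums of ``n`` consecutive R-R intervals
taken at stride ``m`` (``m = n`` gives non-overlapping windows, ``m < n``
overlapping ones).  This module also houses a Pan-Tompkins-style R-peak
detector and a template-correlation signal-quality index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "EcgRecord",
    "RriSequence",
    "RRnIConfig",
    "RRnISequence",
    "QualityReport",
    "detect_r_peaks",
    "assess_quality",
    "rri_from_peaks",
    "clean_rri",
    "build_rrni",
    "enumerate_configs",
    "read_rri_text",
    "write_rri_text",
    "read_ecg_csv",
    "write_ecg_csv",
]

#: maximum fraction of noisy recording tolerated before a record is unusable
NOISE_FRACTION_LIMIT = 0.30

#: minimum spacing between two R peaks, in seconds
REFRACTORY_S = 0.200


@dataclass(frozen=True)
class EcgRecord:
    """Single-lead ECG: amplitude samples at a fixed sampling rate."""

    samples: np.ndarray
    sampling_rate: float
    record_id: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("EcgRecord needs a 1-D signal with at least 2 samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class RriSequence:
    """Ordered R-R intervals in milliseconds with a cumulative time axis.

    ``onset_times`` holds the end time of each interval in ms (cumulative sum
    of the intervals), so it is strictly increasing whenever all intervals
    are positive.
    """

    intervals: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", iv)
        if iv.ndim != 1:
            raise ValueError("intervals must be 1-D")
        if iv.size and np.any(iv <= 0):
            raise ValueError("all intervals must be positive")

    @property
    def onset_times(self) -> np.ndarray:
        return np.cumsum(self.intervals)

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class RRnIConfig:
    """A combined-interval configuration: window width ``n``, stride ``m``."""

    n: int
    m: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not (1 <= self.m <= self.n):
            raise ValueError(f"m must satisfy 1 <= m <= n, got m={self.m}, n={self.n}")

    @property
    def label(self) -> str:
        if self.n == 1:
            return "HRV"
        if self.m == self.n:
            return f"HR{self.n}V"
        return f"HR{self.n}V{self.m}"


@dataclass(frozen=True)
class RRnISequence:
    """Combined-interval sequence: values are sums of ``n`` source intervals."""

    config: RRnIConfig
    values: np.ndarray
    times: np.ndarray  # end time (ms) of each window on the source time axis
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have matching shapes")

    @property
    def element_count(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.element_count


@dataclass(frozen=True)
class QualityReport:
    noise_fraction: float
    usable: bool
    flags: tuple  # per-window booleans, True = window flagged noisy


def detect_r_peaks(
    ecg: EcgRecord,
    *,
    band: tuple = (5.0, 15.0),
    integration_window_s: float = 0.150,
    threshold_fraction: float = 0.35,
    refine_window_s: float = 0.100,
) -> np.ndarray:
    """Detect R-peak sample indices with a band-pass/derivative/integrate scheme.

    Returns strictly increasing indices; a refractory period of 200 ms is
    enforced.  A flat or featureless signal yields an empty array.
    """
    fs = ecg.sampling_rate
    x = ecg.samples
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of signal for peak detection")
    if np.ptp(x) == 0:
        return np.array([], dtype=int)

    nyq = fs / 2.0
    lo = band[0] / nyq
    hi = min(band[1] / nyq, 0.99)
    sos = sps.butter(2, [lo, hi], btype="bandpass", output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    energy = np.gradient(filtered) ** 2
    win = max(1, int(round(integration_window_s * fs)))
    integrated = np.convolve(energy, np.ones(win) / win, mode="same")

    distance = max(1, int(round(REFRACTORY_S * fs)))
    threshold = threshold_fraction * np.percentile(integrated, 99)
    if threshold <= 0:
        return np.array([], dtype=int)
    candidates, _ = sps.find_peaks(integrated, height=threshold, distance=distance)
    if candidates.size == 0:
        return np.array([], dtype=int)

    # refine to the true R deflection: local max of |x| around each candidate
    half = max(1, int(round(refine_window_s * fs)))
    refined = []
    for c in candidates:
        lo_i = max(0, c - half)
        hi_i = min(x.size, c + half + 1)
        refined.append(lo_i + int(np.argmax(np.abs(x[lo_i:hi_i]))))
    peaks = np.unique(np.asarray(refined, dtype=int))
    # de-duplicate refined peaks that collapsed inside the refractory period
    keep = [int(peaks[0])]
    for p in peaks[1:]:
        if p - keep[-1] >= distance:
            keep.append(int(p))
    return np.asarray(keep, dtype=int)


def assess_quality(
    ecg: EcgRecord,
    peaks: np.ndarray,
    *,
    window_s: float = 10.0,
    template_halfwidth_s: float = 0.125,
    correlation_threshold: float = 0.5,
) -> QualityReport:
    """Per-window signal quality from beat-template correlation.

    Each detected beat is correlated against the record's median beat
    template; a window is flagged noisy when its beats correlate poorly (or
    it contains no beats).  ``usable`` requires the flagged fraction to stay
    at or below 30% of the recording.
    """
    fs = ecg.sampling_rate
    x = ecg.samples
    n_windows = max(1, int(np.ceil(x.size / (window_s * fs))))
    peaks = np.asarray(peaks, dtype=int)
    half = max(2, int(round(template_halfwidth_s * fs)))

    snippets, snippet_peaks = [], []
    for p in peaks:
        if p - half < 0 or p + half + 1 > x.size:
            continue
        snippets.append(x[p - half : p + half + 1])
        snippet_peaks.append(p)
    if not snippets:
        flags = tuple([True] * n_windows)
        return QualityReport(noise_fraction=1.0, usable=False, flags=flags)

    beats = np.vstack(snippets)
    template = np.median(beats, axis=0)
    t_c = template - template.mean()
    t_norm = np.linalg.norm(t_c)
    corrs = np.full(len(snippet_peaks), 0.0)
    for i, beat in enumerate(beats):
        b_c = beat - beat.mean()
        denom = np.linalg.norm(b_c) * t_norm
        corrs[i] = float(b_c @ t_c / denom) if denom > 0 else 0.0

    window_of = (np.asarray(snippet_peaks) / (window_s * fs)).astype(int)
    flags = []
    for w in range(n_windows):
        in_w = corrs[window_of == w]
        flags.append(bool(in_w.size == 0 or np.mean(in_w) < correlation_threshold))
    noise_fraction = float(np.mean(flags))
    return QualityReport(
        noise_fraction=noise_fraction,
        usable=noise_fraction <= NOISE_FRACTION_LIMIT,
        flags=tuple(flags),
    )


def rri_from_peaks(peaks: np.ndarray, sampling_rate: float, source_id: str = "") -> RriSequence:
    """Convert R-peak sample indices to an interval sequence in ms."""
    peaks = np.asarray(peaks)
    if peaks.size < 2:
        raise ValueError(f"need at least 2 peaks to form intervals, got {peaks.size}")
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("peak indices must be strictly increasing")
    intervals = np.diff(peaks).astype(float) * 1000.0 / sampling_rate
    return RriSequence(intervals=intervals, source_id=source_id)


def clean_rri(
    rri: RriSequence,
    *,
    physiological_range_ms: tuple = (300.0, 2000.0),
    relative_tolerance: float = 0.20,
    median_window: int = 11,
) -> RriSequence:
    """Drop ectopic-looking intervals.

    An interval is excluded when it falls outside the physiological range or
    deviates from a running median by more than ``relative_tolerance``.
    """
    iv = rri.intervals
    if iv.size == 0:
        return rri
    lo, hi = physiological_range_ms
    running = sps.medfilt(iv, kernel_size=median_window if median_window % 2 else median_window + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(iv - running) / running
    keep = (iv >= lo) & (iv <= hi) & (rel <= relative_tolerance)
    return RriSequence(intervals=iv[keep], source_id=rri.source_id)


def build_rrni(rri: RriSequence, config: RRnIConfig) -> RRnISequence:
    """Windowed sums of width ``n`` at stride ``m``; incomplete tails dropped.

    Element ``k`` is the sum of source intervals ``k*m .. k*m + n - 1``
    (0-based); the element count is ``floor((L - n)/m) + 1`` for source
    length ``L >= n``.
    """
    n, m = config.n, config.m
    L = len(rri)
    if L < n:
        raise ValueError(f"sequence of length {L} too short: need at least n={n} intervals")
    count = (L - n) // m + 1
    cs = np.concatenate([[0.0], np.cumsum(rri.intervals)])
    starts = np.arange(count) * m
    values = cs[starts + n] - cs[starts]
    times = cs[starts + n]  # window end time on the source axis
    return RRnISequence(config=config, values=values, times=times, source_id=rri.source_id)


def enumerate_configs(n_max: int = 3) -> list:
    """All (n, m) configurations with 1 <= m <= n <= n_max.

    Ordered by n then m; count is ``n_max (n_max + 1) / 2``.  For the default
    ``n_max = 3`` the labels are HRV, HR2V1, HR2V, HR3V1, HR3V2, HR3V.
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    return [RRnIConfig(n=n, m=m) for n in range(1, n_max + 1) for m in range(1, n + 1)]


# ---------------------------------------------------------------------------
# plain-text I/O


def read_rri_text(path) -> RriSequence:
    """Read an interval file: one value in ms per line, '#' starts a comment."""
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                values.append(float(line))
    return RriSequence(intervals=np.asarray(values), source_id=str(path))


def write_rri_text(rri: RriSequence, path) -> None:
    with open(path, "w") as fh:
        fh.write("# R-R intervals in ms, one per line\n")
        for v in rri.intervals:
            fh.write(f"{v:.6f}\n")


def read_ecg_csv(path, record_id: str = "") -> EcgRecord:
    """Read a two-column (time_s, amplitude) CSV; sampling rate inferred."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    t, x = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    fs = 1.0 / float(np.median(dt))
    return EcgRecord(samples=x, sampling_rate=fs, record_id=record_id or str(path))


def write_ecg_csv(ecg: EcgRecord, path) -> None:
    t = np.arange(ecg.samples.size) / ecg.sampling_rate
    with open(path, "w") as fh:
        fh.write("time_s,amplitude\n")
        for ti, xi in zip(t, ecg.samples):
            fh.write(f"{ti:.6f},{xi:.6f}\n")
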