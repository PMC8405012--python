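"""Time-domain, spectral and nonlinear variability parameters.

Computes the full ~26-parameter suite for any interval sequence, including
the combined-sequence counts NN50n / pNN50n whose threshold scales with the
window width n (50*n ms instead of 50 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import lombscargle

from hrnv.sequences import RriSequence, RRnISequence, build_rrni, enumerate_configs

__all__ = [
    "SpectralBands",
    "ParameterVector",
    "time_domain",
    "triangular_index",
    "frequency_domain",
    "poincare",
    "sample_entropy",
    "approximate_entropy",
    "dfa",
    "compute_parameters",
    "compute_all",
]

#: emitted in place of -ln(A/B) when no length-(m+1) template matches exist
SAMPEN_SENTINEL = 1000.0

#: histogram bin width for the triangular index, ms (1/128 s convention)
TRIANGULAR_BIN_MS = 7.8125

DFA_SHORT_SCALES = (4, 16)
DFA_LONG_SCALES = (16, 64)


@dataclass(frozen=True)
class SpectralBands:
    """Contiguous VLF / LF / HF band edges in Hz, [low, high)."""

    vlf: tuple = (0.0033, 0.04)
    lf: tuple = (0.04, 0.15)
    hf: tuple = (0.15, 0.40)

    def __post_init__(self) -> None:
        if not (self.vlf[1] == self.lf[0] and self.lf[1] == self.hf[0]):
            raise ValueError("bands must be contiguous (vlf.high == lf.low, lf.high == hf.low)")
        if any(b[1] <= b[0] for b in (self.vlf, self.lf, self.hf)) or self.vlf[0] < 0:
            raise ValueError("band edges must be increasing and non-negative")


@dataclass
class ParameterVector:
    """The named parameter set for one interval sequence.

    ``nn50n`` / ``pnn50n`` are only defined for combined sequences (n > 1)
    and stay None for the plain n = 1 configuration.  ``flags`` records
    per-parameter degeneracies (insufficient data, zero variance, ...).
    """

    label: str = ""
    mean_nn: float = np.nan
    sdnn: float = np.nan
    mean_hr: float = np.nan
    sd_hr: float = np.nan
    rmssd: float = np.nan
    skewness: float = np.nan
    kurtosis: float = np.nan
    triangular_index: float = np.nan
    nn50: float = np.nan
    pnn50: float = np.nan
    nn50n: float | None = None
    pnn50n: float | None = None
    total_power: float = np.nan
    vlf_power: float = np.nan
    lf_power: float = np.nan
    hf_power: float = np.nan
    lf_norm: float = np.nan
    hf_norm: float = np.nan
    lf_hf: float = np.nan
    sd1: float = np.nan
    sd2: float = np.nan
    sd1_sd2: float = np.nan
    sampen: float = np.nan
    apen: float = np.nan
    dfa_a1: float = np.nan
    dfa_a2: float = np.nan
    flags: dict = field(default_factory=dict)

    PARAM_NAMES = (
        "mean_nn", "sdnn", "mean_hr", "sd_hr", "rmssd", "skewness", "kurtosis",
        "triangular_index", "nn50", "pnn50", "nn50n", "pnn50n",
        "total_power", "vlf_power", "lf_power", "hf_power",
        "lf_norm", "hf_norm", "lf_hf",
        "sd1", "sd2", "sd1_sd2", "sampen", "apen", "dfa_a1", "dfa_a2",
    )

    def as_dict(self, prefixed: bool = False) -> dict:
        out = {}
        for name in self.PARAM_NAMES:
            value = getattr(self, name)
            key = f"{self.label}_{name}" if prefixed else name
            out[key] = np.nan if value is None else value
        return out


def _as_values(seq) -> np.ndarray:
    if isinstance(seq, RRnISequence):
        return np.asarray(seq.values, dtype=float)
    if isinstance(seq, RriSequence):
        return np.asarray(seq.intervals, dtype=float)
    return np.asarray(seq, dtype=float)


def _window_n(seq) -> int:
    return seq.config.n if isinstance(seq, RRnISequence) else 1


def time_domain(seq, n: int | None = None, denominator: str = "differences") -> dict:
    """Time-domain fields; NN50n/pNN50n use a 50*n ms threshold when n > 1.

    ``denominator`` selects the pNN50 divisor: the number of successive
    differences (default) or the element count ("elements").
    """
    x = _as_values(seq)
    if x.size < 2:
        raise ValueError("time-domain parameters need at least 2 elements")
    n = _window_n(seq) if n is None else n
    d = np.diff(x)
    denom = d.size if denominator == "differences" else x.size
    hr = 60000.0 / x
    constant = np.ptp(x) == 0  # keep SDNN exactly zero for metronomic input
    out = {
        "mean_nn": float(np.mean(x)),
        "sdnn": 0.0 if constant else float(np.std(x, ddof=1)),
        "mean_hr": float(np.mean(hr)),
        "sd_hr": 0.0 if constant else float(np.std(hr, ddof=1)),
        "rmssd": float(np.sqrt(np.mean(d**2))),
        "skewness": np.nan if constant else float(stats.skew(x)),
        "kurtosis": np.nan if constant else float(stats.kurtosis(x)),
        "nn50": int(np.sum(np.abs(d) > 50.0)),
        "pnn50": 100.0 * float(np.sum(np.abs(d) > 50.0)) / denom,
    }
    if n > 1:
        thr = 50.0 * n
        out["nn50n"] = int(np.sum(np.abs(d) > thr))
        out["pnn50n"] = 100.0 * float(np.sum(np.abs(d) > thr)) / denom
    return out


def triangular_index(seq, bin_width: float = TRIANGULAR_BIN_MS) -> float:
    """Total count divided by the modal-bin count of the value histogram."""
    x = _as_values(seq)
    if x.size < 2:
        raise ValueError("triangular index needs at least 2 elements")
    lo = math.floor(x.min() / bin_width) * bin_width
    hi = math.ceil(x.max() / bin_width) * bin_width
    nbins = max(1, int(round((hi - lo) / bin_width)))
    counts, _ = np.histogram(x, bins=nbins, range=(lo, lo + nbins * bin_width))
    return float(x.size / counts.max())


def _lomb_psd(t_s: np.ndarray, x: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """One-sided PSD estimate (ms^2/Hz) from the Lomb-Scargle periodogram.

    Scaled so that integrating the PSD over frequency recovers the series
    variance (the scaling for even sampling, applied with the mean rate).
    """
    duration = t_s[-1] - t_s[0]
    mean_rate = x.size / duration
    pgram = lombscargle(t_s, x - x.mean(), 2 * np.pi * freqs)
    return pgram * 2.0 / mean_rate


def frequency_domain(
    seq,
    bands: SpectralBands | None = None,
    *,
    oversample: int = 4,
    estimator: str = "lombscargle",
) -> dict:
    """Band powers from a periodogram of the unevenly spaced sequence.

    Default estimator is Lomb-Scargle on the native time axis; "welch"
    resamples to an even grid first.  Normalized units are percentages of
    LF + HF; they are flagged undefined when that sum vanishes.
    """
    bands = bands or SpectralBands()
    x = _as_values(seq)
    if x.size < 8:
        raise ValueError("frequency-domain parameters need at least 8 elements")
    if isinstance(seq, (RriSequence, RRnISequence)):
        t_s = (seq.times if isinstance(seq, RRnISequence) else seq.onset_times) / 1000.0
    else:
        t_s = np.cumsum(x) / 1000.0

    f_hi = bands.hf[1]
    duration = t_s[-1] - t_s[0]
    df = 1.0 / (oversample * duration)
    freqs = np.arange(df, f_hi + df, df)

    if estimator == "lombscargle":
        psd = _lomb_psd(t_s, x, freqs)
    elif estimator == "welch":
        fs_i = 4.0 * f_hi
        grid = np.arange(t_s[0], t_s[-1], 1.0 / fs_i)
        xi = np.interp(grid, t_s, x)
        from scipy.signal import welch

        f_w, p_w = welch(xi - xi.mean(), fs=fs_i, nperseg=min(256, grid.size))
        psd = np.interp(freqs, f_w, p_w)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    def band_power(band: tuple) -> float:
        mask = (freqs >= band[0]) & (freqs < band[1])
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    vlf = band_power(bands.vlf)
    lf = band_power(bands.lf)
    hf = band_power(bands.hf)
    out = {
        "vlf_power": vlf,
        "lf_power": lf,
        "hf_power": hf,
        "total_power": vlf + lf + hf,
    }
    if lf + hf > 0:
        out["lf_norm"] = 100.0 * lf / (lf + hf)
        out["hf_norm"] = 100.0 * hf / (lf + hf)
        out["lf_hf"] = lf / hf if hf > 0 else np.inf
    else:
        out.update(lf_norm=np.nan, hf_norm=np.nan, lf_hf=np.nan)
        out["_flags"] = {"lf_norm": "undefined: LF+HF = 0"}
    return out


def poincare(seq) -> dict:
    """Lag-1 return-map dispersions across (sd1) and along (sd2) the identity.

    sd1 is the population SD of successive differences scaled by 1/sqrt(2);
    up to the (small) mean successive difference this equals RMSSD/sqrt(2).
    """
    x = _as_values(seq)
    if x.size < 3:
        raise ValueError("Poincare parameters need at least 3 elements")
    d = np.diff(x)
    s = x[:-1] + x[1:]
    sd1 = float(np.std(d, ddof=0) / np.sqrt(2))
    sd2 = float(np.std(s, ddof=0) / np.sqrt(2))
    out = {"sd1": sd1, "sd2": sd2}
    if sd2 > 0:
        out["sd1_sd2"] = sd1 / sd2
    else:
        out["sd1_sd2"] = np.nan
        out["_flags"] = {"sd1_sd2": "undefined: sd2 = 0"}
    return out


def _template_counts(
    x: np.ndarray, m: int, r: float, include_self: bool, limit: int | None = None
) -> np.ndarray:
    """Per-template counts of Chebyshev-distance matches at embedding m."""
    templ = np.lib.stride_tricks.sliding_window_view(x, m)
    if limit is not None:
        templ = templ[:limit]
    # pairwise Chebyshev distances over the template set
    dist = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=-1)
    match = dist <= r
    if not include_self:
        np.fill_diagonal(match, False)
    return match.sum(axis=1)


def sample_entropy(seq, embed_dim: int = 2, tolerance_fraction: float = 0.2) -> tuple:
    """-ln(A/B) over template matches; returns (value, flags).

    A is the number of matching template pairs at length ``embed_dim + 1``,
    B at length ``embed_dim``; self-matches are excluded.  When A = 0 the
    value is a documented large sentinel and the degeneracy is flagged.
    """
    x = _as_values(seq)
    if x.size < embed_dim + 2:
        raise ValueError(f"sample entropy needs at least {embed_dim + 2} elements")
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.nan, {"sampen": "undefined: zero variance"}
    r = tolerance_fraction * sd
    # both counts use the first N - m templates so every template has an m+1 extension
    limit = x.size - embed_dim
    b = _template_counts(x, embed_dim, r, include_self=False, limit=limit).sum()
    a = _template_counts(x, embed_dim + 1, r, include_self=False, limit=limit).sum()
    if b == 0:
        return np.nan, {"sampen": "undefined: no template matches at m"}
    if a == 0:
        return SAMPEN_SENTINEL, {"sampen": "degenerate: no matches at m+1, sentinel emitted"}
    return float(-np.log(a / b)), {}


def approximate_entropy(seq, embed_dim: int = 2, tolerance_fraction: float = 0.2) -> float:
    """Phi(m) - Phi(m+1) with self-matches included."""
    x = _as_values(seq)
    if x.size < embed_dim + 2:
        raise ValueError(f"approximate entropy needs at least {embed_dim + 2} elements")
    sd = np.std(x, ddof=1)
    r = tolerance_fraction * sd

    def phi(m: int) -> float:
        counts = _template_counts(x, m, r, include_self=True)
        return float(np.mean(np.log(counts / counts.size)))

    return phi(embed_dim) - phi(embed_dim + 1)


def _dfa_fluctuation(profile: np.ndarray, box: int) -> float:
    n_boxes = profile.size // box
    if n_boxes < 1:
        return np.nan
    trimmed = profile[: n_boxes * box].reshape(n_boxes, box)
    t = np.arange(box)
    residuals = np.empty_like(trimmed)
    for i, segment in enumerate(trimmed):
        slope, intercept = np.polyfit(t, segment, 1)
        residuals[i] = segment - (slope * t + intercept)
    return float(np.sqrt(np.mean(residuals**2)))


def dfa(
    seq,
    short_scales: tuple = DFA_SHORT_SCALES,
    long_scales: tuple = DFA_LONG_SCALES,
) -> tuple:
    """Detrended fluctuation scaling exponents (alpha1, alpha2, flags).

    The series is mean-centered and integrated; per box size the RMS of
    linearly detrended box residuals gives F(s); alpha is the slope of
    log F vs log s over the requested scale range.  alpha2 is flagged
    missing when the sequence is shorter than the largest long-range box.
    """
    x = _as_values(seq)
    flags: dict = {}
    profile = np.cumsum(x - x.mean())

    def alpha(scale_range: tuple) -> float:
        lo, hi = scale_range
        boxes = np.unique(np.round(np.geomspace(lo, hi, num=10)).astype(int))
        boxes = boxes[boxes <= x.size // 2]
        fluct = np.array([_dfa_fluctuation(profile, b) for b in boxes])
        ok = np.isfinite(fluct) & (fluct > 0)
        if ok.sum() < 3:
            return np.nan
        slope, _ = np.polyfit(np.log(boxes[ok]), np.log(fluct[ok]), 1)
        return float(slope)

    if x.size < short_scales[1] + 1:
        a1 = np.nan
        flags["dfa_a1"] = "insufficient length for short scales"
    else:
        a1 = alpha(short_scales)
    if x.size < long_scales[1] + 1:
        a2 = np.nan
        flags["dfa_a2"] = "insufficient length for long scales"
    else:
        a2 = alpha(long_scales)
    return a1, a2, flags


def compute_parameters(
    seq: RRnISequence,
    bands: SpectralBands | None = None,
    *,
    embed_dim: int = 2,
    tolerance_fraction: float = 0.2,
) -> ParameterVector:
    """Full ParameterVector for one combined-interval sequence.

    Individual parameter failures are flagged, never raised, so one bad
    kernel cannot abort the whole vector.
    """
    pv = ParameterVector(label=seq.config.label)
    flags: dict = {}

    def attempt(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ValueError, FloatingPointError) as exc:
            flags[fn.__name__] = str(exc)
            return None

    td = attempt(time_domain, seq)
    if td:
        for k, v in td.items():
            setattr(pv, k, v)
    tri = attempt(triangular_index, seq)
    if tri is not None:
        pv.triangular_index = tri
    fd = attempt(frequency_domain, seq, bands)
    if fd:
        flags.update(fd.pop("_flags", {}))
        for k, v in fd.items():
            setattr(pv, k, v)
    pc = attempt(poincare, seq)
    if pc:
        flags.update(pc.pop("_flags", {}))
        for k, v in pc.items():
            setattr(pv, k, v)
    se = attempt(sample_entropy, seq, embed_dim, tolerance_fraction)
    if se is not None:
        pv.sampen, se_flags = se
        flags.update(se_flags)
    ae = attempt(approximate_entropy, seq, embed_dim, tolerance_fraction)
    if ae is not None:
        pv.apen = ae
    df = attempt(dfa, seq)
    if df is not None:
        pv.dfa_a1, pv.dfa_a2, dfa_flags = df
        flags.update(dfa_flags)
    pv.flags = flags
    return pv


def compute_all(
    rri: RriSequence,
    n_max: int = 3,
    bands: SpectralBands | None = None,
) -> dict:
    """ParameterVector per configuration, keyed by label (HRV, HR2V1, ...)."""
    out = {}
    for config in enumerate_configs(n_max):
        try:
            seq = build_rrni(rri, config)
            out[config.label] = compute_parameters(seq, bands)
        except ValueError as exc:
            pv = ParameterVector(label=config.label)
            pv.flags = {"sequence": str(exc)}
            out[config.label] = pv
    return out


def wide_row(vectors: dict, record_id: str = "") -> pd.DataFrame:
    """One wide row per recording: columns ``<LABEL>_<param>``."""
    row: dict = {"record_id": record_id}
    for label, pv in vectors.items():
        row.update(pv.as_dict(prefixed=True))
    return pd.DataFrame([row])
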