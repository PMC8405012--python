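"""Synthetic tachograms, ECG waveforms and two-group cohorts.

Tachograms come from an integral-pulse-frequency-modulation (IPFM) scheme:
the instantaneous beat rate is a mean rate modulated by two sinusoids (a
low- and a high-frequency component), beats fire at unit crossings of the
integrated rate.  That gives controllable band power so the spectral
estimators downstream can be validated against known ground truth.

Cohorts are generated with an explicit outcome model: feature columns are
drawn first, the binary outcome follows a logistic model whose intercept is
calibrated to the requested prevalence, and any per-group covariates are
then drawn conditionally on the realized outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from hrnv.sequences import EcgRecord, RriSequence

__all__ = [
    "TachogramSpec",
    "CohortSpec",
    "generate_rri",
    "generate_ecg",
    "generate_cohort",
    "default_cohort_spec",
]

MAX_COHORT_RETRIES = 100


@dataclass(frozen=True)
class TachogramSpec:
    """Parameters of one synthetic tachogram."""

    duration_s: float = 300.0
    mean_hr: float = 70.0
    lf_freq: float = 0.10
    hf_freq: float = 0.25
    lf_amp: float = 0.0
    hf_amp: float = 0.0
    noise_sd: float = 0.0  # additive interval noise, ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not (20.0 < self.mean_hr < 250.0):
            raise ValueError(f"mean_hr must be in (20, 250), got {self.mean_hr}")
        if self.lf_freq >= self.hf_freq:
            raise ValueError("lf_freq must be below hf_freq")
        if self.lf_amp < 0 or self.hf_amp < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise_sd must be non-negative")


def generate_rri(spec: TachogramSpec, source_id: str = "synthetic") -> RriSequence:
    """IPFM tachogram: beats at unit crossings of the integrated rate.

    r(t) = (mean_hr/60) * (1 + lf_amp sin(2 pi lf_freq t)
                             + hf_amp sin(2 pi hf_freq t));
    intervals are successive beat-time differences in ms plus optional
    zero-mean Gaussian noise.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.mean_hr / 60.0  # beats per second

    if spec.lf_amp == 0 and spec.hf_amp == 0:
        # metronomic case: constant intervals, kept bit-exact
        n_beats = int(np.floor(spec.duration_s * base))
        if n_beats < 10:
            raise ValueError(f"spec yields only {n_beats} beats; need at least 10")
        intervals = np.full(n_beats, 1000.0 / base)
        if spec.noise_sd > 0:
            intervals = intervals + rng.normal(0.0, spec.noise_sd, size=intervals.size)
            intervals = np.clip(intervals, 1.0, None)
        return RriSequence(intervals=intervals, source_id=source_id)
    else:
        dt = 1e-3
        t = np.arange(0.0, spec.duration_s + dt, dt)
        rate = base * (
            1.0
            + spec.lf_amp * np.sin(2 * np.pi * spec.lf_freq * t)
            + spec.hf_amp * np.sin(2 * np.pi * spec.hf_freq * t)
        )
        if np.any(rate <= 0):
            raise ValueError("modulation amplitudes drive the instantaneous rate non-positive")
        integral = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) * dt / 2.0)])
        n_beats = int(np.floor(integral[-1]))
        beat_times = np.interp(np.arange(1, n_beats + 1, dtype=float), integral, t)

    if n_beats < 10:
        raise ValueError(f"spec yields only {n_beats} beats; need at least 10")
    intervals = np.diff(np.concatenate([[0.0], beat_times])) * 1000.0
    if spec.noise_sd > 0:
        intervals = intervals + rng.normal(0.0, spec.noise_sd, size=intervals.size)
        intervals = np.clip(intervals, 1.0, None)
    return RriSequence(intervals=intervals, source_id=source_id)


def default_beat_template(sampling_rate: float, width_s: float = 0.08) -> np.ndarray:
    """A dominant-R deflection: a narrow raised-cosine spike of unit height."""
    half = max(2, int(round(width_s * sampling_rate / 2)))
    t = np.arange(-half, half + 1) / half
    return 0.5 * (1 + np.cos(np.pi * t))


def generate_ecg(
    rri: RriSequence,
    sampling_rate: float = 250.0,
    template: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    record_id: str = "synthetic",
) -> EcgRecord:
    """Place one template beat at each beat time of the tachogram.

    Beat k sits at the onset of interval k (the first beat at t = 0), so the
    planted R-peak sample indices — stored in ``meta['r_peaks']`` — are the
    rounded cumulative onset times.
    """
    if sampling_rate < 100:
        raise ValueError("sampling_rate must be at least 100 Hz")
    if len(rri) == 0:
        raise ValueError("cannot synthesize ECG from an empty interval sequence")
    template = default_beat_template(sampling_rate) if template is None else np.asarray(template)
    shortest_ms = float(np.min(rri.intervals))
    if template.size / sampling_rate * 1000.0 > shortest_ms:
        raise ValueError(
            f"template spans {template.size / sampling_rate * 1000:.0f} ms, longer than the "
            f"shortest interval ({shortest_ms:.0f} ms)"
        )
    total_ms = float(np.sum(rri.intervals))
    n_samples = int(np.ceil(total_ms / 1000.0 * sampling_rate))
    x = np.zeros(n_samples)
    beat_times_ms = np.concatenate([[0.0], np.cumsum(rri.intervals)[:-1]])
    peak_samples = np.round(beat_times_ms / 1000.0 * sampling_rate).astype(int)
    center = int(np.argmax(template))
    for p in peak_samples:
        lo = p - center
        hi = lo + template.size
        t_lo = max(0, -lo)
        t_hi = template.size - max(0, hi - n_samples)
        x[max(0, lo) : min(hi, n_samples)] += template[t_lo:t_hi]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=x.size)
    return EcgRecord(
        samples=x,
        sampling_rate=sampling_rate,
        record_id=record_id,
        meta={"r_peaks": peak_samples},
    )


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort recipe.

    ``covariates`` maps a variable name to its distribution:
      - continuous: {"mean": m, "sd": s} or per-group
        {"mean": (m0, m1), "sd": (s0, s1)}
      - binary: {"p": q} or {"p": (q0, q1)}
    Variables named in ``feature_effects`` (per-unit log-odds ratios) drive
    the outcome; per-group parameters on other variables create Table-1-like
    group contrasts conditional on the realized outcome.
    """

    n_patients: int = 342
    prevalence: float = 0.19
    covariates: dict = field(default_factory=dict)
    feature_effects: dict = field(default_factory=dict)
    n_noise_features: int = 0  # extra standard-normal feature columns f1..fK
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie strictly between 0 and 1")
        if self.n_patients < 20:
            raise ValueError("n_patients must be at least 20")
        known = set(self.covariates) | {f"f{i}" for i in range(1, self.n_noise_features + 1)}
        missing = set(self.feature_effects) - known
        if missing:
            raise ValueError(f"feature_effects name unknown covariates: {sorted(missing)}")


def default_cohort_spec(n_patients: int = 342, prevalence: float = 0.19, seed: int = 0) -> CohortSpec:
    """A cohort schema with the study's demographic / vitals structure."""
    covariates = {
        "age": {"mean": (65.8, 73.2), "sd": (16.1, 14.8)},
        "male": {"p": (0.522, 0.455)},
        "heart_rate": {"mean": (114.2, 112.7), "sd": (23.3, 26.0)},
        "temperature": {"mean": (38.0, 37.2), "sd": (1.2, 1.2)},
        "resp_rate": {"mean": (19.5, 22.3), "sd": (3.0, 4.5)},
        "sbp": {"mean": (113.0, 100.0), "sd": (30.0, 28.0)},
        "spo2": {"mean": (97.0, 95.5), "sd": (2.5, 3.5)},
        "gcs": {"mean": (13.4, 11.7), "sd": (3.0, 4.1)},
        "icu_disposition": {"p": (0.043, 0.167)},
        "resp_source": {"p": (0.272, 0.455)},
        "urinary_source": {"p": (0.257, 0.076)},
    }
    return CohortSpec(
        n_patients=n_patients, prevalence=prevalence, covariates=covariates, seed=seed
    )


def _is_per_group(value) -> bool:
    return isinstance(value, (tuple, list))


def _draw_marginal(rng: np.random.Generator, spec: dict, n: int, prevalence: float) -> np.ndarray:
    """Marginal draw: per-group parameters are mixed at the target prevalence."""
    if "p" in spec:
        p = spec["p"]
        if _is_per_group(p):
            p = (1 - prevalence) * p[0] + prevalence * p[1]
        return (rng.random(n) < p).astype(float)
    mean, sd = spec["mean"], spec["sd"]
    if _is_per_group(mean):
        mean = (1 - prevalence) * mean[0] + prevalence * mean[1]
    if _is_per_group(sd):
        sd = (1 - prevalence) * sd[0] + prevalence * sd[1]
    return rng.normal(mean, sd, size=n)


def _draw_conditional(rng: np.random.Generator, spec: dict, outcome: np.ndarray) -> np.ndarray:
    n = outcome.size
    if "p" in spec:
        p = spec["p"]
        p = np.where(outcome == 1, p[1], p[0]) if _is_per_group(p) else np.full(n, p)
        return (rng.random(n) < p).astype(float)
    mean, sd = spec["mean"], spec["sd"]
    mean = np.where(outcome == 1, mean[1], mean[0]) if _is_per_group(mean) else np.full(n, mean)
    sd = np.where(outcome == 1, sd[1], sd[0]) if _is_per_group(sd) else np.full(n, sd)
    return rng.normal(mean, sd)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Per-patient cohort table with a binary ``outcome`` column.

    Degenerate single-class outcome draws are retried up to a bounded count
    before raising.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    effect_vars = list(spec.feature_effects)
    noise_vars = [f"f{i}" for i in range(1, spec.n_noise_features + 1)]

    for _attempt in range(MAX_COHORT_RETRIES):
        data: dict = {}
        # stage 1: variables that drive the outcome, drawn marginally
        for name in effect_vars:
            cov = spec.covariates.get(name)
            data[name] = (
                rng.standard_normal(n)
                if cov is None
                else _draw_marginal(rng, cov, n, spec.prevalence)
            )
        # linear predictor with intercept calibrated to the target prevalence
        eta = np.zeros(n)
        for name, beta in spec.feature_effects.items():
            eta += beta * data[name]

        def mean_prob(intercept: float) -> float:
            return float(np.mean(expit(intercept + eta))) - spec.prevalence

        intercept = brentq(mean_prob, -40.0, 40.0)
        outcome = (rng.random(n) < expit(intercept + eta)).astype(int)
        if 0 < outcome.sum() < n:
            break
    else:
        raise RuntimeError(
            f"outcome draw degenerate after {MAX_COHORT_RETRIES} retries; "
            "check prevalence and cohort size"
        )

    # stage 2: remaining covariates, conditional on the realized outcome
    for name, cov in spec.covariates.items():
        if name not in data:
            data[name] = _draw_conditional(rng, cov, outcome)
    for name in noise_vars:
        if name not in data:
            data[name] = rng.standard_normal(n)

    frame = pd.DataFrame(data)
    frame.insert(0, "patient_id", [f"P{i:05d}" for i in range(n)])
    frame["outcome"] = outcome
    return frame


def generate_feature_block(
    n_patients: int,
    outcome: np.ndarray,
    group_specs: tuple,
    *,
    n_max: int = 3,
    duration_s: float = 300.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-patient tachogram-derived features with group-dependent dynamics.

    ``group_specs`` is a pair of TachogramSpec templates (non-outcome,
    outcome); each patient gets a fresh seed.  The full combined-sequence
    parameter suite is computed per patient, so the whole
    tachogram -> feature path is exercised.
    """
    from hrnv.params import compute_all, wide_row

    rows = []
    for i in range(n_patients):
        base = group_specs[int(outcome[i])]
        t_spec = TachogramSpec(
            duration_s=duration_s,
            mean_hr=base.mean_hr,
            lf_freq=base.lf_freq,
            hf_freq=base.hf_freq,
            lf_amp=base.lf_amp,
            hf_amp=base.hf_amp,
            noise_sd=base.noise_sd,
            seed=seed + 7919 * i,
        )
        rri = generate_rri(t_spec, source_id=f"P{i:05d}")
        rows.append(wide_row(compute_all(rri, n_max=n_max), record_id=f"P{i:05d}"))
    return pd.concat(rows, ignore_index=True)
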