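"""Synthetic-EEG generator for virtual UWS/MCS cohorts.

Each virtual subject carries a resting band-power composition per
cortical region (drawn around group templates taken from published
group medians: the UWS-like group is delta-dominant, the MCS-like group
carries more alpha/beta), a set of multiplicative task-modulation
factors applied during motor-imagery cue windows (MCS-like: delta/theta
up and alpha/beta/gamma down over frontal/parietal cortex; UWS-like:
parietal gamma up only), and an attention gain in [0, 1], affinely
linked to the CRS-R score, that scales how strongly imagery cues shift
the Fp1 beta/alpha power ratio.

Signals are sums of band-limited noise: white noise filtered with the
same 6th-order Butterworth design the analysis chain uses, normalized to
unit variance per band, then weighted so the *expected* relative power
per region equals the subject's band weights (or their task-modulated,
renormalized product inside cue windows).  Ocular artifacts (slow,
frontal-dominant, mirrored on a synthetic EOG channel) and brief
high-amplitude transients (> 75 uV) are injected at configurable rates;
ground truth about everything injected is attached to the recording so
downstream stages can be tested against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    BAND_NAMES,
    EOG_CHANNEL,
    REGION_NAMES,
    SCALP_CHANNELS,
    ConfigurationError,
    EEGRecording,
    SessionPlan,
    child_seed,
    default_regions,
)
from .preprocess import band_sos, filt_padlen, filtfilt_noise_var
from scipy import signal as _signal

__all__ = [
    "SubjectProfile",
    "EffectConfig",
    "make_cohort",
    "synthesize_recording",
    "simulate_attention_trace",
    "cohort_metadata_frame",
    "write_cohort_metadata",
    "save_recording",
    "load_recording",
    "load_edf",
]

_BAND_EDGE = {"delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 15.0),
              "beta": (15.0, 30.0), "gamma": (30.0, 45.0)}

# Resting relative-power templates per group and region (normalized
# medians reported for pDoC groups; temporal/occipital reuse parietal).
_REST_TEMPLATES: Dict[str, Dict[str, Tuple[float, ...]]] = {
    "MCS": {
        "frontal": (0.35, 0.28, 0.22, 0.10, 0.01),
        "parietal": (0.36, 0.24, 0.24, 0.15, 0.01),
        "temporal": (0.36, 0.24, 0.24, 0.15, 0.01),
        "occipital": (0.36, 0.24, 0.24, 0.15, 0.01),
    },
    "UWS": {
        "frontal": (0.44, 0.25, 0.18, 0.09, 0.01),
        "parietal": (0.43, 0.25, 0.20, 0.12, 0.01),
        "temporal": (0.43, 0.25, 0.20, 0.12, 0.01),
        "occipital": (0.43, 0.25, 0.20, 0.12, 0.01),
    },
}

# Cue-window multiplicative modulation factors (renormalized in use).
_TASK_MODULATION: Dict[str, Dict[str, Tuple[float, ...]]] = {
    "MCS": {
        "frontal": (1.6, 1.6, 0.45, 0.40, 0.70),
        "parietal": (1.15, 1.9, 0.60, 0.35, 0.50),
        "temporal": (1.0, 1.0, 1.0, 1.0, 1.0),
        "occipital": (1.0, 1.0, 1.0, 1.0, 1.0),
    },
    "UWS": {
        "frontal": (1.0, 1.0, 1.0, 1.0, 1.0),
        "parietal": (1.0, 1.0, 1.0, 1.0, 4.0),
        "temporal": (1.0, 1.0, 1.0, 1.0, 1.0),
        "occipital": (1.0, 1.0, 1.0, 1.0, 1.0),
    },
}

# --- Welch response calibration --------------------------------------
#
# The analysis chain estimates PSDs with short (500 ms) Hamming windows,
# whose spectral kernel smears narrow bands (notably delta) across band
# edges and below the 1 Hz analysis floor.  So that the *measured*
# relative power of synthetic data equals the requested band weights,
# the generator solves a small calibration system: the expected Welch
# band-power response of each unit-variance band-limited noise process
# is computed exactly from the window kernel and the process
# autocovariance, and the band variances are obtained by non-negative
# least squares against the target weights.

@lru_cache(maxsize=8)
def _welch_band_response(fs: float) -> np.ndarray:
    """P[i, j]: expected Welch power measured in band j (over [1, 45] Hz)
    for unit-variance noise synthesized in band i."""
    from scipy.fft import ifft, rfftfreq
    from scipy.linalg import toeplitz
    from .spectral import NFFT_FACTOR, WINDOW_S

    L = int(round(WINDOW_S * fs))
    nfft = NFFT_FACTOR * L
    w = _signal.get_window("hamming", L)
    U = float(np.sum(w**2))
    freqs = rfftfreq(nfft, 1.0 / fs)
    in_range = np.nonzero((freqs >= 1.0) & (freqs <= 45.0))[0]
    n_dense = 1 << 14
    # window kernel rows (no detrending): a_k[n] = w[n] e^{-i w_k n}
    n_idx = np.arange(L)
    E = np.exp(-2j * np.pi * np.outer(in_range, n_idx) / nfft)
    A = w[None, :] * E

    P = np.zeros((len(BAND_NAMES), len(BAND_NAMES)))
    masks = []
    last = BAND_NAMES[-1]
    f_in = freqs[in_range]
    for name in BAND_NAMES:
        f1, f2 = _BAND_EDGE[name]
        if name == last:
            masks.append((f_in >= f1) & (f_in <= f2))
        else:
            masks.append((f_in >= f1) & (f_in < f2))
    for i, band in enumerate(BAND_NAMES):
        f1, f2 = _BAND_EDGE[band]
        _, h = _signal.sosfreqz(band_sos(fs, f1, f2), worN=n_dense,
                                whole=True)
        S = np.abs(h) ** 4
        S /= S.mean()  # unit-variance process
        r = np.real(ifft(S))[:L]
        R = toeplitz(r)
        M = A.conj() @ R
        expected = 2.0 / (fs * U) * np.real(np.einsum("kn,kn->k", M, A))
        for j, mask in enumerate(masks):
            P[i, j] = expected[mask].sum()
    return P


def _mixture_coeffs(fs: float, weights: np.ndarray) -> np.ndarray:
    """Band variances c >= 0 such that the expected Welch-measured
    relative powers equal ``weights``; normalized to unit variance."""
    from scipy.optimize import nnls

    P = _welch_band_response(fs)
    c, _ = nnls(P.T, np.asarray(weights, dtype=float))
    if c.sum() <= 0:
        c = np.asarray(weights, dtype=float).copy()
    return c / c.sum()


_BLINK_TOPO = {"Fp1": 1.0, "Fp2": 1.0, "Fz": 0.55, "F3": 0.5, "F4": 0.5,
               "F7": 0.5, "F8": 0.5, "FC3": 0.3, "FC4": 0.3, "FCz": 0.3,
               "FT7": 0.3, "FT8": 0.3}
_BLINK_TOPO_DEFAULT = 0.08
_BLINK_EOG_GAIN = 1.8


def _as_nested(table: Dict[str, Dict[str, Tuple[float, ...]]]
               ) -> Dict[str, Dict[str, Dict[str, float]]]:
    return {g: {r: dict(zip(BAND_NAMES, v)) for r, v in per.items()}
            for g, per in table.items()}


@dataclass
class EffectConfig:
    """Cohort-level generator parameters (the study conditions).

    ``attention_target_rho`` is the design target for the rank
    correlation between CRS-R and attention responsiveness;
    ``gain_noise_sd`` was calibrated once so the induced correlation
    between CRS-R and the measured session attention index matches it.
    """

    rest_weights: Dict[str, Dict[str, Dict[str, float]]] = field(
        default_factory=lambda: _as_nested(_REST_TEMPLATES))
    weight_concentration: float = 30.0
    task_modulation: Dict[str, Dict[str, Dict[str, float]]] = field(
        default_factory=lambda: _as_nested(_TASK_MODULATION))
    modulation_jitter_rel_sd: float = 0.15
    crs_range: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: {"UWS": (4, 9), "MCS": (10, 20)})
    gain_intercept: float = 0.095
    gain_slope: float = 0.011
    gain_noise_sd: float = 0.04
    attention_target_rho: float = 0.43
    ratio_shift: float = 3.5
    alpha_idle: float = 6.0
    latency_s: float = 4.0
    peak_width_s: float = 1.5
    peak_noise_log_sd: float = 0.9
    rms_uv: float = 12.0
    blink_amp_uv: Tuple[float, float] = (90.0, 140.0)
    spike_amp_uv: Tuple[float, float] = (90.0, 150.0)
    cue_blink_factor: float = 0.3
    age_mean_sd: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"UWS": (45.58, 11.49), "MCS": (48.2, 10.94)})
    duration_mean_sd: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"UWS": (6.08, 3.03), "MCS": (8.58, 5.15)})
    p_male: Dict[str, float] = field(
        default_factory=lambda: {"UWS": 8 / 12, "MCS": 16 / 19})

    @classmethod
    def null(cls) -> "EffectConfig":
        """No group differences and no task effects: both groups share one
        weight template, all modulation factors are 1, attention gain is a
        constant.  Used for type-I calibration."""
        cfg = cls()
        shared = {}
        for region in REGION_NAMES:
            shared[region] = {
                b: 0.5 * (cfg.rest_weights["MCS"][region][b]
                          + cfg.rest_weights["UWS"][region][b])
                for b in BAND_NAMES}
        # renormalize after averaging
        for region, w in shared.items():
            s = sum(w.values())
            shared[region] = {b: v / s for b, v in w.items()}
        cfg.rest_weights = {"MCS": shared, "UWS": json.loads(json.dumps(shared))}
        ones = {r: {b: 1.0 for b in BAND_NAMES} for r in REGION_NAMES}
        cfg.task_modulation = {"MCS": ones,
                               "UWS": json.loads(json.dumps(ones))}
        cfg.gain_slope = 0.0
        cfg.gain_noise_sd = 0.0
        cfg.gain_intercept = 0.2
        # neutralize the Fp1 closed-loop modulation too: under the null
        # the task recording must be distributionally identical to rest
        cfg.ratio_shift = 0.0
        cfg.alpha_idle = 1.0
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubjectProfile:
    """One virtual subject: metadata plus generator ground truth."""

    subject_id: str
    group: str
    crs_r: int
    age: float
    sex: str
    duration_months: float
    rest_band_weights: Dict[str, Dict[str, float]]
    task_modulation: Dict[str, Dict[str, float]]
    attention_gain: float

    def __post_init__(self) -> None:
        if self.group not in ("UWS", "MCS"):
            raise ValueError(f"unknown group {self.group!r}")
        if not 0 <= self.crs_r <= 23:
            raise ValueError("CRS-R total must lie in [0, 23]")
        for region, w in self.rest_band_weights.items():
            s = sum(w.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"band weights for {region} sum to {s}")
            if any(v < 0 for v in w.values()):
                raise ValueError("band weights must be nonnegative")
        for region, m in self.task_modulation.items():
            if any(f <= 0 for f in m.values()):
                raise ValueError("modulation factors must be positive")
        if not 0.0 <= self.attention_gain <= 1.0:
            raise ValueError("attention_gain must lie in [0, 1]")

    def cue_band_weights(self) -> Dict[str, Dict[str, float]]:
        """Task (cue-window) weights: elementwise product with the
        modulation factors, renormalized per region."""
        out: Dict[str, Dict[str, float]] = {}
        for region, w in self.rest_band_weights.items():
            m = self.task_modulation[region]
            prod = {b: w[b] * m[b] for b in w}
            s = sum(prod.values())
            out[region] = {b: v / s for b, v in prod.items()}
        return out


def make_cohort(n_uws: int, n_mcs: int,
                effect_config: Optional[EffectConfig] = None,
                seed: int = 0) -> List[SubjectProfile]:
    """Draw a virtual cohort (UWS-like subjects first, then MCS-like)."""
    if n_uws < 1 or n_mcs < 1:
        raise ValueError("group counts must be >= 1")
    cfg = effect_config or EffectConfig()
    rng = np.random.default_rng(child_seed(seed, "cohort"))
    profiles: List[SubjectProfile] = []
    k = 0
    for group, n in (("UWS", n_uws), ("MCS", n_mcs)):
        for _ in range(n):
            k += 1
            lo, hi = cfg.crs_range[group]
            crs = int(rng.integers(lo, hi + 1))
            mu_a, sd_a = cfg.age_mean_sd[group]
            age = float(np.clip(rng.normal(mu_a, sd_a), 18.0, 65.0))
            mu_d, sd_d = cfg.duration_mean_sd[group]
            dur = float(np.clip(rng.normal(mu_d, sd_d), 3.0, 60.0))
            sex = "M" if rng.random() < cfg.p_male[group] else "F"
            weights: Dict[str, Dict[str, float]] = {}
            for region in REGION_NAMES:
                template = np.array(
                    [cfg.rest_weights[group][region][b] for b in BAND_NAMES])
                if cfg.weight_concentration > 0:
                    w = rng.dirichlet(template * cfg.weight_concentration)
                else:
                    w = template / template.sum()
                weights[region] = dict(zip(BAND_NAMES, map(float, w)))
            modulation: Dict[str, Dict[str, float]] = {}
            for region in REGION_NAMES:
                modulation[region] = {}
                for b in BAND_NAMES:
                    f = cfg.task_modulation[group][region][b]
                    if f != 1.0 and cfg.modulation_jitter_rel_sd > 0:
                        f = float(np.exp(np.log(f) * (
                            1.0 + rng.normal(0.0, cfg.modulation_jitter_rel_sd))))
                    modulation[region][b] = float(f)
            gain = float(np.clip(
                cfg.gain_intercept + cfg.gain_slope * crs
                + (rng.normal(0.0, cfg.gain_noise_sd)
                   if cfg.gain_noise_sd > 0 else 0.0),
                0.0, 1.0))
            profiles.append(SubjectProfile(
                subject_id=f"S{k:02d}", group=group, crs_r=crs, age=age,
                sex=sex, duration_months=dur, rest_band_weights=weights,
                task_modulation=modulation, attention_gain=gain))
    return profiles


def simulate_attention_trace(profile: SubjectProfile,
                             plan: SessionPlan,
                             seed: int = 0,
                             latency_s: float = 4.0,
                             peak_width_s: float = 1.5,
                             peak_noise_log_sd: float = 0.25,
                             dt: float = 0.02,
                             include_practice: bool = True
                             ) -> Tuple[np.ndarray, np.ndarray]:
    """Latent per-trial attention in [0, 1].

    Returns ``(t, traces)`` where ``t`` is time relative to trial start
    and ``traces`` has one row per trial.  Each trial's trace is zero
    before the imagery cue and rises to a peak ``latency_s`` after cue
    onset (a Gaussian bump of width ``peak_width_s``); the peak equals
    ``attention_gain`` scaled by multiplicative log-normal trial noise,
    clipped to 1.
    """
    if plan.n_trials < 1:
        raise ConfigurationError("plan must contain at least one trial")
    rng = np.random.default_rng(child_seed(seed, profile.subject_id, "attn"))
    n_trials = plan.n_trials + (plan.n_practice if include_practice else 0)
    t = np.arange(0.0, plan.trial_duration_s, dt)
    cue_on = plan.trial_baseline_s
    center = cue_on + latency_s
    bump = np.exp(-0.5 * ((t - center) / peak_width_s) ** 2)
    bump[t < cue_on] = 0.0
    traces = np.zeros((n_trials, t.size))
    for i in range(n_trials):
        noise = (np.exp(rng.normal(0.0, peak_noise_log_sd))
                 if peak_noise_log_sd > 0 else 1.0)
        peak = float(np.clip(profile.attention_gain * noise, 0.0, 1.0))
        traces[i] = peak * bump
    return t, traces


def _attention_signal(profile: SubjectProfile, plan: SessionPlan,
                      fs: float, n_samples: int, seed: int,
                      cfg: EffectConfig,
                      include_practice: bool) -> np.ndarray:
    t_rel, traces = simulate_attention_trace(
        profile, plan, seed, cfg.latency_s, cfg.peak_width_s,
        cfg.peak_noise_log_sd, include_practice=include_practice)
    a = np.zeros(n_samples)
    tgrid = np.arange(n_samples) / fs
    for i, start in enumerate(plan.trial_starts_s(include_practice)):
        mask = (tgrid >= start) & (tgrid < start + plan.trial_duration_s)
        a[mask] = np.interp(tgrid[mask] - start, t_rel, traces[i])
    return a


def _cue_activation(plan: SessionPlan, fs: float, n_samples: int,
                    include_practice: bool,
                    ramp_s: float = 0.25) -> np.ndarray:
    """Smooth 0..1 envelope that is 1 inside imagery cue windows."""
    m = np.zeros(n_samples)
    n_ramp = max(int(round(ramp_s * fs)), 1)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    for start in plan.trial_starts_s(include_practice):
        on = int(round((start + plan.trial_baseline_s) * fs))
        off = int(round((start + plan.trial_baseline_s + plan.trial_cue_s) * fs))
        if on >= n_samples:
            continue
        off = min(off, n_samples)
        m[on:off] = 1.0
        lo = max(on - n_ramp, 0)
        m[lo:on] = np.maximum(m[lo:on], ramp[n_ramp - (on - lo):])
        hi = min(off + n_ramp, n_samples)
        m[off:hi] = np.maximum(m[off:hi], ramp[::-1][: hi - off])
    return m


def _blink_shape(fs: float, dur_s: float = 0.5, tau_s: float = 0.1
                 ) -> np.ndarray:
    t = np.arange(int(round(dur_s * fs))) / fs
    return (t / tau_s) * np.exp(1.0 - t / tau_s)


def _spike_shape(fs: float, dur_s: float = 0.04) -> np.ndarray:
    n = max(int(round(dur_s * fs)), 3)
    return np.hanning(n)


def _emg_burst(rng: np.random.Generator, fs: float, n_ch: int,
               dur_s: float = 0.5,
               rms_range: Tuple[float, float] = (15.0, 40.0)) -> np.ndarray:
    """Spatially widespread 8-30 Hz muscle burst accompanying a
    movement transient; independent noise per channel."""
    n = max(int(round(dur_s * fs)), 8)
    pad = int(fs)
    x = rng.standard_normal((n_ch, n + 2 * pad))
    x = _signal.sosfiltfilt(band_sos(fs, 8.0, 30.0), x,
                            axis=-1)[:, pad:pad + n]
    x = x / np.maximum(np.std(x, axis=-1, keepdims=True), 1e-12)
    x *= rng.uniform(*rms_range, size=(n_ch, 1))
    return x * np.hanning(n)[None, :]


def _poisson_times(rng: np.random.Generator, rate_per_min: float,
                   duration_s: float) -> np.ndarray:
    n = rng.poisson(rate_per_min * duration_s / 60.0)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def synthesize_recording(profile: SubjectProfile,
                         plan: SessionPlan,
                         condition: str,
                         artifact_rate: float = 2.0,
                         blink_rate: float = 8.0,
                         seed: int = 0,
                         effect_config: Optional[EffectConfig] = None,
                         channels: Optional[Sequence[str]] = None,
                         include_practice: bool = True,
                         keep_truth: bool = True) -> EEGRecording:
    """Generate one condition's multichannel recording.

    ``artifact_rate`` is the transient-spike rate (events/min);
    ``blink_rate`` the ocular-artifact rate (events/min).  Both artifact
    streams are thinned inside cue windows, where engaged subjects blink
    and move less.  ``channels``
    restricts synthesis to a subset of scalp channels (plus ``EOG`` if
    listed) for fast Monte-Carlo studies.
    """
    if condition not in ("rest", "task"):
        raise ValueError(f"unknown condition {condition!r}")
    cfg = effect_config or EffectConfig()
    regions = default_regions()
    if channels is None:
        names = list(SCALP_CHANNELS) + [EOG_CHANNEL]
    else:
        names = list(channels)
    scalp_names = [ch for ch in names if ch in SCALP_CHANNELS]
    if not scalp_names:
        raise ValueError("at least one scalp channel is required")

    if condition == "rest":
        fs = plan.fs_rest
        duration = plan.rest_duration_s
    else:
        fs = plan.fs_task
        duration = plan.task_duration_s if include_practice else \
            plan.n_trials * plan.trial_duration_s
    n_samp = int(round(duration * fs))
    rng = np.random.default_rng(
        child_seed(seed, profile.subject_id, condition))

    # Per-channel band variances (rest) and cue-window variances (task),
    # calibrated so the Welch-measured relative powers match the
    # profile's weights.
    c_by_region = {
        r: _mixture_coeffs(fs, np.array(
            [profile.rest_band_weights[r][b] for b in BAND_NAMES]))
        for r in REGION_NAMES}
    w_rest = np.array([c_by_region[regions.region_of(ch)]
                       for ch in scalp_names])
    if condition == "task":
        cue_w = profile.cue_band_weights()
        c_cue_by_region = {
            r: _mixture_coeffs(fs, np.array(
                [cue_w[r][b] for b in BAND_NAMES]))
            for r in REGION_NAMES}
        w_cue = np.array([c_cue_by_region[regions.region_of(ch)]
                          for ch in scalp_names])
        m = _cue_activation(plan, fs, n_samp, include_practice)
        a = _attention_signal(profile, plan, fs, n_samp, seed, cfg,
                              include_practice)
    else:
        w_cue = w_rest
        m = None
        a = None

    n_scalp = len(scalp_names)
    data = np.zeros((n_scalp, n_samp))
    fp1 = scalp_names.index("Fp1") if "Fp1" in scalp_names else None
    if condition == "task" and fp1 is not None:
        # Closed-loop modulation at Fp1: a tonic alpha-idling factor
        # lowers the beta/alpha ratio during task blocks, and the latent
        # attention raises it.  The instantaneous variance is
        # renormalized so the modulation shifts Fp1's spectral
        # composition, not its total power.
        shift = 1.0 + cfg.ratio_shift * a
        fp1_mult = {b: np.ones(n_samp) for b in BAND_NAMES}
        fp1_mult["beta"] = shift
        fp1_mult["alpha"] = cfg.alpha_idle / shift
        c_fp1 = (w_rest[fp1][:, None]
                 + (w_cue[fp1] - w_rest[fp1])[:, None] * m[None, :])
        v = sum(c_fp1[bi] * fp1_mult[b] for bi, b in enumerate(BAND_NAMES))
        fp1_norm = 1.0 / np.sqrt(v)
    else:
        fp1_mult = None
        fp1_norm = None
    for bi, band in enumerate(BAND_NAMES):
        f1, f2 = _BAND_EDGE[band]
        # generate with margin and crop the interior: reflect-padding a
        # white sequence inflates edge variance for narrow low bands
        margin = filt_padlen(fs, f1, n_samp)
        x = rng.standard_normal((n_scalp, n_samp + 2 * margin))
        x = _signal.sosfiltfilt(band_sos(fs, f1, f2), x, axis=-1)
        x = x[:, margin:margin + n_samp]
        x /= np.sqrt(filtfilt_noise_var(fs, f1, f2))
        if condition == "rest":
            env = np.sqrt(w_rest[:, bi])[:, None] * np.ones((1, n_samp))
        else:
            env = np.sqrt(w_rest[:, bi][:, None]
                          + (w_cue[:, bi] - w_rest[:, bi])[:, None] * m[None, :])
        if fp1_mult is not None:
            env[fp1] = env[fp1] * np.sqrt(fp1_mult[band]) * fp1_norm
        data += x * env
    data *= cfg.rms_uv

    # --- artifacts ---------------------------------------------------
    art = np.zeros_like(data)
    eog_art = np.zeros(n_samp)
    blink_samples: List[int] = []
    spike_samples: List[Tuple[int, int]] = []
    if blink_rate > 0:
        shape = _blink_shape(fs)
        topo = np.array([_BLINK_TOPO.get(ch, _BLINK_TOPO_DEFAULT)
                         for ch in scalp_names])
        for t0 in _poisson_times(rng, blink_rate, duration - 0.6):
            if condition == "task" and m is not None:
                s0 = int(round(t0 * fs))
                if m[s0] > 0.5 and rng.random() > cfg.cue_blink_factor:
                    continue
            s0 = int(round(t0 * fs))
            amp = rng.uniform(*cfg.blink_amp_uv)
            seg = slice(s0, s0 + shape.size)
            art[:, seg] += amp * np.outer(topo, shape)
            eog_art[seg] += _BLINK_EOG_GAIN * amp * shape
            blink_samples.append(s0)
    if artifact_rate > 0:
        shape = _spike_shape(fs)
        for t0 in _poisson_times(rng, artifact_rate, duration - 0.1):
            s0 = int(round(t0 * fs))
            if condition == "task" and m is not None \
                    and m[s0] > 0.5 and rng.random() > cfg.cue_blink_factor:
                continue
            ch = int(rng.integers(n_scalp))
            amp = rng.uniform(*cfg.spike_amp_uv) * rng.choice([-1.0, 1.0])
            art[ch, s0:s0 + shape.size] += amp * shape[: n_samp - s0]
            burst = _emg_burst(rng, fs, n_scalp)
            art[:, s0:s0 + burst.shape[1]] += burst[:, : n_samp - s0]
            spike_samples.append((s0, ch))
    data = data + art

    # assemble channel matrix in requested order, with EOG if present
    full = np.zeros((len(names), n_samp))
    for i, ch in enumerate(names):
        if ch == EOG_CHANNEL:
            full[i] = eog_art + rng.normal(0.0, 5.0, size=n_samp)
        else:
            full[i] = data[scalp_names.index(ch)]

    events: List[Tuple[int, str]] = []
    if condition == "task":
        starts = plan.trial_starts_s(include_practice)
        n_pr = plan.n_practice if include_practice else 0
        for i, start in enumerate(starts):
            prefix = "practice_" if i < n_pr else ""
            on = int(round((start + plan.trial_baseline_s) * fs))
            off = int(round(
                (start + plan.trial_baseline_s + plan.trial_cue_s) * fs))
            events.append((on, prefix + "cue_on"))
            events.append((min(off, n_samp), prefix + "cue_off"))

    truth = None
    if keep_truth:
        truth = {
            "rest_variances": w_rest,
            "cue_variances": w_cue,
            "scalp_names": scalp_names,
            "blink_samples": blink_samples,
            "spike_samples": spike_samples,
            "artifact_signal": art if (blink_samples or spike_samples) else None,
            "attention": a,
        }
    return EEGRecording(
        data=full, fs=fs, channel_names=names, condition=condition,
        events=events, truth=truth,
        meta={"subject_id": profile.subject_id, "group": profile.group,
              "seed": int(seed)})


# --- I/O -------------------------------------------------------------

def cohort_metadata_frame(cohort: Sequence[SubjectProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": p.subject_id, "group": p.group, "crs_r": p.crs_r,
        "age": p.age, "sex": p.sex, "duration_months": p.duration_months,
    } for p in cohort])


def write_cohort_metadata(cohort: Sequence[SubjectProfile],
                          path: str) -> pd.DataFrame:
    df = cohort_metadata_frame(cohort)
    df.to_csv(path, index=False)
    return df


def save_recording(rec: EEGRecording, path: str) -> None:
    """Persist a recording as a compressed NPZ archive (ground-truth
    annotations are not persisted)."""
    np.savez_compressed(
        path, data=rec.data, fs=rec.fs,
        channel_names=np.array(rec.channel_names),
        condition=rec.condition,
        event_samples=np.array([s for s, _ in rec.events], dtype=np.int64),
        event_labels=np.array([lab for _, lab in rec.events]),
        meta_json=json.dumps(rec.meta))


def load_recording(path: str) -> EEGRecording:
    with np.load(path, allow_pickle=False) as z:
        events = list(zip((int(s) for s in z["event_samples"]),
                          (str(x) for x in z["event_labels"])))
        return EEGRecording(
            data=z["data"], fs=float(z["fs"]),
            channel_names=[str(c) for c in z["channel_names"]],
            condition=str(z["condition"]), events=events,
            meta=json.loads(str(z["meta_json"])))


def load_edf(path: str,
             channel_map: Optional[Dict[str, str]] = None,
             condition: str = "task") -> EEGRecording:
    """Read a user-supplied EDF+ file into the package's data model
    (amplitudes converted to uV; annotations become events)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = [channel_map.get(ch, ch) if channel_map else ch
             for ch in raw.ch_names]
    data = raw.get_data() * 1e6
    events = []
    for ann in raw.annotations:
        events.append((int(round(ann["onset"] * raw.info["sfreq"])),
                       str(ann["description"])))
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]),
                        channel_names=names, condition=condition,
                        events=events)
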