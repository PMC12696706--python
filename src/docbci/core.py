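"""Shared data model: montage, frequency bands, recordings, session plans.

All signal amplitudes in this package are in microvolts (uV), all
frequencies in Hz, all times in seconds.  The channel layout is the
30-channel subset of the international 10-10 system used by portable
BCI amplifiers, grouped into four cortical regions (frontal, parietal,
temporal, occipital); one auxiliary EOG channel may be attached and is
excluded from every EEG-level computation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "F_LOW",
    "F_HIGH",
    "BAND_NAMES",
    "SCALP_CHANNELS",
    "EOG_CHANNEL",
    "BandSet",
    "RegionMap",
    "EEGRecording",
    "SessionPlan",
    "EpochSet",
    "ConfigurationError",
    "ProcessingError",
    "QualityError",
    "default_bands",
    "default_regions",
    "channel_positions",
    "child_seed",
]

F_LOW = 1.0
F_HIGH = 45.0

# Analysis sub-bands; contiguous tiling of [F_LOW, F_HIGH].
_BAND_EDGES: Tuple[Tuple[str, float, float], ...] = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 15.0),
    ("beta", 15.0, 30.0),
    ("gamma", 30.0, 45.0),
)
BAND_NAMES: Tuple[str, ...] = tuple(b[0] for b in _BAND_EDGES)

_REGION_CHANNELS: Dict[str, Tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "F3", "F4", "Fz", "FC3", "FC4", "FCz",
                "F7", "F8", "FT7", "FT8"),
    "parietal": ("C3", "C4", "Cz", "CP3", "CP4", "CPz", "P3", "P4", "Pz"),
    "temporal": ("T3", "T4", "TP7", "TP8", "T5", "T6"),
    "occipital": ("O1", "O2", "Oz"),
}
REGION_NAMES: Tuple[str, ...] = tuple(_REGION_CHANNELS)
SCALP_CHANNELS: Tuple[str, ...] = tuple(
    ch for region in _REGION_CHANNELS.values() for ch in region
)
EOG_CHANNEL = "EOG"


class ConfigurationError(ValueError):
    """A parameter combination that cannot be analysed (e.g. fs too low)."""


class ProcessingError(RuntimeError):
    """A per-subject processing failure (e.g. too many bad channels)."""


class QualityError(RuntimeError):
    """Data quality too poor to continue (e.g. zero usable epochs)."""


@dataclass(frozen=True)
class BandSet:
    """Ordered frequency sub-bands tiling a global analysis range."""

    bands: Tuple[Tuple[str, float, float], ...] = _BAND_EDGES
    f_range: Tuple[float, float] = (F_LOW, F_HIGH)

    def __post_init__(self) -> None:
        lo, hi = self.f_range
        if not self.bands:
            raise ConfigurationError("empty band set")
        prev = lo
        for name, f1, f2 in self.bands:
            if not f1 < f2:
                raise ConfigurationError(f"band {name}: need f_low < f_high")
            if abs(f1 - prev) > 1e-9:
                raise ConfigurationError(
                    f"bands must tile [{lo}, {hi}] contiguously; gap at {f1}"
                )
            prev = f2
        if abs(prev - hi) > 1e-9:
            raise ConfigurationError("bands do not reach the top of f_range")

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def edges(self, name: str) -> Tuple[float, float]:
        for n, f1, f2 in self.bands:
            if n == name:
                return (f1, f2)
        raise KeyError(name)


@dataclass(frozen=True)
class RegionMap:
    """Disjoint channel groups covering the 30 scalp channels."""

    regions: Mapping[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(_REGION_CHANNELS)
    )

    def __post_init__(self) -> None:
        seen: List[str] = []
        for chans in self.regions.values():
            seen.extend(chans)
        if len(seen) != len(set(seen)):
            raise ConfigurationError("region channel groups overlap")
        if set(seen) != set(SCALP_CHANNELS):
            raise ConfigurationError(
                "regions must cover exactly the 30 scalp channels"
            )

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.regions)

    def channels(self, region: str) -> Tuple[str, ...]:
        return tuple(self.regions[region])

    def region_of(self, channel: str) -> str:
        for region, chans in self.regions.items():
            if channel in chans:
                return region
        raise KeyError(channel)


def default_bands() -> BandSet:
    return BandSet()


def default_regions() -> RegionMap:
    return RegionMap()


@dataclass
class EEGRecording:
    """One condition's multichannel signal.

    data : (n_channels, n_samples) array, uV
    events : list of (sample_index, label), e.g. ("cue_on", "cue_off")
    truth : generator-side ground truth (injected artifacts, latent
        attention trace, mixing), populated only for synthetic data.
    """

    data: np.ndarray
    fs: float
    channel_names: List[str]
    condition: str
    events: List[Tuple[int, str]] = field(default_factory=list)
    truth: Optional[dict] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        for sample, _ in self.events:
            if not 0 <= sample <= self.data.shape[1]:
                raise ValueError("event sample index outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def scalp_indices(self) -> np.ndarray:
        """Indices of EEG scalp channels (excludes EOG and other aux)."""
        scalp = set(SCALP_CHANNELS)
        return np.array(
            [i for i, ch in enumerate(self.channel_names) if ch in scalp],
            dtype=int,
        )

    @property
    def scalp_names(self) -> List[str]:
        return [self.channel_names[i] for i in self.scalp_indices]

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def event_samples(self, label: str) -> List[int]:
        return [s for s, lab in self.events if lab == label]


@dataclass(frozen=True)
class SessionPlan:
    """Timing of one recording session.

    A task trial is baseline -> imagery cue -> feedback/inter-trial.
    The imagery window defaults to 5 s, matching the analysis
    segmentation; practice trials precede scored trials and are
    excluded from scoring.
    """

    n_trials: int = 15
    n_practice: int = 5
    trial_baseline_s: float = 4.0
    trial_cue_s: float = 5.0
    trial_iti_s: float = 3.0
    fs_task: float = 250.0
    fs_rest: float = 500.0
    rest_duration_s: float = 300.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("need at least one trial")
        if self.n_practice < 0:
            raise ConfigurationError("n_practice must be >= 0")
        for name in ("trial_baseline_s", "trial_cue_s", "trial_iti_s",
                     "rest_duration_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for fs in (self.fs_task, self.fs_rest):
            if fs <= 2.0 * F_HIGH:
                raise ConfigurationError(
                    f"sampling rate {fs} Hz too low for the {F_HIGH} Hz edge"
                )

    @property
    def trial_duration_s(self) -> float:
        return self.trial_baseline_s + self.trial_cue_s + self.trial_iti_s

    @property
    def task_duration_s(self) -> float:
        return (self.n_trials + self.n_practice) * self.trial_duration_s

    def trial_starts_s(self, include_practice: bool = True) -> List[float]:
        n = self.n_trials + (self.n_practice if include_practice else 0)
        return [i * self.trial_duration_s for i in range(n)]


@dataclass
class EpochSet:
    """Fixed-length epochs with a keep/reject flag per epoch."""

    data: np.ndarray  # (n_epochs, n_channels, n_samples)
    fs: float
    channel_names: List[str]
    keep: np.ndarray  # bool per epoch
    reject_reason: List[str]
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("epochs must be (epochs, channels, samples)")
        if self.data.shape[0] != self.keep.shape[0]:
            raise ValueError("keep mask length mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def kept_data(self) -> np.ndarray:
        return self.data[self.keep]

    @property
    def scalp_indices(self) -> np.ndarray:
        scalp = set(SCALP_CHANNELS)
        return np.array(
            [i for i, ch in enumerate(self.channel_names) if ch in scalp],
            dtype=int,
        )


@lru_cache(maxsize=1)
def _montage_positions() -> Dict[str, np.ndarray]:
    import mne

    try:
        montage = mne.channels.make_standard_montage("colin27_1005")
    except ValueError:  # older MNE name
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    return {name: np.asarray(p, dtype=float) for name, p in pos.items()}

# Fallback aliases in case a montage version drops the legacy temporal names.
_LEGACY_ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}


def channel_positions(names: Sequence[str]) -> np.ndarray:
    """3-D head-frame coordinates (meters) for the given channel names."""
    table = _montage_positions()
    out = np.empty((len(names), 3), dtype=float)
    for i, name in enumerate(names):
        key = name if name in table else _LEGACY_ALIASES.get(name, name)
        out[i] = table[key]
    return out


def child_seed(master_seed: int, *keys: object) -> int:
    """Stable per-(subject, stage) seed below 2**31.

    Mixing through crc32 keeps subject-level reproducibility independent
    of cohort ordering.
    """
    tag = ":".join(str(k) for k in keys)
    mix = zlib.crc32(tag.encode("utf-8"))
    return int((int(master_seed) * 2654435761 + mix) % (2**31 - 1))
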