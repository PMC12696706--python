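"""Welch power spectral density and relative band power.

PSDs use 500 ms Hamming windows with 50% (250 ms) overlap, constant
detrending and density scaling, computed per 5-s epoch and averaged over
kept epochs.  The spectra are evaluated on a zero-padded grid (0.25 s
worth of padding, 0.5 Hz resolution) so that band edges at 1/4/8/15/30/45
Hz land accurately between Fourier bins.

Relative power of a band is its summed PSD over [f1, f2) divided by the
summed PSD over the whole 1-45 Hz range (the top band closes at 45 Hz);
it is unitless, scale-invariant, and the five values sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal

from .core import (
    BandSet,
    ConfigurationError,
    EEGRecording,
    EpochSet,
    QualityError,
    RegionMap,
    channel_positions,
    default_bands,
    default_regions,
)

__all__ = [
    "PSDResult",
    "welch_psd",
    "welch_psd_array",
    "band_fractions",
    "relative_power",
    "relative_power_table",
    "export_topography",
]

WINDOW_S = 0.5
OVERLAP = 0.5
NFFT_FACTOR = 4  # zero-padding factor -> 0.5 Hz grid at 500 ms windows


@dataclass
class PSDResult:
    """Per-channel Welch PSD (uV^2/Hz) on a common frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray  # (n_channels, n_freqs)
    fs: float
    channel_names: List[str]
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.psd < 0):
            raise ValueError("power densities must be nonnegative")


def _welch_params(fs: float, window_s: float = WINDOW_S,
                  overlap: float = OVERLAP,
                  nfft_factor: int = NFFT_FACTOR) -> Tuple[int, int, int]:
    nperseg = int(round(window_s * fs))
    noverlap = int(round(overlap * nperseg))
    return nperseg, noverlap, nfft_factor * nperseg


def welch_psd_array(x: np.ndarray, fs: float,
                    window_s: float = WINDOW_S,
                    overlap: float = OVERLAP,
                    nfft_factor: int = NFFT_FACTOR
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Welch PSD of a (..., samples) array; returns (freqs, psd)."""
    nperseg, noverlap, nfft = _welch_params(fs, window_s, overlap, nfft_factor)
    # No per-window detrending: the analysis chain high-passes at 1 Hz
    # before any PSD, and mean removal inside 500 ms windows would eat a
    # sizeable part of the 1-4 Hz band (the DC kernel is ~2 Hz wide).
    freqs, psd = signal.welch(
        x, fs=fs, window=signal.get_window("hamming", nperseg),
        nperseg=nperseg, noverlap=noverlap, nfft=nfft,
        detrend=False, scaling="density", axis=-1)
    return freqs, psd


def welch_psd(epochs: Union[EpochSet, EEGRecording],
              window_s: float = WINDOW_S,
              overlap: float = OVERLAP,
              nfft_factor: int = NFFT_FACTOR) -> PSDResult:
    """Average modified periodograms within and then across kept epochs.

    Accepts a continuous recording as a degenerate single-epoch case.
    """
    if isinstance(epochs, EEGRecording):
        freqs, psd = welch_psd_array(epochs.data, epochs.fs, window_s,
                                     overlap, nfft_factor)
        return PSDResult(freqs=freqs, psd=psd, fs=epochs.fs,
                         channel_names=list(epochs.channel_names),
                         condition=epochs.condition,
                         meta={"window_s": window_s, "overlap": overlap,
                               "nfft_factor": nfft_factor, "n_epochs": 1})
    if epochs.n_kept == 0:
        raise QualityError("no kept epochs to estimate a PSD from")
    freqs, psd = welch_psd_array(epochs.kept_data, epochs.fs, window_s,
                                 overlap, nfft_factor)
    psd = psd.mean(axis=0)  # equal weight per kept epoch
    return PSDResult(freqs=freqs, psd=psd, fs=epochs.fs,
                     channel_names=list(epochs.channel_names),
                     condition=epochs.condition,
                     meta={"window_s": window_s, "overlap": overlap,
                           "nfft_factor": nfft_factor,
                           "n_epochs": epochs.n_kept,
                           "epoch_average": True})


def _band_masks(freqs: np.ndarray, bands: BandSet) -> Dict[str, np.ndarray]:
    lo, hi = bands.f_range
    if freqs[0] > lo or freqs[-1] < hi:
        raise ConfigurationError(
            f"frequency grid [{freqs[0]}, {freqs[-1]}] does not cover "
            f"[{lo}, {hi}]"
        )
    masks: Dict[str, np.ndarray] = {}
    last = bands.bands[-1][0]
    for name, f1, f2 in bands.bands:
        if name == last:
            masks[name] = (freqs >= f1) & (freqs <= f2)
        else:
            masks[name] = (freqs >= f1) & (freqs < f2)
    return masks


def band_fractions(psd: PSDResult,
                   bands: Optional[BandSet] = None) -> pd.DataFrame:
    """Per-channel relative power: (n_channels, n_bands), rows sum to 1."""
    bands = bands or default_bands()
    masks = _band_masks(psd.freqs, bands)
    power = np.stack([psd.psd[:, m].sum(axis=-1) for m in masks.values()],
                     axis=-1)
    total = power.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise QualityError("zero total power in the analysis range")
    frac = power / total
    return pd.DataFrame(frac, index=psd.channel_names, columns=list(masks))


def relative_power(psd: PSDResult,
                   bands: Optional[BandSet] = None,
                   regions: Optional[RegionMap] = None,
                   subject_id: str = "",
                   group: str = "",
                   condition: Optional[str] = None,
                   require_all_regions: bool = True) -> pd.DataFrame:
    """Region x band relative power, tidy: one row per (region, band).

    The region value is the unweighted mean of its channels' per-channel
    relative powers, so the five band values still sum to one per region.
    With ``require_all_regions=False``, regions without any present
    channel are omitted (for partial-montage simulation studies).
    """
    bands = bands or default_bands()
    regions = regions or default_regions()
    frac = band_fractions(psd, bands)
    rows = []
    cond = psd.condition if condition is None else condition
    for region in regions.names:
        chans = [c for c in regions.channels(region) if c in frac.index]
        if not chans:
            if require_all_regions:
                raise ConfigurationError(f"no channels present for {region}")
            continue
        mean = frac.loc[chans].mean(axis=0)
        for band in bands.names:
            rows.append({"subject_id": subject_id, "group": group,
                         "condition": cond, "region": region,
                         "band": band, "rel_power": float(mean[band])})
    return pd.DataFrame(rows)


def relative_power_table(entries: List[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-subject relative-power frames into one tidy table."""
    table = pd.concat(entries, ignore_index=True)
    cols = ["subject_id", "group", "condition", "region", "band", "rel_power"]
    return table[cols]


def export_topography(psd: PSDResult,
                      bands: Optional[BandSet] = None,
                      path: Optional[str] = None) -> pd.DataFrame:
    """Channel-resolved relative power with 10-10 coordinates, for
    topographic plotting outside this package."""
    bands = bands or default_bands()
    frac = band_fractions(psd, bands)
    scalp = [c for c in frac.index if c != "EOG"]
    frac = frac.loc[scalp]
    pos = channel_positions(scalp)
    out = pd.DataFrame({"channel": scalp,
                        "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2]})
    for band in bands.names:
        out[band] = frac[band].to_numpy()
    if path is not None:
        out.to_csv(path, index=False, float_format="%.10g")
    return out
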