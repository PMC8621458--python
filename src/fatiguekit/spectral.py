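"""EEG spectral features: 1-s-window FFT band powers, eyes-open-normalized
powers, and the full set of pairwise band-power ratios.

Band powers are *integrated* periodogram powers: the one-sided power spectral
density of each non-overlapping 1-s window is summed over the FFT bins whose
frequency lies inside the band (edges inclusive, as printed in the band
definitions) and multiplied by the bin width.  At 250 Hz and 1-s windows the
bin resolution is exactly 1 Hz.

Normalized power expresses task power relative to the subject's own
eyes-open baseline::

    NP(t)[ch, band] = (AO(t)[ch, band] - mean_EO[ch, band]) / mean_EO[ch, band]

and is computed per subject only, never across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocessing import SegmentView

#: canonical band edges in Hz, inclusive on both sides as printed; the shared
#: 4 Hz edge therefore contributes to both delta and theta
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 29.0),
    "gamma": (30.0, 50.0),
}
BAND_NAMES = tuple(BANDS)

#: all ordered band pairs (numerator, denominator), 20 ratios per channel
RATIO_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (b1, b2) for b1 in BAND_NAMES for b2 in BAND_NAMES if b1 != b2
)


def band_bin_count(band: tuple[float, float], df: float = 1.0, n_bins: int = 126) -> int:
    """Number of FFT bins inside a band (edges inclusive), at resolution df."""
    freqs = np.arange(n_bins) * df
    return int(np.sum((freqs >= band[0]) & (freqs <= band[1])))


@dataclass(frozen=True)
class BandPowerSeries:
    """Per-window, per-channel, per-band integrated powers (microvolt^2)."""

    values: np.ndarray  # (n_windows, n_channels, n_bands)
    channel_names: tuple[str, ...]
    band_names: tuple[str, ...] = BAND_NAMES
    window_s: float = 1.0

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def mean_over_windows(self) -> np.ndarray:
        return self.values.mean(axis=0)


@dataclass(frozen=True)
class NormalizedPower:
    """Unitless eyes-open-normalized powers; 0 where AO power equals the EO
    mean, and never below -1 since powers are non-negative."""

    values: np.ndarray  # (n_windows, n_channels, n_bands)
    channel_names: tuple[str, ...]
    band_names: tuple[str, ...] = BAND_NAMES


@dataclass(frozen=True)
class RatioSeries:
    """Per-window, per-channel band-power ratios (20 ordered pairs)."""

    values: np.ndarray  # (n_windows, n_channels, n_ratios)
    channel_names: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...] = RATIO_PAIRS


def band_power_series(
    seg: SegmentView,
    bands: dict[str, tuple[float, float]] = BANDS,
    window: str = "boxcar",
    channel_names: tuple[str, ...] | None = None,
) -> BandPowerSeries:
    """FFT band powers over consecutive non-overlapping 1-s windows."""
    eeg = seg.eeg
    rate = seg.rate
    n_per_win = int(round(rate))
    n_windows = eeg.shape[1] // n_per_win
    if n_windows < 1:
        raise ValueError("segment must be at least 1 s long")
    x = eeg[:, : n_windows * n_per_win].reshape(eeg.shape[0], n_windows, n_per_win)
    freqs, psd = signal.periodogram(
        x, fs=rate, window=window, detrend=False, axis=-1
    )
    df = freqs[1] - freqs[0]
    out = np.empty((n_windows, eeg.shape[0], len(bands)))
    for j, (name, (low, high)) in enumerate(bands.items()):
        mask = (freqs >= low) & (freqs <= high)
        if not mask.any():
            raise ValueError(f"band {name} [{low}, {high}] Hz contains no FFT bins")
        out[:, :, j] = psd[:, :, mask].sum(axis=-1).T * df
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(eeg.shape[0]))
    return BandPowerSeries(values=out, channel_names=channel_names, band_names=tuple(bands))


def normalize_power(ao: BandPowerSeries, eo: BandPowerSeries) -> NormalizedPower:
    """Eyes-open normalization ``(AO(t) - mean_EO) / mean_EO``, elementwise."""
    if ao.band_names != eo.band_names or ao.values.shape[1:] != eo.values.shape[1:]:
        raise ValueError("AO and EO series must share channels and bands")
    eo_mean = eo.values.mean(axis=0)
    zero = np.argwhere(eo_mean == 0)
    if zero.size:
        ch, band = zero[0]
        raise ValueError(
            f"zero EO mean power at channel index {ch}, band {eo.band_names[band]}")
    return NormalizedPower(
        values=(ao.values - eo_mean) / eo_mean,
        channel_names=ao.channel_names,
        band_names=ao.band_names,
    )


def power_ratios(ao: BandPowerSeries) -> RatioSeries:
    """All 20 ordered band-power ratios per window and channel, computed on
    the powers prior to normalization."""
    if np.any(ao.values == 0):
        raise ValueError("zero band power encountered; ratios undefined")
    idx = {name: i for i, name in enumerate(ao.band_names)}
    cols = [ao.values[:, :, idx[b1]] / ao.values[:, :, idx[b2]] for b1, b2 in RATIO_PAIRS]
    return RatioSeries(
        values=np.stack(cols, axis=-1),
        channel_names=ao.channel_names,
        pairs=RATIO_PAIRS,
    )


def spectral_feature_vector(
    ao_np: NormalizedPower,
    ao_ratios: RatioSeries,
    channel_names: tuple[str, ...],
    duration_s: float,
) -> dict[str, float]:
    """Average the first ``floor(duration_s)`` 1-s windows into the 200 named
    spectral features: ``np_<band>_<ch>`` (40) and ``ratio_<b1>_<b2>_<ch>``
    (160)."""
    if duration_s < 1:
        raise ValueError("duration must be at least 1 s")
    n = int(np.floor(duration_s))
    if n > ao_np.values.shape[0] or n > ao_ratios.values.shape[0]:
        raise ValueError("duration exceeds available windows")
    np_mean = ao_np.values[:n].mean(axis=0)  # (channels, bands)
    ratio_mean = ao_ratios.values[:n].mean(axis=0)  # (channels, ratios)
    features: dict[str, float] = {}
    for b, band in enumerate(ao_np.band_names):
        for c, ch in enumerate(channel_names):
            features[f"np_{band}_{ch}"] = float(np_mean[c, b])
    for r, (b1, b2) in enumerate(ao_ratios.pairs):
        for c, ch in enumerate(channel_names):
            features[f"ratio_{b1}_{b2}_{ch}"] = float(ratio_mean[c, r])
    return features
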