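"""Wristband (Empatica E4 style) features.

The blood-volume-pulse signal is analyzed directly in the cardiovascular
frequency bands VLF (0-0.03 Hz), LF (0.04-0.15 Hz), HF (0.15-0.4 Hz) and
TP (0-0.4 Hz) on 30-s windows advanced one second at a time.  Each window is
mean-removed; the DC bin is excluded from every band.  At 30-s windows the
frequency resolution is 1/30 Hz, so no bin falls inside the printed VLF range
and the VLF power is identically zero (kept for structural fidelity).

The ten wristband features are the EO-normalized VLF/LF/HF/TP means, the
pre-normalization LF/HF and LFNU = LF / (TP - VLF) means, and the raw AO
means of IBI, HR, EDA and ST.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocessing import SegmentView

logger = logging.getLogger(__name__)

PPG_BANDS: dict[str, tuple[float, float]] = {
    "vlf": (0.0, 0.03),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.4),
    "tp": (0.0, 0.4),
}
PPG_BAND_NAMES = tuple(PPG_BANDS)

#: stable feature name order
E4_FEATURES = ("vlf", "lf", "hf", "tp", "lf_hf", "lfnu", "ibi", "hr", "eda", "st")

REQUIRED_STREAMS = ("BVP", "EDA", "TEMP", "HR", "IBI")

WINDOW_S = 30.0
STEP_S = 1.0


class MissingStreamError(KeyError):
    """A wristband stream required for the E4 features is absent."""


@dataclass(frozen=True)
class PPGSpectral:
    """Per-window PPG band powers, columns ordered as PPG_BAND_NAMES."""

    values: np.ndarray  # (n_windows, 4)
    band_names: tuple[str, ...] = PPG_BAND_NAMES

    def band(self, name: str) -> np.ndarray:
        return self.values[:, self.band_names.index(name)]


def _window_band_powers(x: np.ndarray, rate: float) -> np.ndarray:
    """Integrated band powers of one mean-removed window, DC bin excluded."""
    x = x - x.mean()
    freqs, psd = signal.periodogram(x, fs=rate, window="boxcar", detrend=False)
    df = freqs[1] - freqs[0]
    out = np.empty(len(PPG_BANDS))
    for j, (low, high) in enumerate(PPG_BANDS.values()):
        mask = (freqs >= low) & (freqs <= high) & (freqs > 0)
        out[j] = psd[mask].sum() * df
    return out


def ppg_spectra(
    bvp: np.ndarray,
    rate: float,
    window_s: float = WINDOW_S,
    step_s: float = STEP_S,
) -> PPGSpectral:
    """Sliding-window band powers of a BVP segment (30-s windows, 1-s step)."""
    bvp = np.asarray(bvp, float)
    n_win = int(round(window_s * rate))
    step = int(round(step_s * rate))
    if bvp.size < n_win:
        raise ValueError(
            f"segment of {bvp.size / rate:.1f} s shorter than the {window_s:.0f}-s window")
    starts = range(0, bvp.size - n_win + 1, step)
    values = np.stack([_window_band_powers(bvp[s:s + n_win], rate) for s in starts])
    return PPGSpectral(values=values)


def lfnu(spectra: PPGSpectral) -> np.ndarray:
    """Normalized-units LF per window: LF / (TP - VLF)."""
    denom = spectra.band("tp") - spectra.band("vlf")
    if np.any(denom <= 0):
        raise ValueError("non-positive TP - VLF denominator in LFNU")
    return spectra.band("lf") / denom


def lf_hf(spectra: PPGSpectral) -> np.ndarray:
    """LF/HF ratio per window, on powers prior to normalization."""
    hf = spectra.band("hf")
    if np.any(hf <= 0):
        raise ValueError("non-positive HF power in LF/HF ratio")
    return spectra.band("lf") / hf


def _normalized_band_means(ao: PPGSpectral, eo: PPGSpectral) -> dict[str, float]:
    eo_mean = eo.values.mean(axis=0)
    out = {}
    for j, name in enumerate(PPG_BAND_NAMES):
        ao_col = ao.values[:, j]
        if eo_mean[j] == 0:
            if np.allclose(ao_col, 0):
                out[name] = 0.0  # empty band (VLF at 30-s resolution)
                continue
            raise ValueError(f"zero EO mean power in PPG band {name}")
        out[name] = float(np.mean((ao_col - eo_mean[j]) / eo_mean[j]))
    return out


def e4_feature_vector(
    ao: SegmentView,
    eo: SegmentView,
    duration_s: float | None = None,
) -> dict[str, float]:
    """The ten wristband features averaged over the (truncated) AO task.

    Raises :class:`MissingStreamError` when any required stream is absent, so
    the caller can flag the subject incomplete.  For AO durations shorter
    than the 30-s spectral window the band powers fall back to a single
    window spanning the whole truncated interval (logged).
    """
    for name in REQUIRED_STREAMS:
        if name not in ao.wristband or name not in eo.wristband:
            raise MissingStreamError(name)
    bvp_rate = ao.wristband["BVP"].rate
    bvp_ao = ao.wristband["BVP"].values
    if duration_s is not None:
        bvp_ao = bvp_ao[: int(np.floor(duration_s * bvp_rate))]
    dur = bvp_ao.size / bvp_rate
    if dur < WINDOW_S:
        logger.warning(
            "AO interval of %.0f s shorter than the 30-s PPG window; "
            "using a single full-length window", dur)
        ao_spec = ppg_spectra(bvp_ao, bvp_rate, window_s=dur)
    else:
        ao_spec = ppg_spectra(bvp_ao, bvp_rate)
    eo_spec = ppg_spectra(eo.wristband["BVP"].values, bvp_rate,
                          window_s=min(WINDOW_S, eo.wristband["BVP"].values.size / bvp_rate))

    features = _normalized_band_means(ao_spec, eo_spec)
    features["lf_hf"] = float(np.mean(lf_hf(ao_spec)))
    features["lfnu"] = float(np.mean(lfnu(ao_spec)))
    for feat, stream in (("ibi", "IBI"), ("hr", "HR"), ("eda", "EDA"), ("st", "TEMP")):
        s = ao.wristband[stream]
        values = s.values
        if duration_s is not None:
            values = values[: int(np.floor(duration_s * s.rate))]
        if values.size == 0:
            raise ValueError(f"stream {stream} empty in the truncated AO interval")
        features[feat] = float(values.mean())
    return {name: features[name] for name in E4_FEATURES}
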