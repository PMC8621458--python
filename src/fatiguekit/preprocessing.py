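"""EEG preprocessing: filtering chain, artifact subspace reconstruction,
and segment views of the EC / EO / AO session blocks.

The filtering chain is a 60 Hz notch followed by a 0.1-100 Hz 4th-order
Butterworth bandpass, both applied forward-backward (zero phase).  Artifact
subspace reconstruction (ASR) removes, window by window, principal-subspace
components whose variance exceeds kappa times the standard deviation seen in a
clean calibration segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_formats import RecordingBundle, Stream, with_eeg

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Notch + bandpass filtering parameters (defaults match the acquisition
    chain: 60 Hz notch, 0.1-100 Hz 4th-order Butterworth, zero phase).

    ``order`` is the designed filter order before forward-backward
    application; the effective attenuation corresponds to twice that order.
    """

    notch_hz: float = 60.0
    notch_q: float = 30.0
    bandpass: tuple[float, float] = (0.1, 100.0)
    order: int = 4

    def validate(self, rate: float) -> None:
        low, high = self.bandpass
        nyq = rate / 2
        if not 0 < low < high < nyq:
            raise ValueError(
                f"bandpass edges {self.bandpass} invalid for Nyquist {nyq} Hz")
        if not 0 < self.notch_hz < nyq:
            raise ValueError(f"notch frequency {self.notch_hz} beyond Nyquist")


@dataclass(frozen=True)
class ASRConfig:
    """ASR parameters: threshold multiplier kappa (default 15), sliding-window
    length in seconds, and which baseline segment supplies the calibration."""

    kappa: float = 15.0
    window_s: float = 0.5
    calibration_segment: str = "EC"

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")


def filter_eeg(eeg: np.ndarray, rate: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase notch-then-bandpass filter along the samples axis."""
    spec.validate(rate)
    b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=rate)
    out = signal.filtfilt(b, a, np.asarray(eeg, float), axis=-1)
    sos = signal.butter(spec.order, spec.bandpass, btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, out, axis=-1)


def apply_filters(bundle: RecordingBundle, spec: FilterSpec = FilterSpec()) -> RecordingBundle:
    """Return a copy of *bundle* whose EEG went through the filtering chain."""
    return with_eeg(bundle, filter_eeg(bundle.eeg, bundle.rate, spec))


def asr_clean(
    eeg: np.ndarray,
    calib: np.ndarray,
    cfg: ASRConfig = ASRConfig(),
    rate: float = 250.0,
) -> np.ndarray:
    """Artifact subspace reconstruction with a fixed calibration segment.

    The calibration covariance is estimated once (Euclidean average, no
    adaptive clean-window search).  Each sliding window (50% overlap,
    overlap-add with a tapered weight) is diagonalized by its own principal
    components; a component whose window variance exceeds
    ``(kappa * calibration std in that direction)**2`` is projected out before
    reconstruction.  Windows with no offending component pass through
    numerically unchanged.
    """
    eeg = np.asarray(eeg, float)
    calib = np.asarray(calib, float)
    n_win = int(round(cfg.window_s * rate))
    if calib.shape[1] < n_win:
        raise ValueError("calibration segment shorter than the ASR window")
    if calib.shape[1] < 10 * rate:
        logger.warning("ASR calibration shorter than 10 s (%d samples)", calib.shape[1])

    calib_cov = (calib @ calib.T) / calib.shape[1]
    kappa_sq = cfg.kappa ** 2

    n = eeg.shape[1]
    if n < n_win:
        raise ValueError("signal shorter than the ASR window")
    hop = max(1, n_win // 2)
    starts = list(range(0, n - n_win + 1, hop))
    if starts[-1] + n_win < n:
        starts.append(n - n_win)
    # strictly positive taper so the overlap-add normalization is well defined
    taper = np.hanning(n_win) + 1e-3

    out = np.zeros_like(eeg)
    weight = np.zeros(n)
    for s in starts:
        win = eeg[:, s:s + n_win]
        win_cov = (win @ win.T) / n_win
        evals, vecs = np.linalg.eigh(win_cov)
        calib_var = np.einsum("ij,jk,ki->i", vecs.T, calib_cov, vecs)
        keep = evals <= kappa_sq * np.maximum(calib_var, 0.0)
        if not np.all(keep):
            proj = vecs[:, keep]
            win = proj @ (proj.T @ win)
        out[:, s:s + n_win] += win * taper
        weight[s:s + n_win] += taper
    return out / weight


def asr_clean_bundle(bundle: RecordingBundle, cfg: ASRConfig = ASRConfig()) -> RecordingBundle:
    """Apply ASR to a bundle's EEG, calibrating on the configured segment."""
    start, end = bundle.segments[cfg.calibration_segment]
    cleaned = asr_clean(bundle.eeg, bundle.eeg[:, start:end], cfg, rate=bundle.rate)
    return with_eeg(bundle, cleaned)


@dataclass(frozen=True)
class SegmentView:
    """A (possibly truncated) view of one session segment.

    EEG and each wristband stream are truncated independently at their own
    sampling rates: a duration T keeps exactly ``floor(T * rate)`` samples.
    """

    name: str
    eeg: np.ndarray
    rate: float
    start_sample: int  # absolute sample index of the segment start
    wristband: dict[str, Stream] = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.eeg.shape[1] / self.rate


def segment(
    bundle: RecordingBundle,
    name: str,
    max_duration_s: float | None = None,
) -> SegmentView:
    """Return the first ``max_duration_s`` seconds (or all) of a segment."""
    if name not in bundle.segments:
        raise KeyError(f"unknown segment {name!r}; expected one of {sorted(bundle.segments)}")
    start, end = bundle.segments[name]
    seg_len_s = (end - start) / bundle.rate
    if max_duration_s is None:
        max_duration_s = seg_len_s
    if max_duration_s > seg_len_s + 1e-9:
        raise ValueError(f"requested {max_duration_s} s exceeds segment length {seg_len_s} s")
    n_keep = int(np.floor(max_duration_s * bundle.rate))
    start_s = start / bundle.rate
    wristband = {}
    for sname, stream in bundle.wristband.items():
        w0 = int(np.floor(start_s * stream.rate))
        w_n = int(np.floor(max_duration_s * stream.rate))
        wristband[sname] = Stream(stream.rate, stream.values[w0:w0 + w_n])
    return SegmentView(
        name=name,
        eeg=bundle.eeg[:, start:start + n_keep],
        rate=bundle.rate,
        start_sample=start,
        wristband=wristband,
    )
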