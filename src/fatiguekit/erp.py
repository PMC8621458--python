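"""Event-related potential analysis of the auditory oddball task.

For every non-frequent stimulus, a 1000 ms epoch from 200 ms before onset to
800 ms after is cut from the (preprocessed) EEG, zero-phase bandpass filtered
0.1-10 Hz, averaged across epochs per channel, and baseline corrected by
subtracting the channel's mean eyes-open amplitude (a conventional
pre-stimulus-mean baseline is available as an option).  The P300 is then read
off the averaged wave as the maximum in the 200-500 ms post-stimulus window:
its height is the amplitude feature and its time the latency feature, giving
2 features x 8 channels = 16 ERP features per subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_formats import MarkerTable, NONFREQUENT

logger = logging.getLogger(__name__)

PRE_MS = 200.0
POST_MS = 800.0
P300_WINDOW_MS = (200.0, 500.0)
ERP_BAND = (0.1, 10.0)


@dataclass(frozen=True)
class ERPWave:
    """Averaged stimulus-locked response of one channel."""

    channel: str
    times_ms: np.ndarray  # -200 .. +796 ms in 4 ms steps (250 samples)
    amplitude_uv: np.ndarray
    n_epochs: int

    def __post_init__(self) -> None:
        if len(self.times_ms) != len(self.amplitude_uv):
            raise ValueError("times and amplitudes must have equal length")


@dataclass(frozen=True)
class GrandAverage:
    """Pointwise mean and standard error of ERPs across subjects."""

    channel: str
    times_ms: np.ndarray
    mean_uv: np.ndarray
    se_uv: np.ndarray
    n: int


def build_erp(
    eeg: np.ndarray,
    markers: MarkerTable,
    eo_eeg: np.ndarray,
    channel_names: tuple[str, ...],
    rate: float = 250.0,
    target_label: str = NONFREQUENT,
    baseline: str = "EO",
    max_onset_sample: int | None = None,
) -> list[ERPWave]:
    """Average stimulus-locked epochs into one ERP wave per channel.

    ``eeg`` is the full preprocessed recording so that pre-stimulus intervals
    of early stimuli (which reach back into the preceding segment) are
    available.  ``max_onset_sample`` restricts which onsets are used, which is
    how AO-duration truncation reaches the ERP features.
    """
    if baseline not in ("EO", "prestim"):
        raise ValueError("baseline must be 'EO' or 'prestim'")
    onsets = markers.where(target_label)
    if max_onset_sample is not None:
        onsets = onsets[onsets < max_onset_sample]
    pre = int(round(PRE_MS / 1000 * rate))
    post = int(round(POST_MS / 1000 * rate))
    n = eeg.shape[1]
    usable = [o for o in onsets if o - pre >= 0 and o + post <= n]
    dropped = len(onsets) - len(usable)
    if dropped:
        logger.info("dropped %d epochs exceeding recording bounds", dropped)
    if not usable:
        raise ValueError(f"no usable {target_label!r} epochs")

    # the 0.1-10 Hz zero-phase bandpass is applied to the continuous record
    # and epochs are cut afterwards: a 0.1 Hz highpass is ill-conditioned on
    # 1-s windows (its time constant exceeds the window), and for a
    # zero-phase LTI filter the two orders differ only by edge artifacts
    sos = signal.butter(4, ERP_BAND, btype="bandpass", fs=rate, output="sos")
    filtered = signal.sosfiltfilt(sos, eeg, axis=-1)
    epochs = np.stack([filtered[:, o - pre:o + post] for o in usable])  # (n_ep, ch, t)
    mean = epochs.mean(axis=0)  # (ch, t)
    if baseline == "EO":
        mean = mean - eo_eeg.mean(axis=1, keepdims=True)
    else:
        mean = mean - mean[:, :pre].mean(axis=1, keepdims=True)

    times_ms = (np.arange(-pre, post) / rate) * 1000.0
    return [
        ERPWave(channel=ch, times_ms=times_ms, amplitude_uv=mean[c], n_epochs=len(usable))
        for c, ch in enumerate(channel_names)
    ]


def detect_p300(erp: ERPWave) -> tuple[float, float]:
    """Amplitude (uV) and latency (ms) of the windowed 200-500 ms maximum.

    Ties are broken toward the earliest time; the window maximum is returned
    even when it is non-positive (a warning is logged in that case).
    """
    lo, hi = P300_WINDOW_MS
    mask = (erp.times_ms >= lo) & (erp.times_ms <= hi)
    if not mask.any():
        raise ValueError("ERP does not cover the 200-500 ms window")
    window = erp.amplitude_uv[mask]
    if np.all(np.isnan(window)):
        raise ValueError("all-NaN ERP window")
    i = int(np.nanargmax(window))
    amplitude = float(window[i])
    latency = float(erp.times_ms[mask][i])
    if amplitude <= 0:
        logger.warning("channel %s: no positive peak in the P300 window", erp.channel)
    return amplitude, latency


def p300_features(erps: list[ERPWave]) -> dict[str, float]:
    """The 16 ERP features: ``p300_amp_<ch>`` and ``p300_lat_<ch>``."""
    features: dict[str, float] = {}
    for erp in erps:
        amp, lat = detect_p300(erp)
        features[f"p300_amp_{erp.channel}"] = amp
        features[f"p300_lat_{erp.channel}"] = lat
    return features


def grand_average(erps: list[ERPWave]) -> GrandAverage:
    """Pointwise mean and standard error across subjects' ERP waves."""
    if not erps:
        raise ValueError("need at least one ERP")
    first = erps[0]
    for erp in erps[1:]:
        if erp.channel != first.channel or not np.array_equal(erp.times_ms, first.times_ms):
            raise ValueError("ERPs must share channel and time axis")
    stack = np.stack([erp.amplitude_uv for erp in erps])
    n = len(erps)
    se = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(stack.shape[1])
    return GrandAverage(
        channel=first.channel,
        times_ms=first.times_ms,
        mean_uv=stack.mean(axis=0),
        se_uv=se,
        n=n,
    )
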