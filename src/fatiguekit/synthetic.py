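"""Synthetic cohorts of five-minute multi-modal fatigue-test sessions.

Every downstream stage of the pipeline is testable without real recordings:
this module generates per-subject bundles with known ground truth — planted
band amplitudes, P300 latency/amplitude, wristband oscillation content and
FAS totals with a controlled linear dependence on chosen features.

EEG background model
--------------------
Each frequency band is a *block-randomized random-phase multisine*: equal
amplitude tones on the 1 Hz FFT-bin grid inside the band, with phases redrawn
independently every 1-s block.  Because the 1-s spectral analysis windows are
aligned to the same block grid, every window's band power is exactly the
planted value (no estimation noise), so band amplitudes can be inverted
analytically from target power ratios; because phases change from block to
block, stimulus-locked ERP averaging still suppresses the background as
1/sqrt(n_epochs).  A classical bandpass-filtered white-noise background is
available via ``SubjectProfile.background = "filtered_noise"``.

P300 responses are positive Gaussian deflections (sigma 40 ms) added on every
channel, peaking a fixed latency after each non-frequent stimulus onset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .extract import FULL_AO_S, extract_subject_features
from .io_formats import (CHANNELS, EEG_RATE, FREQUENT, NONFREQUENT, SEGMENTS,
                         MarkerTable, RecordingBundle, Stream,
                         WRISTBAND_RATES)
from .preprocessing import ASRConfig, FilterSpec
from .spectral import BAND_NAMES, BANDS

SESSION_S = 300.0
P300_SIGMA_MS = 40.0
DEFAULT_BAND_AMP_UV = 4.0

_TARGET_RE = re.compile(
    r"^(ratio_(?P<b1>[a-z]+)_(?P<b2>[a-z]+)|np_(?P<b>[a-z]+))_(?P<ch>\w+)$")


def default_band_amplitudes() -> dict[str, np.ndarray]:
    """Flat 4 uV RMS per band and channel; free parameters of the generator
    (inter-subject variability of baseline band powers is not constrained by
    any study value)."""
    return {band: np.full(len(CHANNELS), DEFAULT_BAND_AMP_UV) for band in BAND_NAMES}


@dataclass
class SubjectProfile:
    """Ground-truth parameters of one synthetic subject."""

    subject_id: str = "S00"
    fas_total: float = 25.0
    band_amplitude: dict[str, np.ndarray] = field(default_factory=default_band_amplitudes)
    #: multiplicative amplitude gain applied to the AO segment only,
    #: per band -> (n_channels,); used to plant normalized-power targets
    ao_band_gain: dict[str, np.ndarray] = field(default_factory=dict)
    p300_latency_ms: float = 312.0
    p300_amplitude_uv: float = 6.0
    hrv_lf_hz: float = 0.1
    hrv_hf_hz: float = 0.25
    hrv_lf_amp: float = 1.0
    hrv_hf_amp: float = 0.8
    ppg_noise_sd: float = 0.1
    eda_level_us: float = 2.0
    st_level_c: float = 33.0
    hr_bpm: float = 70.0
    missing_streams: frozenset = frozenset()
    background: str = "multisine"  # or "filtered_noise"

    def __post_init__(self) -> None:
        if not 10.0 <= self.fas_total <= 50.0:
            raise ValueError("fas_total must lie in [10, 50]")
        if not 0.0 < self.p300_latency_ms < 800.0:
            raise ValueError("p300 latency must lie in (0, 800) ms")
        if self.p300_amplitude_uv < 0:
            raise ValueError("p300 amplitude must be non-negative")
        if not 0.04 < self.hrv_lf_hz < 0.15:
            raise ValueError("hrv_lf_hz must lie in (0.04, 0.15)")
        if not 0.15 < self.hrv_hf_hz < 0.4:
            raise ValueError("hrv_hf_hz must lie in (0.15, 0.4)")
        for band, amp in self.band_amplitude.items():
            amp = np.broadcast_to(np.asarray(amp, float), (len(CHANNELS),)).copy()
            if np.any(amp < 0):
                raise ValueError(f"negative amplitude for band {band}")
            self.band_amplitude[band] = amp
        for band, gain in self.ao_band_gain.items():
            self.ao_band_gain[band] = np.broadcast_to(
                np.asarray(gain, float), (len(CHANNELS),)).copy()
        if self.background not in ("multisine", "filtered_noise"):
            raise ValueError("background must be 'multisine' or 'filtered_noise'")


@dataclass(frozen=True)
class EffectSpec:
    """Planted linear FAS-feature dependence for a cohort.

    ``fas = intercept + sum_j slopes[j] * feature_j + N(0, noise_sd)``, with
    the intercept chosen so that a mid-scale FAS of 30 corresponds to the
    baseline feature values.  ``class_mix`` gives the intended number (or
    weight) of subjects per fatigue class, defaulting to the 3 / 8 / 6
    no-fatigue / substantial / extreme composition of a 17-subject cohort.
    """

    target_features: tuple[str, ...] = (
        "ratio_beta_theta_C3", "ratio_alpha_theta_O2", "ratio_alpha_theta_C3")
    slopes: tuple[float, ...] = (-10.0, -10.0, -10.0)
    noise_sd: float = 2.0
    class_mix: tuple[int, int, int] = (3, 8, 6)  # no fatigue, substantial, extreme

    def __post_init__(self) -> None:
        if len(self.slopes) != len(self.target_features):
            raise ValueError("slopes and target_features must have equal length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(s == 0 for s in self.slopes):
            raise ValueError("slopes must be non-zero")


@dataclass
class SyntheticCohort:
    """Bundles plus ground truth; regenerating with the same seed reproduces
    identical signals bit for bit."""

    bundles: list[RecordingBundle]
    profiles: list[SubjectProfile]
    effect: EffectSpec
    seed: int
    intercept: float
    #: per subject: intended and pipeline-measured target feature values
    target_truth: dict[str, dict[str, dict[str, float]]]
    #: full 226-feature vectors measured at the full AO duration
    measured_features: dict[str, dict[str, float] | None]

    @property
    def fas_by_subject(self) -> dict[str, float]:
        return {b.subject_id: float(b.fas_total) for b in self.bundles}


# ---------------------------------------------------------------------------
# stimulus schedule
# ---------------------------------------------------------------------------

def generate_stimulus_schedule(
    n_total: int = 120,
    frac_nonfrequent: float = 0.2,
    stim_dur_s: float = 1.0,
    isi_s: float = 1.0,
    seed: int = 0,
    ao_start_sample: int = SEGMENTS["AO"][0],
    rate: float = EEG_RATE,
) -> MarkerTable:
    """Oddball schedule: ``n_total`` stimuli, a seeded random permutation of
    frequent / non-frequent labels, onsets ``stim_dur_s + isi_s`` apart from
    the AO segment start (defaults: 120 stimuli, 80:20, 2 s spacing)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 < frac_nonfrequent < 1:
        raise ValueError("frac_nonfrequent must lie in (0, 1)")
    target = n_total * frac_nonfrequent
    n_nf = int(round(target))
    if abs(target - n_nf) > 1e-9:
        raise ValueError(
            f"n_total * frac_nonfrequent = {target} is not an integer count")
    labels = np.array([NONFREQUENT] * n_nf + [FREQUENT] * (n_total - n_nf))
    rng = np.random.default_rng(seed)
    labels = labels[rng.permutation(n_total)]
    period = int(round((stim_dur_s + isi_s) * rate))
    onsets = ao_start_sample + np.arange(n_total, dtype=np.int64) * period
    return MarkerTable(onsets=onsets, labels=tuple(labels))


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _band_tones() -> dict[str, np.ndarray]:
    """Integer tone frequencies per band.  Bands sharing a printed edge (the
    4 Hz delta/theta boundary) would otherwise both place a tone on the same
    FFT bin, whose phase-dependent interference makes window powers
    stochastic; each frequency therefore belongs to exactly one band, the
    edge bin going to the higher band."""
    used: set[int] = set()
    tones: dict[str, np.ndarray] = {}
    for name in reversed(BAND_NAMES):
        low, high = BANDS[name]
        freqs = [f for f in range(int(np.ceil(low)), int(np.floor(high)) + 1)
                 if f not in used]
        used.update(freqs)
        tones[name] = np.array(freqs, dtype=float)
    return tones


BAND_TONES = _band_tones()


def _multisine_band(
    rng: np.random.Generator, freqs: np.ndarray, amp: np.ndarray,
    n_blocks: int, rate: float,
) -> np.ndarray:
    """Block-randomized multisine: (n_channels, n_blocks * rate) samples."""
    k = len(freqs)
    n_per_block = int(round(rate))
    t = np.arange(n_per_block) / rate
    sin_t = np.sin(2 * np.pi * freqs[:, None] * t)  # (k, n_per_block)
    cos_t = np.cos(2 * np.pi * freqs[:, None] * t)
    phases = rng.uniform(0, 2 * np.pi, size=(n_blocks, len(amp), k))
    tone_amp = np.sqrt(2.0 / k)  # unit band RMS before per-channel scaling
    blocks = tone_amp * (
        np.einsum("bck,kt->bct", np.cos(phases), sin_t)
        + np.einsum("bck,kt->bct", np.sin(phases), cos_t)
    )
    out = blocks.transpose(1, 0, 2).reshape(len(amp), n_blocks * n_per_block)
    return out * amp[:, None]


def _filtered_noise_band(
    rng: np.random.Generator, band: tuple[float, float], amp: np.ndarray,
    n_samples: int, rate: float,
) -> np.ndarray:
    from scipy import signal as _signal

    sos = _signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    noise = rng.standard_normal((len(amp), n_samples))
    x = _signal.sosfiltfilt(sos, noise, axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x / rms * amp[:, None]


def synthesize_recording(
    profile: SubjectProfile,
    schedule: MarkerTable,
    seed: int = 0,
) -> RecordingBundle:
    """Synthesize one 300-s session bundle from a subject profile.

    EEG is the sum of the five band components plus a positive Gaussian P300
    deflection on every channel after each non-frequent stimulus; the
    wristband BVP is two sinusoids at the profile's LF/HF frequencies plus
    white noise, and EDA/TEMP/HR/IBI are constant levels with small drift and
    noise at their native rates.
    """
    rng = np.random.default_rng(seed)
    rate = EEG_RATE
    n = int(SESSION_S * rate)
    n_blocks = int(SESSION_S)
    ao_start, ao_end = SEGMENTS["AO"]

    eeg = np.zeros((len(CHANNELS), n))
    for band_name in BAND_NAMES:
        amp = profile.band_amplitude[band_name]
        if profile.background == "multisine":
            comp = _multisine_band(rng, BAND_TONES[band_name], amp, n_blocks, rate)
        else:
            comp = _filtered_noise_band(rng, BANDS[band_name], amp, n, rate)
        gain = profile.ao_band_gain.get(band_name)
        if gain is not None:
            comp[:, ao_start:ao_end] *= gain[:, None]
        eeg += comp

    if profile.p300_amplitude_uv > 0:
        lat_samples = profile.p300_latency_ms / 1000 * rate
        if profile.p300_latency_ms >= 800.0:
            raise ValueError("p300 latency beyond the 800 ms epoch window")
        sigma = P300_SIGMA_MS / 1000 * rate
        half = int(np.ceil(4 * sigma))
        k = np.arange(-half, half + 1)
        bump = profile.p300_amplitude_uv * np.exp(-0.5 * (k / sigma) ** 2)
        for onset in schedule.where(NONFREQUENT):
            center = int(round(onset + lat_samples))
            lo, hi = center - half, center + half + 1
            blo, bhi = max(lo, 0), min(hi, n)
            eeg[:, blo:bhi] += bump[blo - lo:bhi - lo]

    wristband: dict[str, Stream] = {}
    tb = np.arange(int(SESSION_S * WRISTBAND_RATES["BVP"])) / WRISTBAND_RATES["BVP"]
    bvp = (
        profile.hrv_lf_amp * np.sin(2 * np.pi * profile.hrv_lf_hz * tb
                                    + rng.uniform(0, 2 * np.pi))
        + profile.hrv_hf_amp * np.sin(2 * np.pi * profile.hrv_hf_hz * tb
                                      + rng.uniform(0, 2 * np.pi))
        + profile.ppg_noise_sd * rng.standard_normal(tb.size)
    )
    wristband["BVP"] = Stream(WRISTBAND_RATES["BVP"], bvp)
    n4 = int(SESSION_S * 4)
    wristband["EDA"] = Stream(4.0, profile.eda_level_us
                              + 0.05 * np.linspace(0, 1, n4)
                              + 0.01 * rng.standard_normal(n4))
    wristband["TEMP"] = Stream(4.0, profile.st_level_c
                               - 0.1 * np.linspace(0, 1, n4)
                               + 0.02 * rng.standard_normal(n4))
    n1 = int(SESSION_S)
    wristband["HR"] = Stream(1.0, profile.hr_bpm + 0.5 * rng.standard_normal(n1))
    wristband["IBI"] = Stream(1.0, 60.0 / profile.hr_bpm
                              + 0.01 * rng.standard_normal(n1))
    for name in profile.missing_streams:
        wristband.pop(name, None)

    return RecordingBundle(
        eeg=eeg,
        markers=schedule,
        wristband=wristband,
        fas_total=profile.fas_total,
        subject_id=profile.subject_id,
    )


# ---------------------------------------------------------------------------
# cohort generation with planted feature-FAS dependence
# ---------------------------------------------------------------------------

#: per-class FAS distributions (mean, sd, clip-low, clip-high), matching the
#: reported class compositions: no fatigue 19 +/- 2, substantial 27 +/- 3,
#: extreme 37 +/- 3
_CLASS_DISTS = {
    "no_fatigue": (19.0, 2.0, 12.0, 21.0),
    "substantial": (27.0, 3.0, 22.0, 35.0),
    "extreme": (37.0, 3.0, 36.0, 48.0),
}


def _validate_targets(names: tuple[str, ...]) -> list[dict]:
    parsed = []
    for name in names:
        match = _TARGET_RE.match(name)
        ok = False
        if match and match.group("ch") in CHANNELS:
            if match.group("b1"):
                ok = (match.group("b1") in BAND_NAMES and match.group("b2") in BAND_NAMES
                      and match.group("b1") != match.group("b2"))
            else:
                ok = match.group("b") in BAND_NAMES
        if not ok:
            raise ValueError(
                f"unknown or un-plantable target feature {name!r}; valid targets are "
                f"'ratio_<b1>_<b2>_<ch>' and 'np_<band>_<ch>' with bands "
                f"{BAND_NAMES} and channels {CHANNELS}")
        parsed.append({
            "name": name,
            "kind": "ratio" if match.group("b1") else "np",
            "b1": match.group("b1") or match.group("b"),
            "b2": match.group("b2"),
            "ch": CHANNELS.index(match.group("ch")),
        })
    return parsed


def _class_assignment(n: int, mix: tuple[int, int, int]) -> list[str]:
    classes = list(_CLASS_DISTS)
    total = sum(mix)
    if total == n:
        counts = list(mix)
    else:  # largest-remainder proportional scaling
        raw = [n * w / total for w in mix]
        counts = [int(np.floor(x)) for x in raw]
        rem = n - sum(counts)
        for i in sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)[:rem]:
            counts[i] += 1
    out: list[str] = []
    for cls, c in zip(classes, counts):
        out.extend([cls] * c)
    return out


def _solve_band_amplitudes(
    base: dict[str, np.ndarray],
    ratio_constraints: dict[int, list[tuple[str, str, float]]],
) -> dict[str, np.ndarray]:
    """Per-channel log-amplitude least squares: honor all pairwise power-ratio
    constraints exactly (when consistent) while staying close to the baseline
    amplitudes.  Power scales as amplitude squared, so a target ratio v means
    ``log a_b1 - log a_b2 = log(v) / 2``."""
    amps = {band: base[band].copy() for band in BAND_NAMES}
    for ch, constraints in ratio_constraints.items():
        x0 = np.log([amps[band][ch] for band in BAND_NAMES])
        rows, rhs = [], []
        for b1, b2, v in constraints:
            row = np.zeros(len(BAND_NAMES))
            row[BAND_NAMES.index(b1)] = 1.0
            row[BAND_NAMES.index(b2)] = -1.0
            rows.append(row)
            rhs.append(0.5 * np.log(v))
        lam = 1e-6
        A = np.vstack(rows + [np.sqrt(lam) * np.eye(len(BAND_NAMES))])
        b = np.concatenate([rhs, np.sqrt(lam) * x0])
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        for j, band in enumerate(BAND_NAMES):
            amps[band][ch] = np.exp(x[j])
    return amps


def generate_cohort(
    n_subjects: int = 14,
    effect: EffectSpec | None = None,
    seed: int = 0,
    filter_spec: FilterSpec = FilterSpec(),
    asr_config: ASRConfig = ASRConfig(),
) -> SyntheticCohort:
    """Generate a cohort whose named target features relate linearly to the
    FAS totals with the requested slopes plus Gaussian noise.

    Band amplitudes (and AO gains for normalized-power targets) are inverted
    analytically from per-subject intended feature values; the FAS total is
    then set from the feature values the default extraction pipeline actually
    measures on the synthesized recording (full AO duration), so the planted
    linear law holds exactly for the downstream pipeline when
    ``effect.noise_sd == 0``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    effect = effect if effect is not None else EffectSpec()
    targets = _validate_targets(effect.target_features)
    n_t = len(targets)
    rng = np.random.default_rng(seed)

    # intended FAS totals drawn per fatigue class
    classes = _class_assignment(n_subjects, effect.class_mix)
    rng.shuffle(classes)
    intended_fas = np.empty(n_subjects)
    for i, c in enumerate(classes):
        mean, sd, lo, hi = _CLASS_DISTS[c]
        intended_fas[i] = np.clip(rng.normal(mean, sd), lo, hi)

    # baseline feature values and intercept of the planted linear law
    f0 = np.array([1.5 if t["kind"] == "ratio" else 0.5 for t in targets])
    mid = 30.0
    intercept = mid - float(np.dot(effect.slopes, f0))

    subject_seeds = rng.integers(0, 2 ** 31 - 1, size=n_subjects)
    noise = rng.normal(0.0, effect.noise_sd, size=n_subjects) if effect.noise_sd > 0 \
        else np.zeros(n_subjects)

    bundles: list[RecordingBundle] = []
    profiles: list[SubjectProfile] = []
    target_truth: dict[str, dict] = {}
    measured_features: dict[str, dict | None] = {}

    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        srng = np.random.default_rng(subject_seeds[i])
        intended = f0 + (intended_fas[i] - mid) / (n_t * np.asarray(effect.slopes))
        if any(t["kind"] == "ratio" and v <= 1e-2 for t, v in zip(targets, intended)):
            raise ValueError(
                "planted slopes drive a power ratio non-positive; use smaller "
                "|slope| or a baseline further from zero")

        # mild per-subject heterogeneity of baseline amplitudes (free bands)
        base = {band: DEFAULT_BAND_AMP_UV
                * srng.uniform(0.85, 1.2, size=len(CHANNELS))
                for band in BAND_NAMES}
        # every (band, channel) gets a per-subject task-engagement gain on the
        # AO segment so normalized-power features carry genuine inter-subject
        # variance; bands tied together by a ratio target on a channel share
        # one gain there, which cancels in the planted ratio
        ao_gain = {band: srng.uniform(0.9, 1.15, size=len(CHANNELS))
                   for band in BAND_NAMES}
        ratio_constraints: dict[int, list] = {}
        for t, v in zip(targets, intended):
            if t["kind"] == "ratio":
                ratio_constraints.setdefault(t["ch"], []).append((t["b1"], t["b2"], v))
        for ch, constraints in ratio_constraints.items():
            tied = {b for b1, b2, _ in constraints for b in (b1, b2)}
            common = srng.uniform(0.9, 1.15)
            for band in tied:
                ao_gain[band][ch] = common
        for t, v in zip(targets, intended):
            if t["kind"] == "np":
                if v <= -1:
                    raise ValueError("normalized-power target below -1 is unattainable")
                ao_gain[t["b1"]][t["ch"]] = np.sqrt(1.0 + v)
        band_amplitude = _solve_band_amplitudes(base, ratio_constraints)

        lat_choices = np.arange(296.0, 341.0, 4.0)  # on the 4 ms sample grid
        profile = SubjectProfile(
            subject_id=sid,
            fas_total=float(np.clip(intended_fas[i], 10.0, 50.0)),
            band_amplitude=band_amplitude,
            ao_band_gain=ao_gain,
            p300_latency_ms=float(srng.choice(lat_choices)),
            p300_amplitude_uv=float(srng.uniform(4.0, 8.0)),
            hrv_lf_amp=float(srng.uniform(0.8, 1.2)),
            hrv_hf_amp=float(srng.uniform(0.6, 1.0)),
            hr_bpm=float(srng.uniform(60.0, 85.0)),
        )
        schedule = generate_stimulus_schedule(seed=int(subject_seeds[i]) % (2 ** 31))
        bundle = synthesize_recording(profile, schedule, seed=int(subject_seeds[i]))

        features = extract_subject_features(
            bundle, durations=(FULL_AO_S,),
            filter_spec=filter_spec, asr_config=asr_config)
        measured_features[sid] = features[FULL_AO_S] if features else None
        if features is not None:
            measured = np.array([features[FULL_AO_S][t["name"]] for t in targets])
        else:  # incomplete subject: fall back to the intended values
            measured = intended
        fas = float(intercept + np.dot(effect.slopes, measured) + noise[i])
        profile.fas_total = fas
        bundle.fas_total = fas
        target_truth[sid] = {
            t["name"]: {"intended": float(vi), "measured": float(vm)}
            for t, vi, vm in zip(targets, intended, measured)
        }
        bundles.append(bundle)
        profiles.append(profile)

    return SyntheticCohort(
        bundles=bundles, profiles=profiles, effect=effect, seed=seed,
        intercept=intercept, target_truth=target_truth,
        measured_features=measured_features,
    )
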