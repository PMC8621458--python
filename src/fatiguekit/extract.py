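"""Per-subject feature extraction: preprocessed recording -> 226 named
features (16 P300 + 40 normalized band powers + 160 band-power ratios + 10
wristband), optionally at several AO-task durations.
"""

from __future__ import annotations

import logging

from .erp import build_erp, p300_features
from .io_formats import CHANNELS, RecordingBundle
from .preprocessing import ASRConfig, FilterSpec, apply_filters, asr_clean_bundle, segment
from .spectral import BAND_NAMES, RATIO_PAIRS, band_power_series, normalize_power, \
    power_ratios, spectral_feature_vector
from .wristband import E4_FEATURES, MissingStreamError, e4_feature_vector

logger = logging.getLogger(__name__)

FULL_AO_S = 240.0


def all_feature_names(channels: tuple[str, ...] = CHANNELS) -> list[str]:
    """The stable 226-name feature vocabulary, in canonical order."""
    names = [f"p300_{kind}_{ch}" for ch in channels for kind in ("amp", "lat")]
    names += [f"np_{band}_{ch}" for band in BAND_NAMES for ch in channels]
    names += [f"ratio_{b1}_{b2}_{ch}" for (b1, b2) in RATIO_PAIRS for ch in channels]
    names += list(E4_FEATURES)
    return names


def extract_subject_features(
    bundle: RecordingBundle,
    durations: tuple[float, ...] = (FULL_AO_S,),
    filter_spec: FilterSpec = FilterSpec(),
    asr_config: ASRConfig = ASRConfig(),
    erp_baseline: str = "EO",
) -> dict[float, dict[str, float]] | None:
    """Extract the full feature vector at each requested AO duration.

    Returns ``None`` when a required wristband stream is missing (the subject
    is incomplete and must be excluded from the feature matrix).  ERP features
    use the non-frequent stimuli whose onset falls inside the truncated AO
    interval; if none does (possible at the shortest durations), the full AO
    stimuli are used instead (logged).
    """
    cleaned = asr_clean_bundle(apply_filters(bundle, filter_spec), asr_config)
    eo = segment(cleaned, "EO")
    eo_bps = band_power_series(eo, channel_names=cleaned.channel_names)
    ao_start, _ = cleaned.segments["AO"]

    out: dict[float, dict[str, float]] = {}
    for dur in durations:
        ao = segment(cleaned, "AO", dur)
        try:
            max_onset = ao_start + int(dur * cleaned.rate)
            try:
                erps = build_erp(cleaned.eeg, cleaned.markers, eo.eeg,
                                 cleaned.channel_names, rate=cleaned.rate,
                                 baseline=erp_baseline, max_onset_sample=max_onset)
            except ValueError:
                logger.info("subject %s: no target epochs within %.0f s; "
                            "using the full AO task for ERP features",
                            bundle.subject_id, dur)
                erps = build_erp(cleaned.eeg, cleaned.markers, eo.eeg,
                                 cleaned.channel_names, rate=cleaned.rate,
                                 baseline=erp_baseline)
            features = p300_features(erps)

            ao_bps = band_power_series(ao, channel_names=cleaned.channel_names)
            npw = normalize_power(ao_bps, eo_bps)
            ratios = power_ratios(ao_bps)
            features.update(
                spectral_feature_vector(npw, ratios, cleaned.channel_names, dur))
            features.update(e4_feature_vector(ao, eo))  # views already truncated
        except MissingStreamError as err:
            logger.warning("subject %s incomplete: missing stream %s",
                           bundle.subject_id, err)
            return None
        out[dur] = {name: features[name] for name in all_feature_names(cleaned.channel_names)}
    return out
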