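"""End-to-end per-subject feature extraction.

Chains the preprocessing and feature-engineering stages — day alignment,
missing-day exclusion, sleep detection with the validity rule, circadian
metrics, nocturnal peak taxonomy and wavelet structure factors — into a
subjects x features table ready for either selection framework.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import circadian, peaks, wavelet
from .ingest import EpochSeries, drop_missing_days
from .sleep import SleepParams, detect_sleep, filter_valid_sleep, night_slices, sleep_time
from .table import FeatureTable

log = logging.getLogger(__name__)

__all__ = ["FeatureConfig", "extract_features", "build_feature_table"]

CIRCADIAN_NAMES = [
    "M10", "L5", "RA", "ADAT", "IS", "IV",
    "activity_mean", "activity_std", "zero_ratio", "FI_m", "FI_std", "slp_tm",
]


@dataclass(frozen=True)
class FeatureConfig:
    sleep: SleepParams = field(default_factory=SleepParams)
    short_immobile_max: int = 2
    close_gap_max: int = 2
    amplitude_mode: str = "max"
    corr_threshold: float = 0.7
    scale_window: tuple[float, float] = (1.0, 200.0)
    n_scales: int = 64
    normalization: str = "global"
    per_scale: bool = False
    is_hourly: bool = False


def extract_features(series: EpochSeries, config: FeatureConfig = FeatureConfig()) -> dict[str, float]:
    """All features for one subject; undefined values come back NaN."""
    series = series.trim_partial_days()
    series = drop_missing_days(series)

    feats: dict[str, float] = {}
    m10, l5, ra, adat = circadian.m10_l5_ra_adat(series)
    feats.update(M10=m10, L5=l5, RA=ra, ADAT=adat)
    feats["IS"] = (
        circadian.interdaily_stability(series, hourly=config.is_hourly)
        if series.n_days >= 2
        else float("nan")
    )
    feats["IV"] = circadian.intradaily_variability(series)
    mean, std, zr = circadian.global_stats(series)
    feats.update(activity_mean=mean, activity_std=std, zero_ratio=zr)

    intervals = filter_valid_sleep(detect_sleep(series, config.sleep), config.sleep)
    feats["slp_tm"] = sleep_time(intervals, series.epoch_len_s)
    nights = night_slices(series, intervals)
    if nights:
        fis = [circadian.fragmentation_index(n, config.short_immobile_max) for n in nights]
        feats["FI_m"] = float(np.mean(fis))
        feats["FI_std"] = float(np.std(fis))
        feats.update(
            peaks.subject_peak_features(
                nights, close_gap_max=config.close_gap_max,
                amplitude_mode=config.amplitude_mode,
            )
        )
        concat_len = sum(len(n) for n in nights)
        if concat_len > config.scale_window[1]:
            feats.update(
                wavelet.wavelet_features(
                    nights,
                    scales=wavelet.default_scales(*config.scale_window, config.n_scales),
                    corr_threshold=config.corr_threshold,
                    normalization=config.normalization,
                    scale_window=config.scale_window,
                    per_scale=config.per_scale,
                )
            )
        else:
            log.warning("%s: concatenated sleep too short for wavelet analysis",
                        series.subject_id)
    else:
        log.warning("%s: no valid sleep interval", series.subject_id)
        feats["FI_m"] = feats["FI_std"] = float("nan")
        for name in peaks.peak_feature_names():
            feats[name] = float("nan")
    for name in ("structure_pms", "wavelet_fi"):
        feats.setdefault(name, float("nan"))
    return feats


def build_feature_table(
    subjects: list[EpochSeries],
    labels: pd.Series,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureTable:
    """Extract features for every subject and assemble the table.

    Column order is deterministic: circadian block first, then the
    remaining features sorted by name.
    """
    rows = {s.subject_id: extract_features(s, config) for s in subjects}
    X = pd.DataFrame.from_dict(rows, orient="index")
    ordered = CIRCADIAN_NAMES + sorted(c for c in X.columns if c not in CIRCADIAN_NAMES)
    X = X[ordered]
    return FeatureTable(X, labels.loc[X.index])
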