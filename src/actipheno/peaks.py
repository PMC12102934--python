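"""Nocturnal movement "peak" features.

A peak is a maximal run of non-zero counts inside a sleep bout; zeros
separate peaks. Peaks are classified as small/large by amplitude, either
against the night's median (every peak lands in one class) or against the
quartiles (small <= Q1, large >= Q3, middle peaks unclassified). For each
category (p = all, sp/lp = median split, sp_q/lp_q = quartile split) the
per-night amplitude (_a), length (_l) and inter-peak gap (_d) vectors are
summarised with avg/std/max/min/med, the per-night peak count (_nbr) and
close-pair count (_cls, gap <= close_gap_max) are recorded, and everything
is averaged across the subject's valid nights. The first/last peak of the
night contributes its amplitude (_a) and start offset (_t).

Feature names follow the grammar ``<category>_<metric>_<func>``
(``p_a_max``, ``sp_l_avg``, ``lp_q_d_med``, ``sp_cls_nbr`` ...) and the
emitted name set is fixed given the configuration, so downstream tables
are column-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sleep import NightActivity

__all__ = [
    "Peak",
    "extract_peaks",
    "split_peaks",
    "peak_metrics",
    "night_peak_features",
    "aggregate_subject",
    "subject_peak_features",
    "peak_feature_names",
]

CATEGORIES = ("p", "sp", "lp", "sp_q", "lp_q")
VECTOR_METRICS = ("a", "l", "d")
FUNCS = ("avg", "std", "max", "min", "med")

_FUNC_IMPL = {
    "avg": np.mean,
    "std": lambda v: np.std(v),  # population SD
    "max": np.max,
    "min": np.min,
    "med": np.median,
}


@dataclass(frozen=True)
class Peak:
    start: int
    length: int
    amplitude: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def end(self) -> int:
        """One past the last epoch of the run."""
        return self.start + self.length


def extract_peaks(night: NightActivity, *, amplitude_mode: str = "max") -> list[Peak]:
    """Maximal runs of counts > 0, in order of start."""
    if amplitude_mode not in ("max", "mean"):
        raise ValueError(f"unknown amplitude_mode {amplitude_mode!r}")
    x = night.counts
    peaks = []
    n = len(x)
    i = 0
    while i < n:
        if x[i] > 0:
            j = i
            while j < n and x[j] > 0:
                j += 1
            run = x[i:j]
            amp = float(run.max() if amplitude_mode == "max" else run.mean())
            peaks.append(Peak(start=i, length=j - i, amplitude=amp))
            i = j
        else:
            i += 1
    return peaks


def split_peaks(peaks: list[Peak], mode: str = "median") -> tuple[list[Peak], list[Peak]]:
    """Small/large split by amplitude.

    median mode: small = amplitude <= median, large = the rest (ties go
    to small). quartile mode: small = amplitude <= Q1, large = amplitude
    >= Q3 (linear-interpolation quantiles), middle peaks in neither.
    """
    if mode not in ("median", "quartile"):
        raise ValueError(f"unknown split mode {mode!r}")
    if not peaks:
        return [], []
    amps = np.array([p.amplitude for p in peaks])
    if mode == "median":
        cut = np.median(amps)
        small = [p for p in peaks if p.amplitude <= cut]
        large = [p for p in peaks if p.amplitude > cut]
    else:
        q1, q3 = np.quantile(amps, [0.25, 0.75])  # type-7 / linear
        small = [p for p in peaks if p.amplitude <= q1]
        # the boundary tie goes to small, keeping the classes disjoint
        # even when Q1 == Q3 (few or identical amplitudes)
        large = [p for p in peaks if p.amplitude >= q3 and p.amplitude > q1]
    return small, large


def peak_metrics(peaks: list[Peak], night_len: int, close_gap_max: int = 2) -> dict:
    """Per-night metric vectors for one (already classified) peak list.

    Gaps (_d) are end-to-start distances between consecutive members of
    the list, ignoring any interleaved peaks of other classes. ``_cls``
    counts consecutive pairs with gap <= close_gap_max.
    """
    peaks = sorted(peaks, key=lambda p: p.start)
    a = np.array([p.amplitude for p in peaks])
    l = np.array([p.length for p in peaks], dtype=float)
    d = np.array(
        [peaks[k + 1].start - peaks[k].end for k in range(len(peaks) - 1)], dtype=float
    )
    cls = int((d <= close_gap_max).sum()) if len(d) else 0
    out = {"a": a, "l": l, "d": d, "cls": cls, "nbr": len(peaks)}
    if peaks:
        out["first_a"], out["first_t"] = peaks[0].amplitude, float(peaks[0].start)
        out["last_a"], out["last_t"] = peaks[-1].amplitude, float(peaks[-1].start)
    return out


def night_peak_features(night: NightActivity, *, close_gap_max: int = 2,
                        amplitude_mode: str = "max") -> dict[str, float]:
    """All defined per-night feature values; undefined ones are absent."""
    all_peaks = extract_peaks(night, amplitude_mode=amplitude_mode)
    sp, lp = split_peaks(all_peaks, "median")
    sp_q, lp_q = split_peaks(all_peaks, "quartile")
    by_cat = {"p": all_peaks, "sp": sp, "lp": lp, "sp_q": sp_q, "lp_q": lp_q}

    feats: dict[str, float] = {}
    for cat, plist in by_cat.items():
        m = peak_metrics(plist, len(night), close_gap_max)
        for metric in VECTOR_METRICS:
            v = m[metric]
            if len(v) == 0:
                continue
            for func in FUNCS:
                feats[f"{cat}_{metric}_{func}"] = float(_FUNC_IMPL[func](v))
        feats[f"{cat}_nbr"] = float(m["nbr"])
        feats[f"{cat}_cls_nbr"] = float(m["cls"])
    # first/last peak of the night as a whole
    m = peak_metrics(all_peaks, len(night), close_gap_max)
    if all_peaks:
        for which in ("first", "last"):
            for part in ("a", "t"):
                feats[f"p_{which}_{part}"] = m[f"{which}_{part}"]
    return feats


def peak_feature_names() -> list[str]:
    """The full (sorted) feature name set the aggregator can emit."""
    names = [
        f"{cat}_{metric}_{func}"
        for cat in CATEGORIES
        for metric in VECTOR_METRICS
        for func in FUNCS
    ]
    names += [f"{cat}_nbr" for cat in CATEGORIES]
    names += [f"{cat}_cls_nbr" for cat in CATEGORIES]
    names += [
        f"p_{which}_{part}_{func}"
        for which in ("first", "last")
        for part in ("a", "t")
        for func in ("avg", "std")
    ]
    return sorted(names)


def aggregate_subject(per_night: list[dict[str, float]]) -> dict[str, float]:
    """Mean across nights of each per-night feature; nights on which a
    feature is undefined are skipped for it; NaN when undefined on every
    night. first/last scalars additionally get an across-night SD."""
    if not per_night:
        raise ValueError("need at least one valid night")
    out: dict[str, float] = {}
    for name in peak_feature_names():
        if name.startswith("p_first") or name.startswith("p_last"):
            base, func = name.rsplit("_", 1)
            vals = [nf[base] for nf in per_night if base in nf]
            if not vals:
                out[name] = float("nan")
            else:
                out[name] = float(np.mean(vals) if func == "avg" else np.std(vals))
        else:
            vals = [nf[name] for nf in per_night if name in nf]
            out[name] = float(np.mean(vals)) if vals else float("nan")
    return out


def subject_peak_features(nights: list[NightActivity], *, close_gap_max: int = 2,
                          amplitude_mode: str = "max") -> dict[str, float]:
    """Per-night extraction + across-night aggregation in one call."""
    return aggregate_subject(
        [night_peak_features(n, close_gap_max=close_gap_max,
                             amplitude_mode=amplitude_mode) for n in nights]
    )
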