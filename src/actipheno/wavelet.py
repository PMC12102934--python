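"""Morlet wavelet structure analysis of concatenated sleep activity.

The counts inside a subject's valid sleep bouts are concatenated in
chronological order and transformed with a complex Morlet continuous
wavelet transform (omega0 = 6). The coefficient magnitudes, normalized to
[0, 1], form a correlation-coefficient map; for each scale the *structure
parameter* is the fraction of time points whose normalized magnitude
reaches a threshold (default 0.7), i.e. the occupancy of prominent
structure at that time scale. Integrating the structure parameter over a
scale window (default 1-200 min) with the trapezoid rule gives the
integrated structure factor ``structure_pms``; ``wavelet_fi`` (a
wavelet-based fragmentation indicator) is 1 minus the mean per-scale
structure parameter.

Scales are expressed as pseudo-periods in epochs (minutes at 1-min
epoching) and converted internally to wavelet scale via the Morlet
center frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .sleep import NightActivity

__all__ = [
    "WaveletMap",
    "StructureResult",
    "default_scales",
    "concatenate_sleep",
    "morlet_cwt",
    "structure_params",
    "wavelet_features",
]

# complex Morlet with unit gaussian envelope exp(-t^2/2) and omega0 = 6
_OMEGA0 = 6.0
_FC = _OMEGA0 / (2 * np.pi)
_WAVELET = f"cmor2.0-{_FC!r}"


@dataclass(frozen=True)
class WaveletMap:
    scales: np.ndarray  # pseudo-periods, epochs
    coeffs: np.ndarray  # complex, scales x time
    corr: np.ndarray    # normalized |coeffs| in [0, 1]


@dataclass(frozen=True)
class StructureResult:
    scales: np.ndarray
    per_scale: np.ndarray
    structure_pms: float
    wavelet_fi: float


def default_scales(low: float = 1.0, high: float = 200.0, n: int = 64) -> np.ndarray:
    """Log-spaced pseudo-periods covering the configured window."""
    return np.geomspace(low, high, n)


def concatenate_sleep(nights: list[NightActivity]) -> np.ndarray:
    """Chronologically concatenated sleep counts, no padding."""
    if not nights:
        raise ValueError("need at least one night")
    ordered = sorted(nights, key=lambda n: n.night_id)
    return np.concatenate([n.counts for n in ordered])


def morlet_cwt(series: np.ndarray, scales: np.ndarray,
               *, normalization: str = "global") -> WaveletMap:
    """Complex Morlet CWT; ``corr`` is |coeff| scaled to [0, 1].

    ``normalization='global'`` divides by the map-wide maximum,
    ``'per_scale'`` by each scale row's maximum. An all-zero series
    yields an all-zero map.
    """
    series = np.asarray(series, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if (scales <= 0).any():
        raise ValueError("scales must be positive")
    if normalization not in ("global", "per_scale"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if len(series) <= scales.max():
        raise ValueError("series must be longer than the largest scale")
    pywt_scales = _FC * scales  # pseudo-period -> pywt scale
    coeffs, _ = pywt.cwt(series, pywt_scales, _WAVELET, method="fft")
    mag = np.abs(coeffs)
    if normalization == "global":
        peak = mag.max()
        corr = mag / peak if peak > 0 else np.zeros_like(mag)
    else:
        peak = mag.max(axis=1, keepdims=True)
        corr = np.divide(mag, peak, out=np.zeros_like(mag), where=peak > 0)
    return WaveletMap(scales=scales, coeffs=coeffs, corr=corr)


def structure_params(
    wmap: WaveletMap,
    corr_threshold: float = 0.7,
    scale_window: tuple[float, float] = (1.0, 200.0),
) -> StructureResult:
    """Per-scale threshold occupancy and its scale integral.

    The structure parameter of a scale is the fraction of time points
    with normalized magnitude >= ``corr_threshold``; ``structure_pms``
    integrates it (trapezoid) over the scales inside ``scale_window``.
    """
    if not (0.0 < corr_threshold < 1.0):
        raise ValueError("corr_threshold must lie in (0, 1)")
    per_scale = (wmap.corr >= corr_threshold).mean(axis=1)
    lo, hi = scale_window
    mask = (wmap.scales >= lo) & (wmap.scales <= hi)
    if mask.sum() >= 2:
        pms = float(np.trapezoid(per_scale[mask], wmap.scales[mask]))
    else:
        pms = 0.0
    return StructureResult(
        scales=wmap.scales,
        per_scale=per_scale,
        structure_pms=pms,
        wavelet_fi=float(1.0 - per_scale.mean()),
    )


def wavelet_features(
    nights: list[NightActivity],
    *,
    scales: np.ndarray | None = None,
    corr_threshold: float = 0.7,
    normalization: str = "global",
    scale_window: tuple[float, float] = (1.0, 200.0),
    per_scale: bool = False,
) -> dict[str, float]:
    """``structure_pms`` and ``wavelet_fi`` for one subject (optionally
    the per-scale parameters as ``sp_scale_<s>`` columns)."""
    if scales is None:
        scales = default_scales(scale_window[0], scale_window[1])
    series = concatenate_sleep(nights)
    wmap = morlet_cwt(series, scales, normalization=normalization)
    res = structure_params(wmap, corr_threshold, scale_window)
    out = {"structure_pms": res.structure_pms, "wavelet_fi": res.wavelet_fi}
    if per_scale:
        for s, v in zip(res.scales, res.per_scale):
            out[f"sp_scale_{s:.3g}"] = float(v)
    return out
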