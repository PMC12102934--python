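"""Discretized mutual-information estimators and the forward-selection
scoring measures (MIM, mRMR, JMI, MMIFS, LCFS).

Continuous features are discretized by equal-frequency binning (default
4 bins); all information quantities are in nats. With tiny samples these
are plug-in estimates — biased upward, but used only to *rank* candidate
features, never for inference.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "equal_frequency_bins",
    "mutual_information",
    "mi_binned",
    "MEASURES",
    "score_features",
]

N_BINS_DEFAULT = 4


def equal_frequency_bins(x: np.ndarray, n_bins: int = N_BINS_DEFAULT) -> np.ndarray:
    """Bin index per sample using quantile cut points.

    Ties can collapse bins (a constant vector yields a single bin, hence
    zero information with anything).
    """
    x = np.asarray(x, dtype=float)
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="left").astype(np.int64)


def mi_binned(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) between two integer-coded variables."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    n = len(a)
    ka, kb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb) / n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = N_BINS_DEFAULT) -> float:
    """MI (nats) between a continuous feature and an integer label."""
    return mi_binned(equal_frequency_bins(x, n_bins), np.asarray(y, dtype=np.int64))


def _joint_code(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    kb = int(b.max()) + 1
    return a * kb + b


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _score_mim(fb, y, cand, selected, X):
    return {f: mi_binned(fb[f], y) for f in cand}


def _score_mrmr(fb, y, cand, selected, X):
    out = {}
    for f in cand:
        rel = mi_binned(fb[f], y)
        red = np.mean([mi_binned(fb[f], fb[s]) for s in selected]) if selected else 0.0
        out[f] = rel - red
    return out


def _score_jmi(fb, y, cand, selected, X):
    out = {}
    for f in cand:
        if not selected:
            out[f] = mi_binned(fb[f], y)
        else:
            out[f] = sum(mi_binned(_joint_code(fb[f], fb[s]), y) for s in selected)
    return out


def _score_mmifs(fb, y, cand, selected, X, beta: float = 0.5):
    out = {}
    for f in cand:
        rel = mi_binned(fb[f], y)
        red = sum(mi_binned(fb[f], fb[s]) for s in selected)
        out[f] = rel - beta * red
    return out


def _score_lcfs(fb, y, cand, selected, X):
    yf = np.asarray(y, dtype=float)
    out = {}
    for f in cand:
        rel = abs(_pearson(X[f], yf))
        red = np.mean([abs(_pearson(X[f], X[s])) for s in selected]) if selected else 0.0
        out[f] = rel - red
    return out


MEASURES = {
    "MIM": _score_mim,
    "mRMR": _score_mrmr,
    "JMI": _score_jmi,
    "MMIFS": _score_mmifs,
    "LCFS": _score_lcfs,
}


def score_features(
    X: dict[str, np.ndarray],
    y: np.ndarray,
    selected: list[str],
    candidates: list[str],
    measure: str,
    *,
    n_bins: int = N_BINS_DEFAULT,
    beta: float = 0.5,
) -> dict[str, float]:
    """Score every candidate feature given the already-selected set.

    ``X`` maps feature name -> value vector. With an empty selected set
    every measure reduces to its relevance term.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    fb = {f: equal_frequency_bins(X[f], n_bins) for f in set(candidates) | set(selected)}
    yb = np.asarray(y, dtype=np.int64)
    if measure == "MMIFS":
        return _score_mmifs(fb, yb, candidates, selected, X, beta=beta)
    return MEASURES[measure](fb, yb, candidates, selected, X)
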