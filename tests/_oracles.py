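"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (pure-Python loops, exhaustive
enumeration) and shares no code with the package implementations it
checks.
"""

from __future__ import annotations

import math
from itertools import combinations, groupby

import numpy as np


# ---------------------------------------------------------------- sleep


def flip_fixed_point_bruteforce(bits: list[int], min_len: int) -> list[int]:
    """Reference short-run flipping: rebuild the run list from scratch
    every iteration, flip the shortest interior run (< min_len), earliest
    on ties, until none remains."""
    bits = list(bits)
    while True:
        runs = []
        pos = 0
        for val, grp in groupby(bits):
            n = len(list(grp))
            runs.append((val, pos, n))
            pos += n
        interior = runs[1:-1]
        short = [(n, p, v) for v, p, n in interior if n < min_len]
        if not short:
            return bits
        n, p, v = min(short, key=lambda t: (t[0], t[1]))
        for i in range(p, p + n):
            bits[i] = 1 - v


def rest_runs(bits: list[int]) -> list[tuple[int, int]]:
    """[start, end) of maximal 1-runs."""
    out = []
    pos = 0
    for val, grp in groupby(bits):
        n = len(list(grp))
        if val == 1:
            out.append((pos, pos + n))
        pos += n
    return out


# ------------------------------------------------------------- circadian


def window_scan(day: list[float], width: int) -> list[float]:
    return [sum(day[i : i + width]) / width for i in range(len(day) - width + 1)]


def is_naive(days: list[list[float]]) -> float:
    d, p = len(days), len(days[0])
    flat = [x for day in days for x in day]
    n = len(flat)
    grand = sum(flat) / n
    prof = [sum(days[i][h] for i in range(d)) / d for h in range(p)]
    num = n * sum((ph - grand) ** 2 for ph in prof)
    den = p * sum((x - grand) ** 2 for x in flat)
    return num / den


def iv_naive(x: list[float]) -> float:
    n = len(x)
    m = sum(x) / n
    num = n * sum((x[i] - x[i - 1]) ** 2 for i in range(1, n))
    den = (n - 1) * sum((xi - m) ** 2 for xi in x)
    return num / den


def fi_naive(x: list[float], short_max: int) -> float:
    """Run-length fragmentation index, scanning zero runs explicitly."""
    credited = 0
    i = 0
    n = len(x)
    while i < n:
        j = i
        while j < n and (x[j] > 0) == (x[i] > 0):
            j += 1
        if x[i] > 0 or (j - i) <= short_max:
            credited += j - i
        i = j
    return credited / n


# ----------------------------------------------------------------- peaks


def peak_features_naive(counts: list[float], close_gap_max: int = 2) -> dict[str, float]:
    """Per-night peak features by nested loops; mirrors the documented
    taxonomy, not the package code."""

    def runs_pos(x):
        out, i = [], 0
        while i < len(x):
            if x[i] > 0:
                j = i
                while j < len(x) and x[j] > 0:
                    j += 1
                out.append((i, j - i, max(x[i:j])))
                i = j
            else:
                i += 1
        return out

    def quantile(sorted_vals, q):
        # linear interpolation (type 7)
        pos = q * (len(sorted_vals) - 1)
        lo = math.floor(pos)
        hi = math.ceil(pos)
        frac = pos - lo
        return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac

    all_p = runs_pos(counts)
    cats = {"p": all_p}
    if all_p:
        amps = sorted(a for _, _, a in all_p)
        med = quantile(amps, 0.5)
        q1 = quantile(amps, 0.25)
        q3 = quantile(amps, 0.75)
        cats["sp"] = [pk for pk in all_p if pk[2] <= med]
        cats["lp"] = [pk for pk in all_p if pk[2] > med]
        cats["sp_q"] = [pk for pk in all_p if pk[2] <= q1]
        cats["lp_q"] = [pk for pk in all_p if pk[2] >= q3 and pk[2] > q1]
    else:
        cats.update(sp=[], lp=[], sp_q=[], lp_q=[])

    funcs = {
        "avg": lambda v: sum(v) / len(v),
        "std": lambda v: math.sqrt(sum((x - sum(v) / len(v)) ** 2 for x in v) / len(v)),
        "max": max,
        "min": min,
        "med": lambda v: quantile(sorted(v), 0.5),
    }
    feats = {}
    for cat, plist in cats.items():
        vecs = {
            "a": [a for _, _, a in plist],
            "l": [float(l) for _, l, _ in plist],
            "d": [
                plist[k + 1][0] - (plist[k][0] + plist[k][1])
                for k in range(len(plist) - 1)
            ],
        }
        for metric, vec in vecs.items():
            if vec:
                for fname, f in funcs.items():
                    feats[f"{cat}_{metric}_{fname}"] = float(f(vec))
        feats[f"{cat}_nbr"] = float(len(plist))
        feats[f"{cat}_cls_nbr"] = float(
            sum(1 for g in vecs["d"] if g <= close_gap_max)
        )
    if all_p:
        feats["p_first_a"] = float(all_p[0][2])
        feats["p_first_t"] = float(all_p[0][0])
        feats["p_last_a"] = float(all_p[-1][2])
        feats["p_last_t"] = float(all_p[-1][0])
    return feats


# --------------------------------------------------------------- cliques


def maximal_cliques_bruteforce(nodes, edges, size_min, size_max):
    """All maximal cliques in the size band by exhaustive subset search."""
    edges = {frozenset(e) for e in edges}

    def is_clique(sub):
        return all(frozenset(p) in edges for p in combinations(sub, 2))

    cliques = []
    nodes = sorted(nodes)
    for k in range(size_min, size_max + 1):
        for sub in combinations(nodes, k):
            if not is_clique(sub):
                continue
            if any(is_clique(sub + (v,)) for v in nodes if v not in sub):
                continue  # extendable -> not maximal
            cliques.append(tuple(sorted(sub)))
    return sorted(cliques)


# --------------------------------------------------------------- shapley


def shapley_bruteforce(predict, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Direct Shapley formula, one predict call per coalition."""
    k = len(x)
    phi = np.zeros(k)
    idx = list(range(k))
    for j in range(k):
        others = [i for i in idx if i != j]
        for size in range(k):
            for sub in combinations(others, size):
                w = (
                    math.factorial(len(sub))
                    * math.factorial(k - len(sub) - 1)
                    / math.factorial(k)
                )
                row_wo = background.copy()
                row_wo[list(sub)] = x[list(sub)]
                row_w = row_wo.copy()
                row_w[j] = x[j]
                phi[j] += w * (
                    float(predict(row_w[None, :])[0])
                    - float(predict(row_wo[None, :])[0])
                )
    return phi
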