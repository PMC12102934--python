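"""Shapley-value attribution for small classifiers.

Two authored estimators, both using the interventional value function
``v(S) = f(x with features outside S replaced by background means)``
where ``f`` is the model's probability of class 1:

* :func:`exact_shapley` — full enumeration over all 2^k coalitions,
  feasible for the clique models (k <= 6). Satisfies the efficiency and
  dummy axioms exactly (up to float round-off).
* :func:`sampled_shapley` — antithetic permutation sampling for larger
  feature sets (the greedy-selection models, k up to 20), where each
  drawn permutation is paired with its reverse so every marginal
  contribution is evaluated from both directions.

Both batch every synthetic row into a single ``predict`` call, which is
what makes tree ensembles affordable.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["exact_shapley", "sampled_shapley"]


def _evaluate(predict, X: np.ndarray, background: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """v(S) for every (subject, mask) pair in one batched call.

    Returns shape (n_subjects, n_masks).
    """
    n, k = X.shape
    m = len(masks)
    rows = np.where(masks[None, :, :], X[:, None, :], background[None, None, :])
    v = predict(rows.reshape(n * m, k))
    return np.asarray(v, dtype=float).reshape(n, m)


def exact_shapley(predict, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact Shapley values by coalition enumeration.

    predict: callable mapping an (m, k) matrix to m probabilities.
    X: (n, k) rows to explain; background: length-k reference point.
    Returns an (n, k) matrix phi with sum_j phi[i, j] =
    predict(X[i]) - predict(background).
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    n, k = X.shape
    idx = np.arange(2**k)
    masks = (idx[:, None] >> np.arange(k)[None, :] & 1).astype(bool)
    sizes = masks.sum(axis=1)
    # w(|S|) = |S|! (k - |S| - 1)! / k!
    fact = np.array([math.factorial(i) for i in range(k + 1)], dtype=float)

    v = _evaluate(predict, X, background, masks)
    phi = np.zeros((n, k))
    for j in range(k):
        without = idx[~masks[:, j]]
        with_j = without | (1 << j)
        wj = fact[sizes[without]] * fact[k - sizes[without] - 1] / fact[k]
        phi[:, j] = ((v[:, with_j] - v[:, without]) * wj[None, :]).sum(axis=1)
    return phi


def sampled_shapley(
    predict,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 256,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Antithetic permutation-sampling Shapley estimate.

    ``n_permutations`` counts drawn permutations; each is also evaluated
    reversed, so marginals come from 2 x n_permutations orderings.
    Every (permutation, reverse) pair telescopes, so the efficiency
    identity sum_j phi[i, j] = predict(x_i) - predict(background) holds
    exactly for the estimate, while individual phi entries carry
    sampling noise.
    """
    rng = rng if rng is not None else np.random.default_rng()
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    n, k = X.shape
    orders = []
    for _ in range(n_permutations):
        perm = rng.permutation(k)
        orders.append(perm)
        orders.append(perm[::-1])

    masks = np.zeros((len(orders), k + 1, k), dtype=bool)
    for o, perm in enumerate(orders):
        for depth in range(1, k + 1):
            masks[o, depth, perm[:depth]] = True
    v = _evaluate(predict, X, background, masks.reshape(-1, k))
    v = v.reshape(n, len(orders), k + 1)

    phi = np.zeros((n, k))
    marginals = np.diff(v, axis=2)  # (n, orders, k) in insertion order
    for o, perm in enumerate(orders):
        phi[:, perm] += marginals[:, o, :]
    return phi / len(orders)
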