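"""Adaptive Hybrid Feature Selection (AHFS).

Greedy forward selection in which several information-theoretic and
correlation measures (MIM, mRMR, JMI, MMIFS, LCFS) each propose their
best next feature; the deduplicated proposals are arbitrated by a small
single-hidden-layer neural network (2 units by default — larger
evaluator networks overfit at these sample sizes) under stratified
3-fold cross-validation, and the candidate with the highest mean CV
accuracy joins the selected set. A run performs ``n_steps`` such
extensions; the ensemble repeats ``n_runs`` independent runs (to absorb
the network's training stochasticity), keeps each run's
highest-accuracy prefix model, explains it with permutation-sampled
Shapley values, and pools the per-feature Shapley columns exactly as the
clique framework does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .cffs import AggregatedShap, CliqueModelResult, aggregate_shap
from .info import score_features
from .shapley import sampled_shapley
from .table import FeatureTable

log = logging.getLogger(__name__)

__all__ = [
    "AhfsParams",
    "AhfsRun",
    "candidate_set",
    "ahfs_step",
    "ahfs_run",
    "ahfs_ensemble",
    "AhfsEnsembleResult",
]

DEFAULT_MEASURES = ("MIM", "mRMR", "JMI", "MMIFS", "LCFS")


@dataclass(frozen=True)
class AhfsParams:
    n_runs: int = 20
    n_steps: int = 20
    measures: tuple[str, ...] = DEFAULT_MEASURES
    ann_hidden: int = 2
    seed_base: int = 0
    folds: int = 3
    n_bins: int = 4
    mmifs_beta: float = 0.5
    top_k_per_measure: int = 1
    n_permutations: int = 256   # Shapley sampling (antithetic pairs added)

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.n_steps < 1 or self.ann_hidden < 1:
            raise ValueError("n_runs, n_steps and ann_hidden must be >= 1")
        unknown = set(self.measures) - set(DEFAULT_MEASURES)
        if unknown:
            raise ValueError(f"unknown measures {sorted(unknown)}")


@dataclass
class AhfsRun:
    selected: list[str]          # length n_steps, all distinct
    step_accuracy: list[float]
    best_step: int               # 1-based
    shap: pd.DataFrame           # subjects x best-step features
    feature_values: pd.DataFrame
    seed: int
    model: object = None         # refit best-step pipeline
    background: np.ndarray | None = None

    @property
    def best_accuracy(self) -> float:
        return self.step_accuracy[self.best_step - 1]


def _evaluator(ann_hidden: int, seed: int):
    clf = MLPClassifier(
        hidden_layer_sizes=(ann_hidden,),
        activation="logistic",
        solver="lbfgs",
        max_iter=300,
        tol=1e-4,
        random_state=seed,
    )
    return make_pipeline(StandardScaler(), clf)


def _lr_evaluator(ann_hidden: int, seed: int):
    """Test hook: linear evaluator in place of the network."""
    return make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))


def candidate_set(
    selected: list[str],
    remaining: list[str],
    table: FeatureTable,
    measures: tuple[str, ...] = DEFAULT_MEASURES,
    *,
    n_bins: int = 4,
    mmifs_beta: float = 0.5,
    top_k: int = 1,
) -> list[str]:
    """One top proposal per measure (``top_k`` for a wider frontier),
    deduplicated, sorted. Ties within a measure go alphabetical."""
    if not remaining:
        raise ValueError("no remaining features")
    data = table.impute_within_group()
    X = {f: data.X[f].to_numpy(dtype=float) for f in set(selected) | set(remaining)}
    y = data.y.to_numpy()
    proposals: set[str] = set()
    for measure in measures:
        scores = score_features(X, y, selected, remaining, measure,
                                n_bins=n_bins, beta=mmifs_beta)
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        proposals.update(name for name, _ in ordered[:top_k])
    return sorted(proposals)


def _cv_accuracy(X: np.ndarray, y: np.ndarray, make_model, folds: int, seed: int) -> float:
    from .cffs import _quiet_fit

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    with _quiet_fit():
        for train, test in skf.split(X, y):
            model = make_model(seed)
            model.fit(X[train], y[train])
            accs.append(float((model.predict(X[test]) == y[test]).mean()))
    return float(np.mean(accs))


def ahfs_step(
    selected: list[str],
    candidates: list[str],
    table: FeatureTable,
    ann_hidden: int = 2,
    seed: int = 0,
    folds: int = 3,
    evaluator=_evaluator,
) -> tuple[str, float]:
    """Evaluate each candidate appended to the selected set; return the
    (feature, accuracy) with the highest mean CV accuracy, ties to the
    alphabetically lower name."""
    if not candidates:
        raise ValueError("no candidates")
    data = table.impute_within_group()
    y = data.y.to_numpy()
    best: tuple[float, str] | None = None
    for cand in sorted(candidates):
        X = data.X[selected + [cand]].to_numpy(dtype=float)
        try:
            acc = _cv_accuracy(X, y, lambda s: evaluator(ann_hidden, s), folds, seed)
        except Exception as err:  # noqa: BLE001 - a failed candidate is skipped, not fatal
            log.warning("ahfs_step: training failed for %s (%s), skipped", cand, err)
            continue
        if best is None or acc > best[0]:
            best = (acc, cand)
    if best is None:
        raise RuntimeError("all candidates failed to train")
    return best[1], best[0]


def ahfs_run(
    table: FeatureTable,
    params: AhfsParams = AhfsParams(),
    run_seed: int = 0,
    evaluator=_evaluator,
) -> AhfsRun:
    """One greedy run: n_steps extensions, then permutation-sampled
    Shapley values on the best-accuracy prefix model."""
    names = table.feature_names()
    if len(names) < params.n_steps:
        raise ValueError(
            f"need at least {params.n_steps} features, have {len(names)}"
        )
    selected: list[str] = []
    accuracies: list[float] = []
    remaining = sorted(names)
    for step in range(params.n_steps):
        candidates = candidate_set(
            selected, remaining, table, params.measures,
            n_bins=params.n_bins, mmifs_beta=params.mmifs_beta,
            top_k=params.top_k_per_measure,
        )
        step_seed = int((abs(run_seed) * 1009 + step) % 2**31)
        chosen, acc = ahfs_step(
            selected, candidates, table, params.ann_hidden,
            seed=step_seed, folds=params.folds, evaluator=evaluator,
        )
        selected.append(chosen)
        remaining.remove(chosen)
        accuracies.append(acc)

    best_step = int(np.argmax(accuracies)) + 1  # earliest argmax
    best_feats = selected[:best_step]
    data = table.impute_within_group()
    X = data.X[best_feats].to_numpy(dtype=float)
    y = data.y.to_numpy()
    model = evaluator(params.ann_hidden, int(abs(run_seed) % 2**31))
    from .cffs import _quiet_fit

    with _quiet_fit():
        model.fit(X, y)
    rng = np.random.default_rng(np.random.SeedSequence([abs(run_seed), 17]))
    background = X.mean(axis=0)
    phi = sampled_shapley(
        lambda M: model.predict_proba(M)[:, 1], X, background,
        n_permutations=params.n_permutations, rng=rng,
    )
    return AhfsRun(
        selected=selected,
        step_accuracy=accuracies,
        best_step=best_step,
        shap=pd.DataFrame(phi, index=data.X.index, columns=best_feats),
        feature_values=pd.DataFrame(X, index=data.X.index, columns=best_feats),
        seed=run_seed,
        model=model,
        background=background,
    )


@dataclass
class AhfsEnsembleResult:
    runs: list[AhfsRun]
    aggregated: AggregatedShap

    @property
    def selected_slots(self) -> int:
        return sum(len(r.selected) for r in self.runs)

    @property
    def n_best_models(self) -> int:
        return len(self.runs)


def ahfs_ensemble(
    table: FeatureTable,
    params: AhfsParams = AhfsParams(),
    evaluator=_evaluator,
) -> AhfsEnsembleResult:
    """n_runs independent runs; pooled Shapley aggregation of the best
    model of each run (n_runs x n_steps selected-feature slots total)."""
    runs = [
        ahfs_run(table, params, run_seed=params.seed_base + r, evaluator=evaluator)
        for r in range(params.n_runs)
    ]
    as_models = [
        CliqueModelResult(
            clique=tuple(r.shap.columns),
            algorithm="ANN-AHFS",
            cv_accuracy=r.best_accuracy,
            shap=r.shap,
            feature_values=r.feature_values,
            fold_assignments=np.array([]),
            seed=r.seed,
        )
        for r in runs
    ]
    return AhfsEnsembleResult(runs=runs, aggregated=aggregate_shap(as_models))


def write_outputs(result: AhfsEnsembleResult, outdir) -> None:
    """ahfs_runs.csv, aggregated_shap.csv, ranking.csv."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"run": i, "step": s + 1, "feature": feat,
             "accuracy": run.step_accuracy[s]}
            for i, run in enumerate(result.runs)
            for s, feat in enumerate(run.selected)
        ]
    ).to_csv(outdir / "ahfs_runs.csv", index=False)
    result.aggregated.pooled.to_csv(outdir / "aggregated_shap.csv", index=False)
    result.aggregated.ranking.to_csv(outdir / "ranking.csv", index=False)
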