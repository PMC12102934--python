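"""Clique-Forming Feature Selection (CFFS).

Candidate feature subsets are the cliques of a low-correlation graph:
features are first screened (Welch two-sample test p < alpha AND
discretized mutual information with the label >= a floor), the survivors
become nodes, and an edge joins two features whose absolute Pearson
correlation stays at or below a cap, so a clique is a set of mutually
weakly correlated features. Each clique is trained as a small model
(logistic regression, random forest, single-hidden-layer network) under
stratified 3-fold cross-validation; models at or above a 60% accuracy
gate are retained, explained with exact interventional Shapley values,
and their per-subject Shapley columns pooled per feature. Features are
ranked by mean absolute pooled Shapley value.
"""

from __future__ import annotations

import logging
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .info import mutual_information
from .shapley import exact_shapley
from .table import FeatureTable

log = logging.getLogger(__name__)

__all__ = [
    "ScreenParams",
    "CffsParams",
    "CliqueModelResult",
    "AggregatedShap",
    "screen",
    "build_graph",
    "enumerate_cliques",
    "train_clique",
    "filter_models",
    "aggregate_shap",
    "run_cffs",
    "CffsResult",
]

ALGORITHMS = ("LR", "RF", "ANN")


@contextmanager
def _quiet_fit():
    """The capped-iteration networks are *meant* to stop at max_iter on
    these sample sizes; silence the per-fit convergence chatter."""
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


@dataclass(frozen=True)
class ScreenParams:
    welch_alpha: float = 0.05
    mi_min: float = 0.02      # nats
    missing_max: float = 0.2
    max_features: int = 1000  # cap on survivors (strongest Welch p first)

    def __post_init__(self) -> None:
        if not 0 < self.welch_alpha < 1:
            raise ValueError("welch_alpha must lie in (0, 1)")
        if self.mi_min < 0:
            raise ValueError("mi_min must be >= 0")
        if self.max_features < 2:
            raise ValueError("max_features must be >= 2")


@dataclass(frozen=True)
class CffsParams:
    screen: ScreenParams = field(default_factory=ScreenParams)
    corr_max: float = 0.15
    size_min: int = 3
    size_max: int = 6
    expand_subcliques: bool = False
    max_cliques: int = 500    # stride-thinned when enumeration yields more
    algorithms: tuple[str, ...] = ALGORITHMS
    folds: int = 3
    min_accuracy: float = 0.60
    rf_trees: int = 200
    seed: int = 0


@dataclass
class CliqueModelResult:
    clique: tuple[str, ...]
    algorithm: str
    cv_accuracy: float
    shap: pd.DataFrame          # subjects x clique features
    feature_values: pd.DataFrame
    fold_assignments: np.ndarray
    seed: int
    model: object = None        # refit pipeline the Shapley values explain
    background: np.ndarray | None = None


@dataclass
class AggregatedShap:
    """Pooled (feature value, Shapley value) pairs and the ranking."""

    pooled: pd.DataFrame   # columns: feature, subject, feature_value, shap_value
    ranking: pd.DataFrame  # columns: feature, mean_abs_shap, n_pairs


def screen(table: FeatureTable, params: ScreenParams = ScreenParams()) -> list[str]:
    """Welch + mutual-information screening; returns surviving names.

    Screening generates candidates, so no multiple-testing correction is
    applied; when more than ``max_features`` survive both gates, the ones
    with the strongest Welch evidence are kept, bounding the clique
    search. Constant features are dropped (Welch undefined, MI zero).
    Survivor order follows the table's column order.
    """
    table = table.drop_sparse(params.missing_max).impute_within_group()
    y = table.y.to_numpy()
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    kept: list[tuple[float, str]] = []
    for name in table.feature_names():
        x = table.X[name].to_numpy(dtype=float)
        if np.std(x) == 0:
            log.info("screen: dropping constant feature %s", name)
            continue
        _, p = stats.ttest_ind(x[y == 1], x[y == 0], equal_var=False)
        if not (p < params.welch_alpha):
            continue
        if mutual_information(x, y) >= params.mi_min:
            kept.append((float(p), name))
    if len(kept) > params.max_features:
        strongest = set(
            name for _, name in sorted(kept, key=lambda t: (t[0], t[1]))[: params.max_features]
        )
        kept = [(p, name) for p, name in kept if name in strongest]
    return [name for _, name in kept]


def build_graph(table: FeatureTable, screened: list[str], corr_max: float = 0.15) -> nx.Graph:
    """Low-correlation graph: edge iff |pearson r| <= corr_max.

    A zero-variance feature is treated as perfectly correlated with
    everything and gets no edges.
    """
    if len(screened) < 2:
        raise ValueError("need at least 2 screened features")
    X = table.impute_within_group().X[screened].to_numpy(dtype=float)
    g = nx.Graph()
    g.add_nodes_from(screened)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    for i in range(len(screened)):
        for j in range(i + 1, len(screened)):
            if sd[i] == 0 or sd[j] == 0:
                continue
            if abs(r[i, j]) <= corr_max:
                g.add_edge(screened[i], screened[j])
    return g


def enumerate_cliques(
    graph: nx.Graph,
    size_min: int = 3,
    size_max: int = 6,
    expand_subcliques: bool = False,
) -> list[tuple[str, ...]]:
    """Maximal cliques with size in [size_min, size_max], sorted
    deterministically; with ``expand_subcliques`` also every sub-clique
    of those down to size_min. Maximal cliques outside the band are
    ignored."""
    from itertools import combinations

    out: set[tuple[str, ...]] = set()
    for clique in nx.find_cliques(graph):
        members = tuple(sorted(clique))
        if size_min <= len(members) <= size_max:
            out.add(members)
            if expand_subcliques:
                for k in range(size_min, len(members)):
                    out.update(combinations(members, k))
    return sorted(out)


def _make_model(algorithm: str, seed: int, rf_trees: int = 200):
    if algorithm == "LR":
        clf = LogisticRegression(C=1.0, max_iter=1000)
    elif algorithm == "RF":
        clf = RandomForestClassifier(n_estimators=rf_trees, random_state=seed)
    elif algorithm == "ANN":
        clf = MLPClassifier(
            hidden_layer_sizes=(8,),
            activation="logistic",
            alpha=1e-3,
            solver="lbfgs",
            max_iter=500,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return make_pipeline(StandardScaler(), clf)


def train_clique(
    table: FeatureTable,
    clique: tuple[str, ...],
    algorithm: str,
    folds: int = 3,
    seed: int = 0,
    rf_trees: int = 200,
) -> CliqueModelResult | None:
    """Stratified k-fold CV accuracy plus exact Shapley attribution.

    Standardization is fit inside each training fold (no leakage). The
    final model is refit on all subjects for the Shapley computation;
    the value function is the refit model's class-1 probability with
    non-coalition features set to the feature means. Returns None when
    no valid fold split exists after 10 seed redraws.
    """
    if not clique:
        raise ValueError("empty clique")
    data = table.impute_within_group()
    X = data.X[list(clique)].to_numpy(dtype=float)
    y = data.y.to_numpy()
    n = len(y)

    fold_assignments = None
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        assignment = np.empty(n, dtype=int)
        ok = True
        for f, (train, test) in enumerate(skf.split(X, y)):
            if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                ok = False
                break
            assignment[test] = f
        if ok:
            fold_assignments = assignment
            seed = seed + attempt
            break
    if fold_assignments is None:
        log.warning("train_clique: no valid fold split for %s, skipping", clique)
        return None

    accs = []
    with _quiet_fit():
        for f in range(folds):
            train, test = fold_assignments != f, fold_assignments == f
            model = _make_model(algorithm, seed, rf_trees)
            model.fit(X[train], y[train])
            accs.append(float((model.predict(X[test]) == y[test]).mean()))
        cv_accuracy = float(np.mean(accs))

        final = _make_model(algorithm, seed, rf_trees)
        final.fit(X, y)
    background = X.mean(axis=0)
    phi = exact_shapley(lambda M: final.predict_proba(M)[:, 1], X, background)
    return CliqueModelResult(
        clique=tuple(clique),
        algorithm=algorithm,
        cv_accuracy=cv_accuracy,
        shap=pd.DataFrame(phi, index=data.X.index, columns=list(clique)),
        feature_values=pd.DataFrame(X, index=data.X.index, columns=list(clique)),
        fold_assignments=fold_assignments,
        seed=seed,
        model=final,
        background=background,
    )


def filter_models(
    results: list[CliqueModelResult], min_accuracy: float = 0.60
) -> list[CliqueModelResult]:
    """Accuracy gate, boundary inclusive."""
    return [r for r in results if r.cv_accuracy >= min_accuracy]


def aggregate_shap(retained: list[CliqueModelResult]) -> AggregatedShap:
    """Pool per-feature (value, Shapley) pairs across retained models."""
    if not retained:
        raise ValueError("no retained models to aggregate")
    frames = []
    for r in retained:
        for feat in r.clique:
            frames.append(
                pd.DataFrame(
                    {
                        "feature": feat,
                        "subject": r.shap.index,
                        "feature_value": r.feature_values[feat].to_numpy(),
                        "shap_value": r.shap[feat].to_numpy(),
                    }
                )
            )
    pooled = pd.concat(frames, ignore_index=True)
    ranking = (
        pooled.groupby("feature")["shap_value"]
        .agg(mean_abs_shap=lambda s: s.abs().mean(), n_pairs="size")
        .reset_index()
        .sort_values(["mean_abs_shap", "feature"], ascending=[False, True],
                     kind="mergesort")
        .reset_index(drop=True)
    )
    return AggregatedShap(pooled=pooled, ranking=ranking)


@dataclass
class CffsResult:
    screened: list[str]
    graph: nx.Graph
    cliques: list[tuple[str, ...]]
    models: list[CliqueModelResult]
    retained: list[CliqueModelResult]
    aggregated: AggregatedShap | None


def run_cffs(table: FeatureTable, params: CffsParams = CffsParams()) -> CffsResult:
    """The full CFFS pipeline on a feature table."""
    screened = screen(table, params.screen)
    if len(screened) < params.size_min:
        log.warning("only %d features survive screening", len(screened))
        return CffsResult(screened, nx.Graph(), [], [], [], None)
    graph = build_graph(table, screened, params.corr_max)
    cliques = enumerate_cliques(graph, params.size_min, params.size_max,
                                params.expand_subcliques)
    if len(cliques) > params.max_cliques:
        # deterministic thinning: evenly spaced picks from the sorted list
        idx = np.linspace(0, len(cliques) - 1, params.max_cliques).round().astype(int)
        cliques = [cliques[i] for i in sorted(set(idx.tolist()))]
    log.info("CFFS: %d screened features, %d cliques", len(screened), len(cliques))
    models = []
    for ci, clique in enumerate(cliques):
        for ai, algorithm in enumerate(params.algorithms):
            model_seed = int(
                np.random.SeedSequence([params.seed, ci, ai]).generate_state(1)[0]
                % 2**31
            )
            result = train_clique(table, clique, algorithm, params.folds,
                                  model_seed, params.rf_trees)
            if result is not None:
                models.append(result)
    retained = filter_models(models, params.min_accuracy)
    aggregated = aggregate_shap(retained) if retained else None
    return CffsResult(screened, graph, cliques, models, retained, aggregated)


def write_outputs(result: CffsResult, outdir) -> None:
    """clique_models.csv, aggregated_shap.csv, ranking.csv."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"clique": "+".join(m.clique), "algorithm": m.algorithm,
             "cv_accuracy": m.cv_accuracy}
            for m in result.models
        ]
    ).to_csv(outdir / "clique_models.csv", index=False)
    if result.aggregated is not None:
        result.aggregated.pooled.to_csv(outdir / "aggregated_shap.csv", index=False)
        result.aggregated.ranking.to_csv(outdir / "ranking.csv", index=False)


def plot_summary(agg: AggregatedShap, path, top: int = 15) -> None:
    """Basic beeswarm-style summary plot of the pooled Shapley values."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top_feats = agg.ranking["feature"].head(top).tolist()
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(top_feats) + 1.5))
    rng = np.random.default_rng(0)
    for i, feat in enumerate(reversed(top_feats)):
        rows = agg.pooled[agg.pooled["feature"] == feat]
        jitter = rng.uniform(-0.25, 0.25, len(rows))
        vals = rows["feature_value"].to_numpy()
        span = vals.max() - vals.min()
        color = (vals - vals.min()) / span if span > 0 else np.full(len(vals), 0.5)
        ax.scatter(rows["shap_value"], np.full(len(rows), i) + jitter,
                   c=color, cmap="coolwarm", s=8, alpha=0.7)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(range(len(top_feats)))
    ax.set_yticklabels(list(reversed(top_feats)))
    ax.set_xlabel("Shapley value (probability of case)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
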