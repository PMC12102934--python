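import numpy as np
import pandas as pd
import pytest

from actipheno.ahfs import (
    AhfsParams,
    _lr_evaluator,
    ahfs_ensemble,
    ahfs_run,
    ahfs_step,
    candidate_set,
)
from actipheno.info import mutual_information
from actipheno.table import FeatureTable


def toy_table(n=60, seed=0, informative=3, noise=5):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    cols = {}
    for i in range(informative):
        cols[f"inf_{i}"] = y + rng.normal(0, 0.6 + 0.2 * i, n)
    for i in range(noise):
        cols[f"noise_{i}"] = rng.normal(size=n)
    X = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    return FeatureTable(X, pd.Series(y, index=X.index))


class TestCandidateSet:
    def test_perfect_feature_proposed_by_all_mi_measures(self):
        t = toy_table(seed=1)
        t.X["perfect"] = t.y.astype(float)
        names = sorted(t.X.columns)
        for m in ("MIM", "mRMR", "JMI", "MMIFS"):
            assert candidate_set([], names, t, (m,)) == ["perfect"]

    def test_deduplication(self):
        t = toy_table(seed=2)
        t.X["perfect"] = t.y.astype(float)
        cands = candidate_set([], sorted(t.X.columns), t,
                              ("MIM", "mRMR", "JMI", "MMIFS", "LCFS"))
        assert len(cands) == len(set(cands))

    def test_mrmr_demotes_selected_duplicate(self):
        t = toy_table(seed=3, informative=0, noise=2)
        rng = np.random.default_rng(33)
        sig = t.y + rng.normal(0, 0.5, t.n_subjects)
        t.X["sel"] = sig
        t.X["copy_of_sel"] = sig.copy()
        t.X["fresh"] = t.y + rng.normal(0, 0.5, t.n_subjects)
        cands = candidate_set(["sel"], ["copy_of_sel", "fresh"], t, ("mRMR",))
        assert cands == ["fresh"]

    def test_empty_remaining_errors(self):
        with pytest.raises(ValueError):
            candidate_set([], [], toy_table(), ("MIM",))


class TestStep:
    def test_single_candidate_chosen(self):
        t = toy_table(seed=4)
        chosen, acc = ahfs_step([], ["inf_0"], t, seed=1)
        assert chosen == "inf_0" and 0 <= acc <= 1

    def test_perfect_predictor_beats_noise(self):
        t = toy_table(seed=5)
        t.X["perfect"] = t.y.astype(float)
        chosen, acc = ahfs_step([], ["perfect", "noise_0"], t, seed=2)
        assert chosen == "perfect"
        assert acc == 1.0

    def test_choice_matches_exhaustive_retraining(self):
        from actipheno.ahfs import _cv_accuracy, _evaluator

        t = toy_table(seed=6)
        data = t.impute_within_group()
        y = data.y.to_numpy()
        cands = ["inf_0", "inf_1", "noise_0"]
        accs = {}
        for c in sorted(cands):
            X = data.X[[c]].to_numpy(float)
            accs[c] = _cv_accuracy(X, y, lambda s: _evaluator(2, s), 3, 7)
        best = max(sorted(accs), key=lambda c: accs[c])
        chosen, acc = ahfs_step([], cands, t, seed=7)
        assert chosen == best and acc == pytest.approx(accs[best])


class TestRun:
    def test_selected_distinct_and_sized(self):
        t = toy_table(seed=7, informative=2, noise=2)
        run = ahfs_run(t, AhfsParams(n_runs=1, n_steps=2), run_seed=1)
        assert len(run.selected) == 2
        assert len(set(run.selected)) == 2
        assert 1 <= run.best_step <= 2

    def test_too_few_features_errors(self):
        t = toy_table(seed=8, informative=1, noise=1)
        with pytest.raises(ValueError, match="at least"):
            ahfs_run(t, AhfsParams(n_steps=5), run_seed=1)

    def test_separable_trajectory_saturates(self):
        t = toy_table(seed=9, informative=0, noise=3)
        t.X["perfect"] = t.y.astype(float)
        run = ahfs_run(t, AhfsParams(n_steps=3), run_seed=2, evaluator=_lr_evaluator)
        assert run.step_accuracy[0] == 1.0
        assert run.best_step == 1

    def test_deterministic_given_seed(self):
        t = toy_table(seed=10)
        a = ahfs_run(t, AhfsParams(n_steps=3), run_seed=5)
        b = ahfs_run(t, AhfsParams(n_steps=3), run_seed=5)
        assert a.selected == b.selected
        assert a.step_accuracy == b.step_accuracy
        assert np.array_equal(a.shap.to_numpy(), b.shap.to_numpy())

    def test_mim_only_lr_hook_picks_max_mi_feature(self):
        t = toy_table(seed=11)
        params = AhfsParams(n_steps=1, measures=("MIM",))
        run = ahfs_run(t, params, run_seed=3, evaluator=_lr_evaluator)
        mis = {c: mutual_information(t.X[c].to_numpy(), t.y.to_numpy())
               for c in t.X.columns}
        assert run.selected[0] == max(sorted(mis), key=lambda c: mis[c])


class TestEnsemble:
    def test_slot_arithmetic(self):
        t = toy_table(seed=12, informative=2, noise=3)
        ens = ahfs_ensemble(t, AhfsParams(n_runs=2, n_steps=3, seed_base=1))
        assert ens.selected_slots == 6
        assert ens.n_best_models == 2

    def test_sampled_additivity_tolerance(self):
        t = toy_table(seed=13)
        ens = ahfs_ensemble(t, AhfsParams(n_runs=2, n_steps=4, seed_base=2,
                                          n_permutations=64))
        for run in ens.runs:
            fx = run.model.predict_proba(run.feature_values.to_numpy())[:, 1]
            f0 = run.model.predict_proba(run.background[None, :])[0, 1]
            gap = np.abs(run.shap.sum(axis=1).to_numpy() - (fx - f0))
            # the telescoping estimator keeps efficiency to float
            # precision, well inside the 0.05 probability-scale budget
            assert np.quantile(gap, 0.95) <= 0.05
            assert gap.max() <= 1e-9

    def test_pooled_pairs_count(self):
        t = toy_table(seed=14)
        ens = ahfs_ensemble(t, AhfsParams(n_runs=2, n_steps=3, seed_base=3))
        expected = sum(run.best_step for run in ens.runs) * t.n_subjects
        assert len(ens.aggregated.pooled) == expected
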