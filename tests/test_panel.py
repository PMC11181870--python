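"""Concordance panel selection and the SVM classifier with take-one-out."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from nephropep.panel import (
    ConcordanceCriteria,
    consistency_filter,
    loo_auc,
    loo_scores,
    rank_auc,
    select_concordant_panel,
    take_one_out_optimize,
    train_svm_panel,
)

METHODS = ["CKD_EPI_CR", "CKD_EPI_CYS", "CKD_EPI_CR_CYS", "EKFC_CYS"]


def _stats(p_by_method, dir_by_method, peptides):
    """Build per-method screen tables from dicts peptide -> value."""
    out = {}
    for m in METHODS:
        out[m] = pd.DataFrame(
            {
                "p_value": [p_by_method[m].get(p, 0.5) for p in peptides],
                "direction": [dir_by_method[m].get(p, "DOWN") for p in peptides],
            },
            index=pd.Index(peptides, name="peptide_id"),
        )
    return out


class TestConcordanceSelection:
    def test_three_of_four_with_shared_direction_selected(self):
        peps = ["a"]
        p = {m: {"a": 0.01} for m in METHODS[:3]}
        p[METHODS[3]] = {"a": 0.2}
        d = {m: {"a": "DOWN"} for m in METHODS}
        assert select_concordant_panel(_stats(p, d, peps)) == ["a"]

    def test_two_methods_only_not_selected(self):
        peps = ["a"]
        p = {m: {"a": 0.01} for m in METHODS[:2]}
        p.update({m: {"a": 0.5} for m in METHODS[2:]})
        d = {m: {"a": "DOWN"} for m in METHODS}
        assert select_concordant_panel(_stats(p, d, peps)) == []

    def test_direction_conflict_blocks_selection(self):
        peps = ["a"]
        p = {m: {"a": 0.01} for m in METHODS[:3]}
        p[METHODS[3]] = {"a": 0.5}
        d = {m: {"a": "DOWN"} for m in METHODS}
        d[METHODS[0]] = {"a": "UP"}
        assert select_concordant_panel(_stats(p, d, peps)) == []
        crit = ConcordanceCriteria(require_consistent_direction=False)
        assert select_concordant_panel(_stats(p, d, peps), crit) == ["a"]

    def test_monotone_in_p_threshold_and_min_methods(self):
        rng = np.random.default_rng(4)
        peps = [f"p{i}" for i in range(40)]
        p = {m: {q: rng.uniform(0, 0.2) for q in peps} for m in METHODS}
        d = {m: {q: "DOWN" for q in peps} for m in METHODS}
        stats = _stats(p, d, peps)
        prev: set = set()
        for thr in (0.01, 0.05, 0.1, 0.2):
            cur = set(select_concordant_panel(stats, ConcordanceCriteria(p_threshold=thr)))
            assert prev <= cur
            prev = cur
        prev_m = None
        for mm in (4, 3, 2, 1):
            cur = set(select_concordant_panel(stats, ConcordanceCriteria(min_methods=mm)))
            if prev_m is not None:
                assert prev_m <= cur
            prev_m = cur

    def test_invalid_criteria(self):
        with pytest.raises(ValueError):
            ConcordanceCriteria(min_methods=0)
        with pytest.raises(ValueError):
            ConcordanceCriteria(p_threshold=0.0)


class TestConsistencyFilter:
    def test_same_direction_everywhere_kept(self):
        tables = [{"a": "DOWN", "b": "DOWN"}, {"a": "DOWN", "b": "UP"}]
        assert consistency_filter(["a", "b"], tables) == ["a"]

    def test_absence_from_a_cohort_excludes(self):
        tables = [{"a": "DOWN"}, {}]
        assert consistency_filter(["a"], tables) == []

    def test_planted_synthetic_three_cohorts(self, small_cohort):
        """Peptides kept across simulated replicate cohorts are a subset of the
        planted differentials with their planted direction."""
        from nephropep import SimulationConfig, simulate_cohort, wilcoxon_screen
        from nephropep.pipeline import add_egfr_columns, compute_labels, _label_series

        cfg, _, _, truth = small_cohort
        planted = truth.peptides[truth.peptides["is_differential"]]
        tables = []
        sig_sets = []
        for seed in (42, 43, 44):
            import dataclasses

            c = dataclasses.replace(cfg, seed=seed, effect_size=2.0)
            visits, matrix, tr = simulate_cohort(c)
            ve = add_egfr_columns(visits, ["EKFC_CYS"])
            labels = compute_labels(ve, ["EKFC_CYS"])
            lab = _label_series(labels, "EKFC_CYS").reindex(matrix.index)
            keep = lab.isin(["UNCONTROLLED", "CONTROLLED"]).to_numpy()
            stats = wilcoxon_screen(matrix.loc[keep], lab[keep])
            tables.append(stats["direction"].to_dict())
            sig_sets.append(set(stats.index[stats["p_value"] < 0.05]))
        candidates = sorted(set.intersection(*sig_sets))
        kept = consistency_filter(candidates, tables)
        truth_dir = truth.peptides["direction"]
        hits = [p for p in kept if p in planted.index]
        assert len(hits) >= 0.8 * len(kept)  # kept set dominated by planted effects
        for p in hits:
            assert tables[0][p] == truth_dir[p]


def _separable(n=30, d=4, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"S{i:02d}" for i in range(n)]
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    X = rng.lognormal(6, 0.3, (n, d))
    X[y == 1] *= 20.0
    mat = pd.DataFrame(X, index=samples, columns=[f"p{j}" for j in range(d)])
    labels = pd.Series(np.where(y == 1, "UNCONTROLLED", "CONTROLLED"), index=samples)
    return mat, labels, y


class TestSvmPanel:
    def test_separable_clusters_training_auc_one(self):
        mat, labels, y = _separable()
        model = train_svm_panel(mat, labels, list(mat.columns))
        scores = model.decision_scores(mat)
        assert rank_auc(scores.to_numpy(), y) == 1.0

    def test_single_class_rejected(self):
        mat, labels, _ = _separable()
        with pytest.raises(ValueError):
            train_svm_panel(mat, labels.replace("CONTROLLED", "UNCONTROLLED"), list(mat.columns))

    def test_loo_fast_path_matches_public_estimator(self):
        """The low-level LOO scorer must reproduce SVC fold by fold."""
        mat, labels, y = _separable(n=24, d=5, seed=3)
        log_X = np.log1p(mat.to_numpy(float))
        fast = loo_scores(log_X, y)
        n = len(y)
        ref = np.empty(n)
        for i in range(n):
            m = np.ones(n, bool)
            m[i] = False
            mu = log_X[m].mean(0)
            sd = log_X[m].std(0)
            sd = np.where(sd <= 0, 1.0, sd)
            svc = SVC(C=256.0, gamma=2e-5).fit((log_X[m] - mu) / sd, y[m])
            ref[i] = svc.decision_function(((log_X[i] - mu) / sd)[None])[0]
        assert np.max(np.abs(fast - ref)) < 1e-8

    def test_model_roundtrip_dict(self):
        mat, labels, _ = _separable()
        model = train_svm_panel(mat, labels, list(mat.columns))
        d = model.to_dict()
        assert d["peptides"] == list(mat.columns)
        assert d["C"] == 256.0 and d["gamma"] == 2e-5


class TestTakeOneOut:
    def test_never_reduces_loo_auc_and_logs_trace(self, two_group_matrix):
        mat, labels = two_group_matrix
        start_auc = loo_auc(mat, labels, list(mat.columns))
        model = take_one_out_optimize(mat, labels, list(mat.columns))
        assert model.loo_auc >= start_auc - 1e-12
        trace = model.elimination_trace
        assert trace[0]["panel_size"] == mat.shape[1]
        # every round evaluates one LOO per remaining peptide
        for step in trace[1:]:
            assert step["n_candidates"] == step["panel_size"] + 1
        aucs = [t["auc"] for t in trace]
        assert all(b > a for a, b in zip(aucs, aucs[1:]))

    def test_duplicate_column_terminates(self, two_group_matrix):
        mat, labels = two_group_matrix
        mat = mat.copy()
        mat["pep0_dup"] = mat["pep0"]
        model = take_one_out_optimize(mat, labels, list(mat.columns))
        assert len(model.peptides) >= 2

    def test_informative_peptides_survive_noise_peptides(self):
        """Panels of strong + pure-noise peptides keep most informative ones."""
        kept_informative = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 60
            y = np.array([1] * 30 + [0] * 30)
            informative = rng.lognormal(6, 0.5, (n, 8))
            informative[y == 1] *= np.exp(1.5)
            noise = rng.lognormal(6, 0.5, (n, 4))
            cols = [f"inf{j}" for j in range(8)] + [f"noise{j}" for j in range(4)]
            mat = pd.DataFrame(
                np.hstack([informative, noise]),
                index=[f"S{i}" for i in range(n)],
                columns=cols,
            )
            labels = pd.Series(np.where(y == 1, "UNCONTROLLED", "CONTROLLED"), index=mat.index)
            model = take_one_out_optimize(mat, labels, cols)
            kept_informative.append(sum(p.startswith("inf") for p in model.peptides))
        assert np.mean(kept_informative) >= 6

    def test_small_panel_rejected(self, two_group_matrix):
        mat, labels = two_group_matrix
        with pytest.raises(ValueError):
            take_one_out_optimize(mat, labels, ["pep0"])
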