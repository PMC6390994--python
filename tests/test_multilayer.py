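import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

import jointfactor as jf
from jointfactor.multilayer import (UNSCORED, GroupAssignment, group_factor_overlap,
                                    group_label_association)


class TestFit:
    def test_planted_high_level_supports_recovered(self, toy_fit):
        cohort, truth, planted, res = toy_fit
        planted_sets = {frozenset(planted.key_joints(g)) for g in range(planted.k2)}
        assert {frozenset(k) for k in res.key_joints} == planted_sets

    def test_key_joints_nonempty_and_match_composite_support(self, toy_fit):
        *_, res = toy_fit
        C = res.composite_raw
        ids = np.asarray(res.joint_ids)
        for f, keys in enumerate(res.key_joints):
            assert keys == set(ids[C[:, f] > 0])
            assert keys

    def test_reconstruction_associativity(self, toy_fit):
        """W1(W2 H2) equals (W1 W2) H2 exactly — the hierarchy is consistent."""
        *_, res = toy_fit
        W1 = res.layer1.W * res.h1_scale[None, :]
        W2, H2 = res.layer2.W, res.layer2.H
        a = W1 @ (W2 @ H2)
        b = (W1 @ W2) @ H2
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_hungarian_alignment_cosine(self, toy_fit):
        """Fitted composite columns align to planted patterns at cosine >= 0.9."""
        cohort, truth, planted, res = toy_fit
        ids = list(res.joint_ids)
        P = np.zeros((len(ids), planted.k2))
        for g in range(planted.k2):
            P[[ids.index(j) for j in planted.key_joints(g)], g] = 1.0
        C = res.composite.to_numpy()
        sim = (C.T @ P) / (np.linalg.norm(C, axis=0)[:, None] *
                           np.linalg.norm(P, axis=0)[None, :])
        r, c = linear_sum_assignment(-sim)
        assert sim[r, c].mean() >= 0.9

    def test_infeasible_ranks_rejected(self):
        with pytest.raises(ValueError, match="k2"):
            jf.MultilayerNMF(np.ones((5, 5)), k1=2, k2=3)


class TestGroupAssignment:
    def test_argmax_and_ties(self):
        H2 = np.array([[0.1, 0.5, 0.0],
                       [0.9, 0.5, 0.0],
                       [0.0, 0.0, 0.0]])
        a = GroupAssignment.from_scores(H2, ["p1", "p2", "p3"], ["G1", "G2", "G3"])
        assert a.group_name["p1"] == "G2" and not a.is_tie["p1"]
        assert a.group_name["p2"] == "G1" and a.is_tie["p2"]  # lowest index wins
        assert a.group_index["p3"] == UNSCORED
        assert a.group_name["p3"] == "UNSCORED" and not a.is_tie["p3"]

    def test_planted_groups_recovered(self, toy_fit):
        cohort, truth, planted, res = toy_fit
        assignment = res.assign_groups()
        # align fitted factor indices to planted group indices by key sets
        mapping = {}
        for f, keys in enumerate(res.key_joints):
            for g in range(planted.k2):
                if keys == planted.key_joints(g):
                    mapping[f] = g
        fitted = assignment.group_index.map(mapping)
        agree = (fitted.to_numpy() == truth["group"].to_numpy()).mean()
        assert agree >= 0.95

    def test_raw_matrix_projection_matches_training_assignment(self, toy_fit):
        cohort, truth, planted, res = toy_fit
        a_scores = res.assign_groups()
        a_raw = res.assign_groups(cohort.baseline_matrix)
        mask = ~a_scores.is_tie
        assert (a_scores.group_index[mask] == a_raw.group_index[mask]).mean() >= 0.99


class TestProjection:
    def test_training_scores_reproduced(self, toy_fit):
        cohort, *_, res = toy_fit
        H2 = res.project(cohort.baseline_matrix)
        np.testing.assert_allclose(H2, res.layer2.H, atol=1e-4)

    def test_q2_levels_ordering(self, toy_fit):
        *_, res = toy_fit
        q = res.q2_levels()
        assert q["low"] >= q["high"] >= q["group"]
        assert q["low"] > 0

    def test_save_load_round_trip(self, tmp_path, toy_fit):
        cohort, *_, res = toy_fit
        path = tmp_path / "model.npz"
        res.save(path)
        back = jf.MultilayerResults.load(path)
        np.testing.assert_allclose(back.composite_raw, res.composite_raw)
        np.testing.assert_allclose(back.project(cohort.baseline_matrix),
                                   res.project(cohort.baseline_matrix), atol=1e-10)
        assert [set(k) for k in back.key_joints] == [set(k) for k in res.key_joints]


class TestGroupFactorOverlap:
    def test_block_scores_enrich_only_own_factor(self):
        rng = np.random.default_rng(0)
        n = 120
        H2 = np.full((3, n), 0.0)
        groups = np.repeat([0, 1, 2], n // 3)
        H2[groups, np.arange(n)] = rng.uniform(0.5, 1.0, n)
        a = GroupAssignment.from_scores(H2, [f"p{i}" for i in range(n)],
                                        ["G1", "G2", "G3"])
        t = group_factor_overlap(a)
        sig = t[t.significant]
        assert set(zip(sig.group, sig.factor)) == {("G1", "G1"), ("G2", "G2"),
                                                   ("G3", "G3")}

    def test_identical_distributions_rarely_enrich(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            H2 = rng.uniform(0.1, 1.0, (2, 80))
            a = GroupAssignment.from_scores(H2, [f"p{i}" for i in range(80)],
                                            ["G1", "G2"])
            t = group_factor_overlap(a)
            # own-factor enrichment is expected by construction of argmax
            # groups; cross enrichment should be rare
            cross = t[(t.group != t.factor) & t.significant]
            hits += len(cross) > 0
        assert hits <= 10


class TestGroupLabelAssociation:
    def _assignment(self, groups):
        names = sorted(set(groups))
        H2 = np.zeros((len(names), len(groups)))
        for j, g in enumerate(groups):
            H2[names.index(g), j] = 1.0
        return GroupAssignment.from_scores(H2, [f"p{i}" for i in range(len(groups))],
                                           names)

    def test_two_by_two_closed_form(self):
        """For the table (10,0;0,10) each diagonal residual equals sqrt(chi2)."""
        a = self._assignment(["G1"] * 10 + ["G2"] * 10)
        labels = pd.Series(["oligo"] * 10 + ["era"] * 10, index=a.scores.columns)
        t = group_label_association(a, labels)
        assert t.chi2 == pytest.approx(20.0)
        assert t.residual.loc["G1", "oligo"] == pytest.approx(np.sqrt(20.0))
        assert t.enriched.loc["G1", "oligo"] and t.enriched.loc["G2", "era"]

    def test_pure_group_is_enriched(self):
        rng = np.random.default_rng(1)
        groups = ["G1"] * 30 + ["G2"] * 60
        labels = ["sys"] * 30 + list(rng.choice(["oligo", "poly"], 60))
        a = self._assignment(groups)
        t = group_label_association(a, pd.Series(labels, index=a.scores.columns))
        assert t.residual.loc["G1", "sys"] >= 1.96

    def test_null_calibration_global_p_uniformish(self):
        """Independent labels: global p < 0.05 in roughly 5% of replicates."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            groups = rng.choice(["G1", "G2", "G3"], 90)
            labels = rng.choice(["a", "b"], 90)
            a = self._assignment(list(groups))
            t = group_label_association(a, pd.Series(labels, index=a.scores.columns))
            hits += t.p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert hits / n_rep <= 0.05 + 4 * se

    def test_single_label_rejected(self):
        a = self._assignment(["G1", "G2"] * 5)
        labels = pd.Series(["x"] * 10, index=a.scores.columns)
        with pytest.raises(ValueError, match="2 categories"):
            group_label_association(a, labels)
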