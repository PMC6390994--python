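import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import jointfactor as jf
from jointfactor.coinvolvement import bh_fdr

from conftest import small_matrix


@pytest.fixture
def hand_cohort(toy_catalog):
    """Four patients with hand-countable co-involvements."""
    return small_matrix({
        "p1": ["knee_l", "knee_r"],
        "p2": ["knee_l"],
        "p3": ["ankle_l", "knee_l"],
        "p4": ["ankle_l"],
    }, toy_catalog.joint_ids)


class TestCoinvolvement:
    def test_hand_counted_probabilities(self, hand_cohort):
        r = jf.coinvolvement(hand_cohort)
        assert r.freq["knee_l"] == pytest.approx(0.75)
        assert r.cond.loc["knee_l", "ankle_l"] == pytest.approx(1 / 3)
        assert r.cond.loc["ankle_l", "knee_l"] == pytest.approx(0.5)

    def test_self_conditional_is_one(self, hand_cohort):
        r = jf.coinvolvement(hand_cohort)
        for j in ["knee_l", "knee_r", "ankle_l"]:
            assert r.cond.loc[j, j] == 1.0

    def test_identical_patients_give_unit_conditionals(self, toy_catalog):
        X = small_matrix({f"p{i}": ["knee_l", "ankle_r"] for i in range(5)},
                         toy_catalog.joint_ids)
        r = jf.coinvolvement(X)
        assert r.cond.loc["knee_l", "ankle_r"] == 1.0
        assert r.cond.loc["ankle_r", "knee_l"] == 1.0

    def test_default_catalog_has_5041_ordered_pairs(self, catalog, homunculus_sim):
        cohort, _, _ = homunculus_sim
        r = jf.coinvolvement(cohort.baseline_matrix)
        assert r.cond.shape == (71, 71)
        assert r.n_ordered_pairs == 5041

    def test_undefined_conditionals_flagged(self, toy_catalog):
        X = small_matrix({"p1": ["knee_l"]}, toy_catalog.joint_ids)
        r = jf.coinvolvement(X)
        assert r.undefined["ankle_l"]
        assert np.isnan(r.cond.loc["ankle_l", "knee_l"])

    def test_empty_matrix_rejected(self, toy_catalog):
        X = pd.DataFrame(index=toy_catalog.joint_ids)
        with pytest.raises(ValueError, match="empty"):
            jf.coinvolvement(X)

    def test_chain_rule_identity(self, toy_sim):
        """cond[y|x] · P(x) == P(x, y) wherever P(x) > 0."""
        X = toy_sim[0].baseline_matrix
        r = jf.coinvolvement(X)
        ok = r.freq > 0
        lhs = r.cond.loc[ok].mul(r.freq[ok], axis=0)
        np.testing.assert_allclose(lhs.to_numpy(), r.pair.loc[ok].to_numpy(),
                                   atol=1e-12)


class TestSkew:
    def test_symmetric_counts_give_zero_z(self):
        m = (5 + 1) / ((5 + 1) + (5 + 1))
        assert m == 0.5  # z = (m - 0.5)/sigma = 0 by construction

    def test_skew_statistic_formula(self, toy_catalog):
        """9 same-side vs 0 opposite-side patients: z ≈ 4.72."""
        # build a cohort producing exactly those counts for (knee, ankle)
        active = {f"s{i}": ["knee_l", "ankle_l"] for i in range(9)}
        X = small_matrix(active, toy_catalog.joint_ids)
        t = jf.skew_test(X, toy_catalog)
        row = t[(t.x_type == "knee") & (t.y_type == "ankle")].iloc[0]
        assert (row.n_same, row.n_opposite) == (9, 0)
        assert row.m == pytest.approx(10 / 11)
        assert row.z == pytest.approx(4.7196, abs=1e-3)

    def test_count_swap_negates_skew(self, toy_catalog):
        a = {f"s{i}": ["knee_l", "ankle_l"] for i in range(7)}
        b = {f"o{i}": ["knee_l", "ankle_r"] for i in range(7)}
        za = jf.skew_test(small_matrix(a, toy_catalog.joint_ids), toy_catalog)
        zb = jf.skew_test(small_matrix(b, toy_catalog.joint_ids), toy_catalog)
        sel = lambda t: t[(t.x_type == "knee") & (t.y_type == "ankle")].iloc[0]
        assert sel(za).m - 0.5 == pytest.approx(-(sel(zb).m - 0.5))
        assert sel(za).z == pytest.approx(-sel(zb).z)

    def test_per_patient_counting_caps_at_one(self, toy_catalog):
        """A patient with many same-side pairs still counts once."""
        X = small_matrix({"p1": ["knee_l", "ankle_l", "hip_l", "tmj_l"]},
                         toy_catalog.joint_ids)
        t = jf.skew_test(X, toy_catalog)
        assert (t["n_same"] <= 1).all()

    def test_self_pair_measures_bilaterality(self, toy_catalog):
        X = small_matrix({f"p{i}": ["knee_l", "knee_r"] for i in range(10)},
                         toy_catalog.joint_ids)
        t = jf.skew_test(X, toy_catalog)
        row = t[(t.x_type == "knee") & (t.y_type == "knee")].iloc[0]
        assert row.n_same == 0 and row.n_opposite == 10

    def test_perfectly_bilateral_cohort_has_no_positive_skew(self, toy_catalog):
        rng = np.random.default_rng(5)
        cols = {}
        for i in range(120):
            types = rng.choice(toy_catalog.bilateral_types, size=2, replace=False)
            cols[f"p{i}"] = [f"{t}_{s}" for t in types for s in "lr"]
        X = small_matrix(cols, toy_catalog.joint_ids)
        t = jf.skew_test(X, toy_catalog)
        cross = t[t.x_type != t.y_type]
        assert not (cross["significant"] & (cross["z"] > 0)).any()


class TestSymmetryPermutation:
    def test_mirror_symmetric_cohort_has_zero_norm(self, toy_catalog):
        X = small_matrix({f"p{i}": ["knee_l", "knee_r", "ankle_l", "ankle_r"]
                          for i in range(8)}, toy_catalog.joint_ids)
        frob, p = jf.lr_symmetry_perm_test(X, toy_catalog, n_perm=20, seed=0)
        assert frob == pytest.approx(0.0, abs=1e-12)

    def test_planted_handedness_detected(self, toy_catalog):
        """Left knee pulls in the right ankle but not vice versa."""
        cols = {}
        for i in range(60):
            cols[f"a{i}"] = ["knee_l", "ankle_r"]   # strong l-knee -> r-ankle
            cols[f"b{i}"] = ["knee_r"]              # r-knee alone
            cols[f"c{i}"] = ["ankle_l", "hip_l", "hip_r"]
        X = small_matrix(cols, toy_catalog.joint_ids)
        frob, p = jf.lr_symmetry_perm_test(X, toy_catalog, n_perm=199, seed=0)
        assert frob > 0
        assert p < 0.05

    def test_zero_permutations_rejected(self, toy_catalog, hand_cohort):
        with pytest.raises(ValueError):
            jf.lr_symmetry_perm_test(hand_cohort, toy_catalog, n_perm=0)


def _brute_force_bh(p):
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


class TestBHFDR:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_degenerate_inputs(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60),
           st.integers(0, 2**31 - 1))
    def test_matches_brute_force_step_up(self, base, seed):
        """BH q-values agree with a direct step-up implementation."""
        rng = np.random.default_rng(seed)
        p = np.concatenate([np.asarray(base), rng.random(20)])
        np.testing.assert_allclose(bh_fdr(p), _brute_force_bh(p), atol=1e-12)
        assert (bh_fdr(p) >= p - 1e-15).all()
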