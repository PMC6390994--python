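import numpy as np
import pandas as pd
import pytest

import jointfactor as jf
from jointfactor.longitudinal import (MISSING, ZERO, fit_cox, km_curve, logrank,
                                      score_visits, time_to_zero, transitions)

from conftest import small_matrix


@pytest.fixture(scope="module")
def traj_and_cohort(toy_fit):
    cohort, truth, planted, res = toy_fit
    return cohort, truth, res, score_visits(cohort, res)


def exp_surv(rng, n, hr=2.0, censor=None):
    """Two-group exponential survival frame with known hazard ratio."""
    g = np.repeat(["ref", "alt"], n // 2)
    lam = np.where(g == "alt", hr, 1.0)
    t = rng.exponential(1.0 / lam)
    event = np.ones(n, dtype=int)
    if censor is not None:
        event = (t <= censor).astype(int)
        t = np.minimum(t, censor)
    return pd.DataFrame({"time": t, "event": event, "group": g},
                        index=[f"p{i}" for i in range(n)])


class TestScoreVisits:
    def test_zero_visits_short_circuit(self, traj_and_cohort):
        cohort, truth, res, traj = traj_and_cohort
        for v in cohort.visits:
            M = cohort.X[v]
            zero_pats = [p for p in M.columns if M[p].sum() == 0]
            assert (traj.loc[zero_pats, v] == ZERO).all()

    def test_baseline_rescoring_self_consistent(self, traj_and_cohort):
        cohort, truth, res, traj = traj_and_cohort
        assignment = res.assign_groups()
        nontie = assignment.is_tie[~assignment.is_tie].index
        agree = (traj.loc[nontie, 0] == assignment.group_name[nontie]).mean()
        assert agree >= 0.99

    def test_states_are_valid(self, traj_and_cohort):
        cohort, truth, res, traj = traj_and_cohort
        valid = set(res.factor_names) | {ZERO, MISSING, "UNSCORED"}
        assert set(np.unique(traj.to_numpy())) <= valid


class TestTransitions:
    def _stable_traj(self, n=30):
        """Patients stay in their baseline group at every visit."""
        groups = np.repeat(["G1", "G2", "G3"], n // 3)
        traj = pd.DataFrame({0: groups, 6: groups, 12: groups},
                            index=[f"p{i}" for i in range(n)])
        return traj, pd.Series(groups, index=traj.index)

    def test_stable_cohort_diagonal(self):
        traj, strata = self._stable_traj()
        tm = transitions(traj, strata, n_perm=99, seed=0)
        for g in ["G1", "G2", "G3"]:
            assert tm.probability.loc[g, g] == 1.0
            off = [d for d in tm.probability.columns if d != g]
            assert (tm.probability.loc[g, off] == 0).all()

    def test_patient_counts_once_per_destination(self):
        traj = pd.DataFrame({0: ["G1"], 6: ["G2"], 12: ["G2"], 24: ["G2"]},
                            index=["p0"])
        tm = transitions(traj, pd.Series(["G1"], index=["p0"]), n_perm=9, seed=0)
        assert tm.count.loc["G1", "G2"] == 1

    def test_missing_only_followup_excluded_from_denominator(self):
        traj = pd.DataFrame({0: ["G1", "G1"], 6: ["G1", MISSING]},
                            index=["p0", "p1"])
        tm = transitions(traj, pd.Series(["G1", "G1"], index=["p0", "p1"]),
                         n_perm=9, seed=0)
        assert tm.denominator["G1"] == 1

    def test_shuffled_labels_rarely_enriched(self):
        """Permutation null holds its size on label-shuffled stable data."""
        rng = np.random.default_rng(0)
        flagged = total = 0
        for rep in range(30):
            traj, strata = self._stable_traj(30)
            shuffled = pd.Series(rng.permutation(strata.to_numpy()),
                                 index=strata.index)
            tm = transitions(traj, shuffled, n_perm=199, seed=rep)
            flagged += int(tm.enriched.to_numpy().sum())
            total += tm.enriched.size
        assert flagged / total <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)

    def test_zero_perm_rejected(self):
        traj, strata = self._stable_traj()
        with pytest.raises(ValueError):
            transitions(traj, strata, n_perm=0)


class TestTimeToZero:
    def _cohort(self, toy_catalog, visits):
        mats = {}
        for v, actives in visits.items():
            mats[v] = small_matrix(actives, toy_catalog.joint_ids)
        return jf.CohortTable(toy_catalog, mats)

    def test_event_and_censoring(self, toy_catalog):
        cohort = self._cohort(toy_catalog, {
            0: {"p1": ["knee_l"], "p2": ["knee_l"]},
            6: {"p1": [], "p2": ["knee_l"]},
            60: {"p2": ["knee_l"]},
        })
        s = time_to_zero(cohort)
        assert tuple(s.loc["p1"]) == (6, 1)
        assert tuple(s.loc["p2"]) == (60, 0)

    def test_first_crossing_rule(self, toy_catalog):
        """A flare after the first zero visit does not undo the event."""
        cohort = self._cohort(toy_catalog, {
            0: {"p1": ["knee_l"]},
            12: {"p1": []},
            18: {"p1": ["knee_r"]},
        })
        s = time_to_zero(cohort)
        assert tuple(s.loc["p1"]) == (12, 1)

    def test_no_followup_excluded_with_warning(self, toy_catalog):
        cohort = self._cohort(toy_catalog, {
            0: {"p1": ["knee_l"], "p2": ["knee_l"]},
            6: {"p1": ["knee_l"]},
        })
        with pytest.warns(UserWarning, match="no follow-up"):
            s = time_to_zero(cohort)
        assert "p2" not in s.index


class TestCox:
    def test_hazard_ratio_recovered(self):
        rng = np.random.default_rng(0)
        surv = exp_surv(rng, 500, hr=2.0)
        fit = fit_cox(surv, ["group"], reference={"group": "ref"})
        hr = fit.table["HR"].iloc[0]
        assert 1.6 <= hr <= 2.5
        assert fit.table["ci_low"].iloc[0] <= 2.0 <= fit.table["ci_high"].iloc[0]

    def test_matches_exponential_mle(self):
        """Cox HR agrees with the closed-form exponential MLE within 10%."""
        rng = np.random.default_rng(1)
        surv = exp_surv(rng, 1000, hr=2.0)
        fit = fit_cox(surv, ["group"], reference={"group": "ref"})
        by = surv.groupby("group")["time"].agg(["count", "sum"])
        mle = (by.loc["alt", "count"] / by.loc["alt", "sum"]) / \
              (by.loc["ref", "count"] / by.loc["ref", "sum"])
        assert abs(fit.table["HR"].iloc[0] - mle) / mle < 0.10

    def test_r2_and_lr_reported(self):
        rng = np.random.default_rng(2)
        fit = fit_cox(exp_surv(rng, 300, hr=2.0), ["group"])
        assert fit.lr_statistic > 0 and 0 < fit.r2 < 1
        assert fit.lr_p < 0.05

    def test_single_level_refused(self):
        rng = np.random.default_rng(3)
        surv = exp_surv(rng, 50, hr=1.0)
        surv["group"] = "only"
        with pytest.raises(ValueError, match="single level"):
            fit_cox(surv, ["group"])
        with pytest.raises(ValueError, match="covariates"):
            fit_cox(surv, [])


class TestLogrankAndKM:
    def test_identical_groups_null_pvalues_uniform(self):
        """Log-rank p-values are uniform when both groups share the hazard."""
        from scipy import stats
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            surv = exp_surv(rng, 80, hr=1.0)
            _, p = logrank(surv, "group")
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_km_starts_at_one_and_non_increasing(self):
        rng = np.random.default_rng(4)
        surv = exp_surv(rng, 100, hr=2.0, censor=1.5)
        km = km_curve(surv, "group")
        for g, sub in km.groupby("group"):
            sub = sub.sort_values("time")
            assert sub["surviving"].iloc[0] == 1.0
            assert (np.diff(sub["surviving"]) <= 1e-12).all()
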