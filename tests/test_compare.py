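import numpy as np
import pytest

from polyexposure.compare import (MetricError, auc, c_index, delta_pred,
                                  r_squared, risk_stratify)
from polyexposure.simulate import TruthSpec, generate_cohort


# --------------------------------------------------------------------------
# independent O(n^2) pure-Python pair-enumeration oracle
# --------------------------------------------------------------------------

def c_index_brute_force(time, event, risk):
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j or not event[i]:
                continue
            if time[i] < time[j] or (time[i] == time[j] and not event[j]):
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def censored_data(rng, n=50):
    risk = rng.standard_normal(n)
    t = rng.exponential(1.0 / np.exp(0.8 * risk))
    t = np.round(t, 1) + 0.1               # induce ties
    e = (rng.random(n) < 0.6).astype(int)
    e[np.argmin(t)] = 1
    return t, e, risk


class TestRSquared:
    def test_examples(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)
        assert r_squared(y, [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_constant_outcome_rejected(self):
        with pytest.raises(MetricError):
            r_squared([1.0, 1.0], [1.0, 2.0])


class TestAuc:
    def test_examples(self):
        assert auc([0, 1], [0.2, 0.8]) == pytest.approx(1.0)
        assert auc([0, 1, 0, 1], [0.3, 0.3, 0.3, 0.3]) == pytest.approx(0.5)
        # 4 positive-negative pairs, 3 concordant
        assert auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_complement_under_score_negation(self, rng):
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.standard_normal(100)      # continuous, ties negligible
        assert auc(y, s) + auc(y, -s) == pytest.approx(1.0, abs=1e-12)


from hypothesis import given, settings
from hypothesis import strategies as st


@given(st.integers(0, 10_000))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_c_index_matches_brute_force_property(seed):
    t, e, r = censored_data(np.random.default_rng(seed), n=25)
    assert c_index(t, e, r) == c_index_brute_force(t, e, r)


class TestCIndex:
    def test_perfect_ordering(self):
        assert c_index([1, 2, 3], [1, 1, 1], [3.0, 2.0, 1.0]) == 1.0

    def test_all_ties_half(self):
        assert c_index([1, 2, 3], [1, 1, 1], [1.0, 1.0, 1.0]) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_exactly(self, seed):
        t, e, r = censored_data(np.random.default_rng(seed))
        assert c_index(t, e, r) == c_index_brute_force(t, e, r)

    def test_agrees_with_lifelines(self, rng):
        from lifelines.utils import concordance_index
        t, e, r = censored_data(rng)
        # lifelines scores predicted survival times, so higher risk maps to -r
        assert c_index(t, e, r) == pytest.approx(
            concordance_index(t, -r, e), abs=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(MetricError):
            c_index([1, 2], [0, 0], [1.0, 2.0])


class TestDeltaPred:
    def test_identical_models_degenerate(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        p = rng.random(200)
        res = delta_pred(p, p, "logistic", y=y, B=50, seed=1)
        assert res.delta == 0.0
        assert res.ci_lower == res.ci_upper == 0.0

    def test_b_zero_rejected(self, rng):
        with pytest.raises(MetricError):
            delta_pred([0.1, 0.2], [0.1, 0.2], "lm", y=[1.0, 2.0], B=0)

    def test_informative_beats_noise(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            n = 2000
            eta = rng.standard_normal(n)
            y = rng.binomial(1, 1 / (1 + np.exp(-2 * eta)))
            noise = rng.standard_normal(n)
            res = delta_pred(noise, eta, "logistic", y=y, B=300, seed=seed)
            if res.ci_lower > 0:
                wins += 1
        assert wins == 5

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (200, 2000):
            rng = np.random.default_rng(5)
            eta = rng.standard_normal(n)
            y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
            res = delta_pred(rng.standard_normal(n), eta, "logistic", y=y,
                             B=300, seed=7)
            widths.append(res.ci_upper - res.ci_lower)
        assert widths[1] < widths[0]

    def test_deterministic_given_seed(self, rng):
        y = rng.standard_normal(300)
        p1, p2 = rng.standard_normal(300), rng.standard_normal(300)
        a = delta_pred(p1, p2, "lm", y=y, B=100, seed=42)
        b = delta_pred(p1, p2, "lm", y=y, B=100, seed=42)
        assert a.delta == b.delta and (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)


class TestRiskStratify:
    @staticmethod
    def _cox_cohort(effect, n=3000, seed=0):
        spec = TruthSpec(n=n, n_continuous=1, n_categorical=0, family="cox",
                         effects={"exp01": effect}, covariate_effects={},
                         missing_rate=0, unwanted_rate=0, seed=seed)
        syn = generate_cohort(spec)
        f = syn.cohort.frame
        return (syn.linear_predictor, f["TIME"].to_numpy(),
                f["PHENO"].to_numpy())

    def test_null_scores_hr_ci_contains_one(self):
        rng = np.random.default_rng(8)
        _, t, e = self._cox_cohort(0.0, seed=8)
        rs = risk_stratify(rng.standard_normal(len(t)), time=t, event=e)
        assert rs["ci"][0] <= 1.0 <= rs["ci"][1]

    def test_true_log_hazard_scores_stratify(self):
        eta, t, e = self._cox_cohort(1.0, seed=9)
        rs = risk_stratify(eta, time=t, event=e)
        assert rs["ratio"] > 1.0 and rs["ci"][0] > 1.0

    def test_percentile_table_event_totals(self):
        eta, t, e = self._cox_cohort(0.5, seed=10)
        rs = risk_stratify(eta, time=t, event=e)
        tab = rs["table"]
        assert tab["events"].sum() == e.sum()
        assert tab["n"].sum() == len(e)
        assert len(tab) == 100

    def test_too_few_individuals_rejected(self):
        with pytest.raises(MetricError):
            risk_stratify([1.0, 2.0], time=[1, 2], event=[1, 1])

    def test_logistic_odds_ratio_variant(self):
        rng = np.random.default_rng(11)
        n = 2000
        s = rng.standard_normal(n)
        y = rng.binomial(1, 1 / (1 + np.exp(-1.5 * s)))
        rs = risk_stratify(s, y=y, family="logistic")
        assert rs["ratio"] > 1.0 and rs["ci"][0] > 1.0
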