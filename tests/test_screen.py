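"""Spearman screen: correlation, surrogate p-values, multiplicity rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import cortmatch as cm
from cortmatch.screen import (
    ScreenResult,
    bh_fdr,
    pvalue_histogram,
    spearman,
    surrogate_pvalue_two_sided,
)
from cortmatch.surrogates import SurrogateParams


class TestSpearman:
    def test_closed_form_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 summing to 4
        assert spearman(np.array([1, 2, 3, 4, 5.0]),
                        np.array([2, 1, 4, 3, 5.0])) == pytest.approx(0.8)

    def test_monotone_transform_gives_unity(self, rng):
        x = rng.standard_normal(50)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman(x, -x) == pytest.approx(-1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariance_under_increasing_transforms(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(30)
        y = r.standard_normal(30)
        base = spearman(x, y)
        assert spearman(np.exp(x), y**3 + 5 * y) == pytest.approx(base)

    def test_ties_use_average_ranks(self):
        x = np.array([1.0, 1.0, 2.0, 3.0])
        y = np.array([5.0, 5.0, 6.0, 7.0])
        assert spearman(x, y) == pytest.approx(
            stats.spearmanr(x, y).statistic
        )

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            spearman(np.ones(5), np.arange(5.0))


class TestSurrogatePValue:
    def test_observed_beyond_all_nulls(self):
        null = np.linspace(-0.5, 0.5, 99)
        assert surrogate_pvalue_two_sided(0.9, null) == pytest.approx(0.02)

    def test_observed_at_median_caps_at_one(self):
        null = np.linspace(-1, 1, 99)
        assert surrogate_pvalue_two_sided(0.0, null) == 1.0

    def test_hand_counted_tail(self):
        null = np.concatenate([np.full(17, -0.5), np.full(2, 0.5)])
        assert surrogate_pvalue_two_sided(0.2, null) == pytest.approx(0.3)

    def test_empty_null_errors(self):
        with pytest.raises(ValueError, match="empty"):
            surrogate_pvalue_two_sided(0.1, np.array([]))

    def test_abs_tail_variant_agrees_for_symmetric_null(self, rng):
        null = rng.standard_normal(999)
        for obs in (0.1, -0.3, 2.0):
            a = surrogate_pvalue_two_sided(obs, null)
            b = surrogate_pvalue_two_sided(obs, null, method="abs-tail")
            assert abs(a - b) < 0.05
        with pytest.raises(ValueError, match="method"):
            surrogate_pvalue_two_sided(0.1, null, method="bogus")

    def test_never_zero_and_never_above_one(self, rng):
        for _ in range(20):
            null = rng.standard_normal(rng.integers(1, 50))
            p = surrogate_pvalue_two_sided(rng.standard_normal(), null)
            assert 0 < p <= 1


def brute_force_bh(pvals, alpha):
    """Step-up by direct enumeration over all candidate cutoffs."""
    F = len(pvals)
    order = np.argsort(pvals)
    p_sorted = np.asarray(pvals)[order]
    cutoff = 0.0
    for i in range(F, 0, -1):
        if p_sorted[i - 1] <= i * alpha / F:
            cutoff = p_sorted[i - 1]
            break
    return np.asarray(pvals) <= cutoff if cutoff > 0 else np.zeros(F, bool)


class TestBHFDR:
    def test_worked_example(self):
        p = np.array([0.001, 0.01, 0.02, 0.04, 0.5])
        assert bh_fdr(p, 0.05).tolist() == [True, True, True, True, False]

    def test_all_ones_reject_none_all_small_reject_all(self):
        assert not bh_fdr(np.ones(6), 0.05).any()
        assert bh_fdr(np.full(6, 0.001), 0.05).all()

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            F = rng.integers(1, 40)
            p = rng.uniform(1e-6, 1, size=F)
            alpha = rng.uniform(0.01, 0.2)
            assert np.array_equal(bh_fdr(p, alpha), brute_force_bh(p, alpha))

    def test_bonferroni_rejections_subset_of_bh(self, rng):
        for _ in range(100):
            F = rng.integers(2, 50)
            p = rng.uniform(1e-6, 1, size=F)
            bonf = p <= 0.05 / F
            bh = bh_fdr(p, 0.05)
            assert np.all(bh[bonf])


@pytest.fixture(scope="module")
def small_screen():
    geom = cm.make_sphere_geometry(120, 80.0)
    sampler = cm.GRFSampler(geom, cm.GRFParams(range_mm=30.0))
    rng = np.random.default_rng(88)
    draws = sampler.draw(rng, 4)
    target = cm.BrainMap(name="target", values=draws[0], geometry=geom)
    features = [
        cm.BrainMap(name="identical", values=draws[0].copy(), geometry=geom),
        cm.BrainMap(name="indep_1", values=draws[1], geometry=geom),
        cm.BrainMap(name="indep_2", values=draws[2], geometry=geom),
        cm.BrainMap(name="indep_3", values=draws[3], geometry=geom),
    ]
    ensemble = cm.generate_ensemble(
        target, params=SurrogateParams(n_surrogates=99, seed=6)
    )
    return target, features, ensemble


class TestRunScreen:
    def test_identical_feature_gets_rho_one_and_smallest_p(self, small_screen):
        target, features, ensemble = small_screen
        res = cm.run_screen(target, features, ensemble)
        row = res.table.set_index("name").loc["identical"]
        assert row["rho"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(2.0 / (ensemble.n_surrogates + 1))

    def test_flags_follow_their_own_rules(self, small_screen):
        target, features, ensemble = small_screen
        alphas = (0.05, 0.05, 0.01)
        res = cm.run_screen(target, features, ensemble, alphas=alphas)
        F = res.n_features
        t = res.table
        assert t["sig_bonferroni"].equals(t["p"] <= alphas[0] / F)
        assert t["sig_uncorrected"].equals(t["p"] <= alphas[2])
        assert np.array_equal(
            t["sig_fdr"].to_numpy(), bh_fdr(t["p"].to_numpy(), alphas[1])
        )
        assert t["p"].is_monotonic_increasing

    def test_feature_equal_to_surrogate_is_self_included(self, small_screen):
        target, _, ensemble = small_screen
        feature = cm.BrainMap(
            name="surrogate_copy",
            values=ensemble.maps[7].copy(),
            geometry=target.geometry,
        )
        res = cm.run_screen(target, [feature, feature], ensemble)
        S = ensemble.n_surrogates
        assert (res.table["p"] >= 2.0 / (S + 1) - 1e-15).all()

    def test_mismatched_ensemble_rejected(self, small_screen):
        target, features, ensemble = small_screen
        other = cm.BrainMap(
            name="other", values=features[1].values, geometry=target.geometry
        )
        with pytest.raises(ValueError, match="generated from"):
            cm.run_screen(other, features, ensemble)


class TestPValueHistogram:
    def _fake_result(self, pvals):
        df = pd.DataFrame(
            {"name": [f"f{i}" for i in range(len(pvals))], "rho": 0.0, "p": pvals,
             "sig_bonferroni": False, "sig_fdr": False, "sig_uncorrected": False}
        )
        return ScreenResult(table=df, alphas=(0.05, 0.05, 0.01), n_surrogates=1)

    def test_counts_partition_the_features(self, rng):
        res = self._fake_result(rng.uniform(0.001, 1, 82))
        counts, edges = pvalue_histogram(res, bins=10)
        assert counts.sum() == 82
        single, _ = pvalue_histogram(self._fake_result(np.full(82, 0.55)), bins=10)
        assert single.max() == 82

    def test_uniform_pvalues_give_flat_histogram(self, rng):
        res = self._fake_result(rng.uniform(0, 1, 1000))
        counts, _ = pvalue_histogram(res, bins=10)
        chi2 = ((counts - 100.0) ** 2 / 100.0).sum()
        assert chi2 < stats.chi2(9).ppf(0.99)
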