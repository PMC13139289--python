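import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import calcmorph as cm
from calcmorph.cohort import RegionEffects, _lognormal_sigma


def bh_oracle(pvals):
    """Literal step-up definition: p_adj(i) = min_{k>=rank_i} m*p(k)/k."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running = min(running, m * pvals[i] / (rank_from_top + 1))
        adj[i] = min(running, 1.0)
    return adj


class TestDescribe:
    def test_median_and_iqr(self):
        d = cm.describe([1, 2, 3, 4, 5])
        assert d["median"] == 3
        assert d["iqr"] == 2
        assert d["min"] == 1

    def test_constant_vector(self):
        d = cm.describe([4.0, 4.0, 4.0])
        assert d["iqr"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cm.describe([])

    def test_synthetic_s_distribution_matches_targets(self):
        # heavy right skew makes the sample IQR noisy; average a few draws
        meds, iqrs = [], []
        for seed in range(5):
            spec = cm.SyntheticCohortSpec(n=1232, zero_fraction=0.0, seed=seed)
            d = cm.describe(cm.synthesize_cohort(spec)["S"])
            meds.append(d["median"])
            iqrs.append(d["iqr"])
        assert np.mean(meds) == pytest.approx(62.75, rel=0.10)
        assert np.mean(iqrs) == pytest.approx(193.35, rel=0.10)


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert cm.spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert cm.spearman(x, -(x**3)) == pytest.approx(-1.0)

    def test_tied_ranks_oracle(self):
        # mid-ranks of x=(1,2,2,4) are (1, 2.5, 2.5, 4); Pearson of the
        # rank vectors is 4.5/sqrt(4.5*5) = sqrt(0.9)
        got = cm.spearman([1, 2, 2, 4], [10, 20, 30, 40])
        assert got == pytest.approx(np.sqrt(0.9), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cm.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestZscore:
    def test_two_point_sample_sd_convention(self):
        np.testing.assert_allclose(
            cm.zscore([0.0, 10.0]), [-np.sqrt(0.5), np.sqrt(0.5)]
        )

    def test_idempotent_and_affine_invariant(self):
        rng = np.random.default_rng(2)
        x = rng.normal(5, 3, 40)
        z = cm.zscore(x)
        np.testing.assert_allclose(cm.zscore(z), z, atol=1e-12)
        np.testing.assert_allclose(cm.zscore(4.0 * x - 7.0), z, atol=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cm.zscore([3.0, 3.0, 3.0])


class TestVif:
    def test_orthogonal_predictors_unity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 3))
        q, _ = np.linalg.qr(x - x.mean(0))
        v = cm.vif(q)
        np.testing.assert_allclose(v, 1.0, atol=1e-8)

    def test_correlated_pair_closed_form(self):
        # two predictors with exact sample correlation 0.8:
        # VIF = 1/(1-0.64) = 2.777...
        rng = np.random.default_rng(1)
        z = rng.normal(size=(500, 2))
        q, _ = np.linalg.qr(z - z.mean(0))
        x1 = q[:, 0]
        x2 = 0.8 * q[:, 0] + 0.6 * q[:, 1]
        v = cm.vif(np.column_stack([x1, x2]))
        np.testing.assert_allclose(v, 1.0 / (1.0 - 0.64), rtol=1e-10)

    def test_duplicated_predictor_rejected(self):
        x = np.random.default_rng(3).normal(size=(50, 1))
        with pytest.raises(ValueError, match="collinearity"):
            cm.vif(np.column_stack([x, x]))


class TestBhAdjust:
    def test_single_p_unchanged(self):
        adj, _ = cm.bh_adjust([0.03])
        assert adj[0] == pytest.approx(0.03)

    def test_all_ones_none_rejected(self):
        adj, reject = cm.bh_adjust([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_textbook_step_up_case(self):
        adj, reject = cm.bh_adjust([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        assert reject.all()

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n=st.integers(1, 6),
        seed=st.integers(0, 100_000),
    )
    def test_matches_brute_force_oracle(self, n, seed):
        p = np.random.default_rng(seed).uniform(0, 1, n)
        adj, _ = cm.bh_adjust(p)
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
        # step-up adjustment is monotone in raw-p order and >= raw p
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cm.bh_adjust([0.5, 1.5])


class TestFitModel:
    @staticmethod
    def _toy_table(n=400, seed=0, beta_s=-0.2, beta_t=0.0, noise=0.5):
        spec = cm.SyntheticCohortSpec(
            n=n,
            seed=seed,
            regions={"roi": RegionEffects(beta_s=beta_s, beta_t=beta_t,
                                          noise_sd=noise)},
        )
        return cm.synthesize_cohort(spec)

    def test_noiseless_single_predictor_unit_beta_std(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        table = pd.DataFrame(
            {
                "S": x,
                "T": rng.normal(size=100),
                "age": rng.uniform(40, 90, 100),
                "sex": rng.integers(0, 2, 100),
                "population": rng.integers(0, 2, 100),
                "ticv": rng.normal(1.4e6, 1e5, 100),
                "roi": 2.0 * x,
            }
        )
        fit = cm.fit_model(table, 1, "roi")
        assert fit.estimates["S"].beta_std == pytest.approx(1.0, abs=1e-9)
        assert fit.estimates["S"].beta == pytest.approx(2.0, abs=1e-9)

    def test_beta_std_equals_beta_on_z_scored_table(self):
        tab = self._toy_table()
        zt = tab.copy()
        for col in ("S", "T", "age", "ticv", "roi"):
            zt[col] = cm.zscore(zt[col])
        fit = cm.fit_model(zt, 3, "roi")
        for name in ("S", "T", "age", "ticv"):
            e = fit.estimates[name]
            assert e.beta == pytest.approx(e.beta_std, abs=1e-12)

    def test_orthogonal_predictors_match_single_models(self):
        rng = np.random.default_rng(9)
        n = 300
        z = rng.normal(size=(n, 2))
        q, _ = np.linalg.qr(z - z.mean(0))
        table = pd.DataFrame(
            {
                "S": q[:, 0],
                "T": q[:, 1],
                "age": rng.uniform(40, 90, n),
                "sex": rng.integers(0, 2, n),
                "population": rng.integers(0, 2, n),
                "ticv": rng.normal(1.4e6, 1e5, n),
            }
        )
        table["roi"] = (
            -3.0 * table["S"] + 2.0 * table["T"] + rng.normal(0, 0.1, n)
        )
        b1 = cm.fit_model(table, 1, "roi").estimates["S"].beta
        b2 = cm.fit_model(table, 2, "roi").estimates["T"].beta
        f3 = cm.fit_model(table, 3, "roi")
        assert f3.estimates["S"].beta == pytest.approx(b1, abs=2e-2)
        assert f3.estimates["T"].beta == pytest.approx(b2, abs=2e-2)

    def test_rank_deficient_design_rejected(self):
        tab = self._toy_table(n=50)
        tab["T"] = tab["S"]
        with pytest.raises(ValueError):
            cm.fit_model(tab, 3, "roi")

    def test_fdr_family_is_per_model_across_regions(self):
        spec = cm.SyntheticCohortSpec(
            n=300,
            seed=11,
            regions={
                "a": RegionEffects(beta_s=-0.3),
                "b": RegionEffects(beta_s=0.0),
                "c": RegionEffects(beta_s=0.0),
            },
        )
        tab = cm.synthesize_cohort(spec)
        fits = cm.fit_models(tab, ["a", "b", "c"], models=(1,))
        s_rows = fits[fits.predictor == "S"]
        np.testing.assert_allclose(
            np.sort(s_rows.p_adj.to_numpy()),
            np.sort(bh_oracle(s_rows.p.to_numpy())),
        )
        assert np.all(fits.p_adj >= fits.p - 1e-15)
        assert np.all(fits.vif >= 1.0 - 1e-12)


class TestSynthesizeCohort:
    def test_deterministic_given_seed(self):
        a = cm.synthesize_cohort(cm.SyntheticCohortSpec(seed=21))
        b = cm.synthesize_cohort(cm.SyntheticCohortSpec(seed=21))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_fraction_and_skew(self):
        spec = cm.SyntheticCohortSpec(seed=2)
        tab = cm.synthesize_cohort(spec)
        n_zero = int((tab["S"] == 0).sum())
        assert n_zero == round(spec.zero_fraction * spec.n)
        assert (tab["T"] == 0).sum() == n_zero
        s = tab["S"][tab["S"] > 0]
        assert s.mean() > s.median()  # right-skewed

    def test_spearman_targets_recovered(self):
        spec = cm.SyntheticCohortSpec(seed=13)
        tab = cm.synthesize_cohort(spec)
        assert cm.spearman(tab["S"], tab["T"]) == pytest.approx(
            spec.rho_s_t, abs=0.05
        )
        assert cm.spearman(tab["age"], tab["S"]) == pytest.approx(
            spec.rho_age_s, abs=0.05
        )

    def test_lognormal_sigma_inverts_iqr(self):
        med, sigma = 62.75, _lognormal_sigma(62.75, 193.35)
        from scipy import stats

        q1, q3 = med * np.exp(np.array([-1, 1]) * stats.norm.ppf(0.75) * sigma)
        assert q3 - q1 == pytest.approx(193.35, rel=1e-9)

    def test_null_effect_estimates_center_on_zero(self):
        est = []
        for seed in range(30):
            tab = cm.synthesize_cohort(
                cm.SyntheticCohortSpec(
                    n=400, seed=300 + seed,
                    regions={"roi": RegionEffects(beta_s=0.0)},
                )
            )
            f = cm.fit_model(tab, 1, "roi").estimates["S"]
            est.append(f.beta_std / f.se_std)
        # t-statistics under the null: mean near 0, spread near 1
        assert abs(np.mean(est)) < 0.5

    def test_attenuation_when_true_effect_is_s_only(self):
        # S and T are strongly correlated; with a true S-only effect the
        # T coefficient from Model 2 shrinks toward 0 once S enters (Model 3)
        t2, t3 = [], []
        for seed in range(10):
            tab = cm.synthesize_cohort(
                cm.SyntheticCohortSpec(
                    n=800, seed=40 + seed,
                    regions={"roi": RegionEffects(beta_s=-0.2, beta_t=0.0)},
                )
            )
            t2.append(cm.fit_model(tab, 2, "roi").estimates["T"].beta_std)
            t3.append(cm.fit_model(tab, 3, "roi").estimates["T"].beta_std)
        assert abs(np.mean(t3)) < abs(np.mean(t2))
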