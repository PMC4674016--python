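import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from labgrowth.growth import (
    ClassModel,
    GrowthParams,
    MCMCConfig,
    PriorSpec,
    breed_standard_fraction,
    class_conditional_posterior,
    classify_and_correct,
    convergence_diagnostics,
    effective_sample_size,
    filter_extreme_heights,
    log_likelihood,
    mean_height,
    sample_posterior,
)


def obs_frame(ages, heights, sex="female"):
    return pd.DataFrame({
        "dog_id": [f"d{i}" for i in range(len(ages))],
        "sex": sex,
        "age_days": ages,
        "height_recorded_cm": heights,
    })


class TestFilterExtremeHeights:
    def test_zero_and_one_removed(self):
        obs = obs_frame([100, 200, 300], [0.0, 1.0, 55.0])
        kept, removed, gone = filter_extreme_heights(obs)
        assert kept["height_recorded_cm"].tolist() == [55.0]
        assert sorted(removed["height_recorded_cm"]) == [0.0, 1.0]

    def test_clean_data_untouched(self):
        obs = obs_frame([100, 200], [30.0, 40.0])
        kept, removed, gone = filter_extreme_heights(obs)
        assert len(removed) == 0 and gone == []

    def test_fully_removed_dog_reported(self):
        obs = pd.DataFrame({
            "dog_id": ["a", "a", "b"], "sex": "female",
            "age_days": [100, 200, 150],
            "height_recorded_cm": [30.0, 40.0, 0.0],
        })
        _, _, gone = filter_extreme_heights(obs)
        assert gone == ["b"]


class TestMeanHeight:
    def test_published_18_month_means(self, female_params, male_params):
        assert round(mean_height(547, female_params), 1) == 55.1
        assert round(mean_height(547, male_params), 1) == 58.9

    def test_asymptote(self, female_params):
        assert mean_height(1e9, female_params) == pytest.approx(female_params.a)

    def test_gap_halves_every_half_life(self, female_params):
        t = 100.0
        hl = female_params.half_life_days
        gap = lambda age: female_params.a - mean_height(age, female_params)
        assert gap(t + hl) == pytest.approx(gap(t) / 2, rel=1e-12)

    def test_negative_age_rejected(self, female_params):
        with pytest.raises(ValueError):
            mean_height(-1, female_params)

    @given(
        a=st.floats(40, 70), b=st.floats(0.001, 0.1), c=st.floats(0, 100),
        age=st.floats(0, 2000), dt=st.floats(0.1, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_bounded(self, a, b, c, age, dt):
        p = GrowthParams(a=a, b=b, c=c, sd=5.0)
        h0, h1 = mean_height(age, p), mean_height(age + dt, p)
        assert h0 <= h1 <= a
        if h0 < a - 1e-9:  # strictly increasing until float saturation
            assert h0 < h1


class TestLogLikelihood:
    def test_single_observation_at_mode(self, female_params):
        mu = mean_height(400, female_params)
        obs = obs_frame([400], [mu])
        cm = ClassModel(pi=(0.0, 1.0, 0.0))
        expected = 0.5 * np.log(female_params.tau / (2 * np.pi))
        assert log_likelihood(obs, female_params, cm) == pytest.approx(expected)

    def test_degenerate_mixture_equals_scaled_component(self, female_params):
        obs = obs_frame([300, 400], [20.0, 21.0])
        cm = ClassModel(pi=(0.0, 0.0, 1.0))
        mus = mean_height(np.array([300.0, 400.0]), female_params) / 2.54
        direct = sps.norm.logpdf(
            [20.0, 21.0], loc=mus, scale=female_params.sd
        ).sum()
        assert log_likelihood(obs, female_params, cm) == pytest.approx(direct)

    def test_matches_bruteforce_enumeration(self, rng):
        ages = rng.uniform(50, 540, 25)
        heights = rng.uniform(8, 150, 25)
        params = GrowthParams(a=56, b=0.013, c=8, sd=4.7)
        cm = ClassModel(pi=(0.1, 0.8, 0.1))
        dens = np.zeros(25)
        for pi_k, m in zip(cm.pi, cm.mean_multipliers):
            dens += pi_k * sps.norm.pdf(
                heights, loc=mean_height(ages, params) * m, scale=params.sd
            )
        assert log_likelihood(obs_frame(ages, heights), params, cm) == pytest.approx(
            np.log(dens).sum(), rel=1e-12
        )


class TestClassConditionalPosterior:
    def test_matches_bruteforce_enumeration(self, rng):
        """Gibbs full conditional == normalized three-component densities."""
        for _ in range(200):
            params = GrowthParams(
                a=rng.uniform(40, 70), b=rng.uniform(0.005, 0.05),
                c=rng.uniform(0, 50), sd=rng.uniform(1, 10),
            )
            cm = ClassModel(pi=tuple(rng.dirichlet([1, 1, 1])))
            age = rng.uniform(0, 600)
            h = rng.uniform(5, 160)
            got = class_conditional_posterior(h, age, params, cm)
            dens = np.array([
                pi_k * sps.norm.pdf(h, mean_height(age, params) * m, params.sd)
                for pi_k, m in zip(cm.pi, cm.mean_multipliers)
            ])
            assert np.allclose(got, dens / dens.sum(), atol=1e-12)
            assert got.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exact_height_is_confidently_ok(self, female_params):
        p = GrowthParams(a=55.1, b=0.0132, c=7.03, sd=1.0)
        cm = ClassModel(pi=(1 / 3, 1 / 3, 1 / 3))
        post = class_conditional_posterior(mean_height(500, p), 500, p, cm)
        assert post[1] > 0.99

    def test_degenerate_prior_pins_class(self, female_params):
        cm = ClassModel(pi=(0.0, 1.0, 0.0))
        post = class_conditional_posterior(21.7, 500, female_params, cm)
        assert np.allclose(post, [0, 1, 0])

    def test_downscaled_adult_height_flagged_in2cm(self, female_params):
        post = class_conditional_posterior(
            21.7, 500, female_params, ClassModel(pi=(0.1, 0.8, 0.1))
        )
        assert np.argmax(post) == 2


class TestSampler:
    def test_seeded_determinism(self, clean_cohort):
        obs, _ = clean_cohort
        f = obs[obs.sex == "female"].head(200).reset_index(drop=True)
        mcmc = MCMCConfig(n_adapt=100, n_burn=100, n_keep=200, seed=42)
        r1 = sample_posterior(f, mcmc=mcmc)
        r2 = sample_posterior(f, mcmc=mcmc)
        for k in ("a", "b", "c", "tau"):
            assert np.array_equal(r1.chains[k], r2.chains[k])
        assert np.array_equal(r1.class_post, r2.class_post)

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            sample_posterior(obs_frame([], []))

    def test_mixed_sexes_rejected(self, contaminated_cohort):
        obs, _ = contaminated_cohort
        with pytest.raises(ValueError):
            sample_posterior(obs, mcmc=MCMCConfig(n_keep=10))

    def test_matches_grid_posterior_with_fixed_curve(self, rng):
        """With b, c and the classes pinned, the sampler's posterior for the
        asymptote agrees with a dense-grid numerical posterior over (a, tau)."""
        params = GrowthParams(a=55.0, b=0.0132, c=7.0, sd=4.0)
        ages = rng.uniform(100, 540, 10)
        h = mean_height(ages, params) + rng.normal(0, params.sd, 10)
        obs = obs_frame(ages, h)
        priors = PriorSpec()
        fixed = {"b": params.b, "c": params.c, "classes": np.ones(10, int)}
        res = sample_posterior(
            obs, priors,
            MCMCConfig(n_adapt=0, n_burn=500, n_keep=8000, seed=7),
            fixed=fixed,
        )
        g = 1 - np.exp(-params.b * (ages + params.c))
        a_grid = np.linspace(40, 70, 400)
        tau_grid = np.linspace(1e-3, 0.5, 400)
        A, T = np.meshgrid(a_grid, tau_grid, indexing="ij")
        loglik = np.zeros_like(A)
        for gi, hi in zip(g, h):
            loglik += 0.5 * np.log(T) - 0.5 * T * (hi - A * gi) ** 2
        logpost = (
            loglik
            + sps.norm.logpdf(A, priors.a_mean, 1 / np.sqrt(priors.a_precision))
            + sps.gamma.logpdf(T, priors.tau_shape, scale=1 / priors.tau_rate)
        )
        w = np.exp(logpost - logpost.max())
        a_mean_grid = float((A * w).sum() / w.sum())
        assert res.posterior_mean("a") == pytest.approx(a_mean_grid, abs=0.15)

    def test_identifiability_with_clean_data(self):
        """With zero contamination the mixture collapses onto the ok class."""
        from labgrowth.synthetic import CohortConfig, generate_cohort

        obs, _ = generate_cohort(
            CohortConfig(n_dogs=300, contamination_probs=(0, 1, 0),
                         sex_ratio=0.0, seed=13)
        )
        assert len(obs) >= 1000
        res = sample_posterior(
            obs, mcmc=MCMCConfig(n_adapt=300, n_burn=500, n_keep=1000, seed=3)
        )
        assert res.chains["pi"][:, 1].mean() >= 0.95

    def test_credible_interval_coverage_small_replicate(self):
        """95% intervals for the asymptote cover the truth in repeated sims
        (full 20-replicate check lives in the acceptance suite)."""
        from labgrowth.synthetic import CohortConfig, generate_cohort

        hits = 0
        for seed in range(5):
            obs, _ = generate_cohort(CohortConfig(n_dogs=120, seed=60 + seed))
            f = obs[obs.sex == "female"].reset_index(drop=True)
            res = sample_posterior(
                f, mcmc=MCMCConfig(n_adapt=400, n_burn=600, n_keep=1500,
                                   seed=seed)
            )
            lo, hi = res.credible_interval("a")
            hits += lo <= 55.1 <= hi
        assert hits >= 4


class TestClassifyAndCorrect:
    @staticmethod
    def _result_like(post):
        from labgrowth.growth import PosteriorResult

        return PosteriorResult(
            chains={}, class_post=np.asarray(post, dtype=float),
            acceptance={}, proposal_scales={}, n_obs=len(post), seed=0,
        )

    def test_in2cm_correction_arithmetic(self):
        obs = obs_frame([500], [21.7])
        res = self._result_like([[0.0, 0.1, 0.9]])
        corr, report = classify_and_correct(obs, res)
        assert corr["height_corrected_cm"].iloc[0] == pytest.approx(21.7 * 2.54)
        assert report == {"cm2in": 0, "ok": 0, "in2cm": 1}

    def test_ok_unchanged(self):
        obs = obs_frame([500], [55.0])
        corr, _ = classify_and_correct(obs, self._result_like([[0.05, 0.9, 0.05]]))
        assert corr["height_corrected_cm"].iloc[0] == 55.0
        assert corr["multiplier_applied"].iloc[0] == 1.0

    def test_subthreshold_falls_back_to_ok(self):
        obs = obs_frame([500], [30.0])
        res = self._result_like([[0.45, 0.2, 0.35]])
        corr, _ = classify_and_correct(obs, res, threshold=0.5)
        assert corr["class_label"].iloc[0] == "ok"

    def test_exact_tie_goes_to_ok(self):
        obs = obs_frame([500], [30.0])
        corr, _ = classify_and_correct(obs, self._result_like([[0.5, 0.0, 0.5]]))
        assert corr["class_label"].iloc[0] == "ok"

    def test_recovers_true_classes_on_contaminated_adults(self, female_params):
        """Post-hoc contaminated mature observations are recovered by the
        fitted model at >=99% accuracy (classes sit ~2.54x apart vs sd~5cm)."""
        from labgrowth.synthetic import CohortConfig, contaminate_units, generate_cohort

        obs, truth = generate_cohort(
            CohortConfig(n_dogs=150, contamination_probs=(0, 1, 0),
                         sex_ratio=0.0, seed=77)
        )
        mature = obs["age_days"] >= 180
        stored, labels = contaminate_units(
            obs.loc[mature, "height_recorded_cm"], (0.05, 0.9, 0.05), seed=8
        )
        obs.loc[mature, "height_recorded_cm"] = stored
        true_labels = np.where(mature, "ok", "ok").astype(object)
        true_labels[np.flatnonzero(mature)] = labels
        res = sample_posterior(
            obs, mcmc=MCMCConfig(n_adapt=400, n_burn=600, n_keep=1500, seed=5)
        )
        corr, _ = classify_and_correct(obs, res)
        contaminated = np.flatnonzero(true_labels != "ok")
        assert len(contaminated) > 20
        agree = (
            corr["class_label"].to_numpy()[contaminated]
            == true_labels[contaminated]
        ).mean()
        assert agree >= 0.99


class TestBreedStandardFraction:
    def test_all_inside_band(self):
        df = obs_frame([400] * 5, [56.5] * 5, sex="male")
        df["height_corrected_cm"] = df["height_recorded_cm"]
        r = breed_standard_fraction(df, "male", 365)
        assert r.point == 1.0

    def test_all_outside_band(self):
        df = obs_frame([400] * 5, [50.0] * 5, sex="male")
        df["height_corrected_cm"] = df["height_recorded_cm"]
        assert breed_standard_fraction(df, "male", 365).point == 0.0

    def test_no_qualifying_measurements(self):
        df = obs_frame([100], [55.0], sex="female")
        df["height_corrected_cm"] = df["height_recorded_cm"]
        with pytest.raises(ValueError):
            breed_standard_fraction(df, "female", 365)

    def test_normal_band_oracle(self, male_params, rng):
        """At mature ages the fraction in [56,57] approaches the normal-band
        probability Phi((57-mu)/sd) - Phi((56-mu)/sd)."""
        n = 40000
        ages = rng.uniform(500, 547, n)
        mu = mean_height(ages, male_params)
        df = obs_frame(ages, mu, sex="male")
        df["height_corrected_cm"] = mu + rng.normal(0, male_params.sd, n)
        expected = sps.norm.cdf(57, mu, male_params.sd) - sps.norm.cdf(
            56, mu, male_params.sd
        )
        r = breed_standard_fraction(df, "male", 365)
        assert r.point == pytest.approx(expected.mean(), abs=0.01)
        assert r.lower < r.point < r.upper


class TestDiagnostics:
    def test_iid_chain_has_full_ess(self, rng):
        n = 4000
        ess = effective_sample_size(rng.standard_normal(n))
        assert ess == pytest.approx(n, rel=0.15)

    def test_ar1_chain_matches_closed_form(self, rng):
        phi, n = 0.5, 40000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        expected = n * (1 - phi) / (1 + phi)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.15)

    def test_flagging_and_report_shape(self, clean_cohort):
        obs, _ = clean_cohort
        f = obs[obs.sex == "female"].head(150).reset_index(drop=True)
        res = sample_posterior(
            f, mcmc=MCMCConfig(n_adapt=100, n_burn=100, n_keep=400, seed=1)
        )
        report = convergence_diagnostics(res)
        assert set(report["param"]) == {"a", "b", "c", "tau"}
        assert report["ess"].gt(0).all()
        near_constant = type(res)(
            chains={**res.chains, "a": np.full(400, 5.0)
                    + np.linspace(0, 1e-9, 400)},
            class_post=res.class_post, acceptance=res.acceptance,
            proposal_scales=res.proposal_scales, n_obs=res.n_obs, seed=0,
        )
        rep2 = convergence_diagnostics(near_constant)
        assert bool(rep2.loc[rep2["param"] == "a", "flagged"].iloc[0])

    def test_multichain_rhat_close_to_one(self, clean_cohort):
        obs, _ = clean_cohort
        f = obs[obs.sex == "female"].head(200).reset_index(drop=True)
        runs = [
            sample_posterior(
                f, mcmc=MCMCConfig(n_adapt=300, n_burn=500, n_keep=2000, seed=s)
            )
            for s in (1, 2)
        ]
        report = convergence_diagnostics(runs)
        assert (report["rhat"] < 1.1).all()
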