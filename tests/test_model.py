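"""Mixing model: priors, likelihood contract, sampling, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famix import (
    CCSet,
    FattyAcidMixingModel,
    MixingModelSpec,
    SourceSummary,
    apply_ccs,
    build_model,
    informative_alpha,
    simulate_consumers_from_summary,
)

FA3 = ["16:1n-7", "20:5n-3", "22:6n-3"]


class TestInformativeAlpha:
    def test_uniform_weights_reproduce_noninformative_prior(self):
        np.testing.assert_allclose(informative_alpha(np.full(4, 0.25)), np.ones(4))

    def test_concentration_is_k_times_weight(self):
        got = informative_alpha([0.7, 0.15, 0.1, 0.04, 0.01])
        np.testing.assert_allclose(got, [3.5, 0.75, 0.5, 0.2, 0.05])

    def test_zero_weight_floored(self):
        got = informative_alpha([0.5, 0.5, 0.0])
        assert got[2] == pytest.approx(0.01)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            informative_alpha([0.0, 0.0])

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            informative_alpha([0.5, 0.6])

    def test_prior_predictive_ordering_follows_weights(self):
        alpha = informative_alpha([0.6, 0.25, 0.1, 0.05])
        draws = np.random.default_rng(0).dirichlet(alpha, size=4000)
        medians = np.median(draws, axis=0)
        assert np.all(np.diff(medians) < 0)


class TestModelConstruction:
    def test_single_source_rejected(self, predator_sources, mixed_consumers):
        with pytest.raises(ValueError, match="at least two sources"):
            FattyAcidMixingModel(mixed_consumers, predator_sources[:1])

    def test_prey_space_sources_rejected(self, prey_sources, mixed_consumers):
        with pytest.raises(ValueError, match="prey space"):
            FattyAcidMixingModel(mixed_consumers, prey_sources)

    def test_underdetermined_geometry_warns(self, mixed_consumers):
        fa = FA3[:1]
        sources = [
            SourceSummary(n, fa, [m], [1.0]) for n, m in [("a", 10), ("b", 20), ("c", 30)]
        ]
        pred = apply_ccs(sources, CCSet(fa, [1.0]))
        cons = simulate_consumers_from_summary([15.0], [1.0], n=4, seed=0, fa_names=fa)
        with pytest.warns(UserWarning, match="under-determined"):
            FattyAcidMixingModel(cons, pred)

    def test_missing_factor_is_an_error(self, predator_sources, mixed_consumers):
        with pytest.raises(KeyError, match="factor"):
            FattyAcidMixingModel(mixed_consumers, predator_sources, factor="day")

    def test_build_model_from_spec(self, predator_sources, mixed_consumers):
        spec = MixingModelSpec(sources=predator_sources)
        model = build_model(mixed_consumers, spec)
        assert model.K == 2 and model.J == 3

    def test_spec_rejects_nonzero_trophic_modification(self, predator_sources):
        with pytest.raises(ValueError, match="must be zero"):
            MixingModelSpec(
                sources=predator_sources, trophic_modification=np.array([1.0, 0, 0])
            )

    def test_spec_rejects_other_error_structures(self, predator_sources):
        with pytest.raises(ValueError, match="Residual"):
            MixingModelSpec(sources=predator_sources, error_structure="process_only")


class TestPosteriorContract:
    def test_simplex_closure_is_exact(self, toy_fit):
        K = toy_fit.model.K
        sums = toy_fit.p_draws().sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert np.all(toy_fit.p_draws() > 0)
        assert np.all(toy_fit.epsilon_draws() > 0)
        assert toy_fit.draws.shape[2] == toy_fit.model.L * K + toy_fit.model.J

    def test_seeded_fit_is_reproducible(self, mixed_consumers, predator_sources):
        def run():
            m = FattyAcidMixingModel(mixed_consumers, predator_sources)
            return m.fit(n_chains=2, n_iter=8000, n_burnin=4000, thin=10, seed=5)

        a, b = run(), run()
        np.testing.assert_array_equal(a.draws, b.draws)
        pd.testing.assert_frame_equal(a.summary(), b.summary())

    def test_summary_layout_and_export(self, toy_fit, tmp_path):
        df = toy_fit.summary()
        assert list(df.columns) == [
            "level", "source", "median", "q2.5", "q25", "q75", "q97.5", "mean", "sd",
        ]
        assert set(df["source"]) == {"krill", "herring"}
        assert np.all(df["q2.5"] <= df["median"]) and np.all(df["median"] <= df["q97.5"])
        toy_fit.to_csv(tmp_path / "summary.csv")
        back = pd.read_csv(tmp_path / "summary.csv")
        assert len(back) == len(df)
        text = toy_fit.summary_text()
        assert "posterior diet proportions" in text

    def test_draws_frame_is_chains_by_iterations(self, toy_fit):
        df = toy_fit.draws_to_frame()
        C, D, P = toy_fit.draws.shape
        assert len(df) == C * D
        assert df["chain"].nunique() == C
        assert list(df.columns[2:]) == toy_fit.param_names


class TestPosteriorCorrectness:
    def test_prior_only_fit_matches_dirichlet_closed_form(self, predator_sources):
        alpha = np.array([2.0, 1.0])
        model = FattyAcidMixingModel(None, predator_sources, prior_alpha=alpha)
        res = model.fit(n_chains=3, n_iter=150_000, n_burnin=50_000, thin=30, seed=2)
        P = res.p_draws()
        for k in range(2):
            marginal = stats.beta(alpha[k], alpha.sum() - alpha[k])
            got = np.percentile(P[:, k], [25, 50, 75])
            np.testing.assert_allclose(got, marginal.ppf([0.25, 0.5, 0.75]), atol=0.02)

    def test_identical_sources_return_the_prior(self):
        fa = FA3
        same = [
            SourceSummary(n, fa, [20.0, 30.0, 50.0], [2.0, 2.0, 2.0]) for n in "abc"
        ]
        pred = apply_ccs(same, CCSet(fa, np.ones(3)))
        cons = simulate_consumers_from_summary(
            [20.0, 30.0, 50.0], [2.0, 2.0, 2.0], n=6, seed=3, fa_names=fa
        )
        res = FattyAcidMixingModel(cons, pred).fit(
            n_chains=3, n_iter=100_000, n_burnin=50_000, thin=25, seed=4
        )
        med = res.median()
        # Dirichlet(1,1,1) marginal median is ~0.293
        for v in med.values():
            assert abs(v - 0.293) < 0.05

    def test_degenerate_identification_of_pure_diet(self, predator_sources):
        mu = predator_sources[0].means
        cons = simulate_consumers_from_summary(
            mu, np.full(3, 0.05), n=6, seed=6, fa_names=FA3
        )
        tight = [
            SourceSummary(s.source_name, FA3, s.means, np.full(3, 0.05))
            for s in predator_sources
        ]
        pred = apply_ccs(tight, CCSet(FA3, np.ones(3)))
        res = FattyAcidMixingModel(cons, pred).fit(
            n_chains=3, n_iter=80_000, n_burnin=40_000, thin=20, seed=7
        )
        assert res.median()["krill"] > 0.95

    def test_even_mixture_recovered(self, predator_sources):
        w = np.array([0.5, 0.5])
        mu = np.column_stack([s.means for s in predator_sources]) @ w
        sd = np.column_stack([s.sds for s in predator_sources]) @ w
        cons = simulate_consumers_from_summary(mu, sd * 0.3, n=10, seed=8, fa_names=FA3)
        res = FattyAcidMixingModel(cons, predator_sources).fit(
            n_chains=3, n_iter=100_000, n_burnin=50_000, thin=25, seed=9
        )
        assert res.median()["krill"] == pytest.approx(0.5, abs=0.05)

    def test_factor_levels_get_independent_diets(self, predator_sources):
        mu = np.column_stack([s.means for s in predator_sources])
        groups = {"0": np.array([0.9, 0.1]), "1": np.array([0.2, 0.8])}
        profiles = []
        for lev, w in groups.items():
            ds = simulate_consumers_from_summary(
                mu @ w, np.full(3, 0.5), n=6, seed=int(lev) + 10,
                fa_names=FA3, factor_labels={"day": lev},
            )
            profiles.extend(ds.profiles)
        from famix import ConsumerDataset

        cons = ConsumerDataset(profiles, ["day"])
        res = FattyAcidMixingModel(cons, predator_sources, factor="day").fit(
            n_chains=3, n_iter=100_000, n_burnin=50_000, thin=25, seed=11
        )
        assert res.median("0")["krill"] > 0.75
        assert res.median("1")["krill"] < 0.35

    def test_plot_posterior_returns_axes(self, toy_fit):
        import matplotlib

        matplotlib.use("Agg")
        ax = toy_fit.plot_posterior()
        assert ax.get_ylabel() == "diet proportion"
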