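import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import obslearn as ol
from obslearn.inference import (
    ChainConfig,
    ObservationalLearningModel,
    compare_models,
    compute_dic,
    native_to_unit,
    split_rhat,
    unit_to_native,
)


class TestTransforms:
    @pytest.mark.parametrize(
        "u,name,expected",
        [(0.5, "beta", 15.0), (0.0, "rho", 0.0), (1.0, "tau", 10.0), (0.25, "alpha", 0.25)],
    )
    def test_linear_map(self, u, name, expected):
        assert unit_to_native(u, name) == pytest.approx(expected)

    @given(st.floats(0.0, 1.0), st.sampled_from(["alpha", "kappa", "w", "beta", "rho", "tau", "upsilon"]))
    @settings(deadline=None)
    def test_round_trip_is_exact(self, u, name):
        assert native_to_unit(unit_to_native(u, name), name) == pytest.approx(u, abs=1e-12)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            unit_to_native(0.5, "gamma")


class TestChainConfig:
    def test_study_schedule_retains_18000_draws(self):
        assert ChainConfig.paper().n_retained == 18_000

    def test_reduced_schedule_arithmetic(self):
        assert ChainConfig(3, 400, 100, 5).n_retained == 180

    def test_non_integral_retention_rejected(self):
        with pytest.raises(ValueError, match="not integral"):
            ChainConfig(3, 401, 100, 5)

    def test_burnin_must_precede_end(self):
        with pytest.raises(ValueError):
            ChainConfig(3, 100, 100, 5)


def _mini_fit(toy_trials, micro_chains, model=3, seed=5):
    return ObservationalLearningModel(toy_trials, model, "choice").fit(
        micro_chains, seed=seed
    )


class TestFit:
    def test_requires_two_subjects(self, toy_trials):
        one = toy_trials[toy_trials["subject"] == "s00"]
        with pytest.raises(ValueError, match="at least 2 subjects"):
            ObservationalLearningModel(one, 1, "choice")

    def test_retained_draw_count_obeys_schedule(self, toy_trials, micro_chains):
        res = _mini_fit(toy_trials, micro_chains)
        assert res.n_retained == micro_chains.n_retained
        assert res.draws_unit.shape == (
            micro_chains.n_chains,
            micro_chains.n_retained_per_chain,
            2,
            len(res.model.free_params),
        )

    def test_subject_draws_within_native_ranges(self, toy_trials, micro_chains):
        res = _mini_fit(toy_trials, micro_chains)
        sub = res.subject_posterior_mean(native=True)
        from obslearn.models import PARAM_RANGES

        for name in res.model.free_params:
            lo, hi = PARAM_RANGES[name]
            assert sub[name].between(lo, hi).all()

    def test_fit_is_reproducible(self, toy_trials, micro_chains):
        r1 = _mini_fit(toy_trials, micro_chains, seed=9)
        r2 = _mini_fit(toy_trials, micro_chains, seed=9)
        np.testing.assert_array_equal(r1.draws_unit, r2.draws_unit)
        np.testing.assert_array_equal(r1.deviance, r2.deviance)

    def test_summary_has_all_free_parameters(self, toy_trials, micro_chains):
        res = _mini_fit(toy_trials, micro_chains)
        assert list(res.summary().index) == list(res.model.free_params)


class TestDic:
    def test_identity_holds(self, toy_trials, micro_chains):
        res = _mini_fit(toy_trials, micro_chains)
        fs = res.fit_summary()
        assert fs.dic == pytest.approx(fs.d_hat + 2 * fs.p_d)
        assert fs.dic == pytest.approx(fs.d_bar + fs.p_d)

    def test_degenerate_posterior_has_zero_effective_parameters(
        self, toy_trials, micro_chains
    ):
        res = _mini_fit(toy_trials, micro_chains)
        # collapse every draw onto one point: p_D must vanish and DIC = D-hat
        res.draws_unit[:] = res.draws_unit[0, 0]
        ll = res.model.loglike_unit(res.draws_unit[0, 0])
        res.deviance[:] = -2.0 * ll.sum()
        res._fit_summary = None
        fs = compute_dic(res)
        assert fs.p_d == pytest.approx(0.0, abs=1e-9)
        assert fs.dic == pytest.approx(fs.d_hat)

    def test_chain_order_invariance(self, toy_trials, micro_chains):
        res = _mini_fit(toy_trials, micro_chains)
        fs = res.fit_summary()
        perm = [1, 0]
        res2 = _mini_fit(toy_trials, micro_chains)
        res2.draws_unit = res2.draws_unit[perm]
        res2.deviance = res2.deviance[perm]
        res2._fit_summary = None
        fs2 = compute_dic(res2)
        assert fs2.d_bar == pytest.approx(fs.d_bar)
        assert fs2.d_hat == pytest.approx(fs.d_hat)

    def test_too_few_draws_rejected(self, toy_trials, micro_chains):
        res = _mini_fit(toy_trials, micro_chains)
        res.deviance = res.deviance[:1, :1]
        res.draws_unit = res.draws_unit[:1, :1]
        res._fit_summary = None
        with pytest.raises(ValueError, match="at least 2"):
            compute_dic(res)


class TestCompare:
    def test_ranking_and_winner(self, toy_trials, micro_chains):
        fits = [
            ObservationalLearningModel(toy_trials, m, "choice").fit(micro_chains, seed=3)
            for m in (1, 2)
        ]
        tab = compare_models(fits)
        assert list(tab["dic"]) == sorted(tab["dic"])
        assert tab["winner"].sum() == 1
        assert tab.loc[0, "winner"]
        assert tab.loc[0, "delta_dic"] == 0.0

    def test_mismatched_data_rejected(self, toy_trials, micro_chains, small_design):
        rng = np.random.default_rng(1)
        other = pd.concat(
            [
                ol.simulate_observer(1, ol.ParameterSet(), small_design, rng, subject=s)
                for s in ("a", "b")
            ]
        )
        f1 = ObservationalLearningModel(toy_trials, 1, "choice").fit(micro_chains, seed=1)
        f2 = ObservationalLearningModel(other, 2, "choice").fit(micro_chains, seed=1)
        with pytest.raises(ValueError, match="same data"):
            compare_models([f1, f2])


class TestRhat:
    def test_identical_chains_give_unity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        chains = np.stack([x, x, x])
        assert split_rhat(chains) == pytest.approx(1.0, abs=0.05)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = np.stack(
            [rng.standard_normal(200), rng.standard_normal(200) + 10.0]
        )
        assert split_rhat(chains) > 1.5


class TestShrinkage:
    def test_subject_estimates_shrink_toward_group_mean(self, small_design):
        """Hierarchical posterior means lie between the per-subject maximum
        likelihood estimate and the group mean (spot check on kappa)."""
        from scipy.optimize import minimize_scalar

        rng = np.random.default_rng(42)
        kappas = [0.15, 0.8]  # two deliberately extreme subjects
        tabs = []
        for i, k in enumerate(kappas):
            ps = ol.ParameterSet(kappa=k, beta=8.0, rho=0.0, tau=1.0)
            tabs.append(
                ol.simulate_observer(2, ps, small_design, rng, subject=f"s{i}")
            )
        trials = pd.concat(tabs, ignore_index=True)
        cc = ChainConfig(n_chains=2, n_iterations=2000, burn_in=500, thin=5)
        res = ObservationalLearningModel(trials, 2, "choice").fit(cc, seed=8)
        post = res.subject_posterior_mean()["kappa"]
        group = res.group_posterior_mean()["kappa"]

        def mle_kappa(table):
            def nll(k):
                ps = ol.ParameterSet(kappa=float(np.clip(k, 1e-4, 1)), beta=8.0,
                                     rho=0.0, tau=1.0)
                return ol.negative_log_likelihood(2, ps, table, "choice")

            return minimize_scalar(nll, bounds=(1e-3, 1.0), method="bounded").x

        for i in range(2):
            mle = mle_kappa(tabs[i])
            lo, hi = sorted([mle, group])
            assert lo - 0.12 <= post.iloc[i] <= hi + 0.12
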