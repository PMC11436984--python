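import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import obslearn as ol
from obslearn.models import (
    MODELS,
    LatentState,
    ParameterSet,
    get_model,
    negative_log_likelihood,
    observe_and_update,
    predictability_of,
    response_probability,
    update_acp,
)

from conftest import relabel_all_vertex


# ---------------------------------------------------------------------------
# independent brute-force likelihood (oracle): written directly from the
# model equations, structured unlike the package implementation
# ---------------------------------------------------------------------------

def naive_nll(model_id, p, trials, stream, alpha_dem=0.2, beta_dem=9.0):
    total = 0.0
    obs = trials[trials["condition"] != "individual"]
    for (site, cond, _blk), g in obs.groupby(["site", "condition", "block"], sort=True):
        g = g.sort_values("trial")
        qd = {0: 0.5, 1: 0.5}
        qo = {0: 0.5, 1: 0.5}
        qa = {0: 0.5, 1: 0.5}
        acp = 0.0
        last_choice = None
        last_pred = None
        w = 0.0 if cond.startswith("action_only") else p["w"]
        dm = site == "dmpfc"
        for _, row in g.iterrows():
            if not row["observation_absent"] and not pd.isna(row["dem_action"]):
                v1 = w * qo[1] + (1 - w) * qa[1]
                v0 = w * qo[0] + (1 - w) * qa[0]
                stick = p["rho"] * (
                    (1 if last_pred == 1 else 0) - (1 if last_pred == 0 else 0)
                )
                pa = 1 / (1 + math.exp(-(p["beta"] * (v1 - v0) + stick)))
                if stream == "prediction":
                    pr = int(row["prediction"])
                    total -= math.log(pa if pr == 1 else 1 - pa)
                if not pd.isna(row["prediction"]):
                    last_pred = int(row["prediction"])
                a = int(row["dem_action"])
                visible = bool(row["outcome_visible"]) and not pd.isna(row["dem_reward"])
                r_belief = float(row["dem_reward"]) if visible else 1.0
                qd[a] += alpha_dem * (r_belief - qd[a])
                p1 = 1 / (1 + math.exp(-beta_dem * (qd[1] - qd[0])))
                ent = 0.0
                for q in (p1, 1 - p1):
                    if q > 0:
                        ent -= q * math.log2(q)
                predv = 1 - ent
                if model_id >= 4:
                    acp += (p["upsilon"] / p["tau"] if dm else p["upsilon"]) * (predv - acp)
                if visible:
                    if model_id in (4, 6):
                        ro = acp
                    elif model_id in (1, 3) and dm:
                        ro = p["alpha"] / p["tau"]
                    else:
                        ro = p["alpha"]
                    qo[a] += ro * (float(row["dem_reward"]) - qo[a])
                if model_id in (5, 6):
                    ra = acp
                elif model_id in (2, 3) and dm:
                    ra = p["kappa"] / p["tau"]
                else:
                    ra = p["kappa"]
                qa[a] += ra * (1 - qa[a])
                qa[1 - a] += ra * (0 - qa[1 - a])
            v1 = w * qo[1] + (1 - w) * qa[1]
            v0 = w * qo[0] + (1 - w) * qa[0]
            stick = p["rho"] * (
                (1 if last_choice == 1 else 0) - (1 if last_choice == 0 else 0)
            )
            pc = 1 / (1 + math.exp(-(p["beta"] * (v1 - v0) + stick)))
            if stream == "choice":
                c = int(row["choice"])
                total -= math.log(pc if c == 1 else 1 - pc)
            last_choice = int(row["choice"])
    return total


PARAMS = dict(alpha=0.45, kappa=0.3, w=0.6, beta=7.0, rho=0.4, tau=2.5, upsilon=0.5)


class TestPredictability:
    def test_coin_flip_has_zero_predictability(self):
        assert predictability_of((0.5, 0.5)) == pytest.approx(0.0)

    def test_deterministic_demonstrator_is_fully_predictable(self):
        assert predictability_of((1.0, 0.0)) == pytest.approx(1.0)

    def test_skewed_distribution_matches_binary_entropy(self):
        h = -(0.9 * math.log2(0.9) + 0.1 * math.log2(0.1))
        assert predictability_of((0.9, 0.1)) == pytest.approx(1.0 - h)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            predictability_of((0.7, 0.7))
        with pytest.raises(ValueError):
            predictability_of((-0.1, 1.1))

    @given(st.floats(0.0, 1.0))
    @settings(deadline=None)
    def test_range_is_unit_interval(self, p1):
        assert 0.0 <= predictability_of((p1, 1.0 - p1)) <= 1.0 + 1e-12


class TestAcpUpdate:
    def test_zero_rate_freezes(self):
        assert update_acp(0.37, 0.9, 0.0, 2.0, "vertex") == pytest.approx(0.37)

    def test_one_step_arithmetic(self):
        assert update_acp(0.0, 0.5, 0.4, 1.0, "vertex") == pytest.approx(0.2)

    @given(
        st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0)
    )
    @settings(deadline=None)
    def test_tau_one_reduces_stimulated_to_control_update(self, acp, pred, ups):
        v = update_acp(acp, pred, ups, 1.0, "vertex")
        d = update_acp(acp, pred, ups, 1.0, "dmpfc")
        assert v == pytest.approx(d)

    def test_zero_tau_under_stimulation_rejected(self):
        with pytest.raises(ZeroDivisionError):
            update_acp(0.2, 0.5, 0.4, 0.0, "dmpfc")


class TestValueUpdates:
    def test_outcome_delta_rule_one_step(self):
        # alpha=0.5, Q=0.5, R=1 -> Q=0.75
        ps = ParameterSet(alpha=0.5)
        state = LatentState()
        observe_and_update(get_model(1), state, ps, action=1, reward=1.0, site="vertex")
        assert state.q_outcome[1] == pytest.approx(0.75)

    def test_direct_tau_scales_both_channels_tenfold(self):
        ps = ParameterSet(alpha=0.4, kappa=0.4, tau=10.0)
        sv, sd = LatentState(), LatentState()
        observe_and_update(get_model(3), sv, ps, 1, 1.0, "vertex")
        observe_and_update(get_model(3), sd, ps, 1, 1.0, "dmpfc")
        for ch in ("q_outcome", "q_action"):
            inc_v = getattr(sv, ch)[1] - 0.5
            inc_d = getattr(sd, ch)[1] - 0.5
            assert inc_d == pytest.approx(inc_v / 10.0)

    def test_zero_acp_freezes_action_channel(self):
        ps = ParameterSet(upsilon=0.5)
        state = LatentState()
        state.acp = 0.0
        observe_and_update(get_model(5), state, ps, 1, None, "vertex")
        assert state.q_action == [0.5, 0.5]


class TestResponseProbability:
    def test_symmetric_values_give_half(self):
        assert response_probability(0.3, 0.3, beta=5.0, rho=0.0) == pytest.approx(0.5)

    def test_scalar_logistic(self):
        # value difference 0.2 at beta 5 -> 1/(1+e^-1)
        p = response_probability(0.6, 0.4, beta=5.0, rho=0.0)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-1.0)))

    def test_flat_softmax(self):
        assert response_probability(0.9, 0.1, beta=0.0, rho=0.0) == pytest.approx(0.5)

    def test_positive_rho_is_sticky_by_default(self):
        p_stay = response_probability(0.5, 0.5, beta=5.0, rho=1.0, ca=1, cb=0)
        assert p_stay > 0.5
        p_repel = response_probability(0.5, 0.5, beta=5.0, rho=1.0, ca=1, cb=0, sticky=False)
        assert p_repel < 0.5


class TestLikelihood:
    def test_coin_flip_likelihood(self, toy_trials):
        ps = ParameterSet(beta=0.0, rho=0.0)
        sub = toy_trials[toy_trials["subject"] == "s00"]
        n = (sub["condition"] != "individual").sum()
        nll = negative_log_likelihood(1, ps, sub, "choice")
        assert nll == pytest.approx(n * math.log(2))

    @pytest.mark.parametrize("model_id", list(MODELS))
    @pytest.mark.parametrize("stream", ["choice", "prediction"])
    def test_matches_independent_brute_force(self, toy_trials, model_id, stream):
        ps = ParameterSet(**PARAMS)
        sub = toy_trials[toy_trials["subject"] == "s00"]
        mine = negative_log_likelihood(model_id, ps, sub, stream)
        oracle = naive_nll(model_id, PARAMS, sub, stream)
        assert mine == pytest.approx(oracle, rel=1e-10)

    @pytest.mark.parametrize("model_id", list(MODELS))
    def test_tau_one_makes_stimulation_site_irrelevant(self, toy_trials, model_id):
        ps = ParameterSet(**{**PARAMS, "tau": 1.0})
        sub = toy_trials[toy_trials["subject"] == "s00"]
        nll_mixed = negative_log_likelihood(model_id, ps, sub, "choice")
        nll_vertex = negative_log_likelihood(
            model_id, ps, relabel_all_vertex(sub), "choice"
        )
        assert nll_mixed == pytest.approx(nll_vertex, rel=1e-12)

    def test_model6_reduces_to_model5_without_outcome_channel(self, toy_trials):
        """On Action-Only data the outcome channel never updates, so the
        predictability-both model follows predictability-action exactly
        (likewise action-outcome reduces to the action model)."""
        ps = ParameterSet(**PARAMS)
        sub = toy_trials[
            (toy_trials["subject"] == "s00")
            & toy_trials["condition"].str.startswith("action_only")
        ]
        for stream in ("choice", "prediction"):
            assert negative_log_likelihood(6, ps, sub, stream) == pytest.approx(
                negative_log_likelihood(5, ps, sub, stream), rel=1e-12
            )
            assert negative_log_likelihood(3, ps, sub, stream) == pytest.approx(
                negative_log_likelihood(2, ps, sub, stream), rel=1e-12
            )

    @pytest.mark.parametrize("dead", [{"alpha": 0.05}, {"alpha": 0.95}, {"w": 0.1}, {"w": 0.9}])
    def test_alpha_and_w_are_dead_in_action_only(self, toy_trials, dead):
        ps0 = ParameterSet(**PARAMS)
        ps1 = ParameterSet(**{**PARAMS, **dead})
        sub = toy_trials[
            (toy_trials["subject"] == "s00")
            & toy_trials["condition"].str.startswith("action_only")
        ]
        assert negative_log_likelihood(2, ps0, sub, "choice") == pytest.approx(
            negative_log_likelihood(2, ps1, sub, "choice"), rel=1e-12
        )

    def test_true_parameters_beat_random_perturbations(self, design):
        """Simulation oracle: at large N the generating parameters have lower
        negative log-likelihood than randomly perturbed parameter sets."""
        gen = ParameterSet(alpha=0.4, w=0.5, beta=8.0, rho=0.3, tau=4.0, upsilon=0.5)
        rng = np.random.default_rng(17)
        tabs = [
            ol.simulate_observer(5, gen, design, rng, subject=f"s{i}") for i in range(6)
        ]
        nll_true = sum(negative_log_likelihood(5, gen, t, "choice") for t in tabs)
        rng_p = np.random.default_rng(99)
        worse = 0
        for _ in range(20):
            pert = ParameterSet(
                alpha=float(rng_p.uniform(0, 1)),
                w=float(rng_p.uniform(0, 1)),
                beta=float(rng_p.uniform(0, 30)),
                rho=float(rng_p.uniform(0, 3)),
                tau=float(rng_p.uniform(0.5, 10)),
                upsilon=float(rng_p.uniform(0, 1)),
            )
            nll_p = sum(negative_log_likelihood(5, pert, t, "choice") for t in tabs)
            worse += nll_p >= nll_true
        assert worse == 20

    def test_missing_response_raises(self, toy_trials):
        sub = toy_trials[toy_trials["subject"] == "s00"].copy()
        sub.loc[sub.index[5], "choice"] = pd.NA
        with pytest.raises(ValueError, match="missing choice"):
            negative_log_likelihood(1, ParameterSet(), sub, "choice")

    @given(
        st.integers(1, 6),
        st.floats(0.01, 1.0),
        st.floats(0.0, 1.0),
        st.floats(0.0, 30.0),
        st.floats(0.0, 3.0),
        st.floats(1.0, 10.0),
        st.floats(0.0, 1.0),
        st.integers(0, 10_000),
    )
    @settings(deadline=None, max_examples=40)
    def test_probabilities_and_latents_stay_finite(
        self, model_id, alpha, kappa, beta, rho, tau, upsilon, seed
    ):
        """Fuzz: with tau >= 1 (effective rates <= 1) no latent quantity goes
        NaN and all response probabilities stay inside (0, 1)."""
        d = ol.build_design(
            subsessions_per_visit=1, blocks_per_condition_per_subsession=1
        )
        ps = ParameterSet(
            alpha=alpha, kappa=kappa, w=0.5, beta=beta, rho=rho, tau=tau, upsilon=upsilon
        )
        df = ol.simulate_observer(model_id, ps, d, np.random.default_rng(seed),
                                  sites=("vertex", "dmpfc"))
        nll, trace = negative_log_likelihood(model_id, ps, df, "choice", return_trace=True)
        assert math.isfinite(nll)
        assert trace["p_choice"].between(0, 1, inclusive="neither").all()
        assert not trace["acp"].isna().any()


class TestParameterSet:
    @pytest.mark.parametrize("bad", [{"alpha": -0.1}, {"beta": 31}, {"rho": 3.5}, {"tau": 11}])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            ParameterSet(**bad)

    def test_free_parameters_per_model(self):
        assert set(get_model(1).free_params) == {"alpha", "kappa", "w", "beta", "rho", "tau"}
        assert set(get_model(5).free_params) == {"alpha", "w", "beta", "rho", "tau", "upsilon"}
        assert set(get_model(6).free_params) == {"w", "beta", "rho", "tau", "upsilon"}
        assert len(MODELS) == 6
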