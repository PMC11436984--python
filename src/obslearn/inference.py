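"""Hierarchical Bayesian estimation and DIC model comparison.

Subject-level parameters live on the unit interval and are mapped linearly
onto their native ranges ([0,1] for learning rates and the channel weight,
[0,30] for the softmax temperature, [0,3] for perseverance, [0,10] for the
stimulation divisor).  Each unit-scale parameter is drawn from a group-level
beta distribution parameterized by a mean m and precision s (shape a = m*s,
b = (1-m)*s), with uniform hyperpriors m ~ U(0.001, 0.999) and
s ~ U(0.001, 10).

Sampling is Metropolis-within-Gibbs: component-wise Gaussian random-walk
proposals on the unit-scale subject parameters (vectorized across subjects,
which are conditionally independent given the hyperparameters) and
random-walk steps on each beta mean and precision.  Proposal scales adapt
toward a ~35% acceptance rate during burn-in only, so the post-burn-in chain
is a valid fixed-kernel MCMC.  Model comparison uses the Deviance
Information Criterion, DIC = D(θ̄) + 2 p_D = D̄ + p_D with
p_D = D̄ − D(θ̄); smaller is better.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln

from . import _core
from .models import MODELS, PARAM_NAMES, PARAM_RANGES, ModelSpec, get_model
from .belief import FIXED_ALPHA_DEM, FIXED_BETA_DEM

__all__ = [
    "unit_to_native",
    "native_to_unit",
    "PriorSpec",
    "ChainConfig",
    "FitSummary",
    "ObservationalLearningModel",
    "FitResults",
    "compute_dic",
    "compare_models",
    "split_rhat",
]


def unit_to_native(u, name: str):
    """Map a unit-interval value onto the parameter's native range."""
    if name not in PARAM_RANGES:
        raise KeyError(f"unknown parameter {name!r}")
    lo, hi = PARAM_RANGES[name]
    return lo + (hi - lo) * np.asarray(u, dtype=float)


def native_to_unit(x, name: str):
    """Exact inverse of :func:`unit_to_native`."""
    if name not in PARAM_RANGES:
        raise KeyError(f"unknown parameter {name!r}")
    lo, hi = PARAM_RANGES[name]
    return (np.asarray(x, dtype=float) - lo) / (hi - lo)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperprior bounds for the group-level beta distributions."""

    mean_bounds: tuple[float, float] = (0.001, 0.999)
    precision_bounds: tuple[float, float] = (0.001, 10.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_bounds[0] < self.mean_bounds[1] < 1.0:
            raise ValueError("mean bounds must satisfy 0 < lo < hi < 1")
        if not 0.0 < self.precision_bounds[0] < self.precision_bounds[1]:
            raise ValueError("precision bounds must be positive and ordered")


@dataclass(frozen=True)
class ChainConfig:
    """MCMC schedule. The study schedule is 3 chains x 40,000 iterations,
    10,000 burn-in, thinning 5 → 18,000 retained draws per parameter."""

    n_chains: int = 3
    n_iterations: int = 40_000
    burn_in: int = 10_000
    thin: int = 5

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_iterations, self.thin) < 1 or self.burn_in < 0:
            raise ValueError("chain counts must be positive")
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if (self.n_iterations - self.burn_in) % self.thin != 0:
            raise ValueError(
                f"retained count per chain ({self.n_iterations - self.burn_in}"
                f"/{self.thin}) is not integral"
            )

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @property
    def n_retained(self) -> int:
        return self.n_chains * self.n_retained_per_chain

    @classmethod
    def paper(cls) -> "ChainConfig":
        return cls()

    @classmethod
    def reduced(cls) -> "ChainConfig":
        """Desk-scale schedule used by default in tests and examples."""
        return cls(n_chains=3, n_iterations=4_000, burn_in=1_000, thin=5)


@dataclass(frozen=True)
class FitSummary:
    """Deviance bookkeeping: DIC = d_hat + 2 p_d = d_bar + p_d."""

    d_bar: float
    d_hat: float

    @property
    def p_d(self) -> float:
        return self.d_bar - self.d_hat

    @property
    def dic(self) -> float:
        return self.d_bar + self.p_d


def split_rhat(chains: np.ndarray) -> float:
    """Split-R̂ convergence diagnostic for one scalar quantity.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half
    before computing the classic potential-scale-reduction factor.
    """
    c, n = chains.shape
    half = n // 2
    if half < 2:
        return float("nan")
    seqs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = seqs.shape
    means = seqs.mean(axis=1)
    w = seqs.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# data packing
# ---------------------------------------------------------------------------

def _compute_pred_val(arrays: dict, alpha_dem: float, beta_dem: float) -> np.ndarray:
    """Per-trial predictability (1 − entropy of the simulated demonstrator
    choice distribution), replayed once at pack time.

    The internal simulation has no subject-level parameters (its learning
    rate and temperature are fixed by the grid search), so this trajectory
    depends only on the data and can be shared across all likelihood
    evaluations.  Uses the same :mod:`obslearn.belief` /
    :func:`obslearn.models.predictability_of` code path as the pure-Python
    likelihood, so the two implementations agree exactly.
    """
    from .belief import DemonstratorBelief, step_belief
    from .models import predictability_of

    n = arrays["block_code"].shape[0]
    out = np.full(n, np.nan)
    belief = None
    cur_block = None
    for t in range(n):
        if arrays["block_code"][t] != cur_block:
            cur_block = arrays["block_code"][t]
            belief = DemonstratorBelief(alpha=alpha_dem, beta=beta_dem)
        if arrays["obs_absent"][t] == 0 and arrays["dem_action"][t] >= 0:
            a = int(arrays["dem_action"][t])
            r = arrays["dem_reward"][t]
            belief, _ = step_belief(belief, a, float(r) if r >= 0 else 1.0)
            p1 = belief.p_better
            out[t] = predictability_of((1.0 - p1, p1))
    return out


def _pack_trials(trials: pd.DataFrame, stream: str):
    obs = trials[trials["condition"] != "individual"].copy()
    if obs.empty:
        raise ValueError("no observational-condition trials to fit")
    obs = obs.sort_values(["subject", "site", "condition", "block", "trial"], kind="mergesort")
    subjects = list(pd.unique(obs["subject"]))
    if obs["choice"].isna().any():
        bad = obs.index[obs["choice"].isna()][0]
        raise ValueError(f"missing choice response at row {bad}")
    if stream == "prediction":
        scored = ~obs["observation_absent"].astype(bool)
        if obs.loc[scored, "prediction"].isna().any():
            bad = obs.index[scored & obs["prediction"].isna()][0]
            raise ValueError(f"missing prediction response at row {bad}")

    block_key = (
        obs["subject"].astype(str)
        + "|" + obs["site"].astype(str)
        + "|" + obs["condition"].astype(str)
        + "|" + obs["block"].astype(str)
    )
    block_code = pd.factorize(block_key)[0].astype(np.int32)
    visible = obs["outcome_visible"].astype(bool).to_numpy()
    dem_reward = obs["dem_reward"].fillna(-1).to_numpy(dtype=np.int8)
    dem_reward = np.where(visible, dem_reward, -1).astype(np.int8)

    arrays = {
        "block_code": block_code,
        "is_dmpfc": (obs["site"] == "dmpfc").to_numpy(dtype=np.uint8),
        "action_only": obs["condition"].str.startswith("action_only").to_numpy(dtype=np.uint8),
        "obs_absent": obs["observation_absent"].astype(bool).to_numpy(dtype=np.uint8),
        "dem_action": obs["dem_action"].fillna(-1).to_numpy(dtype=np.int8),
        "dem_reward": dem_reward,
        "prediction": obs["prediction"].fillna(-1).to_numpy(dtype=np.int8),
        "choice": obs["choice"].fillna(-1).to_numpy(dtype=np.int8),
    }
    counts = obs.groupby("subject", sort=False).size().reindex(pd.unique(obs["subject"]))
    offsets = np.zeros(len(subjects) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum(counts.to_numpy())
    return subjects, offsets, arrays


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------

class ObservationalLearningModel:
    """One observational-learning model bound to a multi-subject trial table.

    Parameters
    ----------
    trials
        Trial table (schema of :mod:`obslearn.io`) containing every subject,
        both stimulation sites, and at least the observational conditions
        (individual-learning trials are dropped automatically).
    model
        Model id 1-6, name, or :class:`~obslearn.models.ModelSpec`.
    stream
        Which behavior to fit: ``"choice"`` (choices for self) or
        ``"prediction"`` (predictions of the demonstrator's action).

    Examples
    --------
    >>> mod = ObservationalLearningModel(trials, model=5, stream="choice")
    >>> res = mod.fit(ChainConfig.reduced(), seed=7)
    >>> res.summary()
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        model: int | str | ModelSpec,
        stream: str = "choice",
        priors: PriorSpec = PriorSpec(),
        *,
        sticky: bool = True,
        alpha_dem: float = FIXED_ALPHA_DEM,
        beta_dem: float = FIXED_BETA_DEM,
    ) -> None:
        if stream not in ("choice", "prediction"):
            raise ValueError(f"stream must be 'choice' or 'prediction', got {stream!r}")
        self.spec = get_model(model)
        self.stream = stream
        self.priors = priors
        self.sticky = sticky
        self.alpha_dem = float(alpha_dem)
        self.beta_dem = float(beta_dem)
        self.subjects, self._offsets, self._arrays = _pack_trials(trials, stream)
        if len(self.subjects) < 2:
            raise ValueError("hierarchical estimation requires at least 2 subjects")
        self.free_params = self.spec.free_params
        self._free_idx = np.array([PARAM_NAMES.index(p) for p in self.free_params])
        h = hashlib.sha256()
        for key in sorted(self._arrays):
            h.update(self._arrays[key].tobytes())
        h.update(np.asarray(self._offsets).tobytes())
        h.update(stream.encode())
        self.data_hash = h.hexdigest()
        self._arrays["pred_val"] = _compute_pred_val(
            self._arrays, self.alpha_dem, self.beta_dem
        )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    # -- likelihood ---------------------------------------------------------

    def _native_matrix(self, unit: np.ndarray) -> np.ndarray:
        """(n_subj, n_free) unit draws → full (n_subj, 7) native matrix."""
        full = np.zeros((unit.shape[0], len(PARAM_NAMES)))
        for k, name in enumerate(self.free_params):
            full[:, self._free_idx[k]] = unit_to_native(unit[:, k], name)
        return full

    def loglike_native(self, native: np.ndarray) -> np.ndarray:
        """Per-subject log-likelihood at native-scale parameters (n_subj, 7)."""
        stream_id = _core.STREAM_CHOICE if self.stream == "choice" else _core.STREAM_PREDICTION
        return _core.batch_loglik(
            self.spec.id,
            stream_id,
            np.ascontiguousarray(native, dtype=np.float64),
            self._offsets,
            self._arrays["block_code"],
            self._arrays["is_dmpfc"],
            self._arrays["action_only"],
            self._arrays["obs_absent"],
            self._arrays["dem_action"],
            self._arrays["dem_reward"],
            self._arrays["prediction"],
            self._arrays["choice"],
            self._arrays["pred_val"],
            1.0 if self.sticky else -1.0,
        )

    def loglike_unit(self, unit: np.ndarray) -> np.ndarray:
        return self.loglike_native(self._native_matrix(unit))

    # -- sampling -----------------------------------------------------------

    def fit(
        self,
        chain_config: ChainConfig | None = None,
        seed: int = 0,
        *,
        init_retries: int = 20,
    ) -> "FitResults":
        """Run the Metropolis-within-Gibbs sampler and return the results."""
        cc = chain_config or ChainConfig.reduced()
        n_free = len(self.free_params)
        n_subj = self.n_subjects
        mean_lo, mean_hi = self.priors.mean_bounds
        prec_lo, prec_hi = self.priors.precision_bounds

        n_keep = cc.n_retained_per_chain
        draws_u = np.empty((cc.n_chains, n_keep, n_subj, n_free))
        draws_m = np.empty((cc.n_chains, n_keep, n_free))
        draws_s = np.empty((cc.n_chains, n_keep, n_free))
        deviance = np.empty((cc.n_chains, n_keep))

        for chain in range(cc.n_chains):
            rng = np.random.default_rng([int(seed), chain])
            # --- initialization (restart on non-finite likelihood)
            for attempt in range(init_retries):
                m = rng.uniform(0.2, 0.8, n_free)
                s = rng.uniform(2.0, 8.0, n_free)
                u = rng.beta(m * s, (1 - m) * s, size=(n_subj, n_free))
                u = np.clip(u, 1e-4, 1 - 1e-4)
                ll = self.loglike_unit(u)
                if np.all(np.isfinite(ll)):
                    break
            else:
                raise RuntimeError(
                    f"chain {chain}: no finite-likelihood initialization "
                    f"in {init_retries} attempts"
                )

            sd_u = np.full(n_free, 0.15)
            sd_m = np.full(n_free, 0.08)
            sd_s = np.full(n_free, 0.8)
            acc_u = np.zeros(n_free)
            acc_m = np.zeros(n_free)
            acc_s = np.zeros(n_free)
            tick = 0
            keep = 0

            hi_vec = np.array([PARAM_RANGES[p][1] for p in self.free_params])
            stream_id = (
                _core.STREAM_CHOICE if self.stream == "choice" else _core.STREAM_PREDICTION
            )
            arr = self._arrays

            for it in range(cc.n_iterations):
                a_vec = m * s
                b_vec = (1 - m) * s
                # --- subject-level updates (numba sweep, in-place on u, ll)
                normals = rng.standard_normal((n_free, n_subj))
                unifs = rng.random((n_free, n_subj))
                acc_u += _core.sweep_subject_params(
                    self.spec.id,
                    stream_id,
                    u,
                    ll,
                    a_vec,
                    b_vec,
                    self._free_idx,
                    hi_vec,
                    sd_u,
                    normals,
                    unifs,
                    self._offsets,
                    arr["block_code"],
                    arr["is_dmpfc"],
                    arr["action_only"],
                    arr["obs_absent"],
                    arr["dem_action"],
                    arr["dem_reward"],
                    arr["prediction"],
                    arr["choice"],
                    arr["pred_val"],
                    1.0 if self.sticky else -1.0,
                )

                # --- hyperparameter updates
                sum_lu = np.log(u).sum(axis=0)
                sum_l1mu = np.log1p(-u).sum(axis=0)
                for j in range(n_free):
                    a_j, b_j = m[j] * s[j], (1 - m[j]) * s[j]
                    lp_cur = (
                        (a_j - 1) * sum_lu[j]
                        + (b_j - 1) * sum_l1mu[j]
                        - n_subj * betaln(a_j, b_j)
                    )
                    m_new = m[j] + sd_m[j] * rng.standard_normal()
                    if mean_lo < m_new < mean_hi:
                        a_n, b_n = m_new * s[j], (1 - m_new) * s[j]
                        lp_new = (
                            (a_n - 1) * sum_lu[j]
                            + (b_n - 1) * sum_l1mu[j]
                            - n_subj * betaln(a_n, b_n)
                        )
                        if np.log(rng.random()) < lp_new - lp_cur:
                            m[j] = m_new
                            lp_cur = lp_new
                            acc_m[j] += 1
                    s_new = s[j] + sd_s[j] * rng.standard_normal()
                    if prec_lo < s_new < prec_hi:
                        a_n, b_n = m[j] * s_new, (1 - m[j]) * s_new
                        lp_new = (
                            (a_n - 1) * sum_lu[j]
                            + (b_n - 1) * sum_l1mu[j]
                            - n_subj * betaln(a_n, b_n)
                        )
                        if np.log(rng.random()) < lp_new - lp_cur:
                            s[j] = s_new
                            acc_s[j] += 1

                # --- proposal adaptation, burn-in only
                tick += 1
                if it < cc.burn_in and tick == 50:
                    sd_u *= np.exp(acc_u / tick - 0.35)
                    sd_m *= np.exp(acc_m / tick - 0.35)
                    sd_s *= np.exp(acc_s / tick - 0.35)
                    np.clip(sd_u, 1e-3, 1.0, out=sd_u)
                    np.clip(sd_m, 1e-3, 0.5, out=sd_m)
                    np.clip(sd_s, 1e-2, 5.0, out=sd_s)
                    acc_u[:] = acc_m[:] = acc_s[:] = 0.0
                    tick = 0

                if it >= cc.burn_in and (it - cc.burn_in) % cc.thin == 0:
                    draws_u[chain, keep] = u
                    draws_m[chain, keep] = m
                    draws_s[chain, keep] = s
                    deviance[chain, keep] = -2.0 * ll.sum()
                    keep += 1

        return FitResults(
            model=self,
            chain_config=cc,
            seed=int(seed),
            draws_unit=draws_u,
            draws_group_mean=draws_m,
            draws_group_precision=draws_s,
            deviance=deviance,
        )


@dataclass
class FitResults:
    """Posterior draws and deviance bookkeeping for one fitted model.

    Draw arrays keep the chain axis: ``draws_unit`` has shape
    (n_chains, n_draws, n_subjects, n_free); flattened accessors concatenate
    chains (the order is irrelevant for every reported quantity).
    """

    model: ObservationalLearningModel
    chain_config: ChainConfig
    seed: int
    draws_unit: np.ndarray
    draws_group_mean: np.ndarray
    draws_group_precision: np.ndarray
    deviance: np.ndarray
    _fit_summary: FitSummary | None = field(default=None, repr=False)

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def n_retained(self) -> int:
        return int(np.prod(self.deviance.shape))

    def subject_posterior_mean(self, native: bool = True) -> pd.DataFrame:
        """Posterior-mean subject parameters (rows: subjects, cols: params)."""
        mean_u = self.draws_unit.reshape(-1, *self.draws_unit.shape[2:]).mean(axis=0)
        out = {}
        for k, name in enumerate(self.model.free_params):
            out[name] = unit_to_native(mean_u[:, k], name) if native else mean_u[:, k]
        return pd.DataFrame(out, index=self.model.subjects)

    def group_posterior_mean(self, native: bool = True) -> pd.Series:
        mean_m = self.draws_group_mean.reshape(-1, self.draws_group_mean.shape[-1]).mean(axis=0)
        vals = {}
        for k, name in enumerate(self.model.free_params):
            vals[name] = float(unit_to_native(mean_m[k], name)) if native else float(mean_m[k])
        return pd.Series(vals)

    def hyper_rhat(self) -> pd.DataFrame:
        rows = {}
        for k, name in enumerate(self.model.free_params):
            rows[name] = {
                "rhat_mean": split_rhat(self.draws_group_mean[:, :, k]),
                "rhat_precision": split_rhat(self.draws_group_precision[:, :, k]),
            }
        return pd.DataFrame(rows).T

    def fit_summary(self) -> FitSummary:
        if self._fit_summary is None:
            self._fit_summary = compute_dic(self)
        return self._fit_summary

    @property
    def dic(self) -> float:
        rhat = self.hyper_rhat()
        worst = np.nanmax(rhat.to_numpy())
        if worst > 1.05:
            warnings.warn(
                f"hyperparameter split-R-hat up to {worst:.3f} (> 1.05); "
                "DIC may be unreliable",
                RuntimeWarning,
                stacklevel=2,
            )
        return self.fit_summary().dic

    def summary(self) -> pd.DataFrame:
        """Group-level posterior summary on the native scale, plus diagnostics."""
        flat_m = self.draws_group_mean.reshape(-1, self.draws_group_mean.shape[-1])
        rhat = self.hyper_rhat()
        rows = []
        for k, name in enumerate(self.model.free_params):
            native = unit_to_native(flat_m[:, k], name)
            rows.append(
                {
                    "parameter": name,
                    "group_mean": native.mean(),
                    "sd": native.std(ddof=1),
                    "hdi_2.5%": np.percentile(native, 2.5),
                    "hdi_97.5%": np.percentile(native, 97.5),
                    "rhat": rhat.loc[name, "rhat_mean"],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def draws_long(self) -> pd.DataFrame:
        """Retained subject-level draws in long (tidy) format."""
        c, d, n, p = self.draws_unit.shape
        recs = []
        for k, name in enumerate(self.model.free_params):
            native = unit_to_native(self.draws_unit[..., k], name)
            for chain in range(c):
                for subj_i, subj in enumerate(self.model.subjects):
                    recs.append(
                        pd.DataFrame(
                            {
                                "chain": chain,
                                "draw": np.arange(d),
                                "subject": subj,
                                "parameter": name,
                                "value": native[chain, :, subj_i],
                            }
                        )
                    )
        return pd.concat(recs, ignore_index=True)


def compute_dic(results: FitResults) -> FitSummary:
    """Deviance bookkeeping from retained draws.

    D̄ is the posterior-mean deviance; D̂ is the deviance at the posterior
    means of the unit-scale subject parameters (transform-consistent and
    bounded); p_D = D̄ − D̂ and DIC = D̄ + p_D.
    """
    if results.n_retained < 2:
        raise ValueError("DIC requires at least 2 retained draws")
    d_bar = float(results.deviance.mean())
    mean_u = results.draws_unit.reshape(-1, *results.draws_unit.shape[2:]).mean(axis=0)
    ll_hat = results.model.loglike_unit(mean_u)
    d_hat = float(-2.0 * ll_hat.sum())
    return FitSummary(d_bar=d_bar, d_hat=d_hat)


def compare_models(results: list[FitResults]) -> pd.DataFrame:
    """Rank fitted models by DIC (ascending; lower fits better).

    All fits must be on the same data and stream (checked via data hash).
    Ties are broken by model id and flagged.
    """
    if not results:
        raise ValueError("nothing to compare")
    h0 = results[0].model.data_hash
    for r in results[1:]:
        if r.model.data_hash != h0:
            raise ValueError("fits were not computed on the same data/stream")
    rows = []
    for r in results:
        fs = r.fit_summary()
        rows.append(
            {
                "model": r.spec.id,
                "name": r.spec.name,
                "d_bar": fs.d_bar,
                "d_hat": fs.d_hat,
                "p_d": fs.p_d,
                "dic": fs.dic,
            }
        )
    tab = pd.DataFrame(rows).sort_values(["dic", "model"], kind="mergesort").reset_index(drop=True)
    tab["delta_dic"] = tab["dic"] - tab["dic"].iloc[0]
    tab["winner"] = False
    tab.loc[0, "winner"] = True
    tab["tied"] = tab["dic"].duplicated(keep=False)
    return tab
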