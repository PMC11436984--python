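"""Validity checks as runnable experiments.

* :func:`parameter_recovery` — simulate data from known parameters, refit,
  and correlate generating with recovered values.
* :func:`model_recovery` — simulate from each model, fit all candidates,
  and tabulate DIC winners into a confusion matrix.
* :func:`stimulation_effect_simulation` — compare behavior generated with
  tau = 1 (no stimulation effect) against tau > 1.
* :func:`behavior_summaries` — model-free condition summaries, paired
  vertex-minus-dmpfc differences, and parameter/behavior correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .inference import ChainConfig, ObservationalLearningModel, compare_models, unit_to_native
from .models import MODELS, PARAM_RANGES, ParameterSet, get_model
from .task import ExperimentDesign, build_design, simulate_observer

__all__ = [
    "RecoveryReport",
    "ConfusionMatrix",
    "parameter_recovery",
    "model_recovery",
    "stimulation_effect_simulation",
    "behavior_summaries",
    "DEFAULT_GENERATING_MEANS",
]

#: Unit-scale group means used when no fitted posterior is available to draw
#: generating parameters from (realistic mid-range reinforcement-learning
#: values; tau defaults to its no-effect value 1).
DEFAULT_GENERATING_MEANS = {
    "alpha": 0.35,
    "kappa": 0.35,
    "w": 0.5,
    "beta": 0.2,      # native 6
    "rho": 0.1,       # native 0.3
    "tau": 0.1,       # native 1 (no stimulation effect)
    "upsilon": 0.4,
}

#: Spread (beta precision) of subject draws around a group mean.
SUBJECT_PRECISION = 10.0


def _draw_subject_units(
    means: np.ndarray, n_subjects: int, rng: np.random.Generator, precision: float = SUBJECT_PRECISION
) -> np.ndarray:
    a = means * precision
    b = (1.0 - means) * precision
    u = rng.beta(a, b, size=(n_subjects, means.size))
    return np.clip(u, 0.001, 0.999)


def _params_from_units(free_names, units_row, stream) -> ParameterSet:
    kwargs = {"stream": stream}
    for name, u in zip(free_names, units_row):
        kwargs[name] = float(unit_to_native(u, name))
    return ParameterSet(**kwargs)


@dataclass
class RecoveryReport:
    """Parameter-recovery outcome: per-parameter Pearson r plus scatter pairs."""

    model_id: int
    stream: str
    correlations: pd.Series
    pairs: pd.DataFrame
    n_instances: int
    n_subjects: int
    seed: int
    failed_instances: list = field(default_factory=list)

    @property
    def min_r(self) -> float:
        return float(self.correlations.min())


def parameter_recovery(
    model: int | str = 5,
    n_instances: int = 10,
    n_subjects: int = 30,
    chain_config: ChainConfig | None = None,
    seed: int = 0,
    *,
    stream: str = "choice",
    design: ExperimentDesign | None = None,
    subject_precision: float = SUBJECT_PRECISION,
) -> RecoveryReport:
    """Simulate, refit, and correlate generating vs recovered parameters.

    Instances cover the parameter space via a Latin hypercube over the
    unit-scale group means (each instance is one synthetic group study of
    ``n_subjects``); subjects scatter around each instance's means with a
    beta distribution of precision ``subject_precision``.  Recovered values
    are posterior-mean subject parameters; correlations pool the
    (generating, recovered) pairs across all instances.  Instances whose fit
    fails are recorded and excluded, never silently dropped.
    """
    spec = get_model(model)
    design = design or build_design()
    cc = chain_config or ChainConfig.reduced()
    free = spec.free_params
    rng = np.random.default_rng([int(seed), 101])
    lhs = qmc.LatinHypercube(d=len(free), seed=int(seed) % (2**31 - 1))
    # keep group means away from the degenerate edges of the unit cube
    instance_means = 0.05 + 0.90 * lhs.random(n_instances)

    gen_rows = []
    rec_rows = []
    failed = []
    for inst in range(n_instances):
        units = _draw_subject_units(instance_means[inst], n_subjects, rng, subject_precision)
        tables = []
        for i in range(n_subjects):
            ps = _params_from_units(free, units[i], stream)
            tables.append(
                simulate_observer(
                    spec.id, ps, design, rng, subject=f"i{inst:02d}s{i:02d}"
                )
            )
        trials = pd.concat(tables, ignore_index=True)
        try:
            fit = ObservationalLearningModel(trials, spec.id, stream).fit(
                cc, seed=int(seed) + 1000 + inst
            )
        except Exception as err:  # recorded, never silent
            warnings.warn(f"instance {inst} failed to fit: {err}", RuntimeWarning, stacklevel=2)
            failed.append((inst, str(err)))
            continue
        recovered = fit.subject_posterior_mean(native=True)
        for k, name in enumerate(free):
            gen_native = unit_to_native(units[:, k], name)
            for i in range(n_subjects):
                gen_rows.append(
                    {"instance": inst, "subject": i, "parameter": name,
                     "generating": gen_native[i]}
                )
                rec_rows.append(recovered.iloc[i][name])
    pairs = pd.DataFrame(gen_rows)
    pairs["recovered"] = rec_rows
    corrs = {}
    for name in free:
        sub = pairs[pairs["parameter"] == name]
        if sub["generating"].nunique() <= 1 or sub["recovered"].nunique() <= 1:
            corrs[name] = float("nan")
            warnings.warn(
                f"correlation undefined for {name} (constant vector)",
                RuntimeWarning,
                stacklevel=2,
            )
        else:
            corrs[name] = stats.pearsonr(sub["generating"], sub["recovered"])[0]
    return RecoveryReport(
        model_id=spec.id,
        stream=stream,
        correlations=pd.Series(corrs),
        pairs=pairs,
        n_instances=n_instances,
        n_subjects=n_subjects,
        seed=int(seed),
        failed_instances=failed,
    )


@dataclass
class ConfusionMatrix:
    """Generating-model x best-fitting-model counts over simulation runs."""

    counts: pd.DataFrame

    @property
    def proportions(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)


def model_recovery(
    model_ids=tuple(MODELS),
    n_sims_per_model: int = 10,
    chain_config: ChainConfig | None = None,
    seed: int = 0,
    *,
    stream: str = "choice",
    design: ExperimentDesign | None = None,
    n_subjects: int = 30,
    generating_means: dict | None = None,
    fit_model_ids=None,
) -> ConfusionMatrix:
    """Fit all candidate models to data generated by each model in turn.

    Generating parameters are posterior-like beta draws around
    ``generating_means`` (defaults to :data:`DEFAULT_GENERATING_MEANS` with a
    clear stimulation effect, tau = 5, so the stimulation mechanism is
    expressed in the data).  Each simulation's winner is the DIC-minimal fit.
    """
    design = design or build_design()
    cc = chain_config or ChainConfig.reduced()
    fit_ids = tuple(fit_model_ids) if fit_model_ids is not None else tuple(model_ids)
    means = dict(DEFAULT_GENERATING_MEANS)
    means["tau"] = 0.5  # native 5: disruptive stimulation effect
    means.update(generating_means or {})
    rng = np.random.default_rng([int(seed), 202])

    counts = pd.DataFrame(
        0, index=pd.Index(model_ids, name="generating"),
        columns=pd.Index(fit_ids, name="winner"),
    )
    for gen_id in model_ids:
        spec = get_model(gen_id)
        free = spec.free_params
        mean_vec = np.array([means[p] for p in free])
        for sim in range(n_sims_per_model):
            units = _draw_subject_units(mean_vec, n_subjects, rng)
            tables = [
                simulate_observer(
                    spec.id,
                    _params_from_units(free, units[i], stream),
                    design,
                    rng,
                    subject=f"m{gen_id}s{i:02d}",
                )
                for i in range(n_subjects)
            ]
            trials = pd.concat(tables, ignore_index=True)
            fits = []
            for fid in fit_ids:
                fits.append(
                    ObservationalLearningModel(trials, fid, stream).fit(
                        cc, seed=int(seed) + 31 * gen_id + sim
                    )
                )
            table = compare_models(fits)
            winner = int(table.loc[table["winner"], "model"].iloc[0])
            counts.loc[gen_id, winner] += 1
    return ConfusionMatrix(counts=counts)


def stimulation_effect_simulation(
    model: int | str = 5,
    tau_values=(1.0, 5.0),
    n_datasets: int = 30,
    n_reps: int = 100,
    seed: int = 0,
    *,
    stream: str = "choice",
    design: ExperimentDesign | None = None,
    generating_means: dict | None = None,
) -> pd.DataFrame:
    """Condition-level behavior under different stimulation divisors.

    For each tau, simulate ``n_datasets`` subjects ``n_reps`` times from the
    model (all other parameters drawn from the generating distribution with
    matched seeds across tau arms) and report the mean proportion of
    better-option choices per condition in dmpfc-labelled sessions, with the
    replicate spread and the paired difference relative to the first tau.
    """
    spec = get_model(model)
    design = design or build_design()
    means = dict(DEFAULT_GENERATING_MEANS)
    means.update(generating_means or {})
    free = [p for p in spec.free_params if p != "tau"]
    mean_vec = np.array([means[p] for p in free])

    rows = []
    for rep in range(n_reps):
        for ds in range(n_datasets):
            # identical subject parameters and seeds across tau arms
            rng_par = np.random.default_rng([int(seed), 303, rep, ds])
            units = _draw_subject_units(mean_vec, 1, rng_par)[0]
            for tau in tau_values:
                ps_kwargs = {"stream": stream, "tau": float(tau)}
                for name, uv in zip(free, units):
                    ps_kwargs[name] = float(unit_to_native(uv, name))
                ps = ParameterSet(**ps_kwargs)
                rng_sim = np.random.default_rng([int(seed), 404, rep, ds])
                df = simulate_observer(
                    spec.id, ps, design, rng_sim, subject=f"r{rep}d{ds}"
                )
                dm = df[(df["site"] == "dmpfc") & (df["condition"] != "individual")]
                for cond, grp in dm.groupby("condition"):
                    rows.append(
                        {
                            "rep": rep,
                            "dataset": ds,
                            "tau": float(tau),
                            "condition": cond,
                            "p_better": float(grp["choice"].mean()),
                        }
                    )
    raw = pd.DataFrame(rows)
    out = (
        raw.groupby(["condition", "tau"])["p_better"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )
    base = float(tau_values[0])
    ref = out[out["tau"] == base].set_index("condition")["mean"]
    out["diff_vs_first_tau"] = out.apply(
        lambda r: r["mean"] - ref[r["condition"]], axis=1
    )
    return out


def behavior_summaries(
    trials: pd.DataFrame, parameter_deltas: pd.Series | None = None
) -> dict:
    """Model-free condition summaries and stimulation-difference correlations.

    Returns a dict with:

    ``by_condition``
        Per subject x site x condition: proportion of better-option choices,
        proportion of correct predictions, and imitation rate (trial-wise
        agreement with the demonstrator's same-trial choice).
    ``site_differences``
        Vertex-minus-dmpfc differences per subject x condition (subjects
        missing a site are excluded with a warning).
    ``correlations``
        If ``parameter_deltas`` is given (indexed by subject), Pearson r
        between those deltas and each behavioral vertex-minus-dmpfc
        difference, with two-sided and one-sided (positive) p-values.
    """
    obs = trials.copy()

    def _summary(grp: pd.DataFrame) -> pd.Series:
        out = {"p_better": grp["choice"].astype("Float64").mean()}
        mask = grp["prediction"].notna() & grp["dem_action"].notna()
        if mask.any():
            sub = grp[mask]
            out["p_correct_prediction"] = float(
                (sub["prediction"] == sub["dem_action"]).mean()
            )
            out["imitation_rate"] = float((sub["choice"] == sub["dem_action"]).mean())
        else:
            out["p_correct_prediction"] = float("nan")
            out["imitation_rate"] = float("nan")
        return pd.Series(out)

    by_cond = (
        obs.groupby(["subject", "site", "condition"])
        .apply(_summary, include_groups=False)
        .reset_index()
    )

    wide = by_cond.pivot_table(
        index=["subject", "condition"], columns="site", values="p_better"
    )
    complete = wide.dropna()
    dropped = sorted(
        set(wide.index.get_level_values("subject"))
        - set(complete.index.get_level_values("subject"))
    )
    if dropped:
        warnings.warn(
            f"subjects missing a stimulation site excluded: {dropped}",
            RuntimeWarning,
            stacklevel=2,
        )
    diffs = (complete["vertex"] - complete["dmpfc"]).rename("vertex_minus_dmpfc").reset_index()

    result = {"by_condition": by_cond, "site_differences": diffs}
    if parameter_deltas is not None:
        rows = []
        for cond, grp in diffs.groupby("condition"):
            joined = grp.set_index("subject")["vertex_minus_dmpfc"].to_frame().join(
                parameter_deltas.rename("param_delta"), how="inner"
            )
            if len(joined) < 3 or joined["param_delta"].nunique() <= 1:
                continue
            r, p_two = stats.pearsonr(joined["param_delta"], joined["vertex_minus_dmpfc"])
            p_one = p_two / 2 if r > 0 else 1 - p_two / 2
            rows.append(
                {
                    "condition": cond,
                    "r": r,
                    "p_two_sided": p_two,
                    "p_one_sided_positive": p_one,
                    "n": len(joined),
                }
            )
        result["correlations"] = pd.DataFrame(rows)
    return result
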