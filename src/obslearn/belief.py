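"""Observer-side simulation of the demonstrator.

Observational-learning models infer from the demonstrator's perspective: the
observer runs a small Rescorla-Wagner Q-learner "as if" they were the
demonstrator, updating simulated option values from the demonstrator's
observed actions (and outcomes, when visible) and converting them into
demonstrator choice probabilities through a logistic softmax.

The simulation has two parameters, a learning rate ``alpha_dem`` and a
softmax temperature ``beta_dem``.  They are not fitted per subject: a grid
search over demonstrator traces picks a single best pair, which is then held
fixed for every downstream model (defaults ``alpha_dem=0.2``,
``beta_dem=9``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DemonstratorBelief",
    "step_belief",
    "grid_search_sim_params",
    "FIXED_ALPHA_DEM",
    "FIXED_BETA_DEM",
]

#: Simulation parameters held fixed downstream after the grid search.
FIXED_ALPHA_DEM = 0.2
FIXED_BETA_DEM = 9.0


def _logistic(x: float) -> float:
    # overflow-safe scalar logistic
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@dataclass(frozen=True)
class DemonstratorBelief:
    """Simulated demonstrator value state (two options, 1 = better option).

    Values start at the uninformative midpoint 0.5 and, with binary rewards
    and a learning rate in [0, 1], remain inside [0, 1].  The state is reset
    at every block boundary because each block uses a fresh stimulus pair.
    """

    alpha: float = FIXED_ALPHA_DEM
    beta: float = FIXED_BETA_DEM
    q: tuple[float, float] = (0.5, 0.5)
    last_delta: float = field(default=0.0, compare=False)

    @property
    def p_better(self) -> float:
        """Softmax probability that the simulated demonstrator picks option 1."""
        return _logistic(self.beta * (self.q[1] - self.q[0]))

    def prob(self, action: int) -> float:
        p1 = self.p_better
        return p1 if action == 1 else 1.0 - p1


def step_belief(
    state: DemonstratorBelief, action: int, reward: float
) -> tuple[DemonstratorBelief, float]:
    """Delta-rule update of the simulated demonstrator after one observation.

    The chosen option's value moves toward ``reward`` by ``alpha`` times the
    prediction error.  Returns the updated state and the post-update
    probability of the *observed* option, ``p_demonstrator(action)``.

    In blocks where the demonstrator's outcome is hidden, callers pass a
    pseudo-reward of 1 for the chosen option so the simulation tracks choice
    tendencies rather than values.
    """
    if action not in (0, 1):
        raise ValueError(f"action must be 0 or 1, got {action!r}")
    q = list(state.q)
    delta = reward - q[action]
    q[action] = q[action] + state.alpha * delta
    new = replace(state, q=(q[0], q[1]), last_delta=delta)
    return new, new.prob(action)


def _trace_loglik(actions, rewards, alpha: float, beta: float) -> float:
    """Predictive log-likelihood of one demonstrator block under (alpha, beta).

    Each action is scored with the probability computed *before* updating on
    that action, so the first observation of a block is always worth log 0.5.
    """
    state = DemonstratorBelief(alpha=alpha, beta=beta)
    ll = 0.0
    for a, r in zip(actions, rewards):
        ll += np.log(state.prob(int(a)))
        state, _ = step_belief(state, int(a), float(r))
    return ll


def grid_search_sim_params(
    traces,
    alpha_grid=None,
    beta_grid=None,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Maximum-likelihood grid search for the simulation parameters.

    Parameters
    ----------
    traces
        Iterable of demonstrator blocks; each supplies ``actions`` and
        ``rewards`` attributes (e.g. :class:`obslearn.task.DemonstratorTrace`)
        or is a plain ``(actions, rewards)`` pair.
    alpha_grid, beta_grid
        Candidate learning rates (default 0.1..1.0 in steps of 0.1) and
        temperatures (default integers 1..10).

    Returns
    -------
    (alpha, beta), surface
        The grid point with the highest summed log-likelihood of the observed
        demonstrator actions (ties broken toward smaller alpha, then smaller
        beta) and the full likelihood surface as a tidy DataFrame.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("grid search requires at least one demonstrator trace")
    if alpha_grid is None:
        alpha_grid = np.round(np.arange(0.1, 1.0 + 1e-9, 0.1), 10)
    if beta_grid is None:
        beta_grid = np.arange(1.0, 10.0 + 1e-9, 1.0)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    beta_grid = np.asarray(beta_grid, dtype=float)
    if alpha_grid.size == 0 or beta_grid.size == 0:
        raise ValueError("parameter grids must be nonempty")

    pairs = []
    for tr in traces:
        if hasattr(tr, "actions"):
            pairs.append((np.asarray(tr.actions), np.asarray(tr.rewards)))
        else:
            a, r = tr
            pairs.append((np.asarray(a), np.asarray(r)))

    rows = []
    best = None  # (ll, alpha, beta)
    for a_ in alpha_grid:
        for b_ in beta_grid:
            ll = sum(_trace_loglik(acts, rews, a_, b_) for acts, rews in pairs)
            rows.append({"alpha_dem": a_, "beta_dem": b_, "loglik": ll})
            # strict > keeps the smallest alpha, then smallest beta, on ties
            if best is None or ll > best[0] + 1e-12:
                best = (ll, a_, b_)
    surface = pd.DataFrame(rows)
    return (best[1], best[2]), surface
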