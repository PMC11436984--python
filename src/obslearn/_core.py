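"""Numba-compiled trial-likelihood kernels.

These mirror :class:`obslearn.models.ModelRunner` exactly (a test asserts
bit-level agreement with the pure-Python path) and exist because the
hierarchical sampler evaluates the trial likelihood millions of times.

Data layout: one subject's trials are packed into flat arrays sorted by
(site, condition, block, trial); blocks are delimited by changes of
``block_code``.  Missing integers are encoded as -1.  Multiple subjects are
concatenated with an ``offsets`` vector (CSR-style).
"""

from __future__ import annotations

import numpy as np
from numba import njit

STREAM_CHOICE = 0
STREAM_PREDICTION = 1

# parameter vector layout (matches models.PARAM_NAMES)
ALPHA, KAPPA, W, BETA, RHO, TAU, UPSILON = 0, 1, 2, 3, 4, 5, 6

LOG2 = 0.6931471805599453


@njit(cache=True, fastmath=False)
def _softplus(x):
    # log(1 + exp(x)), overflow-safe
    if x > 0.0:
        return x + np.log1p(np.exp(-x))
    return np.log1p(np.exp(x))


@njit(cache=True, fastmath=False)
def _logistic(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True, fastmath=False)
def subject_loglik(
    model_id,
    stream,
    params,          # float64[7] native scale
    block_code,      # int32[n]  (changes at block boundaries)
    is_dmpfc,        # uint8[n]
    action_only,     # uint8[n]
    obs_absent,      # uint8[n]
    dem_action,      # int8[n]  (-1 = absent)
    dem_reward,      # int8[n]  (-1 = hidden/absent)
    prediction,      # int8[n]  (-1 = absent)
    choice,          # int8[n]
    pred_val,        # float64[n] per-trial predictability (1 - entropy of the
                     #   simulated demonstrator choice distribution); data-only,
                     #   precomputed at pack time since alpha_dem/beta_dem are fixed
    sticky_sign,     # +1.0 sticky (default), -1.0 printed-sign convention
):
    """Total log-likelihood of one subject's responses for one stream.

    Returns -inf when the accumulation becomes non-finite (e.g. divergent
    accumulated predictability when upsilon/tau > 2), so samplers can simply
    reject such proposals.
    """
    alpha = params[ALPHA]
    kappa = params[KAPPA]
    w_free = params[W]
    beta = params[BETA]
    rho = params[RHO]
    tau = params[TAU]
    ups = params[UPSILON]

    out_mod_tau = model_id == 1 or model_id == 3
    act_mod_tau = model_id == 2 or model_id == 3
    out_mod_acp = model_id == 4 or model_id == 6
    act_mod_acp = model_id == 5 or model_id == 6
    uses_acp = model_id >= 4

    ll = 0.0
    cur_block = -2147483648
    qo0 = qo1 = qa0 = qa1 = 0.5
    acp = 0.0
    prev_c = -1
    prev_p = -1

    n = block_code.shape[0]
    for t in range(n):
        if block_code[t] != cur_block:
            cur_block = block_code[t]
            qo0 = qo1 = qa0 = qa1 = 0.5
            acp = 0.0
            prev_c = -1
            prev_p = -1
        w = 0.0 if action_only[t] == 1 else w_free
        dmpfc = is_dmpfc[t] == 1

        if obs_absent[t] == 0 and dem_action[t] >= 0:
            # --- prediction response, scored on pre-observation values
            if stream == STREAM_PREDICTION and prediction[t] >= 0:
                v1 = w * qo1 + (1.0 - w) * qa1
                v0 = w * qo0 + (1.0 - w) * qa0
                c1 = 1.0 if prev_p == 1 else 0.0
                c0 = 1.0 if prev_p == 0 else 0.0
                x = beta * (v1 - v0) + sticky_sign * rho * (c1 - c0)
                if prediction[t] == 1:
                    ll -= _softplus(-x)
                else:
                    ll -= _softplus(x)
            if prediction[t] >= 0:
                prev_p = prediction[t]

            a = dem_action[t]
            visible = dem_reward[t] >= 0

            # --- predictability and AcP (entropy precomputed from the
            #     parameter-free demonstrator simulation)
            if uses_acp:
                rate = ups / tau if dmpfc else ups
                acp = acp + rate * (pred_val[t] - acp)
                if not np.isfinite(acp) or acp > 1e12 or acp < -1e12:
                    return -np.inf

            # --- value updates
            if visible:
                r = float(dem_reward[t])
                rate = alpha
                if out_mod_tau and dmpfc:
                    rate = alpha / tau
                elif out_mod_acp:
                    rate = acp
                if a == 1:
                    qo1 += rate * (r - qo1)
                else:
                    qo0 += rate * (r - qo0)
            rate = kappa
            if act_mod_tau and dmpfc:
                rate = kappa / tau
            elif act_mod_acp:
                rate = acp
            if a == 1:
                qa1 += rate * (1.0 - qa1)
                qa0 += rate * (0.0 - qa0)
            else:
                qa0 += rate * (1.0 - qa0)
                qa1 += rate * (0.0 - qa1)

        # --- own choice, scored on post-update values
        if stream == STREAM_CHOICE and choice[t] >= 0:
            v1 = w * qo1 + (1.0 - w) * qa1
            v0 = w * qo0 + (1.0 - w) * qa0
            c1 = 1.0 if prev_c == 1 else 0.0
            c0 = 1.0 if prev_c == 0 else 0.0
            x = beta * (v1 - v0) + sticky_sign * rho * (c1 - c0)
            if choice[t] == 1:
                ll -= _softplus(-x)
            else:
                ll -= _softplus(x)
        if choice[t] >= 0:
            prev_c = choice[t]

    if not np.isfinite(ll):
        return -np.inf
    return ll


@njit(cache=True, fastmath=False)
def sweep_subject_params(
    model_id,
    stream,
    u,               # float64[n_subj, n_free]  (updated in place, unit scale)
    ll,              # float64[n_subj]          (updated in place)
    a_vec,           # float64[n_free] beta shape a per free parameter
    b_vec,           # float64[n_free] beta shape b
    free_idx,        # int64[n_free] position of each free param in the 7-vector
    hi,              # float64[n_free] native range upper bound (lower is 0)
    sd_u,            # float64[n_free] proposal scales
    normals,         # float64[n_free, n_subj] pre-drawn N(0,1)
    unifs,           # float64[n_free, n_subj] pre-drawn U(0,1)
    offsets,
    block_code,
    is_dmpfc,
    action_only,
    obs_absent,
    dem_action,
    dem_reward,
    prediction,
    choice,
    pred_val,
    sticky_sign,
):
    """One Metropolis-within-Gibbs sweep over all subject-level parameters.

    Component-wise random-walk proposals on the unit scale, accepted against
    the trial likelihood plus the group-level beta density (whose
    normalization cancels).  Returns per-parameter acceptance rates.
    """
    n_subj, n_free = u.shape
    acc = np.zeros(n_free)
    p7 = np.zeros(7)
    for j in range(n_free):
        for i in range(n_subj):
            cur = u[i, j]
            prop = cur + sd_u[j] * normals[j, i]
            if prop <= 0.0 or prop >= 1.0:
                continue
            for k in range(7):
                p7[k] = 0.0
            for k in range(n_free):
                p7[free_idx[k]] = u[i, k] * hi[k]
            p7[free_idx[j]] = prop * hi[j]
            lo_i = offsets[i]
            hi_i = offsets[i + 1]
            ll_new = subject_loglik(
                model_id,
                stream,
                p7,
                block_code[lo_i:hi_i],
                is_dmpfc[lo_i:hi_i],
                action_only[lo_i:hi_i],
                obs_absent[lo_i:hi_i],
                dem_action[lo_i:hi_i],
                dem_reward[lo_i:hi_i],
                prediction[lo_i:hi_i],
                choice[lo_i:hi_i],
                pred_val[lo_i:hi_i],
                sticky_sign,
            )
            log_r = (
                ll_new
                - ll[i]
                + (a_vec[j] - 1.0) * (np.log(prop) - np.log(cur))
                + (b_vec[j] - 1.0) * (np.log1p(-prop) - np.log1p(-cur))
            )
            if np.log(unifs[j, i]) < log_r:
                u[i, j] = prop
                ll[i] = ll_new
                acc[j] += 1.0 / n_subj
    return acc


@njit(cache=True, fastmath=False)
def batch_loglik(
    model_id,
    stream,
    params,          # float64[n_subj, 7]
    offsets,         # int64[n_subj + 1]
    block_code,
    is_dmpfc,
    action_only,
    obs_absent,
    dem_action,
    dem_reward,
    prediction,
    choice,
    pred_val,
    sticky_sign,
):
    """Per-subject log-likelihoods over concatenated subject arrays."""
    n_subj = offsets.shape[0] - 1
    out = np.empty(n_subj, dtype=np.float64)
    for s in range(n_subj):
        lo = offsets[s]
        hi = offsets[s + 1]
        out[s] = subject_loglik(
            model_id,
            stream,
            params[s],
            block_code[lo:hi],
            is_dmpfc[lo:hi],
            action_only[lo:hi],
            obs_absent[lo:hi],
            dem_action[lo:hi],
            dem_reward[lo:hi],
            prediction[lo:hi],
            choice[lo:hi],
            pred_val[lo:hi],
            sticky_sign,
        )
    return out
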