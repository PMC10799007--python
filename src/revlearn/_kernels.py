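"""Compiled inner loops for model likelihoods and their gradients.

Choices are coded 0 = A, 1 = B; outcomes are 0/1.  All kernels run the exact
forward recursions of :mod:`revlearn.models` and propagate derivatives of the
evolving option values with respect to the native parameters alongside the
values themselves (forward-mode accumulation), so gradients are exact to
machine precision.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "rp_nll_grad",
    "ewa_nll_grad",
    "rp_nll",
    "ewa_nll",
    "rp_simulate_optimal",
]


@njit(cache=True, fastmath=False)
def _log_sigmoid(x):
    # log(1/(1+exp(-x))) without overflow
    if x >= 0.0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


@njit(cache=True, fastmath=False)
def rp_nll_grad(choices, outcomes, alpha_pos, alpha_neg, beta, v0):
    """Per-subject NLL and gradient for the RP model.

    choices, outcomes: int8 arrays of shape (S, T); alpha_pos/alpha_neg/beta:
    float arrays (S,).  Returns (nll[S], grad[S, 3]) with grad columns
    (d/d alpha_pos, d/d alpha_neg, d/d beta) of the *negative* log-likelihood.
    """
    S, T = choices.shape
    nll = np.zeros(S)
    grad = np.zeros((S, 3))
    for s in range(S):
        ap = alpha_pos[s]
        an = alpha_neg[s]
        be = beta[s]
        vA = v0
        vB = v0
        # d v / d alpha_pos, d v / d alpha_neg for each option
        gAp = 0.0
        gAn = 0.0
        gBp = 0.0
        gBn = 0.0
        ll = 0.0
        dp = 0.0  # d ll / d alpha_pos
        dn = 0.0
        db = 0.0
        for t in range(T):
            d = vA - vB
            x = be * d
            if choices[s, t] == 0:  # chose A
                ll += _log_sigmoid(x)
                pA = 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1.0 + math.exp(x))
                coef = (1.0 - pA) * be
                db += (1.0 - pA) * d
            else:
                ll += _log_sigmoid(-x)
                pA = 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1.0 + math.exp(x))
                coef = -pA * be
                db += -pA * d
            dp += coef * (gAp - gBp)
            dn += coef * (gAn - gBn)
            # feedback update of the chosen option
            R = outcomes[s, t]
            if choices[s, t] == 0:
                pe = R - vA
                if R == 1:
                    vA += ap * pe
                    gAp = (1.0 - ap) * gAp + pe
                    gAn = (1.0 - ap) * gAn
                else:
                    vA += an * pe
                    gAn = (1.0 - an) * gAn + pe
                    gAp = (1.0 - an) * gAp
            else:
                pe = R - vB
                if R == 1:
                    vB += ap * pe
                    gBp = (1.0 - ap) * gBp + pe
                    gBn = (1.0 - ap) * gBn
                else:
                    vB += an * pe
                    gBn = (1.0 - an) * gBn + pe
                    gBp = (1.0 - an) * gBp
        nll[s] = -ll
        grad[s, 0] = -dp
        grad[s, 1] = -dn
        grad[s, 2] = -db
    return nll, grad


@njit(cache=True, fastmath=False)
def ewa_nll_grad(choices, outcomes, phi, rho, beta, v0):
    """Per-subject NLL and gradient for the EWA model.

    Returns (nll[S], grad[S, 3]) with grad columns (d/d phi, d/d rho, d/d beta).
    """
    S, T = choices.shape
    nll = np.zeros(S)
    grad = np.zeros((S, 3))
    for s in range(S):
        ph = phi[s]
        rh = rho[s]
        be = beta[s]
        vA = v0
        vB = v0
        nA = 1.0
        nB = 1.0
        gvA_ph = 0.0
        gvA_rh = 0.0
        gnA_rh = 0.0
        gvB_ph = 0.0
        gvB_rh = 0.0
        gnB_rh = 0.0
        ll = 0.0
        dph = 0.0
        drh = 0.0
        db = 0.0
        for t in range(T):
            d = vA - vB
            x = be * d
            pA = 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1.0 + math.exp(x))
            if choices[s, t] == 0:
                ll += _log_sigmoid(x)
                coef = (1.0 - pA) * be
                db += (1.0 - pA) * d
            else:
                ll += _log_sigmoid(-x)
                coef = -pA * be
                db += -pA * d
            dph += coef * (gvA_ph - gvB_ph)
            drh += coef * (gvA_rh - gvB_rh)
            R = outcomes[s, t]
            if choices[s, t] == 0:
                n_new = rh * nA + 1.0
                dn_new = nA + rh * gnA_rh
                num = ph * nA * vA + R
                v_new = num / n_new
                gv_ph_new = (nA * vA + ph * nA * gvA_ph) / n_new
                gv_rh_new = (ph * (gnA_rh * vA + nA * gvA_rh) * n_new - num * dn_new) / (n_new * n_new)
                vA = v_new
                nA = n_new
                gvA_ph = gv_ph_new
                gvA_rh = gv_rh_new
                gnA_rh = dn_new
            else:
                n_new = rh * nB + 1.0
                dn_new = nB + rh * gnB_rh
                num = ph * nB * vB + R
                v_new = num / n_new
                gv_ph_new = (nB * vB + ph * nB * gvB_ph) / n_new
                gv_rh_new = (ph * (gnB_rh * vB + nB * gvB_rh) * n_new - num * dn_new) / (n_new * n_new)
                vB = v_new
                nB = n_new
                gvB_ph = gv_ph_new
                gvB_rh = gv_rh_new
                gnB_rh = dn_new
        nll[s] = -ll
        grad[s, 0] = -dph
        grad[s, 1] = -drh
        grad[s, 2] = -db
    return nll, grad


@njit(cache=True, fastmath=False)
def rp_nll(choices, outcomes, alpha_pos, alpha_neg, beta, v0):
    """Per-subject RP negative log-likelihood only (no gradient)."""
    S, T = choices.shape
    nll = np.zeros(S)
    for s in range(S):
        ap = alpha_pos[s]
        an = alpha_neg[s]
        be = beta[s]
        vA = v0
        vB = v0
        ll = 0.0
        for t in range(T):
            x = be * (vA - vB)
            if choices[s, t] == 0:
                ll += _log_sigmoid(x)
            else:
                ll += _log_sigmoid(-x)
            R = outcomes[s, t]
            if choices[s, t] == 0:
                vA += (ap if R == 1 else an) * (R - vA)
            else:
                vB += (ap if R == 1 else an) * (R - vB)
        nll[s] = -ll
    return nll


@njit(cache=True, fastmath=False)
def ewa_nll(choices, outcomes, phi, rho, beta, v0):
    """Per-subject EWA negative log-likelihood only."""
    S, T = choices.shape
    nll = np.zeros(S)
    for s in range(S):
        ph = phi[s]
        rh = rho[s]
        be = beta[s]
        vA = v0
        vB = v0
        nA = 1.0
        nB = 1.0
        ll = 0.0
        for t in range(T):
            x = be * (vA - vB)
            if choices[s, t] == 0:
                ll += _log_sigmoid(x)
            else:
                ll += _log_sigmoid(-x)
            R = outcomes[s, t]
            if choices[s, t] == 0:
                n_new = rh * nA + 1.0
                vA = (ph * nA * vA + R) / n_new
                nA = n_new
            else:
                n_new = rh * nB + 1.0
                vB = (ph * nB * vB + R) / n_new
                nB = n_new
        nll[s] = -ll
    return nll


@njit(cache=True, fastmath=False)
def rp_simulate_optimal(high_is_A, rewarded_is_A, alpha_pos, alpha_neg, beta, uniforms, v0):
    """Simulate RP agents on a fixed schedule; return optimal-choice indicators.

    high_is_A, rewarded_is_A: int8 (T,); parameter arrays (N,);
    uniforms: (N, T) choice randomness.  Returns int8 (N, T) with 1 where the
    simulated choice equals the schedule's high-probability shape.
    """
    N = alpha_pos.shape[0]
    T = high_is_A.shape[0]
    out = np.zeros((N, T), dtype=np.int8)
    for i in range(N):
        ap = alpha_pos[i]
        an = alpha_neg[i]
        be = beta[i]
        vA = v0
        vB = v0
        for t in range(T):
            x = be * (vA - vB)
            pA = 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1.0 + math.exp(x))
            chose_A = uniforms[i, t] < pA
            if chose_A == (high_is_A[t] == 1):
                out[i, t] = 1
            if chose_A:
                R = 1.0 if rewarded_is_A[t] == 1 else 0.0
                vA += (ap if R == 1.0 else an) * (R - vA)
            else:
                R = 1.0 if rewarded_is_A[t] == 0 else 0.0
                vB += (ap if R == 1.0 else an) * (R - vB)
    return out
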