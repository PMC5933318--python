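"""Metropolis-within-Gibbs kernel for the switching first-difference CRW.

Hot loops are numba-compiled.  All tracks are concatenated into flat site
arrays; ``loc_of[g]`` is the site's index within its own track, so
process terms exist only at local index >= 2 (local 1 carries a broad
independent prior on the first displacement).  Observations are linear
interpolations between their interval's two grid sites with fraction j,
with per-coordinate scaled Student-t errors fixed per Argos class.

Parameter vector layout (length 9):
  0 gamma_1   persistence, state 1 (transit)
  1 gamma_2   persistence, state 2 (ARS)
  2 theta_1   mean turn angle, state 1 (radians)
  3 theta_2   mean turn angle, state 2
  4 alpha_1   P(next state = 1 | state 1)
  5 alpha_2   P(next state = 1 | state 2)
  6 sigma_lon process-noise sd (degrees)
  7 sigma_lat process-noise sd (degrees)
  8 rho       process-noise correlation
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def t_logpdf(r, nu, tau):
    """log density at r of tau times a Student-t with nu dof."""
    z = r / tau
    return (math.lgamma(0.5 * (nu + 1.0)) - math.lgamma(0.5 * nu)
            - 0.5 * math.log(nu * math.pi) - math.log(tau)
            - 0.5 * (nu + 1.0) * math.log(1.0 + z * z / nu))


@njit(cache=True)
def _sigma_terms(s1, s2, rho):
    """(inv11, inv12, inv22, logdet) of the 2x2 process covariance."""
    one_m = 1.0 - rho * rho
    inv11 = 1.0 / (s1 * s1 * one_m)
    inv22 = 1.0 / (s2 * s2 * one_m)
    inv12 = -rho / (s1 * s2 * one_m)
    logdet = math.log(s1 * s1 * s2 * s2 * one_m)
    return inv11, inv12, inv22, logdet


@njit(cache=True)
def _proc_term(x, g, l, state, p, inv11, inv12, inv22, logdet, s0):
    """Log process density contribution of site g (local index l)."""
    if l == 1:
        e0 = x[g, 0] - x[g - 1, 0]
        e1 = x[g, 1] - x[g - 1, 1]
        return -0.5 * ((e0 / s0) ** 2 + (e1 / s0) ** 2) \
            - math.log(s0 * s0) - LOG2PI
    # l >= 2
    g_ = p[0] if state == 1 else p[1]
    th = p[2] if state == 1 else p[3]
    c = math.cos(th)
    s = math.sin(th)
    dp0 = x[g - 1, 0] - x[g - 2, 0]
    dp1 = x[g - 1, 1] - x[g - 2, 1]
    m0 = g_ * (c * dp0 - s * dp1)
    m1 = g_ * (s * dp0 + c * dp1)
    e0 = x[g, 0] - x[g - 1, 0] - m0
    e1 = x[g, 1] - x[g - 1, 1] - m1
    quad = inv11 * e0 * e0 + 2.0 * inv12 * e0 * e1 + inv22 * e1 * e1
    return -0.5 * (quad + logdet) - LOG2PI


@njit(cache=True)
def _proc_ll_total(x, b, loc_of, p, inv11, inv12, inv22, logdet):
    """Sum of process terms at local index >= 2 (the parameter-dependent part)."""
    total = 0.0
    for g in range(x.shape[0]):
        l = loc_of[g]
        if l >= 2:
            total += _proc_term(x, g, l, b[g], p,
                                inv11, inv12, inv22, logdet, 1.0)
    return total


@njit(cache=True)
def _obs_ll_for_site(x, g, obs_y, obs_a, obs_bsite, obs_j, obs_nu, obs_tau,
                     sop, soi):
    """Observation log-likelihood of all fixes whose prediction touches site g."""
    total = 0.0
    for k in range(sop[g], sop[g + 1]):
        m = soi[k]
        a = obs_a[m]
        bb = obs_bsite[m]
        j = obs_j[m]
        p0 = (1.0 - j) * x[a, 0] + j * x[bb, 0]
        p1 = (1.0 - j) * x[a, 1] + j * x[bb, 1]
        total += t_logpdf(obs_y[m, 0] - p0, obs_nu[m, 0], obs_tau[m, 0])
        total += t_logpdf(obs_y[m, 1] - p1, obs_nu[m, 1], obs_tau[m, 1])
    return total


@njit(cache=True)
def run_chain(seed, n_iter, n_burn, thin,
              x, b, tr_of, loc_of,
              obs_y, obs_a, obs_bsite, obs_j, obs_nu, obs_tau,
              sop, soi,
              params, s0, sigma_prior_scale,
              gamma_prior, alpha_prior,
              x_scale_init, n_tracks):
    """Run one MCMC chain in place; return retained draws.

    Returns (param_keep (K,9), x_keep (K,N,2), b_sum (N,), acc (2,)) where
    K = (n_iter - n_burn) // thin, b_sum accumulates retained states, and
    acc holds mean acceptance rates for location and parameter moves.
    """
    np.random.seed(seed)
    N = x.shape[0]
    K = (n_iter - n_burn) // thin
    param_keep = np.empty((K, 9))
    x_keep = np.empty((K, N, 2))
    b_sum = np.zeros(N)

    x_scale = np.full(n_tracks, x_scale_init)
    p_scale = np.full(7, 0.2)  # gamma1,gamma2,theta1,theta2,ls1,ls2,zrho
    x_acc = np.zeros(n_tracks)
    x_try = np.zeros(n_tracks)
    p_acc = np.zeros(7)
    p_try = np.zeros(7)
    tot_x_acc = 0.0
    tot_x_try = 0.0
    tot_p_acc = 0.0
    tot_p_try = 0.0

    inv11, inv12, inv22, logdet = _sigma_terms(params[6], params[7], params[8])
    kept = 0

    for it in range(n_iter):
        # ---- locations: single-site random-walk Metropolis -------------
        for g in range(N):
            tr = tr_of[g]
            sc = x_scale[tr]
            old0 = x[g, 0]
            old1 = x[g, 1]
            ll_old = _obs_ll_for_site(x, g, obs_y, obs_a, obs_bsite, obs_j,
                                      obs_nu, obs_tau, sop, soi)
            for h in range(g, min(g + 3, N)):
                lh = loc_of[h]
                if tr_of[h] != tr or lh < 1:
                    continue
                if lh < loc_of[g]:  # next track started
                    break
                ll_old += _proc_term(x, h, lh, b[h], params,
                                     inv11, inv12, inv22, logdet, s0)
            x[g, 0] = old0 + sc * np.random.standard_normal()
            x[g, 1] = old1 + sc * np.random.standard_normal()
            ll_new = _obs_ll_for_site(x, g, obs_y, obs_a, obs_bsite, obs_j,
                                      obs_nu, obs_tau, sop, soi)
            for h in range(g, min(g + 3, N)):
                lh = loc_of[h]
                if tr_of[h] != tr or lh < 1:
                    continue
                if lh < loc_of[g]:
                    break
                ll_new += _proc_term(x, h, lh, b[h], params,
                                     inv11, inv12, inv22, logdet, s0)
            x_try[tr] += 1.0
            if math.log(np.random.random()) < ll_new - ll_old:
                x_acc[tr] += 1.0
            else:
                x[g, 0] = old0
                x[g, 1] = old1

        # ---- behavioral states: single-site Gibbs -----------------------
        for g in range(N):
            l = loc_of[g]
            if l < 1:
                continue
            lp1 = 0.0
            lp2 = 0.0
            if l >= 2:
                lp1 += _proc_term(x, g, l, 1, params,
                                  inv11, inv12, inv22, logdet, s0)
                lp2 += _proc_term(x, g, l, 2, params,
                                  inv11, inv12, inv22, logdet, s0)
                a_prev = params[4] if b[g - 1] == 1 else params[5]
                lp1 += math.log(max(a_prev, 1e-300))
                lp2 += math.log(max(1.0 - a_prev, 1e-300))
            if g + 1 < N and tr_of[g + 1] == tr_of[g] and loc_of[g + 1] == l + 1 \
                    and l + 1 >= 2:
                nxt = b[g + 1]
                if nxt == 1:
                    lp1 += math.log(max(params[4], 1e-300))
                    lp2 += math.log(max(params[5], 1e-300))
                else:
                    lp1 += math.log(max(1.0 - params[4], 1e-300))
                    lp2 += math.log(max(1.0 - params[5], 1e-300))
            mx = lp1 if lp1 > lp2 else lp2
            p1 = math.exp(lp1 - mx)
            p2 = math.exp(lp2 - mx)
            b[g] = 1 if np.random.random() < p1 / (p1 + p2) else 2

        # ---- switching probabilities: conjugate beta Gibbs ---------------
        n11 = 0.0
        n12 = 0.0
        n21 = 0.0
        n22 = 0.0
        for g in range(N):
            if loc_of[g] >= 2:
                if b[g - 1] == 1:
                    if b[g] == 1:
                        n11 += 1.0
                    else:
                        n12 += 1.0
                else:
                    if b[g] == 1:
                        n21 += 1.0
                    else:
                        n22 += 1.0
        params[4] = np.random.beta(alpha_prior[0] + n11, alpha_prior[1] + n12)
        params[5] = np.random.beta(alpha_prior[2] + n21, alpha_prior[3] + n22)

        # ---- movement parameters: random-walk Metropolis ----------------
        ll_cur = _proc_ll_total(x, b, loc_of, params,
                                inv11, inv12, inv22, logdet)
        for k in range(7):
            p_try[k] += 1.0
            pnew = params.copy()
            extra = 0.0  # log prior + Jacobian difference (new - old)
            if k < 2:  # gamma on logit scale, beta prior
                gcur = params[k]
                u = math.log(gcur / (1.0 - gcur)) \
                    + p_scale[k] * np.random.standard_normal()
                gnew = 1.0 / (1.0 + math.exp(-u))
                pnew[k] = gnew
                if not pnew[0] > pnew[1]:  # ordering: state 1 more persistent
                    continue
                pa = gamma_prior[2 * k]
                pb = gamma_prior[2 * k + 1]
                # beta(pa,pb) prior plus logit-scale Jacobian
                extra = (pa * (math.log(gnew) - math.log(gcur))
                         + pb * (math.log(1.0 - gnew) - math.log(1.0 - gcur)))
            elif k < 4:  # theta: wrapped uniform
                th = params[k] + p_scale[k] * np.random.standard_normal()
                pnew[k] = math.atan2(math.sin(th), math.cos(th))
            elif k < 6:  # log sigma, half-t prior on sd
                scur = params[k + 2]
                snew = scur * math.exp(p_scale[k] * np.random.standard_normal())
                pnew[k + 2] = snew
                A2 = 3.0 * sigma_prior_scale * sigma_prior_scale
                extra = (-2.0 * math.log(1.0 + snew * snew / A2)
                         + 2.0 * math.log(1.0 + scur * scur / A2)
                         + math.log(snew) - math.log(scur))
            else:  # rho via atanh, uniform prior on (-1,1)
                rcur = params[8]
                z = 0.5 * math.log((1.0 + rcur) / (1.0 - rcur)) \
                    + p_scale[k] * np.random.standard_normal()
                rnew = math.tanh(z)
                pnew[8] = rnew
                extra = (math.log(1.0 - rnew * rnew)
                         - math.log(1.0 - rcur * rcur))
            i11, i12, i22, ld = _sigma_terms(pnew[6], pnew[7], pnew[8])
            ll_new = _proc_ll_total(x, b, loc_of, pnew, i11, i12, i22, ld)
            if math.log(np.random.random()) < ll_new - ll_cur + extra:
                params = pnew
                ll_cur = ll_new
                inv11, inv12, inv22, logdet = i11, i12, i22, ld
                p_acc[k] += 1.0

        # ---- adapt proposal scales during burn-in only -------------------
        if it < n_burn and (it + 1) % 50 == 0:
            for tr in range(n_tracks):
                if x_try[tr] > 0:
                    rate = x_acc[tr] / x_try[tr]
                    x_scale[tr] *= math.exp(rate - 0.35)
                    x_scale[tr] = min(max(x_scale[tr], 1e-5), 5.0)
            for k in range(7):
                if p_try[k] > 0:
                    rate = p_acc[k] / p_try[k]
                    p_scale[k] *= math.exp(rate - 0.30)
                    p_scale[k] = min(max(p_scale[k], 1e-4), 5.0)
            x_acc[:] = 0.0
            x_try[:] = 0.0
            p_acc[:] = 0.0
            p_try[:] = 0.0
        if it >= n_burn:
            tot_x_acc += x_acc.sum()
            tot_x_try += x_try.sum()
            tot_p_acc += p_acc.sum()
            tot_p_try += p_try.sum()
            x_acc[:] = 0.0
            x_try[:] = 0.0
            p_acc[:] = 0.0
            p_try[:] = 0.0

        # ---- retention ---------------------------------------------------
        if it >= n_burn and (it - n_burn) % thin == thin - 1:
            param_keep[kept] = params
            x_keep[kept] = x
            for g in range(N):
                b_sum[g] += b[g]
            kept += 1

    acc = np.empty(2)
    acc[0] = tot_x_acc / max(tot_x_try, 1.0)
    acc[1] = tot_p_acc / max(tot_p_try, 1.0)
    return param_keep, x_keep, b_sum, acc
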