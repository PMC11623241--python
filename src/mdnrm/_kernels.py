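"""Numba-compiled log-posterior/gradient kernel.

One compiled routine serves every model variant through small integer
mode flags; the Python-level :class:`~mdnrm._target.Target` prepares the
per-row index arrays.  Falls back transparently when numba is missing —
the numpy path in ``_target`` computes the identical quantities.

Parameter vector layout: ``x = [theta, u = log(alpha), beta]``.

Modes
-----
alpha_mode : 0 none; 1 one alpha entry per row (MDNRM a/b/r); 2 one entry
    per response class with flat base index (2PL-NRM).
beta_mode : 0 easiness cancels (omitted from the likelihood); 1 one entry
    per response class at ``b_base + t``.
alpha_prior : 0 none; 1 Gamma(shape, rate); 2 half-normal(scale).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=False)
def logp_grad(
    x,
    th_base,      # (N,) flat base index into the theta block
    a_idx,        # (N,) alpha index (mode 1) or flat base (mode 2); dummy if 0
    b_base,       # (N,) flat base index into the beta block (mode 1)
    resp,         # (N,) observed response class
    iparams,      # int64: C, n_theta, n_alpha, n_beta, theta_md,
                  #        alpha_mode, beta_mode, alpha_prior, prior_only
    fparams,      # float64: gamma_shape, gamma_rate, halfnormal_scale,
                  #        theta_prec, beta_prec, theta_const, beta_const,
                  #        alpha_const
):
    C = iparams[0]
    n_theta, n_alpha, n_beta = iparams[1], iparams[2], iparams[3]
    theta_md, alpha_mode, beta_mode = iparams[4], iparams[5], iparams[6]
    alpha_prior, prior_only = iparams[7], iparams[8]
    gamma_shape, gamma_rate, halfnormal_scale = fparams[0], fparams[1], fparams[2]
    theta_prec, beta_prec = fparams[3], fparams[4]
    theta_const, beta_const, alpha_const = fparams[5], fparams[6], fparams[7]
    dim = x.shape[0]
    grad = np.zeros(dim)
    logp = 0.0

    # --- priors ---------------------------------------------------------
    for k in range(n_theta):
        logp += -0.5 * theta_prec * x[k] * x[k] + theta_const
        grad[k] = -theta_prec * x[k]
    off_b = n_theta + n_alpha
    for k in range(n_beta):
        v = x[off_b + k]
        logp += -0.5 * beta_prec * v * v + beta_const
        grad[off_b + k] = -beta_prec * v
    if n_alpha > 0:
        for k in range(n_alpha):
            u = x[n_theta + k]
            a = np.exp(u)
            if alpha_prior == 1:
                logp += gamma_shape * u - gamma_rate * a + alpha_const
                grad[n_theta + k] = gamma_shape - gamma_rate * a
            else:
                r = a / halfnormal_scale
                logp += u - 0.5 * r * r + alpha_const
                grad[n_theta + k] = 1.0 - r * r

    if prior_only:
        return logp, grad

    # --- likelihood ------------------------------------------------------
    N = th_base.shape[0]
    z = np.empty(C)
    p = np.empty(C)
    for n in range(N):
        tb = th_base[n]
        if alpha_mode == 1:
            a_val = np.exp(x[n_theta + a_idx[n]])
        else:
            a_val = 1.0
        for t in range(C):
            th = x[tb + t] if theta_md == 1 else x[tb]
            if alpha_mode == 2:
                a_t = np.exp(x[n_theta + a_idx[n] + t])
                zt = a_t * th
            else:
                zt = a_val * th
            if beta_mode == 1:
                zt += x[off_b + b_base[n] + t]
            z[t] = zt
        zmax = z[0]
        for t in range(1, C):
            if z[t] > zmax:
                zmax = z[t]
        se = 0.0
        for t in range(C):
            p[t] = np.exp(z[t] - zmax)
            se += p[t]
        for t in range(C):
            p[t] /= se
        r_n = resp[n]
        logp += z[r_n] - zmax - np.log(se)
        # g_t = 1[t == r] - p_t scattered onto each parameter block
        ga_sum = 0.0
        for t in range(C):
            g = (1.0 if t == r_n else 0.0) - p[t]
            if theta_md == 1:
                if alpha_mode == 2:
                    a_t = np.exp(x[n_theta + a_idx[n] + t])
                    grad[tb + t] += a_t * g
                else:
                    grad[tb + t] += a_val * g
            else:
                if alpha_mode == 2:
                    a_t = np.exp(x[n_theta + a_idx[n] + t])
                    grad[tb] += a_t * g
                    grad[n_theta + a_idx[n] + t] += x[tb] * g * a_t
                else:
                    grad[tb] += a_val * g
            if beta_mode == 1:
                grad[off_b + b_base[n] + t] += g
            if alpha_mode == 1:
                th = x[tb + t] if theta_md == 1 else x[tb]
                ga_sum += th * g
        if alpha_mode == 1:
            grad[n_theta + a_idx[n]] += ga_sum * a_val
    return logp, grad


@njit(cache=True, fastmath=False)
def leapfrog(
    x, p, grad, eps, inv_mass,
    th_base, a_idx, b_base, resp, iparams, fparams,
):
    """One leapfrog step plus the joint (potential + kinetic) log density."""
    dim = x.shape[0]
    p1 = np.empty(dim)
    x1 = np.empty(dim)
    for k in range(dim):
        p1[k] = p[k] + 0.5 * eps * grad[k]
        x1[k] = x[k] + eps * inv_mass[k] * p1[k]
    logp, grad1 = logp_grad(x1, th_base, a_idx, b_base, resp, iparams, fparams)
    kin = 0.0
    for k in range(dim):
        p1[k] = p1[k] + 0.5 * eps * grad1[k]
        kin += p1[k] * inv_mass[k] * p1[k]
    joint = logp - 0.5 * kin if np.isfinite(logp) else -np.inf
    return x1, p1, logp, grad1, joint
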