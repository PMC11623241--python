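"""Flat-vector posterior density and analytic gradient for the NUTS kernel.

The sampler works on an unconstrained vector ``x = [theta, u, beta]`` where
``u = log(alpha)`` maps the nonnegative discrimination parameter to the real
line (the log-Jacobian ``+u`` per entry is included in the density).  The
categorical/softmax likelihood has the standard gradient
``d loglik / d z_t = 1[t = r] - p_t``, which is scattered back onto the
parameter arrays with ``bincount`` so a full gradient evaluation is a
handful of vectorized passes over the N table rows.

Easiness terms that carry no response index are constant within a row's
softmax and cancel analytically; they are omitted from the likelihood code
path (the values are identical) and contribute through the prior only.
"""

from __future__ import annotations

import numpy as np

from .data import ResponseTable
from .models import (
    AlphaPrior,
    ModelSpec,
    ParameterSet,
    Variant,
    parameter_shapes,
)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class Target:
    """Log posterior (up to nothing — constants included) with gradient."""

    def __init__(
        self,
        spec: ModelSpec,
        table: ResponseTable,
        prior_only: bool = False,
    ) -> None:
        self.spec = spec
        self.table = table
        self.prior_only = prior_only
        I, J, C = table.n_cases, table.n_raters, spec.n_classes
        self.I, self.J, self.C = I, J, C
        shapes = parameter_shapes(spec, I, J)
        self.shapes = shapes
        self.sizes = {k: int(np.prod(v)) for k, v in shapes.items()}
        self.names = [n for n in ("theta", "alpha", "beta") if n in shapes]
        self.dim = sum(self.sizes.values())
        self.slices: dict[str, slice] = {}
        off = 0
        for name in self.names:
            self.slices[name] = slice(off, off + self.sizes[name])
            off += self.sizes[name]

        n = table.n_rows
        i, j, s, r = (
            table.case_id,
            table.rater_id,
            table.ground_truth,
            table.response,
        )
        self._n = n
        self._resp = r
        self._rows = np.arange(n)
        v = spec.variant
        if v.multidimensional:
            # (N, C) flat indices into theta for each response class t
            self._ti = ((j * C + s) * C)[:, None] + np.arange(C)[None, :]
            if v in (Variant.MDNRM_A, Variant.MDNRM_R):
                self._ai = i * C + s
            elif v is Variant.MDNRM_B:
                self._ai = s
            else:
                self._ai = None
            if spec.beta_response_indexed:
                if v is Variant.MDNRM_A:
                    self._bi = np.broadcast_to(np.arange(C), (n, C))
                else:
                    self._bi = (i * C)[:, None] + np.arange(C)[None, :]
            else:
                self._bi = None  # cancels
        else:
            self._ti = j  # (N,)
            self._ai = (i * C)[:, None] + np.arange(C)[None, :] if v is Variant.NRM_2PL else None
            self._bi = (i * C)[:, None] + np.arange(C)[None, :]

        # prior precisions and normalizing constants
        self._theta_prec = 1.0 / spec.theta_scale**2
        self._beta_prec = 1.0 / spec.beta_scale**2
        self._theta_const = -(_LOG_SQRT_2PI + np.log(spec.theta_scale))
        self._beta_const = -(_LOG_SQRT_2PI + np.log(spec.beta_scale))

        # flat-index arrays and mode flags for the compiled kernel
        dummy = np.zeros(n, dtype=np.int64)
        if v.multidimensional:
            k_theta_md = 1
            k_th_base = ((j * C + s) * C).astype(np.int64)
            if v in (Variant.MDNRM_A, Variant.MDNRM_R):
                k_alpha_mode, k_a_idx = 1, (i * C + s).astype(np.int64)
            elif v is Variant.MDNRM_B:
                k_alpha_mode, k_a_idx = 1, s.astype(np.int64)
            else:
                k_alpha_mode, k_a_idx = 0, dummy
            if spec.beta_response_indexed:
                k_beta_mode = 1
                k_b_base = dummy if v is Variant.MDNRM_A else (i * C).astype(np.int64)
            else:
                k_beta_mode, k_b_base = 0, dummy
        else:
            k_theta_md = 0
            k_th_base = j.astype(np.int64)
            if v is Variant.NRM_2PL:
                k_alpha_mode, k_a_idx = 2, (i * C).astype(np.int64)
            else:
                k_alpha_mode, k_a_idx = 0, dummy
            k_beta_mode, k_b_base = 1, (i * C).astype(np.int64)
        if spec.alpha_prior is AlphaPrior.GAMMA:
            k_alpha_prior = 1
            alpha_const = _gamma_const(spec.gamma_shape, spec.gamma_rate)
        elif spec.alpha_prior is AlphaPrior.HALF_NORMAL:
            k_alpha_prior = 2
            alpha_const = float(
                np.log(2.0) - _LOG_SQRT_2PI - np.log(spec.halfnormal_scale)
            )
        else:
            k_alpha_prior, alpha_const = 0, 0.0
        iparams = np.array(
            [C, self.sizes["theta"], self.sizes.get("alpha", 0),
             self.sizes["beta"], k_theta_md, k_alpha_mode, k_beta_mode,
             k_alpha_prior, 1 if prior_only else 0],
            dtype=np.int64,
        )
        fparams = np.array(
            [spec.gamma_shape, spec.gamma_rate, spec.halfnormal_scale,
             self._theta_prec, self._beta_prec,
             self._theta_const, self._beta_const, alpha_const],
            dtype=np.float64,
        )
        self._kernel_args = (
            k_th_base, k_a_idx, k_b_base, table.response.astype(np.int64),
            iparams, fparams,
        )

    # -- packing ----------------------------------------------------------

    def pack(self, params: ParameterSet) -> np.ndarray:
        """ParameterSet -> unconstrained flat vector (alpha -> log alpha)."""
        parts = []
        for name in self.names:
            arr = getattr(self, "_pack_" + name)(params)
            parts.append(np.asarray(arr, dtype=float).ravel())
        return np.concatenate(parts)

    def _pack_theta(self, p):
        return p.theta

    def _pack_alpha(self, p):
        return np.log(p.alpha)

    def _pack_beta(self, p):
        return p.beta

    def unpack(self, x: np.ndarray) -> ParameterSet:
        """Flat unconstrained vector -> ParameterSet on the natural scale."""
        theta = x[self.slices["theta"]].reshape(self.shapes["theta"])
        beta = x[self.slices["beta"]].reshape(self.shapes["beta"])
        alpha = None
        if "alpha" in self.shapes:
            alpha = np.exp(x[self.slices["alpha"]]).reshape(self.shapes["alpha"])
        return ParameterSet(theta=theta, beta=beta, alpha=alpha)

    # -- density ----------------------------------------------------------

    def _likelihood_terms(self, x: np.ndarray):
        """Return (loglik_rows (N,), Z (N,C), A (N,) or None, TH (N,C) or None)."""
        spec, v, C = self.spec, self.spec.variant, self.C
        if v.multidimensional:
            th_flat = x[self.slices["theta"]]
            TH = th_flat[self._ti]  # (N, C)
            if self._ai is not None:
                A = np.exp(x[self.slices["alpha"]])[self._ai]
                Z = A[:, None] * TH
            else:
                A = None
                Z = TH.copy()
            if self._bi is not None:
                Z = Z + x[self.slices["beta"]][self._bi]
        else:
            TH = None
            theta = x[self.slices["theta"]]
            thj = theta[self._ti]  # (N,)
            B = x[self.slices["beta"]][self._bi]
            if v is Variant.NRM_2PL:
                A = np.exp(x[self.slices["alpha"]])[self._ai]  # (N, C)
                Z = A * thj[:, None] + B
            else:
                A = None
                Z = thj[:, None] + B
        Zmax = Z.max(axis=1)
        lse = Zmax + np.log(np.exp(Z - Zmax[:, None]).sum(axis=1))
        ll = Z[self._rows, self._resp] - lse
        return ll, Z, lse, A, TH

    def pointwise_loglik(self, x: np.ndarray) -> np.ndarray:
        return self._likelihood_terms(x)[0]

    def logp_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Joint log density (priors + likelihood + transform Jacobian) and
        its gradient on the unconstrained vector.  Dispatches to the numba
        kernel when available; the numpy path computes the same values."""
        from ._kernels import HAVE_NUMBA, logp_grad

        if HAVE_NUMBA:
            return logp_grad(np.asarray(x, dtype=float), *self._kernel_args)
        return self._logp_and_grad_numpy(x)

    def leapfrog(self, x, p, grad, eps, inv_mass):
        """Compiled leapfrog step (or None when numba is unavailable)."""
        from ._kernels import leapfrog

        return leapfrog(x, p, grad, eps, inv_mass, *self._kernel_args)

    @property
    def compiled_leapfrog(self):
        from ._kernels import HAVE_NUMBA

        return self.leapfrog if HAVE_NUMBA else None

    def _logp_and_grad_numpy(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        spec, v, C = self.spec, self.spec.variant, self.C
        grad = np.zeros_like(x)
        logp = 0.0

        # priors (+ log-Jacobian of the alpha log-transform)
        th = x[self.slices["theta"]]
        be = x[self.slices["beta"]]
        logp += float(
            -0.5 * self._theta_prec * np.dot(th, th) + self._theta_const * th.size
        )
        logp += float(
            -0.5 * self._beta_prec * np.dot(be, be) + self._beta_const * be.size
        )
        grad[self.slices["theta"]] = -self._theta_prec * th
        grad[self.slices["beta"]] = -self._beta_prec * be
        if "alpha" in self.shapes:
            u = x[self.slices["alpha"]]
            a = np.exp(u)
            if spec.alpha_prior is AlphaPrior.GAMMA:
                k, lam = spec.gamma_shape, spec.gamma_rate
                logp += float(np.sum(k * u - lam * a)) + _gamma_const(k, lam) * u.size
                grad[self.slices["alpha"]] = k - lam * a
            else:
                sc = spec.halfnormal_scale
                logp += float(
                    np.sum(u - 0.5 * (a / sc) ** 2)
                    + (np.log(2.0) - _LOG_SQRT_2PI - np.log(sc)) * u.size
                )
                grad[self.slices["alpha"]] = 1.0 - (a / sc) ** 2

        if self.prior_only:
            return logp, grad

        ll, Z, lse, A, TH = self._likelihood_terms(x)
        logp += float(ll.sum())
        P = np.exp(Z - lse[:, None])
        G = -P
        G[self._rows, self._resp] += 1.0  # (N, C): d loglik / d z

        if v.multidimensional:
            w = (A[:, None] * G) if A is not None else G
            grad[self.slices["theta"]] += np.bincount(
                self._ti.ravel(), weights=w.ravel(), minlength=self.sizes["theta"]
            )
            if A is not None:
                ga = (TH * G).sum(axis=1)  # d loglik / d alpha_active
                acc = np.bincount(
                    self._ai, weights=ga, minlength=self.sizes["alpha"]
                )
                grad[self.slices["alpha"]] += acc * np.exp(x[self.slices["alpha"]])
            if self._bi is not None:
                grad[self.slices["beta"]] += np.bincount(
                    self._bi.ravel(), weights=G.ravel(), minlength=self.sizes["beta"]
                )
        else:
            thj = x[self.slices["theta"]][self._ti]
            if v is Variant.NRM_2PL:
                grad[self.slices["theta"]] += np.bincount(
                    self._ti, weights=(A * G).sum(axis=1),
                    minlength=self.sizes["theta"],
                )
                ga = thj[:, None] * G
                acc = np.bincount(
                    self._ai.ravel(), weights=ga.ravel(),
                    minlength=self.sizes["alpha"],
                )
                grad[self.slices["alpha"]] += acc * np.exp(x[self.slices["alpha"]])
            else:
                grad[self.slices["theta"]] += np.bincount(
                    self._ti, weights=G.sum(axis=1),
                    minlength=self.sizes["theta"],
                )
            grad[self.slices["beta"]] += np.bincount(
                self._bi.ravel(), weights=G.ravel(), minlength=self.sizes["beta"]
            )
        return logp, grad

    # -- initialization ---------------------------------------------------

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """Draw an initial unconstrained point from the prior (jittered chains)."""
        spec = self.spec
        x = np.empty(self.dim)
        x[self.slices["theta"]] = rng.normal(
            0.0, spec.theta_scale, self.sizes["theta"]
        )
        x[self.slices["beta"]] = rng.normal(
            0.0, spec.beta_scale, self.sizes["beta"]
        )
        if "alpha" in self.shapes:
            if spec.alpha_prior is AlphaPrior.GAMMA:
                a = rng.gamma(spec.gamma_shape, 1.0 / spec.gamma_rate,
                              self.sizes["alpha"])
            else:
                a = np.abs(rng.normal(0.0, spec.halfnormal_scale,
                                      self.sizes["alpha"]))
            x[self.slices["alpha"]] = np.log(np.maximum(a, 1e-6))
        return x


def _gamma_const(shape: float, rate: float) -> float:
    from math import lgamma, log

    return shape * log(rate) - lgamma(shape)
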