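"""Nominal response model variants for graded multiclass observer studies.

Six related item-response models share one softmax likelihood.  For case
(item) *i*, rater (test-taker) *j* with ground-truth class *s*, the
probability of response class *t* is

    Pr(r_ij = t | s) = softmax(z_ijs·)_t

and the variants differ only in the logit:

======================  =============================  ===========================
variant                 logit z                        parameter shapes
======================  =============================  ===========================
``nrm_2pl``             alpha_it * theta_j + beta_it   theta (J,), alpha/beta (I,C)
``nrm_1pl``             theta_j + beta_it              theta (J,), beta (I,C)
``mdnrm_orig``          theta_jst + beta_is            theta (J,C,C), beta (I,C)
``mdnrm_a``             alpha_is * theta_jst + beta_s  alpha (I,C), beta (C,)
``mdnrm_b``             alpha_s  * theta_jst + beta_is alpha (C,), beta (I,C)
``mdnrm_r``             alpha_is * theta_jst + beta_is alpha (I,C), beta (I,C)
======================  =============================  ===========================

The multidimensional (MDNRM) variants condition on the ground truth: the
ability parameter is a C x C matrix per rater whose diagonal measures the
tendency to answer the true class.

Two consequences of these logit forms, kept deliberately as written:

* in every MDNRM variant the easiness term carries no response index, so it
  is constant across t and cancels in the softmax — the likelihood does not
  identify beta (its posterior equals its prior);
* in ``nrm_1pl`` the same holds for theta_j.

An opt-in ``beta_response_indexed`` flag re-indexes the MDNRM easiness by
the response class (beta_it / beta_t), which does not cancel; it is an
extension, not used for reproducing the published analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats
from scipy.special import log_softmax

from .data import ResponseTable

__all__ = [
    "Variant",
    "AlphaPrior",
    "ModelSpec",
    "ParameterSet",
    "ShapeError",
    "parameter_shapes",
    "logits",
    "class_probabilities",
    "pointwise_loglik",
    "log_prior",
]


class Variant(str, Enum):
    NRM_2PL = "nrm_2pl"
    NRM_1PL = "nrm_1pl"
    MDNRM_ORIG = "mdnrm_orig"
    MDNRM_A = "mdnrm_a"
    MDNRM_B = "mdnrm_b"
    MDNRM_R = "mdnrm_r"

    @property
    def multidimensional(self) -> bool:
        return self in (
            Variant.MDNRM_ORIG,
            Variant.MDNRM_A,
            Variant.MDNRM_B,
            Variant.MDNRM_R,
        )

    @property
    def has_alpha(self) -> bool:
        return self not in (Variant.NRM_1PL, Variant.MDNRM_ORIG)


class AlphaPrior(str, Enum):
    """Prior family for the (nonnegative) discrimination parameter."""

    GAMMA = "gamma"          # Gamma(shape=2, rate=2), mean 1
    HALF_NORMAL = "halfnormal"  # half-normal, scale 10
    NONE = "none"            # variant has no alpha


class ShapeError(ValueError):
    """A parameter array does not match the variant's required shape."""


@dataclass(frozen=True)
class ModelSpec:
    """A model variant plus its prior configuration.

    Defaults follow the published analysis: Normal(0, 2) on every ability
    and easiness entry; Gamma(2, 2) or half-normal(10) on discrimination.
    """

    variant: Variant
    n_classes: int
    alpha_prior: AlphaPrior = AlphaPrior.GAMMA
    gamma_shape: float = 2.0
    gamma_rate: float = 2.0
    halfnormal_scale: float = 10.0
    theta_scale: float = 2.0
    beta_scale: float = 2.0
    beta_response_indexed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", Variant(self.variant))
        object.__setattr__(self, "alpha_prior", AlphaPrior(self.alpha_prior))
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.variant.has_alpha:
            if self.alpha_prior is AlphaPrior.NONE:
                raise ValueError(
                    f"{self.variant.value} has a discrimination parameter; "
                    "alpha_prior must be gamma or halfnormal"
                )
        elif self.alpha_prior is not AlphaPrior.NONE:
            # normalize: variants without alpha always carry prior 'none'
            object.__setattr__(self, "alpha_prior", AlphaPrior.NONE)
        for name in ("gamma_shape", "gamma_rate", "halfnormal_scale",
                     "theta_scale", "beta_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def label(self) -> str:
        if not self.variant.has_alpha:
            return self.variant.value
        return f"{self.variant.value}+{self.alpha_prior.value}"


def parameter_shapes(
    spec: ModelSpec, n_cases: int, n_raters: int
) -> dict[str, tuple[int, ...]]:
    """Required array shape per parameter family for this variant."""
    I, J, C = n_cases, n_raters, spec.n_classes
    v = spec.variant
    shapes: dict[str, tuple[int, ...]] = {}
    shapes["theta"] = (J, C, C) if v.multidimensional else (J,)
    if v in (Variant.MDNRM_A, Variant.MDNRM_R, Variant.NRM_2PL):
        shapes["alpha"] = (I, C)
    elif v is Variant.MDNRM_B:
        shapes["alpha"] = (C,)
    if v is Variant.MDNRM_A:
        shapes["beta"] = (C,)
    else:
        shapes["beta"] = (I, C)
    return shapes


@dataclass
class ParameterSet:
    """One concrete value of (theta, alpha, beta), shaped for a variant."""

    theta: np.ndarray
    beta: np.ndarray
    alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)

    def validate(self, spec: ModelSpec, n_cases: int, n_raters: int) -> None:
        shapes = parameter_shapes(spec, n_cases, n_raters)
        for name, want in shapes.items():
            arr = getattr(self, name)
            if name == "alpha" and arr is None:
                raise ShapeError(f"variant {spec.variant.value} requires alpha")
            if arr.shape != want:
                raise ShapeError(
                    f"{name} has shape {arr.shape}, expected {want} "
                    f"for variant {spec.variant.value}"
                )
        if "alpha" not in shapes and self.alpha is not None:
            raise ShapeError(
                f"variant {spec.variant.value} has no discrimination parameter"
            )
        for name in shapes:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ShapeError(f"{name} contains non-finite entries")

    def to_frame(self):
        """Columnar (parameter, index..., value) serialization."""
        import pandas as pd

        rows = []
        for name in ("theta", "alpha", "beta"):
            arr = getattr(self, name)
            if arr is None:
                continue
            for idx in np.ndindex(arr.shape):
                rows.append((name, *idx, float(arr[idx])))
        width = max(len(r) for r in rows) - 2
        cols = ["parameter"] + [f"index{k}" for k in range(width)] + ["value"]
        padded = [r[:1] + r[1:-1] + (None,) * (width - (len(r) - 2)) + r[-1:]
                  for r in rows]
        return pd.DataFrame(padded, columns=cols)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def row_logits(
    spec: ModelSpec,
    params: ParameterSet,
    table: ResponseTable,
    include_constant_beta: bool = True,
) -> np.ndarray:
    """(N, C) matrix of logits, one row per table row, columns = response class.

    In the multidimensional variants (without the response-indexed easiness
    extension) beta is constant across the response class, so it shifts the
    whole logit vector and cancels in the softmax; ``include_constant_beta=
    False`` omits that term, which leaves every downstream probability
    bit-identical while making the cancellation exact in floating point.
    """
    params.validate(spec, table.n_cases, table.n_raters)
    i, j, s = table.case_id, table.rater_id, table.ground_truth
    v = spec.variant
    if v.multidimensional:
        th = params.theta[j, s, :]  # (N, C)
        if v in (Variant.MDNRM_A, Variant.MDNRM_R):
            a = params.alpha[i, s][:, None]
        elif v is Variant.MDNRM_B:
            a = params.alpha[s][:, None]
        else:
            a = 1.0
        if spec.beta_response_indexed:
            b = params.beta[None, :] if v is Variant.MDNRM_A else params.beta[i, :]
        elif include_constant_beta:
            b = (params.beta[s] if v is Variant.MDNRM_A else params.beta[i, s])[:, None]
        else:
            b = 0.0
        return a * th + b
    th = params.theta[j][:, None]  # (N, 1)
    if v is Variant.NRM_2PL:
        return params.alpha[i, :] * th + params.beta[i, :]
    return th + params.beta[i, :]


def logits(
    spec: ModelSpec,
    params: ParameterSet,
    case: int,
    rater: int,
    truth: int,
) -> np.ndarray:
    """Length-C logit vector for one (case, rater, ground-truth) triple."""
    if not 0 <= truth < spec.n_classes:
        raise IndexError(f"truth {truth} outside [0, {spec.n_classes})")
    n_cases = len(params.beta) if params.beta.ndim == 2 else (
        len(params.alpha) if params.alpha is not None and params.alpha.ndim == 2
        else case + 1
    )
    n_raters = len(params.theta)
    params.validate(spec, n_cases, n_raters)
    if not 0 <= case < n_cases:
        raise IndexError(f"case {case} outside [0, {n_cases})")
    if not 0 <= rater < n_raters:
        raise IndexError(f"rater {rater} outside [0, {n_raters})")
    v = spec.variant
    if v.multidimensional:
        th = params.theta[rater, truth, :]
        if v in (Variant.MDNRM_A, Variant.MDNRM_R):
            a = params.alpha[case, truth]
        elif v is Variant.MDNRM_B:
            a = params.alpha[truth]
        else:
            a = 1.0
        if spec.beta_response_indexed:
            b = params.beta if v is Variant.MDNRM_A else params.beta[case, :]
        else:
            b = params.beta[truth] if v is Variant.MDNRM_A else params.beta[case, truth]
        return a * th + b
    th = params.theta[rater]
    if v is Variant.NRM_2PL:
        return params.alpha[case, :] * th + params.beta[case, :]
    return th + params.beta[case, :]


def class_probabilities(z: np.ndarray) -> np.ndarray:
    """Softmax of a logit vector, computed max-subtracted for stability."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite logits")
    e = np.exp(z - np.max(z, axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def pointwise_loglik(
    spec: ModelSpec, params: ParameterSet, table: ResponseTable
) -> np.ndarray:
    """log Pr(response_n | case_n, rater_n, truth_n) per table row, in row order.

    A constant-across-response easiness term is dropped before the softmax
    (it cancels exactly), so the result is bit-invariant to beta in the
    multidimensional variants.
    """
    z = row_logits(spec, params, table, include_constant_beta=False)
    logp = log_softmax(z, axis=-1)
    return logp[np.arange(table.n_rows), table.response]


def log_prior(spec: ModelSpec, params: ParameterSet) -> float:
    """Joint log prior density of a parameter set (sum over all entries)."""
    total = float(
        stats.norm.logpdf(params.theta, scale=spec.theta_scale).sum()
        + stats.norm.logpdf(params.beta, scale=spec.beta_scale).sum()
    )
    if spec.variant.has_alpha:
        a = params.alpha
        if np.any(a < 0):
            return -np.inf
        if spec.alpha_prior is AlphaPrior.GAMMA:
            total += float(
                stats.gamma.logpdf(
                    a, spec.gamma_shape, scale=1.0 / spec.gamma_rate
                ).sum()
            )
        else:
            total += float(
                stats.halfnorm.logpdf(a, scale=spec.halfnormal_scale).sum()
            )
    return total
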