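"""MCMC fitting of nominal response models and convergence diagnostics.

:func:`fit` runs independent NUTS chains on the unconstrained posterior,
initialized from the prior, and returns named draws plus the pointwise
log-likelihood matrix needed for information-criterion model comparison.
The default sampler settings (8 chains, 1,000 warmup, 8,000 retained draws
per chain) match the published analysis; desk-scale work uses far fewer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtri

from ._target import Target
from .data import ResponseTable
from .models import ModelSpec, ParameterSet
from .nuts import nuts_sample

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "fit",
    "rhat",
    "rhat_array",
    "convergence_report",
    "ConvergenceReport",
]


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings; defaults mirror the published run."""

    n_chains: int = 8
    n_warmup: int = 1000
    n_samples: int = 8000
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10
    thin: int = 1

    def __post_init__(self) -> None:
        for name in ("n_chains", "n_warmup", "n_samples", "thin"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class PosteriorDraws:
    """Named chain-indexed MCMC draws plus the pointwise log-likelihood.

    ``draws[name]`` has shape (chain, draw, \\*parameter shape); ``loglik``
    is (S, N) with S = chains x draws pooled in chain-major order.
    """

    draws: dict[str, np.ndarray]
    loglik: np.ndarray
    spec: ModelSpec
    config: McmcConfig
    table_shape: tuple[int, int, int]  # (I, J, C)
    divergences: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    step_sizes: np.ndarray = field(default_factory=lambda: np.zeros(0))
    prior_only: bool = False

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Pooled draws: (S, \\*parameter shape)."""
        arr = self.draws[name]
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    def parameter_set(self, s: int) -> ParameterSet:
        """The s-th pooled draw as a ParameterSet."""
        return ParameterSet(
            theta=self.stacked("theta")[s],
            beta=self.stacked("beta")[s],
            alpha=self.stacked("alpha")[s] if "alpha" in self.draws else None,
        )

    def to_inference_data(self):
        """Convert to an :class:`arviz.InferenceData` (log_likelihood included)."""
        import arviz as az

        S = self.n_chains * self.n_draws
        ll = self.loglik.reshape(self.n_chains, self.n_draws, -1)
        return az.from_dict(
            posterior={k: v for k, v in self.draws.items()},
            log_likelihood={"obs": ll},
        )

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Write draws + loglik as .npz with a JSON sidecar (spec/config)."""
        from pathlib import Path

        path = Path(path)
        arrays = {f"draws_{k}": v for k, v in self.draws.items()}
        arrays["loglik"] = self.loglik
        arrays["divergences"] = self.divergences
        arrays["step_sizes"] = self.step_sizes
        np.savez(path.with_suffix(".npz"), **arrays)
        spec = asdict(self.spec)
        spec["variant"] = self.spec.variant.value
        spec["alpha_prior"] = self.spec.alpha_prior.value
        sidecar = {
            "spec": spec,
            "config": asdict(self.config),
            "table_shape": list(self.table_shape),
            "prior_only": self.prior_only,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        from pathlib import Path

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as npz:
            draws = {
                k[len("draws_"):]: npz[k] for k in npz.files if k.startswith("draws_")
            }
            return cls(
                draws=draws,
                loglik=npz["loglik"],
                spec=ModelSpec(**meta["spec"]),
                config=McmcConfig(**meta["config"]),
                table_shape=tuple(meta["table_shape"]),
                divergences=npz["divergences"],
                step_sizes=npz["step_sizes"],
                prior_only=meta.get("prior_only", False),
            )


def fit(
    spec: ModelSpec,
    table: ResponseTable,
    config: McmcConfig,
    prior_only: bool = False,
) -> PosteriorDraws:
    """Sample the posterior of ``spec`` given ``table`` with NUTS.

    Chains are initialized independently from the prior; one master seed
    fans out per-chain seeds through :class:`numpy.random.SeedSequence`, so
    identical inputs give bit-identical draws.  Divergence counts are kept
    on the result, never dropped.  With ``prior_only=True`` the likelihood
    term is switched off (prior-predictive check).
    """
    if spec.n_classes != table.n_classes:
        raise ValueError(
            f"spec has C={spec.n_classes} but table has C={table.n_classes}"
        )
    target = Target(spec, table, prior_only=prior_only)
    n_kept = config.n_samples // config.thin
    chain_draws = np.empty((config.n_chains, n_kept, target.dim))
    divergences = np.zeros(config.n_chains, dtype=int)
    step_sizes = np.zeros(config.n_chains)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for c, ss in enumerate(seeds):
        rng = np.random.Generator(np.random.PCG64(ss))
        x0 = target.initial_point(rng)
        logp0, _ = target.logp_and_grad(x0)
        if not np.isfinite(logp0):
            raise FloatingPointError(
                f"chain {c}: non-finite log density at the prior-drawn "
                "initial point; check parameter scales"
            )
        res = nuts_sample(
            target.logp_and_grad,
            x0,
            n_warmup=config.n_warmup,
            n_samples=config.n_samples,
            rng=rng,
            target_accept=config.target_accept,
            max_treedepth=config.max_treedepth,
            leapfrog=target.compiled_leapfrog,
        )
        chain_draws[c] = res.draws[config.thin - 1 :: config.thin]
        divergences[c] = int(res.divergent.sum())
        step_sizes[c] = res.step_size

    # unpack flat draws into named natural-scale arrays
    draws: dict[str, np.ndarray] = {}
    for name in target.names:
        sl, shape = target.slices[name], target.shapes[name]
        block = chain_draws[:, :, sl].reshape(config.n_chains, n_kept, *shape)
        if name == "alpha":
            block = np.exp(block)
        draws[name] = block

    # pointwise log-likelihood at every retained draw
    flat = chain_draws.reshape(config.n_chains * n_kept, target.dim)
    loglik = np.empty((flat.shape[0], table.n_rows))
    for s in range(flat.shape[0]):
        loglik[s] = target.pointwise_loglik(flat[s])

    return PosteriorDraws(
        draws=draws,
        loglik=loglik,
        spec=spec,
        config=config,
        table_shape=(table.n_cases, table.n_raters, table.n_classes),
        divergences=divergences,
        step_sizes=step_sizes,
        prior_only=prior_only,
    )


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def _split_chains(x: np.ndarray) -> np.ndarray:
    """(chains, draws) -> (2*chains, draws//2), dropping an odd last draw."""
    m, n = x.shape
    half = n // 2
    return np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)


def rhat_array(x: np.ndarray, rank_normalize: bool = True) -> float:
    """Split-R̂ of one scalar parameter given draws shaped (chains, draws).

    Rank-normalized by default: pooled draws are replaced by normal scores
    ``Phi^{-1}((rank - 3/8) / (S + 1/4))`` before the classic
    between/within variance ratio is computed on split half-chains.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need draws shaped (n_chains >= 2, n_draws)")
    if x.shape[1] < 4:
        raise ValueError("need at least 4 draws per chain")
    z = _split_chains(x)
    if np.ptp(z) == 0.0:
        warnings.warn("zero-variance parameter: R-hat undefined", RuntimeWarning)
        return float("nan")
    if rank_normalize:
        S = z.size
        ranks = np.argsort(np.argsort(z, axis=None)).reshape(z.shape) + 1.0
        z = ndtri((ranks - 3.0 / 8.0) / (S + 0.25))
    m, n = z.shape
    chain_means = z.mean(axis=1)
    w = z.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w == 0.0:
        warnings.warn("zero within-chain variance: R-hat undefined", RuntimeWarning)
        return float("nan")
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def rhat(
    draws: PosteriorDraws, parameter: str, index: tuple[int, ...] = ()
) -> float:
    """Rank-normalized split-R̂ for one named parameter entry."""
    arr = draws.draws[parameter]
    x = arr[(slice(None), slice(None)) + tuple(index)]
    return rhat_array(x)


@dataclass
class ConvergenceReport:
    max_rhat: float
    converged: bool
    table: pd.DataFrame  # parameter, index, rhat — sorted worst first
    threshold: float


def convergence_report(
    draws: PosteriorDraws, threshold: float = 1.10
) -> ConvergenceReport:
    """R̂ for every parameter entry; converged iff the max is below threshold."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for name, arr in draws.draws.items():
            shape = arr.shape[2:]
            for idx in np.ndindex(shape) if shape else [()]:
                x = arr[(slice(None), slice(None)) + idx]
                rows.append((name, idx, rhat_array(x)))
    table = pd.DataFrame(rows, columns=["parameter", "index", "rhat"])
    table = table.sort_values("rhat", ascending=False, ignore_index=True)
    max_rhat = float(np.nanmax(table["rhat"])) if len(table) else float("nan")
    return ConvergenceReport(
        max_rhat=max_rhat,
        converged=bool(max_rhat < threshold),
        table=table,
        threshold=threshold,
    )
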