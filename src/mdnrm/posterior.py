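"""Posterior summaries and ability-parameter comparison.

Summary tables follow the published layout (rad_index, index1, index2,
Mean, SD, HDI_3%, HDI_97%, Rhat).  Two ability entries are compared by the
probability of direction (PD) of their pooled-draw difference, together
with the 94% highest-density interval of that difference; the reported
significance flag is "0 lies outside the 94% HDI", with PD always attached
so users may apply their own cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorDraws, rhat_array

__all__ = [
    "ParameterSummary",
    "ContrastResult",
    "hdi",
    "pd_direction",
    "compare_abilities",
    "summary_table",
    "plot_contrast",
]


def hdi(draws: np.ndarray, prob: float = 0.94) -> tuple[float, float]:
    """Shortest contiguous interval containing ``prob`` of the draws.

    Sliding-window minimum width over the sorted sample; the window holds
    ``ceil(prob * n)`` draws.  A point mass collapses to (v, v).
    """
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must lie strictly between 0 and 1")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    k = int(np.ceil(prob * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    lo = int(np.argmin(widths))
    return float(x[lo]), float(x[lo + k])


def pd_direction(diff_draws: np.ndarray) -> float:
    """Probability of direction: the larger of Pr(>0) and Pr(<0).

    Exact zeros are split evenly between the two signs, so a sample
    symmetric about 0 gives exactly 0.5.
    """
    x = np.asarray(diff_draws, dtype=float).ravel()
    if len(x) == 0:
        raise ValueError("empty sample")
    pos = np.count_nonzero(x > 0)
    neg = np.count_nonzero(x < 0)
    zeros = len(x) - pos - neg
    p_pos = (pos + 0.5 * zeros) / len(x)
    return float(max(p_pos, 1.0 - p_pos))


@dataclass(frozen=True)
class ContrastResult:
    """PD/HDI verdict on the difference of two ability entries (A - B)."""

    a: tuple
    b: tuple
    pd: float
    hdi_low: float
    hdi_high: float
    prob: float = 0.94

    @property
    def significant(self) -> bool:
        """True iff 0 lies outside the HDI of the difference (derived, not stored)."""
        return not (self.hdi_low <= 0.0 <= self.hdi_high)

    def to_dict(self) -> dict:
        return {
            "a": list(self.a),
            "b": list(self.b),
            "pd": self.pd,
            "hdi_low": self.hdi_low,
            "hdi_high": self.hdi_high,
            "hdi_prob": self.prob,
            "significant": self.significant,
        }


def _theta_draws(draws: PosteriorDraws, index: tuple) -> np.ndarray:
    theta = draws.stacked("theta")
    if theta.ndim == 1 + len(index):
        return theta[(slice(None),) + tuple(index)]
    raise IndexError(
        f"theta index {index} has {len(index)} components but the fitted "
        f"variant stores theta with {theta.ndim - 1} index dimensions "
        "(NRM variants take a single rater index)"
    )


def compare_abilities(
    draws: PosteriorDraws,
    a: tuple,
    b: tuple,
    prob: float = 0.94,
) -> ContrastResult:
    """Contrast two ability entries, e.g. ``a=(1, 2, 2), b=(5, 2, 2)``.

    Indices are (rater, truth-class, response-class) for the
    multidimensional variants and (rater,) for the unidimensional ones.
    Draws are pooled across chains before PD and HDI are computed.
    """
    diff = _theta_draws(draws, tuple(a)) - _theta_draws(draws, tuple(b))
    lo, hi = hdi(diff, prob=prob)
    return ContrastResult(
        a=tuple(a), b=tuple(b), pd=pd_direction(diff),
        hdi_low=lo, hdi_high=hi, prob=prob,
    )


#: published column layout of the ability-parameter tables
SUMMARY_COLUMNS = ["Mean", "SD", "HDI_3%", "HDI_97%", "Rhat"]


@dataclass(frozen=True)
class ParameterSummary:
    parameter: str
    index: tuple
    mean: float
    sd: float
    hdi_low: float
    hdi_high: float
    rhat: float


def summary_table(
    draws: PosteriorDraws, parameter_family: str, hdi_prob: float = 0.94
) -> pd.DataFrame:
    """One row per index tuple of a parameter family, published-table layout.

    For a three-index family the index columns are named
    ``rad_index, index1, index2``; fewer indices drop trailing columns.
    Means/SDs pool all chains; Rhat is the rank-normalized split diagnostic.
    """
    if parameter_family not in draws.draws:
        raise KeyError(
            f"unknown parameter family {parameter_family!r}; "
            f"have {sorted(draws.draws)}"
        )
    arr = draws.draws[parameter_family]  # (chain, draw, *shape)
    shape = arr.shape[2:]
    index_names = (
        ["rad_index", "index1", "index2"][: len(shape)]
        if parameter_family == "theta"
        else [f"index{k}" for k in range(len(shape))]
    )
    import warnings as _warnings

    rows = []
    for idx in (np.ndindex(shape) if shape else [()]):
        x = arr[(slice(None), slice(None)) + idx]
        pooled = x.ravel()
        lo, hi = hdi(pooled, prob=hdi_prob)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            r = rhat_array(x)
        rows.append(
            dict(zip(index_names, idx))
            | {
                "Mean": pooled.mean(),
                "SD": pooled.std(ddof=1),
                "HDI_3%": lo,
                "HDI_97%": hi,
                "Rhat": r,
            }
        )
    return pd.DataFrame(rows, columns=index_names + SUMMARY_COLUMNS)


def plot_contrast(
    draws: PosteriorDraws, a: tuple, b: tuple, prob: float = 0.94, path=None
):
    """Histogram of both ability posteriors and of their difference with the
    sign split annotated (the figure style used for PD reporting)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    da = _theta_draws(draws, tuple(a))
    db = _theta_draws(draws, tuple(b))
    diff = da - db
    result = compare_abilities(draws, a, b, prob=prob)
    fig, axes = plt.subplots(1, 3, figsize=(10, 3))
    for ax, x, title in zip(axes[:2], (da, db), (f"theta{a}", f"theta{b}")):
        ax.hist(x, bins=60, color="steelblue")
        ax.set_title(title)
    ax = axes[2]
    ax.hist(diff[diff > 0], bins=40, color="seagreen", label="> 0")
    ax.hist(diff[diff <= 0], bins=40, color="indianred", label="<= 0")
    ax.axvline(0.0, color="black", lw=1)
    ax.set_title(f"difference, PD = {result.pd:.3f}")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
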