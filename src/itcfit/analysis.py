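"""Posterior summaries: shortest credible intervals, medians, correlations.

Credible intervals are highest-density-style *shortest* intervals: among all
contiguous windows of ``ceil(level * n)`` order statistics, the narrowest
one.  For unimodal marginals this coincides with the highest-density
interval as n grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import ExperimentDesign, ParameterState, model_heats
from .sampler import PARAM_NAMES, PosteriorSamples

__all__ = [
    "IntervalEstimate",
    "shortest_credible_interval",
    "posterior_summary",
    "correlation_matrix",
    "enthalpy_concentration_tradeoff",
]


@dataclass(frozen=True)
class IntervalEstimate:
    """A (lower, upper) interval for one scalar parameter.

    ``method`` distinguishes Bayesian shortest credible intervals ("BCI")
    from normal-theory regression confidence intervals ("NlRCI");
    ``bound_uncertainty`` optionally carries bootstrap SDs of the bounds.
    """

    parameter: str
    lower: float
    upper: float
    level: float
    method: str = "BCI"
    bound_uncertainty: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.level <= 1.0):
            raise ValueError("level must be in (0, 1]")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def shortest_credible_interval(
    samples: Sequence[float], level: float, parameter: str = ""
) -> IntervalEstimate:
    """Shortest interval containing ``level`` of the draws.

    Scans all windows of ``m = ceil(level * n)`` consecutive order
    statistics and returns the narrowest (ties broken toward the lower
    lower-bound).
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("need at least one sample")
    if not (0.0 < level <= 1.0):
        raise ValueError("level must be in (0, 1]")
    m = math.ceil(level * n)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lowest lower bound
    return IntervalEstimate(parameter, float(x[i]), float(x[i + m - 1]), level)


def posterior_summary(
    samples: PosteriorSamples, levels: Sequence[float] = (0.95,)
) -> pd.DataFrame:
    """Median, mean and shortest credible intervals for each parameter.

    The entropic term TdS = dH - dG is computed per draw before summarising,
    so its interval reflects the joint dG/dH posterior, not a combination
    of marginal bounds.
    """
    if len(samples) == 0:
        raise ValueError("empty sample set")
    columns = {name: samples[name] for name in PARAM_NAMES}
    columns["TdS"] = samples.TdS
    rows = []
    for name, x in columns.items():
        row = {
            "parameter": name,
            "median": float(np.median(x)),
            "mean": float(np.mean(x)),
        }
        for lv in levels:
            iv = shortest_credible_interval(x, lv, name)
            row[f"lower_{int(round(lv * 100))}"] = iv.lower
            row[f"upper_{int(round(lv * 100))}"] = iv.upper
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


def correlation_matrix(
    samples: PosteriorSamples,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations over (dG, dH, dH0, Ls, R0, ln sigma).

    Returns ``(corr, boot_sd)`` DataFrames.  Bootstrap uncertainty comes
    from resampling the stored (post-thinning) states with replacement.
    Zero-variance columns give NaN entries (flagged via NaN, never silently
    zero); the diagonal is exactly 1 wherever the column varies.
    """
    if len(samples) < 10:
        raise ValueError("need at least 10 samples")
    rng = rng or np.random.default_rng()
    X = np.column_stack([samples[name] for name in PARAM_NAMES])
    corr = _corr(X)
    n = X.shape[0]
    boots = np.empty((n_bootstrap, len(PARAM_NAMES), len(PARAM_NAMES)))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        boots[b] = _corr(X[idx])
    sd = np.nanstd(boots, axis=0, ddof=0)
    names = list(PARAM_NAMES)
    return (
        pd.DataFrame(corr, index=names, columns=names),
        pd.DataFrame(sd, index=names, columns=names),
    )


def _corr(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    ok = sd > 0
    k = X.shape[1]
    out = np.full((k, k), np.nan)
    if ok.any():
        sub = np.corrcoef(X[:, ok], rowvar=False)
        out[np.ix_(ok, ok)] = sub
    # exact ones on the varying diagonal
    for i in range(k):
        if ok[i]:
            out[i, i] = 1.0
    return out


def enthalpy_concentration_tradeoff(
    samples: PosteriorSamples,
    design: ExperimentDesign,
    R0_grid: Sequence[float] | None = None,
) -> dict:
    """Linear enthalpy-concentration compensation ridge.

    Fits least-squares lines Ls(R0) and dH(R0) through the posterior draws
    and evaluates the model heat curve along the ridge at a grid of R0
    values, holding dG, dH0 at the last stored state.  Nearly identical
    heat curves along the ridge demonstrate that dH and the concentrations
    are jointly underdetermined by a single titration.
    """
    R0 = samples["R0"]
    if np.std(R0) <= 1e-12 * abs(float(np.mean(R0))):
        raise ValueError("degenerate R0 samples: no variance to regress over")
    Ls, dH = samples["Ls"], samples["dH"]
    ls_slope, ls_icpt = np.polyfit(R0, Ls, 1)
    dh_slope, dh_icpt = np.polyfit(R0, dH, 1)
    last = samples.draws.iloc[-1]
    if R0_grid is None:
        lo, hi = np.percentile(R0, [2.5, 97.5])
        R0_grid = np.linspace(lo, hi, 5)
    curves = []
    for r0 in np.asarray(R0_grid, dtype=float):
        state = ParameterState(
            dG=float(last["dG"]),
            dH=float(dh_icpt + dh_slope * r0),
            dH0=float(last["dH0"]),
            Ls=float(ls_icpt + ls_slope * r0),
            R0=float(r0),
            sigma=float(np.exp(last["ln_sigma"])),
        )
        curves.append(model_heats(state, design))
    return {
        "Ls_slope": float(ls_slope),
        "Ls_intercept": float(ls_icpt),
        "dH_slope": float(dh_slope),
        "dH_intercept": float(dh_icpt),
        "R0_grid": np.asarray(R0_grid, dtype=float),
        "heat_curves": np.array(curves),
    }
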