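"""Interval-calibration curves and KDE-based Kullback-Leibler divergences.

Calibration: a well-calibrated interval procedure contains its reference
value in a fraction of experiments equal to the stated level, so the
observed-containment-versus-level curve lies on the diagonal.

Consistency: the KL divergence between the (dG, dH) marginals of two
experiments measures how much information is lost when one experiment's
distribution stands in for the other's.  Densities are Gaussian kernel
density estimates over posterior draws (or over Gaussian pseudo-draws for
the least-squares analysis), and the integral is estimated by a Monte Carlo
average over the first sample set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import KernelDensity

from .analysis import IntervalEstimate

__all__ = [
    "KlEstimate",
    "coverage_curve",
    "kl_divergence_2d",
    "kl_matrix",
    "DEFAULT_KDE_BANDWIDTH",
]

#: Gaussian-kernel bandwidth in kcal/mol for (dG, dH) density estimates.
DEFAULT_KDE_BANDWIDTH = 0.03

_LOG_FLOOR = -700.0  # below exp-underflow; clip instead of propagating -inf


@dataclass(frozen=True)
class KlEstimate:
    """A KDE-based divergence estimate in nats."""

    value: float
    bandwidth: float
    n1: int
    n2: int


def coverage_curve(
    intervals: Sequence[Sequence[IntervalEstimate]],
    reference: float,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Observed containment fraction per stated level, with bootstrap SDs.

    ``intervals[i]`` holds one experiment's intervals over a common level
    grid; ``reference`` is the value the intervals are meant to contain
    (the true value for simulations, or the median of per-experiment
    estimates for real replicates).  Bootstrapping resamples experiments.
    """
    if len(intervals) < 2:
        raise ValueError("need at least two experiments")
    levels = [iv.level for iv in intervals[0]]
    if not levels:
        raise ValueError("empty level grid")
    for ivs in intervals:
        if [iv.level for iv in ivs] != levels:
            raise ValueError("experiments must share a common level grid")
    rng = rng or np.random.default_rng()
    hits = np.array(
        [[iv.contains(reference) for iv in ivs] for ivs in intervals], dtype=float
    )  # (n_exp, n_levels)
    n_exp = hits.shape[0]
    observed = hits.mean(axis=0)
    idx = rng.integers(0, n_exp, size=(n_bootstrap, n_exp))
    boot = hits[idx].mean(axis=1)  # (n_bootstrap, n_levels)
    return pd.DataFrame(
        {
            "level": levels,
            "observed": observed,
            "bootstrap_sd": boot.std(axis=0, ddof=0),
            "n_experiments": n_exp,
        }
    )


def _kde(samples: np.ndarray, bandwidth: float) -> KernelDensity:
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth)
    kde.fit(samples)
    return kde


def kl_divergence_2d(
    samples_1,
    samples_2,
    bandwidth: float = DEFAULT_KDE_BANDWIDTH,
) -> KlEstimate:
    """KL divergence D(p1 || p2) between two (dG, dH) sample clouds.

    Both sample sets are (n, 2) arrays in kcal/mol.  Gaussian KDEs p1-hat
    and p2-hat are fitted to each cloud and the divergence is the Monte
    Carlo average of ``ln p1-hat - ln p2-hat`` over the first cloud.  The
    estimator is asymmetric in its arguments and exactly zero when the two
    clouds are identical.  Vanishing p2-hat under cloud 1 (disjoint
    supports) is clipped at the exp-underflow floor with a warning.
    """
    x1 = np.atleast_2d(np.asarray(samples_1, dtype=float))
    x2 = np.atleast_2d(np.asarray(samples_2, dtype=float))
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both sample sets must be non-empty")
    if x1.shape[1] != 2 or x2.shape[1] != 2:
        raise ValueError("expected (n, 2) arrays of (dG, dH) draws")
    k1 = _kde(x1, bandwidth)
    k2 = _kde(x2, bandwidth)
    lp1 = k1.score_samples(x1)
    lp2 = k2.score_samples(x1)
    if x2.shape != x1.shape or not np.array_equal(x1, x2):
        # evaluating p1-hat at its own training points is upward-biased
        # (every point sits in its own kernel); remove the self term,
        # leaving the leave-one-out density.  Skipped for identical inputs
        # so that the self-divergence is exactly zero.
        n1 = x1.shape[0]
        if n1 > 1:
            log_self = -math.log(2.0 * math.pi * bandwidth * bandwidth)
            dens = np.exp(lp1)
            loo = (n1 * dens - math.exp(log_self)) / (n1 - 1)
            lp1 = np.log(np.maximum(loo, np.exp(_LOG_FLOOR)))
    if np.any(lp2 <= _LOG_FLOOR):
        warnings.warn(
            "second density vanishes under the first sample set; "
            "log-density clipped",
            RuntimeWarning,
        )
        lp2 = np.maximum(lp2, _LOG_FLOOR)
    return KlEstimate(
        value=float(np.mean(lp1 - lp2)),
        bandwidth=bandwidth,
        n1=x1.shape[0],
        n2=x2.shape[0],
    )


def kl_matrix(
    experiments: Sequence[np.ndarray],
    bandwidth: float = DEFAULT_KDE_BANDWIDTH,
    log_scale: bool = False,
    diagonal_sentinel: float = 1.0,
) -> np.ndarray:
    """Pairwise divergence matrix across experiments.

    Entry (i, j) is D(p_i || p_j); the matrix is asymmetric.  With
    ``log_scale`` the natural log of each divergence is reported and the
    diagonal (log of zero) is replaced by ``diagonal_sentinel`` for
    visualisation.
    """
    if len(experiments) < 2:
        raise ValueError("need at least two experiments")
    k = len(experiments)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                out[i, j] = diagonal_sentinel if log_scale else 0.0
                continue
            d = kl_divergence_2d(experiments[i], experiments[j], bandwidth).value
            out[i, j] = math.log(d) if log_scale and d > 0 else (
                _LOG_FLOOR if log_scale else d
            )
    return out
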