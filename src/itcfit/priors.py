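"""Likelihood, priors and log-posterior for the Bayesian binding model.

The observed heats are modelled as the deterministic binding heats plus iid
Gaussian noise of unknown scale sigma.  Priors are uniform on the energies
(dG, dH over fixed boxes; dH0 over a data-derived box spanning the observed
heat range), lognormal or uniform on the two concentrations depending on the
selected concentration model, and Jeffreys (1/sigma) on the noise scale,
made proper by finite bounds on ln sigma.

Three concentration models are provided:

* ``general`` — lognormal priors on both concentrations with 10% relative
  uncertainty (deviations from the stated values allowed but penalised);
* ``flat-r0`` — uniform prior on the cell concentration (unknown titrand
  purity), lognormal 10% on the syringe concentration;
* ``comparison`` — uniform cell concentration and a nearly-sharp (0.1%)
  syringe concentration, mimicking the assumptions of the standard
  least-squares analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binding import ExperimentDesign, ParameterState, _heats_from_coords

__all__ = [
    "PriorConfig",
    "lognormal_params",
    "lognormal_logpdf",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "make_log_posterior",
    "posterior_pack",
]

_MODEL_ALIASES = {
    "general": "general",
    "flatr0": "flat-r0",
    "flat-r0": "flat-r0",
    "flat_r0": "flat-r0",
    "comparison": "comparison",
}

LN2PI = math.log(2.0 * math.pi)


def lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """Log-scale (mu, s) of a lognormal with given mean and coefficient of
    variation.

    The convention used everywhere in this package (simulator and prior
    alike): the concentration itself is lognormal, with mean equal to the
    stated value and standard deviation ``cv * mean``.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    s2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * s2
    return mu, math.sqrt(s2)


def lognormal_logpdf(x: float, mean: float, cv: float) -> float:
    """Log-density at ``x`` of the mean/CV-parameterised lognormal."""
    if x <= 0:
        return -math.inf
    mu, s = lognormal_params(mean, cv)
    z = (math.log(x) - mu) / s
    return -math.log(x * s) - 0.5 * LN2PI - 0.5 * z * z


@dataclass(frozen=True)
class PriorConfig:
    """Prior hyper-parameters for one analysis.

    ``model_name`` selects the concentration model.  Energy boxes are in
    kcal/mol; ``sigma_lo_factor``/``sigma_hi_factor`` set the bounds of the
    (flat-in-log) noise prior as multiples of the observed heat range.
    """

    model_name: str = "general"
    dG_bounds: tuple[float, float] = (-40.0, 40.0)
    dH_bounds: tuple[float, float] = (-100.0, 100.0)
    titrant_cv: float | None = None
    titrand_cv: float | None = None
    R0_flat_factor: float = 10.0
    sigma_lo_factor: float = 1e-4
    sigma_hi_factor: float = 10.0

    def __post_init__(self) -> None:
        name = _MODEL_ALIASES.get(self.model_name.lower().replace(" ", ""))
        if name is None:
            raise ValueError(f"unknown prior model {self.model_name!r}")
        object.__setattr__(self, "model_name", name)
        if self.dG_bounds[0] >= self.dG_bounds[1]:
            raise ValueError("dG bounds out of order")
        if self.dH_bounds[0] >= self.dH_bounds[1]:
            raise ValueError("dH bounds out of order")
        # per-model defaults
        if self.titrant_cv is None:
            object.__setattr__(
                self, "titrant_cv", 0.001 if self.model_name == "comparison" else 0.1
            )
        if self.titrand_cv is None:
            object.__setattr__(
                self, "titrand_cv", 0.1 if self.model_name == "general" else None
            )
        if self.titrant_cv is not None and self.titrant_cv < 0:
            raise ValueError("titrant_cv must be non-negative")

    @property
    def r0_is_flat(self) -> bool:
        return self.model_name in ("flat-r0", "comparison")


def _heat_stats(heats: np.ndarray) -> tuple[float, float, float]:
    q = np.asarray(heats, dtype=float)
    qmin, qmax = float(q.min()), float(q.max())
    return qmin, qmax, qmax - qmin


def log_likelihood(
    state: ParameterState, heats: Sequence[float], design: ExperimentDesign
) -> float:
    """Gaussian log-likelihood of observed heats (cal) given a state."""
    if state.sigma <= 0:
        raise ValueError("sigma must be positive")
    q = np.asarray(heats, dtype=float)
    qstar = _heats_from_coords(state.dG, state.dH, state.dH0, state.Ls, state.R0, design)
    n = q.size
    r = q - qstar
    return float(
        -0.5 * n * LN2PI
        - n * math.log(state.sigma)
        - 0.5 * float(r @ r) / (state.sigma**2)
    )


def log_prior(
    state: ParameterState,
    config: PriorConfig,
    heats: Sequence[float],
    design: ExperimentDesign,
) -> float:
    """Joint log-prior density (nats, up to an additive constant).

    Returns -inf outside any bound.  The dH0 box spans the observed heat
    range extended by one range-width on each side (same cal units as the
    likelihood); the noise prior is flat in ln sigma between bounds scaled
    from the heat range, which is the proper-bounds version of the Jeffreys
    1/sigma prior.
    """
    qmin, qmax, dq = _heat_stats(np.asarray(heats, dtype=float))
    lo, hi = config.dG_bounds
    if not (lo < state.dG < hi):
        return -math.inf
    lo, hi = config.dH_bounds
    if not (lo < state.dH < hi):
        return -math.inf
    if not (qmin - dq < state.dH0 < qmax + dq):
        return -math.inf
    ln_sig = math.log(state.sigma)
    if not (
        math.log(dq * config.sigma_lo_factor)
        < ln_sig
        < math.log(dq * config.sigma_hi_factor)
    ):
        return -math.inf

    lp = 0.0
    # titrant: lognormal in every model
    lp += lognormal_logpdf(state.Ls, design.stated_titrant, config.titrant_cv)
    # titrand: lognormal (general) or flat box (flat-r0 / comparison)
    if config.r0_is_flat:
        lo = design.stated_titrand / config.R0_flat_factor
        hi = design.stated_titrand * config.R0_flat_factor
        if not (lo < state.R0 < hi):
            return -math.inf
    else:
        lp += lognormal_logpdf(state.R0, design.stated_titrand, config.titrand_cv)
    # Jeffreys on sigma == flat on ln sigma: constant inside the bounds
    return lp


def log_posterior(
    state: ParameterState,
    config: PriorConfig,
    heats: Sequence[float],
    design: ExperimentDesign,
) -> float:
    lp = log_prior(state, config, heats, design)
    if not math.isfinite(lp):
        return -math.inf
    return lp + log_likelihood(state, heats, design)


def make_log_posterior(
    heats: Sequence[float],
    design: ExperimentDesign,
    config: PriorConfig,
    exclude_first: bool = False,
):
    """Compile a fast log-posterior over sampler coordinates.

    Returns ``f(x) -> float`` with ``x = (dG, dH, dH0, Ls, R0, ln sigma)``.
    The sampler works on ln sigma; because the Jeffreys prior is flat in
    ln sigma, no extra Jacobian term appears in the returned density.
    ``exclude_first`` drops injection 1 from the likelihood (first-injection
    anomaly), never from the heat model itself.
    """
    q = np.asarray(heats, dtype=float)
    if q.size != design.n_injections:
        raise ValueError("number of heats does not match the design")
    qmin, qmax, dq = _heat_stats(q)
    dG_lo, dG_hi = config.dG_bounds
    dH_lo, dH_hi = config.dH_bounds
    dH0_lo, dH0_hi = qmin - dq, qmax + dq
    ls_lo, ls_hi = math.log(dq * config.sigma_lo_factor), math.log(
        dq * config.sigma_hi_factor
    )
    mu_L, s_L = lognormal_params(design.stated_titrant, config.titrant_cv)
    if config.r0_is_flat:
        R0_lo = design.stated_titrand / config.R0_flat_factor
        R0_hi = design.stated_titrand * config.R0_flat_factor
        mu_R = s_R = None
    else:
        mu_R, s_R = lognormal_params(design.stated_titrand, config.titrand_cv)
        R0_lo, R0_hi = 0.0, math.inf

    V0 = design.cell_volume
    v = np.asarray(design.injection_volumes)
    d = design.dilution_factors()
    one_minus_vv0 = 1.0 - v / V0
    RT = 1.9872e-3 * design.temperature
    n_keep = q.size - (1 if exclude_first else 0)
    keep = slice(1, None) if exclude_first else slice(None)
    q_kept = q[keep]
    const = -0.5 * n_keep * LN2PI

    def logpost(x: np.ndarray) -> float:
        dG, dH, dH0, Ls, R0, ln_sig = x
        if not (dG_lo < dG < dG_hi and dH_lo < dH < dH_hi):
            return -math.inf
        if not (dH0_lo < dH0 < dH0_hi and ls_lo < ln_sig < ls_hi):
            return -math.inf
        if Ls <= 0 or not (R0_lo < R0 < R0_hi):
            return -math.inf
        # prior (same constants as log_prior, so the two paths agree exactly)
        zl = (math.log(Ls) - mu_L) / s_L
        lp = -math.log(Ls * s_L) - 0.5 * LN2PI - 0.5 * zl * zl
        if mu_R is not None:
            zr = (math.log(R0) - mu_R) / s_R
            lp += -math.log(R0 * s_R) - 0.5 * LN2PI - 0.5 * zr * zr
        # likelihood
        Ka = math.exp(-dG / RT)
        Rtot = R0 * d
        Ltot = Ls * (1.0 - d)
        s = Rtot + Ltot + 1.0 / Ka
        disc = s * s - 4.0 * Rtot * Ltot
        c = 0.5 * (s - np.sqrt(np.maximum(disc, 0.0)))
        dq_c = c.copy()
        dq_c[1:] -= c[:-1] * one_minus_vv0[1:]
        qstar = V0 * dH * 1.0e3 * dq_c + dH0
        r = q_kept - qstar[keep]
        sigma2 = math.exp(2.0 * ln_sig)
        return lp + const - n_keep * ln_sig - 0.5 * float(r @ r) / sigma2

    return logpost


def posterior_pack(
    heats: Sequence[float],
    design: ExperimentDesign,
    config: PriorConfig,
    exclude_first: bool = False,
) -> dict:
    """Precomputed constants of the log-posterior, packed as plain arrays.

    Consumed by the compiled sampler core; numerically identical to
    :func:`make_log_posterior`.
    """
    q = np.asarray(heats, dtype=float)
    if q.size != design.n_injections:
        raise ValueError("number of heats does not match the design")
    qmin, qmax, dq = _heat_stats(q)
    mu_L, s_L = lognormal_params(design.stated_titrant, config.titrant_cv)
    if config.r0_is_flat:
        R0_lo = design.stated_titrand / config.R0_flat_factor
        R0_hi = design.stated_titrand * config.R0_flat_factor
        mu_R = s_R = 0.0
        r0_flat = 1.0
    else:
        mu_R, s_R = lognormal_params(design.stated_titrand, config.titrand_cv)
        R0_lo, R0_hi = 0.0, math.inf
        r0_flat = 0.0
    bounds = np.array(
        [
            config.dG_bounds[0], config.dG_bounds[1],
            config.dH_bounds[0], config.dH_bounds[1],
            qmin - dq, qmax + dq,
            math.log(dq * config.sigma_lo_factor),
            math.log(dq * config.sigma_hi_factor),
            R0_lo, R0_hi,
        ]
    )
    conc = np.array([mu_L, s_L, mu_R, s_R, r0_flat])
    v = np.asarray(design.injection_volumes)
    n_keep = q.size - (1 if exclude_first else 0)
    return {
        "q": q,
        "vfrac": 1.0 - v / design.cell_volume,
        "d": design.dilution_factors(),
        "V0": design.cell_volume,
        "RT": 1.9872e-3 * design.temperature,
        "bounds": bounds,
        "conc": conc,
        "const": -0.5 * n_keep * LN2PI,
        "n_keep": n_keep,
        "skip_first": bool(exclude_first),
    }
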