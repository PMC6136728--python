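"""Nonlinear least-squares baseline analysis.

The standard single-site analysis fits four parameters to the integrated
heats: association constant Ka, molar enthalpy dH, stoichiometry n and a
constant per-injection offset dH0.  The syringe concentration is fixed at
its stated value and the effective cell concentration is ``n * [R]0stated``
— the stoichiometry soaks up titrand concentration error, which is why the
fitted n of a clean 1:1 titration tracks the ratio of true to stated cell
concentration.  Confidence intervals are normal-theory: point estimate
plus/minus the standard normal quantile times the standard error.

Ka is fitted on the log scale for conditioning; its standard error is
back-transformed by the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .analysis import IntervalEstimate
from .binding import (
    ExperimentDesign,
    R_GAS,
    association_constant,
    complex_concentration,
)

__all__ = ["NlsFit", "FitFailureError", "nls_fit", "nls_confidence_interval"]


class FitFailureError(RuntimeError):
    """Nonlinear least squares failed to converge."""


@dataclass(frozen=True)
class NlsFit:
    """Point estimates, standard errors and residual variance of an NLS fit.

    ``dG`` and its error are derived from Ka via dG = -RT ln Ka.
    """

    Ka: float
    dH: float
    n_stoich: float
    dH0: float
    se_Ka: float
    se_dH: float
    se_n: float
    se_dH0: float
    residual_variance: float
    temperature: float
    n_obs: int

    @property
    def dG(self) -> float:
        return -R_GAS * self.temperature * math.log(self.Ka)

    @property
    def se_dG(self) -> float:
        # delta method through dG = -RT ln Ka
        return R_GAS * self.temperature * self.se_Ka / self.Ka

    def parameter(self, name: str) -> tuple[float, float]:
        table = {
            "Ka": (self.Ka, self.se_Ka),
            "dG": (self.dG, self.se_dG),
            "dH": (self.dH, self.se_dH),
            "n": (self.n_stoich, self.se_n),
            "dH0": (self.dH0, self.se_dH0),
        }
        return table[name]


def _predicted_heats(
    ln_Ka: float, dH: float, n_stoich: float, dH0: float, design: ExperimentDesign
) -> np.ndarray:
    V0 = design.cell_volume
    v = np.asarray(design.injection_volumes)
    d = design.dilution_factors()
    Ka = math.exp(ln_Ka)
    Rtot = n_stoich * design.stated_titrand * d
    Ltot = design.stated_titrant * (1.0 - d)
    c = complex_concentration(Rtot, Ltot, Ka)
    c_prev = np.concatenate(([0.0], c[:-1]))
    dq = c - c_prev * (1.0 - v / V0)
    return V0 * dH * 1.0e3 * dq + dH0


def nls_fit(
    heats,
    design: ExperimentDesign,
    exclude_first: bool = False,
    initial_dG: float = -8.0,
) -> NlsFit:
    """Fit (Ka, dH, n, dH0) to observed heats (cal) by least squares.

    Standard errors come from the residual-variance-scaled inverse of the
    Gauss-Newton normal matrix at the optimum.  ``initial_dG`` (kcal/mol)
    seeds the Ka search; additional starts over a dG grid are tried on
    non-convergence.
    """
    q = np.asarray(heats, dtype=float)
    if q.size != design.n_injections:
        raise ValueError("number of heats does not match the design")
    if q.size < 5:
        raise ValueError("need at least 5 injections to fit 4 parameters")
    keep = np.ones(q.size, dtype=bool)
    if exclude_first:
        keep[0] = False

    # rough initial guesses: offset from the final (saturated) heats,
    # enthalpy from the total evolved heat over the cell contents
    dH0_init = float(np.median(q[-3:]))
    moles_R = design.stated_titrand * design.cell_volume
    dH_init = float(np.sum(q - dH0_init)) / (moles_R * 1.0e3)
    if dH_init == 0.0:
        dH_init = -1.0

    def residuals(p):
        ln_Ka, dH, n_st, dH0 = p
        if n_st <= 0:
            return np.full(int(keep.sum()), 1e6)
        return (_predicted_heats(ln_Ka, dH, n_st, dH0, design) - q)[keep]

    RT = R_GAS * design.temperature
    best = None
    for dg0 in (initial_dG, -5.0, -10.0, -14.0):
        p0 = np.array([-dg0 / RT, dH_init, 1.0, dH0_init])
        try:
            sol = optimize.least_squares(residuals, p0, method="lm", max_nfev=20000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError("least-squares optimisation did not converge")

    m = int(keep.sum())
    dof = m - 4
    s2 = 2.0 * best.cost / dof if dof > 0 else float("nan")
    J = best.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError as exc:
        raise FitFailureError(f"singular normal matrix: {exc}") from exc
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    ln_Ka, dH, n_st, dH0 = best.x
    Ka = math.exp(ln_Ka)
    return NlsFit(
        Ka=Ka,
        dH=float(dH),
        n_stoich=float(n_st),
        dH0=float(dH0),
        se_Ka=float(Ka * se[0]),
        se_dH=float(se[1]),
        se_n=float(se[2]),
        se_dH0=float(se[3]),
        residual_variance=float(s2),
        temperature=design.temperature,
        n_obs=m,
    )


def nls_confidence_interval(
    fit: NlsFit, parameter: str, level: float
) -> IntervalEstimate:
    """Normal-theory interval: estimate +/- z * SE at the requested level."""
    est, se = fit.parameter(parameter)
    if not math.isfinite(se):
        raise ValueError(f"no finite standard error for {parameter}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    iv = IntervalEstimate(
        parameter, est - z * se, est + z * se, level, method="NlRCI"
    )
    return iv
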