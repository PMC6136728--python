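"""Model / Results interface over the Bayesian and least-squares analyses.

Usage mirrors the fitting-object idiom of statistical modelling packages::

    design = mgedta_design()
    model = BayesianITC(heats, design, prior_model="general")
    res = model.fit(n_samples=5000, thin=2000, seed=1)
    print(res.summary())
    res.credible_interval("dG", 0.95)

    nls = ITCLeastSquares(heats, design).fit()
    nls.conf_int("dH", 0.95)

Heats are always in cal internally; constructors accept ``units="ucal"``
for convenience.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import (
    IntervalEstimate,
    correlation_matrix,
    enthalpy_concentration_tradeoff,
    posterior_summary,
    shortest_credible_interval,
)
from .binding import ExperimentDesign, ParameterState, model_heats
from .frequentist import NlsFit, nls_confidence_interval, nls_fit
from .priors import PriorConfig, log_posterior, make_log_posterior
from .sampler import (
    PARAM_NAMES,
    PosteriorSamples,
    SamplerConfig,
    convergence_report,
    run_chain,
)

__all__ = [
    "BayesianITC",
    "BayesianITCResults",
    "ITCLeastSquares",
    "ITCLeastSquaresResults",
]

_UNIT_SCALE = {"cal": 1.0, "ucal": 1e-6}


def _to_cal(heats, units: str) -> np.ndarray:
    try:
        scale = _UNIT_SCALE[units]
    except KeyError:
        raise ValueError(f"unknown heat units {units!r}") from None
    return np.asarray(heats, dtype=float) * scale


class BayesianITC:
    """Bayesian single-site binding model for one titration experiment.

    Parameters
    ----------
    heats : array-like
        Integrated injection heats, one per injection.
    design : ExperimentDesign
        Cell volume, injection schedule, temperature and stated
        concentrations.
    prior_model : str or PriorConfig
        "general", "flat-r0" or "comparison", or a full PriorConfig.
    units : {"cal", "ucal"}
        Units of ``heats``.
    exclude_first : bool
        Drop injection 1 from the likelihood (first-injection anomaly).
    """

    def __init__(
        self,
        heats: Sequence[float],
        design: ExperimentDesign,
        prior_model: str | PriorConfig = "general",
        units: str = "cal",
        exclude_first: bool = False,
        data_id: str | None = None,
    ):
        self.heats = _to_cal(heats, units)
        if self.heats.size != design.n_injections:
            raise ValueError(
                f"{self.heats.size} heats but design has "
                f"{design.n_injections} injections"
            )
        self.design = design
        self.prior = (
            prior_model
            if isinstance(prior_model, PriorConfig)
            else PriorConfig(model_name=prior_model)
        )
        self.exclude_first = exclude_first
        self.data_id = data_id

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        design: ExperimentDesign,
        heat_column: str = "heat",
        **kwargs,
    ) -> "BayesianITC":
        return cls(frame[heat_column].to_numpy(), design, **kwargs)

    def log_posterior(self, state: ParameterState) -> float:
        return log_posterior(state, self.prior, self.heats, self.design)

    def compiled_log_posterior(self):
        return make_log_posterior(
            self.heats, self.design, self.prior, self.exclude_first
        )

    def fit(
        self,
        n_samples: int = 5000,
        thin: int = 2000,
        seed: int | None = None,
        n_chains: int = 1,
        start: ParameterState | str | None = None,
        **sampler_kwargs,
    ) -> "BayesianITCResults":
        """Sample the posterior; with ``n_chains > 1`` the extra chains are
        kept for convergence diagnostics and the first is the primary.
        ``start="map"`` warm-starts each chain at the posterior mode
        (recommended with shortened chains)."""
        chains = []
        for c in range(n_chains):
            cfg = SamplerConfig(
                n_stored_samples=n_samples,
                thin=thin,
                seed=None if seed is None else seed + c,
                **sampler_kwargs,
            )
            chains.append(
                run_chain(
                    self.heats,
                    self.design,
                    self.prior,
                    cfg,
                    exclude_first=self.exclude_first,
                    data_id=self.data_id,
                    initial_state=start,
                )
            )
        return BayesianITCResults(self, chains)


class BayesianITCResults:
    """Posterior draws plus summaries for one fitted titration."""

    def __init__(self, model: BayesianITC, chains: list[PosteriorSamples]):
        self.model = model
        self.chains = chains
        self.samples = chains[0]

    # -- summaries ---------------------------------------------------------
    def summary(self, levels: Sequence[float] = (0.95,)) -> pd.DataFrame:
        return posterior_summary(self.samples, levels)

    def credible_interval(self, parameter: str, level: float = 0.95) -> IntervalEstimate:
        x = self.samples.TdS if parameter == "TdS" else self.samples[parameter]
        return shortest_credible_interval(x, level, parameter)

    def median(self, parameter: str) -> float:
        x = self.samples.TdS if parameter == "TdS" else self.samples[parameter]
        return float(np.median(x))

    def mean(self, parameter: str) -> float:
        x = self.samples.TdS if parameter == "TdS" else self.samples[parameter]
        return float(np.mean(x))

    def corr(self, n_bootstrap: int = 1000, rng=None):
        return correlation_matrix(self.samples, n_bootstrap, rng)

    def tradeoff(self, **kwargs):
        return enthalpy_concentration_tradeoff(self.samples, self.model.design, **kwargs)

    def dG_dH_draws(self) -> np.ndarray:
        """(n, 2) array of (dG, dH) draws for density comparison."""
        return np.column_stack([self.samples["dG"], self.samples["dH"]])

    def convergence(self, level: float = 0.95, **kwargs) -> pd.DataFrame:
        if len(self.chains) < 2:
            raise ValueError("fit with n_chains >= 2 for convergence diagnostics")
        return convergence_report(self.chains, level, **kwargs)

    @property
    def acceptance_rates(self) -> dict[str, float]:
        return self.samples.acceptance_rates


class ITCLeastSquares:
    """Standard nonlinear least-squares single-site analysis."""

    def __init__(
        self,
        heats: Sequence[float],
        design: ExperimentDesign,
        units: str = "cal",
        exclude_first: bool = False,
    ):
        self.heats = _to_cal(heats, units)
        self.design = design
        self.exclude_first = exclude_first

    def fit(self, **kwargs) -> "ITCLeastSquaresResults":
        fit = nls_fit(self.heats, self.design, self.exclude_first, **kwargs)
        return ITCLeastSquaresResults(self, fit)


class ITCLeastSquaresResults:
    """NLS point estimates, standard errors and normal-theory intervals."""

    def __init__(self, model: ITCLeastSquares, fit: NlsFit):
        self.model = model
        self.fit_result = fit

    def conf_int(self, parameter: str, level: float = 0.95) -> IntervalEstimate:
        return nls_confidence_interval(self.fit_result, parameter, level)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in ("Ka", "dG", "dH", "n", "dH0"):
            est, se = self.fit_result.parameter(name)
            rows.append({"parameter": name, "estimate": est, "se": se})
        return pd.DataFrame(rows).set_index("parameter")

    def gaussian_draws(
        self, n: int, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """(n, 2) Gaussian (dG, dH) pseudo-draws from the normal
        approximation, for KL comparison against Bayesian posteriors."""
        rng = rng or np.random.default_rng()
        f = self.fit_result
        dg = rng.normal(f.dG, f.se_dG, size=n)
        dh = rng.normal(f.dH, f.se_dH, size=n)
        return np.column_stack([dg, dh])
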