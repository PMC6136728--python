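"""Synthetic titration experiments with concentration error and heat noise.

Each simulated experiment draws *true* cell and syringe concentrations from
lognormal laws centred on the stated values (mean = stated, CV =
``concentration_cv`` — the identical convention the lognormal concentration
prior uses), evaluates the noise-free binding heats, and adds iid Gaussian
noise.  The defaults reproduce the 50-curve validation study: 24 injections,
dG = -10 kcal/mol, dH = -5 kcal/mol, dH0 = 0.5 ucal, stated concentrations
0.1 mM (cell) and 1 mM (syringe), 10% concentration error and 1 ucal heat
noise, on the standard VP-ITC 2 uL + 23 x 12 uL schedule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .binding import (
    ExperimentDesign,
    ParameterState,
    mgedta_design,
    model_heats,
)
from .priors import lognormal_params

__all__ = ["SimulationSpec", "draw_true_concentrations", "simulate_experiment", "generate_study"]


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth parameters and noise settings for a simulation study."""

    true_dG: float = -10.0
    true_dH: float = -5.0
    true_dH0: float = 0.5e-6
    stated_R0: float = 1e-4
    stated_Ls: float = 1e-3
    concentration_cv: float = 0.1
    noise_sd: float = 1e-6
    n_injections: int = 24
    n_replicates: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.concentration_cv < 0 or self.noise_sd < 0:
            raise ValueError("concentration_cv and noise_sd must be non-negative")
        if self.n_injections < 1 or self.n_replicates < 1:
            raise ValueError("counts must be at least 1")
        if self.stated_R0 <= 0 or self.stated_Ls <= 0:
            raise ValueError("stated concentrations must be positive")

    def default_design(self, **kwargs) -> ExperimentDesign:
        return mgedta_design(
            n_injections=self.n_injections,
            stated_titrand=self.stated_R0,
            stated_titrant=self.stated_Ls,
            **kwargs,
        )


def draw_true_concentrations(
    spec: SimulationSpec, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw (R0_true, Ls_true) in mol/L.

    Lognormal with mean equal to the stated concentration and coefficient of
    variation ``concentration_cv``; a CV of zero returns the stated values
    exactly.
    """
    if spec.concentration_cv == 0.0:
        return spec.stated_R0, spec.stated_Ls
    mu_r, s_r = lognormal_params(spec.stated_R0, spec.concentration_cv)
    mu_l, s_l = lognormal_params(spec.stated_Ls, spec.concentration_cv)
    r0 = float(rng.lognormal(mu_r, s_r))
    ls = float(rng.lognormal(mu_l, s_l))
    return r0, ls


def simulate_experiment(
    spec: SimulationSpec,
    design: ExperimentDesign | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, ParameterState]:
    """One simulated experiment: observed heats (cal) and the true state.

    ``q_i = q*_i(true state) + eps_i`` with ``eps_i ~ Normal(0, noise_sd^2)``.
    The returned ParameterState records the drawn true concentrations so
    recovery can be scored; its ``sigma`` is the noise SD used (or a floor
    for noiseless simulations, where sigma has no effect on the heats).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    design = design if design is not None else spec.default_design()
    if design.n_injections != spec.n_injections:
        raise ValueError("design does not match spec.n_injections")
    r0, ls = draw_true_concentrations(spec, rng)
    truth = ParameterState(
        dG=spec.true_dG,
        dH=spec.true_dH,
        dH0=spec.true_dH0,
        Ls=ls,
        R0=r0,
        sigma=spec.noise_sd if spec.noise_sd > 0 else 1e-12,
    )
    q = model_heats(truth, design)
    if spec.noise_sd > 0:
        q = q + spec.noise_sd * rng.standard_normal(q.size)
    return q, truth


def generate_study(
    spec: SimulationSpec, design: ExperimentDesign | None = None
) -> list[tuple[np.ndarray, ParameterState]]:
    """``n_replicates`` independent experiments, reproducible from the seed.

    Each replicate draws fresh true concentrations and fresh noise from a
    single seeded stream.
    """
    rng = np.random.default_rng(spec.seed)
    design = design if design is not None else spec.default_design()
    return [
        simulate_experiment(spec, design, rng) for _ in range(spec.n_replicates)
    ]
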