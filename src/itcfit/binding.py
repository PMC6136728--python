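"""Deterministic 1:1 binding heat model for titration calorimetry.

The sample cell of a perfusion-type calorimeter holds a fixed active volume
``V0``.  Each injection of volume ``v_n`` displaces an equal volume of the
current cell contents, so after ``n`` injections only a fraction
``d_n = prod_{i<=n}(1 - v_i/V0)`` of the original titrand remains, while the
total titrant concentration has risen to ``Ls * (1 - d_n)``.  The complex
concentration at each step follows from 1:1 mass-action equilibrium, and the
heat evolved during injection ``n`` is the enthalpy times the change in moles
of complex inside the cell, corrected for the complex carried out with the
displaced volume, plus a constant per-injection dilution/stirring offset.

Internal unit conventions (conversions happen only at the I/O boundary):

* heats in cal, molar energies in kcal/mol,
* volumes in L, concentrations in mol/L,
* temperatures in K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "R_GAS",
    "ExperimentDesign",
    "ParameterState",
    "InvalidDesignError",
    "association_constant",
    "complex_concentration",
    "model_heats",
    "mgedta_design",
]

#: Gas constant in kcal/(mol K).
R_GAS = 1.9872e-3


class InvalidDesignError(ValueError):
    """Raised for physically inadmissible designs or parameter states."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Instrument and protocol constants for one titration.

    Parameters
    ----------
    cell_volume : float
        Active cell volume ``V0`` in L.
    injection_volumes : sequence of float
        Programmed injection volumes ``v_1..v_N`` in L.
    temperature : float
        Absolute temperature in K.
    stated_titrand : float
        Stated (intended) cell titrand concentration ``[R]0`` in mol/L.
    stated_titrant : float
        Stated syringe titrant concentration ``[L]s`` in mol/L.
    heat_units : {"cal", "ucal"}
        Unit in which heats files for this design are written.
    dilution_model : {"displaced", "exponential"}
        Convention for the cumulative dilution factor: stepwise displaced
        volume (default) or the continuous-overflow limit
        ``exp(-V_cum/V0)``.
    """

    cell_volume: float
    injection_volumes: Sequence[float]
    temperature: float
    stated_titrand: float
    stated_titrant: float
    heat_units: Literal["cal", "ucal"] = "ucal"
    dilution_model: Literal["displaced", "exponential"] = "displaced"

    def __post_init__(self) -> None:
        v = np.asarray(self.injection_volumes, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise InvalidDesignError("need at least one injection volume")
        if self.cell_volume <= 0:
            raise InvalidDesignError("cell volume must be positive")
        if np.any(v <= 0):
            raise InvalidDesignError("injection volumes must be positive")
        if np.any(v >= self.cell_volume):
            raise InvalidDesignError(
                "an injection volume equals or exceeds the cell volume"
            )
        if self.temperature <= 0:
            raise InvalidDesignError("temperature must be positive")
        if self.stated_titrand <= 0 or self.stated_titrant <= 0:
            raise InvalidDesignError("stated concentrations must be positive")
        object.__setattr__(self, "injection_volumes", tuple(float(x) for x in v))

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def dilution_factors(self) -> np.ndarray:
        """Cumulative dilution factor ``d_n`` after each injection."""
        v = np.asarray(self.injection_volumes)
        if self.dilution_model == "exponential":
            return np.exp(-np.cumsum(v) / self.cell_volume)
        return np.cumprod(1.0 - v / self.cell_volume)


@dataclass(frozen=True)
class ParameterState:
    """One point in the six-dimensional parameter space.

    Fields: binding free energy ``dG`` and enthalpy ``dH`` (kcal/mol),
    per-injection dilution/stirring heat ``dH0`` (cal), true syringe titrant
    concentration ``Ls`` and true cell titrand concentration ``R0`` (mol/L),
    and the per-injection heat noise ``sigma`` (cal).
    """

    dG: float
    dH: float
    dH0: float
    Ls: float
    R0: float
    sigma: float = field(default=1e-6)

    def __post_init__(self) -> None:
        if self.Ls <= 0 or self.R0 <= 0:
            raise ValueError("concentrations must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def association_constant(self, temperature: float) -> float:
        return association_constant(self.dG, temperature)

    @property
    def TdS(self) -> float:
        """Entropic contribution ``T dS = dH - dG`` in kcal/mol."""
        return self.dH - self.dG

    def as_array(self) -> np.ndarray:
        """(dG, dH, dH0, Ls, R0, ln sigma) — the sampler's coordinates."""
        return np.array(
            [self.dG, self.dH, self.dH0, self.Ls, self.R0, np.log(self.sigma)]
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ParameterState":
        return cls(
            dG=float(x[0]), dH=float(x[1]), dH0=float(x[2]),
            Ls=float(x[3]), R0=float(x[4]), sigma=float(np.exp(x[5])),
        )


def association_constant(dG: float, temperature: float) -> float:
    """Association constant ``Ka = exp(-dG / (R T))`` in 1/M.

    ``dG`` is the standard binding free energy in kcal/mol (negative for
    favourable binding), ``temperature`` the absolute temperature in K.
    """
    if temperature <= 0:
        raise InvalidDesignError("temperature must be positive")
    return float(np.exp(-dG / (R_GAS * temperature)))


def complex_concentration(Rtot, Ltot, Ka):
    """Equilibrium 1:1 complex concentration [RL] in mol/L.

    Solves the mass-action quadratic ``Ka (Rtot-[RL]) (Ltot-[RL]) = [RL]``
    and returns the physically admissible root

    ``[RL] = (S - sqrt(S^2 - 4 Rtot Ltot)) / 2``, ``S = Rtot + Ltot + 1/Ka``.

    Accepts scalars or arrays (broadcast).  ``0 <= [RL] <= min(Rtot, Ltot)``.
    """
    Rtot = np.asarray(Rtot, dtype=float)
    Ltot = np.asarray(Ltot, dtype=float)
    if np.any(Rtot < 0) or np.any(Ltot < 0):
        raise ValueError("total concentrations must be non-negative")
    if not np.all(np.asarray(Ka) > 0):
        raise ValueError("Ka must be positive")
    s = Rtot + Ltot + 1.0 / Ka
    disc = s * s - 4.0 * Rtot * Ltot
    # disc >= (Rtot - Ltot)^2 >= 0 analytically; guard rounding
    rl = 0.5 * (s - np.sqrt(np.maximum(disc, 0.0)))
    out = np.clip(rl, 0.0, np.minimum(Rtot, Ltot))
    return float(out) if out.ndim == 0 else out


def model_heats(state: ParameterState, design: ExperimentDesign) -> np.ndarray:
    """Noise-free integrated heats ``q*_1..q*_N`` in cal.

    For injection ``n`` the evolved heat is the enthalpy (converted from
    kcal/mol to cal/mol) times the change in moles of complex in the cell,
    ``V0 (c_n - c_{n-1} (1 - v_n/V0))``, plus the constant offset ``dH0``;
    ``c_0 = 0``.
    """
    return _heats_from_coords(
        state.dG, state.dH, state.dH0, state.Ls, state.R0, design
    )


def _heats_from_coords(dG, dH, dH0, Ls, R0, design: ExperimentDesign) -> np.ndarray:
    V0 = design.cell_volume
    v = np.asarray(design.injection_volumes)
    d = design.dilution_factors()
    Ka = association_constant(dG, design.temperature)
    Rtot = R0 * d
    Ltot = Ls * (1.0 - d)
    c = complex_concentration(Rtot, Ltot, Ka)
    c_prev = np.concatenate(([0.0], c[:-1]))
    dq = c - c_prev * (1.0 - v / V0)
    return V0 * dH * 1.0e3 * dq + dH0


def mgedta_design(
    cell_volume: float = 1.43e-3,
    first_injection: float = 2e-6,
    main_injection: float = 12e-6,
    n_injections: int = 24,
    temperature: float = 298.15,
    stated_titrand: float = 1e-4,
    stated_titrant: float = 1e-3,
    **kwargs,
) -> ExperimentDesign:
    """Standard VP-ITC metal:chelator protocol used throughout the docs/tests.

    One small 2 µL priming injection followed by 23 main 12 µL injections
    into a 1.43 mL cell at 298.15 K; stated concentrations 0.1 mM titrand and
    1 mM titrant.
    """
    volumes = [first_injection] + [main_injection] * (n_injections - 1)
    return ExperimentDesign(
        cell_volume=cell_volume,
        injection_volumes=volumes,
        temperature=temperature,
        stated_titrand=stated_titrand,
        stated_titrant=stated_titrant,
        **kwargs,
    )
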