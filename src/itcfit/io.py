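"""Reading experiment files and writing traces/summaries.

Integrated-heat files are plain CSV with columns ``injection``,
``volume_uL`` and ``heat`` (units declared by flag or manifest; other
columns are ignored with a warning).  An experiment is either a CSV plus
explicit design keywords, or a YAML/JSON manifest::

    heats_file: curve.csv
    heat_units: ucal
    design:
      cell_volume_mL: 1.43
      temperature_K: 298.15
      stated_titrand_mM: 0.1
      stated_titrant_mM: 1.0

Outputs embed the seed, prior model and software version in ``#`` header
comments and round-trip losslessly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import ExperimentDesign, ParameterState
from .sampler import PosteriorSamples

__all__ = ["ExperimentBundle", "FormatError", "read_experiment", "write_samples", "write_summary", "read_samples"]

_KNOWN_COLUMNS = {"injection", "volume_uL", "heat"}


class FormatError(ValueError):
    """A heats file or manifest is malformed."""


@dataclass
class ExperimentBundle:
    """One experiment: design, heats (cal) and optional ground truth."""

    identifier: str
    design: ExperimentDesign
    heats: np.ndarray
    true_state: ParameterState | None = None
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if len(self.heats) != self.design.n_injections:
            raise FormatError(
                f"{len(self.heats)} heats but {self.design.n_injections} "
                "injection volumes"
            )


def _design_from_mapping(m: dict, volumes_L, heat_units: str) -> ExperimentDesign:
    required = ["cell_volume_mL", "temperature_K", "stated_titrand_mM", "stated_titrant_mM"]
    for key in required:
        if key not in m:
            raise FormatError(f"missing required design field {key!r}")
    return ExperimentDesign(
        cell_volume=float(m["cell_volume_mL"]) * 1e-3,
        injection_volumes=volumes_L,
        temperature=float(m["temperature_K"]),
        stated_titrand=float(m["stated_titrand_mM"]) * 1e-3,
        stated_titrant=float(m["stated_titrant_mM"]) * 1e-3,
        heat_units=heat_units,
        dilution_model=m.get("dilution_model", "displaced"),
    )


def read_experiment(
    path: str | Path,
    units: str | None = None,
    design: dict | None = None,
    column_map: dict[str, str] | None = None,
) -> ExperimentBundle:
    """Load one experiment from a CSV (plus design mapping) or a manifest.

    ``units`` overrides the declared heat unit ("cal" or "ucal");
    ``column_map`` renames non-standard CSV columns, e.g.
    ``{"DH": "heat"}`` for instrument exports.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in (".yaml", ".yml", ".json"):
        with open(path) as fh:
            manifest = (
                json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
            )
        heats_file = path.parent / manifest["heats_file"]
        units = units or manifest.get("heat_units", "ucal")
        design = manifest.get("design", design)
    else:
        heats_file = path
        units = units or "ucal"
    if design is None:
        raise FormatError("no experiment design supplied (manifest or keyword)")

    table = pd.read_csv(heats_file, comment="#")
    if column_map:
        table = table.rename(columns=column_map)
    unknown = set(table.columns) - _KNOWN_COLUMNS
    if unknown:
        warnings.warn(f"ignoring unknown columns {sorted(unknown)}", UserWarning)
    for col in ("volume_uL", "heat"):
        if col not in table.columns:
            raise FormatError(f"missing required column {col!r}")
    volumes_L = table["volume_uL"].to_numpy(dtype=float) * 1e-6
    scale = {"cal": 1.0, "ucal": 1e-6}.get(units)
    if scale is None:
        raise FormatError(f"unknown heat units {units!r}")
    heats_cal = table["heat"].to_numpy(dtype=float) * scale
    des = _design_from_mapping(dict(design), volumes_L, units)
    return ExperimentBundle(
        identifier=path.stem,
        design=des,
        heats=heats_cal,
        provenance={"source": str(path), "units": units},
    )


def _header(meta: dict) -> str:
    lines = [f"# itcfit {__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def write_samples(samples: PosteriorSamples, path: str | Path) -> Path:
    """Write an MCMC trace as CSV with a provenance header."""
    if len(samples) == 0:
        raise ValueError("refusing to write an empty trace")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(samples.provenance))
        samples.draws.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_samples(path: str | Path) -> PosteriorSamples:
    """Read back a trace written by :func:`write_samples`."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, _, v = line.lstrip("# ").partition(":")
                meta[k.strip()] = v.strip()
    draws = pd.read_csv(path, comment="#")
    return PosteriorSamples(draws, provenance=meta)


def write_summary(summary: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    """Write a summary table as CSV with a provenance header."""
    if summary.empty:
        raise ValueError("refusing to write an empty summary")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(meta or {}))
        summary.to_csv(fh, float_format="%.17g")
    return path
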