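"""Unit-safe model parameters: rate constants, cell panels, tumor geometry.

All rates are stored internally in per-minute units; the converters in this
module are the only sanctioned way to get there from the half-life /
per-hour / fraction-per-hour forms that parameter tables in the literature
typically report.  Conversions are linear (divide by 60), matching the
customary pharmacokinetic bookkeeping for small rates, not a
continuous-compounding transform.

Counts are continuous reals throughout: the model is a deterministic
mean-field description of very large vesicle populations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "RateConstant",
    "KineticRates",
    "CellPopulation",
    "TumorSpec",
    "IsolationYields",
    "DEFAULT_ELIMINATION_PER_MIN",
    "DEFAULT_UPTAKE_PER_MIN",
    "DEFAULT_TUMOR_SECRETION_PER_HOUR",
    "DEFAULT_TUMOR_CELL_DENSITY",
    "default_rates",
    "default_tumor_spec",
    "halflife_to_rate",
    "rate_to_halflife",
    "fraction_per_hour_to_rate",
    "per_hour_to_per_minute",
    "tumor_cell_count",
    "tumor_to_population",
    "load_config",
    "save_config",
]

# Baseline plasma clearance constants.  The elimination constant is the
# printed literature value for a 7-minute small-EV half-life; the uptake
# constant corresponds to the measured spontaneous cellular uptake of
# ~1%/hour.  Both are deliberately stored at the reported precision rather
# than recomputed, so downstream steady states reproduce published figures.
DEFAULT_ELIMINATION_PER_MIN: float = 0.099
DEFAULT_UPTAKE_PER_MIN: float = 0.0001667

#: Breast-cancer cell secretion rate, EVs per cell per hour (upper end of the
#: reported ~60-65 range, the value used in published simulations).
DEFAULT_TUMOR_SECRETION_PER_HOUR: float = 65.0

#: Solid-tumor packing density, cells per cm^3 (spherical-tumor approximation).
DEFAULT_TUMOR_CELL_DENSITY: float = 1e9


class StabilityError(ValueError):
    """Raised when elimination + uptake >= 1 per minute.

    The 1-minute explicit update ``N[k] = N[k-1]*(1 - E - U) + inflow`` loses
    monotone convergence (overshoots, then oscillates) once the per-step
    removal fraction reaches 1, so such parameter sets are rejected up front.
    """


@dataclass(frozen=True)
class RateConstant:
    """A nonnegative first-order rate constant, per minute."""

    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(f"rate constant must be finite and >= 0, got {self.value}")

    def scaled(self, factor: float) -> "RateConstant":
        if factor <= 0:
            raise ValueError(f"rate multiplier must be > 0, got {factor}")
        return RateConstant(self.value * factor)


@dataclass(frozen=True)
class KineticRates:
    """Per-minute elimination and uptake rate constants for one EV class."""

    elimination: RateConstant
    uptake: RateConstant

    def __post_init__(self) -> None:
        if self.total >= 1.0:
            raise StabilityError(
                "elimination + uptake must be < 1 per minute for the 1-minute "
                f"update to be stable; got {self.total:.6g}"
            )

    @property
    def total(self) -> float:
        """Combined per-minute removal rate E + U."""
        return self.elimination.value + self.uptake.value

    def with_multipliers(self, elimination_multiplier: float, uptake_multiplier: float) -> "KineticRates":
        return KineticRates(
            elimination=self.elimination.scaled(elimination_multiplier),
            uptake=self.uptake.scaled(uptake_multiplier),
        )


@dataclass(frozen=True)
class CellPopulation:
    """One EV-secreting cell type.

    Attributes
    ----------
    name : label for reporting.
    count : number of cells, >= 0 (continuous).
    secretion_rate : EVs per cell per minute, >= 0.
    rates : clearance kinetics of the EVs this population secretes.
    """

    name: str
    count: float
    secretion_rate: float
    rates: KineticRates

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"cell count must be >= 0, got {self.count}")
        if self.secretion_rate < 0:
            raise ValueError(f"secretion rate must be >= 0, got {self.secretion_rate}")

    @property
    def total_secretion(self) -> float:
        """Whole-population secretion, EVs per minute (N_c * S_rc)."""
        return self.count * self.secretion_rate


@dataclass(frozen=True)
class TumorSpec:
    """Spherical-tumor scenario: geometry plus EV kinetics modifiers.

    diameter is in cm, cell_density in cells per cm^3, secretion_rate in EVs
    per cell per minute.  The multipliers rescale the baseline elimination
    and uptake rate constants for tumor-derived EVs (e.g. immune evasion
    lowers elimination; the tumor microenvironment raises uptake).
    """

    diameter: float
    cell_density: float = DEFAULT_TUMOR_CELL_DENSITY
    secretion_rate: float = DEFAULT_TUMOR_SECRETION_PER_HOUR / 60.0
    uptake_multiplier: float = 1.0
    elimination_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"tumor diameter must be > 0 cm, got {self.diameter}")
        if self.cell_density <= 0:
            raise ValueError(f"cell density must be > 0 cm^-3, got {self.cell_density}")
        if self.secretion_rate < 0:
            raise ValueError(f"secretion rate must be >= 0, got {self.secretion_rate}")
        if self.uptake_multiplier <= 0 or self.elimination_multiplier <= 0:
            raise ValueError("rate multipliers must be > 0")


@dataclass(frozen=True)
class IsolationYields:
    """Fractions of tumor and normal EVs recovered by an isolation protocol."""

    yield_tumor: float = 1.0
    yield_normal: float = 1.0

    def __post_init__(self) -> None:
        for label, y in (("yield_tumor", self.yield_tumor), ("yield_normal", self.yield_normal)):
            if not 0.0 <= y <= 1.0:
                raise ValueError(f"{label} must lie in [0, 1], got {y}")


def default_rates() -> KineticRates:
    """Baseline plasma clearance: E = 0.099 min^-1, U = 0.0001667 min^-1."""
    return KineticRates(
        elimination=RateConstant(DEFAULT_ELIMINATION_PER_MIN),
        uptake=RateConstant(DEFAULT_UPTAKE_PER_MIN),
    )


def default_tumor_spec(diameter_cm: float = 1.0) -> TumorSpec:
    """A breast-tumor scenario at the default density and secretion rate."""
    return TumorSpec(diameter=diameter_cm)


# ---------------------------------------------------------------------------
# Unit conversions


def halflife_to_rate(half_life: float) -> RateConstant:
    """Convert an elimination half-life (minutes) to a per-minute rate, ln(2)/t_half."""
    if half_life <= 0:
        raise ValueError(f"half-life must be > 0 minutes, got {half_life}")
    return RateConstant(math.log(2.0) / half_life)


def rate_to_halflife(rate: RateConstant | float) -> float:
    """Inverse of :func:`halflife_to_rate`, for reporting."""
    value = rate.value if isinstance(rate, RateConstant) else rate
    if value <= 0:
        raise ValueError(f"rate must be > 0 per minute, got {value}")
    return math.log(2.0) / value


def fraction_per_hour_to_rate(fraction_per_hour: float) -> RateConstant:
    """Convert a fraction-removed-per-hour (e.g. 0.01 for 1%/hour) to per minute.

    The conversion is the plain linear one, fraction/60.
    """
    if not 0.0 <= fraction_per_hour <= 1.0:
        raise ValueError(f"fraction per hour must lie in [0, 1], got {fraction_per_hour}")
    return RateConstant(fraction_per_hour / 60.0)


def per_hour_to_per_minute(rate_per_hour: float) -> float:
    """Convert any nonnegative per-hour rate (e.g. EVs/cell/hour) to per minute."""
    if rate_per_hour < 0:
        raise ValueError(f"rate must be >= 0, got {rate_per_hour}")
    return rate_per_hour / 60.0


# ---------------------------------------------------------------------------
# Tumor geometry


def tumor_cell_count(spec: TumorSpec) -> float:
    """Number of tumor cells for a spherical tumor: (4/3)*pi*(d/2)^3 * density."""
    radius = spec.diameter / 2.0
    return (4.0 / 3.0) * math.pi * radius**3 * spec.cell_density


def tumor_to_population(spec: TumorSpec, baseline: KineticRates) -> CellPopulation:
    """Realize a tumor scenario as a :class:`CellPopulation`.

    The baseline rates are rescaled by the spec's multipliers; a combination
    whose total removal reaches 1/minute raises :class:`StabilityError`.
    """
    rates = baseline.with_multipliers(spec.elimination_multiplier, spec.uptake_multiplier)
    return CellPopulation(
        name=f"tumor_{spec.diameter:g}cm",
        count=tumor_cell_count(spec),
        secretion_rate=spec.secretion_rate,
        rates=rates,
    )


# ---------------------------------------------------------------------------
# Parameter files
#
# Schema (YAML or JSON):
#   baseline_rates:
#     elimination: {half_life_min: 7}          # or {rate_per_min: 0.099}
#     uptake: {fraction_per_hour: 0.01}        # or {rate_per_min: 0.0001667}
#   blood_panel:
#     - {name: platelets, count: 1.5e12, secretion_per_cell_per_hour: 65}
#   tumor:
#     diameter_cm: 1.0
#     cell_density_per_cm3: 1.0e9
#     secretion_per_cell_per_hour: 65
#     uptake_multiplier: 1.0
#     elimination_multiplier: 1.0


@dataclass
class ModelConfig:
    """A fully parsed parameter file, rates normalized to per-minute."""

    baseline_rates: KineticRates
    blood_panel: list[CellPopulation] = field(default_factory=list)
    tumor: TumorSpec | None = None


def _parse_elimination(section: Mapping[str, Any]) -> RateConstant:
    if "rate_per_min" in section:
        return RateConstant(float(section["rate_per_min"]))
    if "half_life_min" in section:
        return halflife_to_rate(float(section["half_life_min"]))
    raise KeyError("elimination requires 'rate_per_min' or 'half_life_min'")


def _parse_uptake(section: Mapping[str, Any]) -> RateConstant:
    if "rate_per_min" in section:
        return RateConstant(float(section["rate_per_min"]))
    if "fraction_per_hour" in section:
        return fraction_per_hour_to_rate(float(section["fraction_per_hour"]))
    raise KeyError("uptake requires 'rate_per_min' or 'fraction_per_hour'")


def load_config(path: str | Path) -> ModelConfig:
    """Read a YAML or JSON parameter file and normalize all rates to per-minute."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a mapping at top level")

    rates_section = data.get("baseline_rates", {})
    if rates_section:
        baseline = KineticRates(
            elimination=_parse_elimination(rates_section.get("elimination", {})),
            uptake=_parse_uptake(rates_section.get("uptake", {})),
        )
    else:
        baseline = default_rates()

    panel: list[CellPopulation] = []
    for entry in data.get("blood_panel", []) or []:
        panel.append(
            CellPopulation(
                name=str(entry["name"]),
                count=float(entry["count"]),
                secretion_rate=per_hour_to_per_minute(float(entry["secretion_per_cell_per_hour"])),
                rates=baseline,
            )
        )

    tumor = None
    if "tumor" in data and data["tumor"]:
        t = data["tumor"]
        tumor = TumorSpec(
            diameter=float(t["diameter_cm"]),
            cell_density=float(t.get("cell_density_per_cm3", DEFAULT_TUMOR_CELL_DENSITY)),
            secretion_rate=per_hour_to_per_minute(
                float(t.get("secretion_per_cell_per_hour", DEFAULT_TUMOR_SECRETION_PER_HOUR))
            ),
            uptake_multiplier=float(t.get("uptake_multiplier", 1.0)),
            elimination_multiplier=float(t.get("elimination_multiplier", 1.0)),
        )

    return ModelConfig(baseline_rates=baseline, blood_panel=panel, tumor=tumor)


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a parameter file, echoing the normalized per-minute rates for provenance."""
    path = Path(path)
    data: dict[str, Any] = {
        "baseline_rates": {
            "elimination": {"rate_per_min": config.baseline_rates.elimination.value},
            "uptake": {"rate_per_min": config.baseline_rates.uptake.value},
        },
        "blood_panel": [
            {
                "name": pop.name,
                "count": pop.count,
                "secretion_per_cell_per_hour": pop.secretion_rate * 60.0,
                "secretion_per_cell_per_min": pop.secretion_rate,
            }
            for pop in config.blood_panel
        ],
    }
    if config.tumor is not None:
        data["tumor"] = {
            "diameter_cm": config.tumor.diameter,
            "cell_density_per_cm3": config.tumor.cell_density,
            "secretion_per_cell_per_hour": config.tumor.secretion_rate * 60.0,
            "uptake_multiplier": config.tumor.uptake_multiplier,
            "elimination_multiplier": config.tumor.elimination_multiplier,
        }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
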