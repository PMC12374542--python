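"""Synthetic blood-cell EV-source panels, calibrated to a target plasma pool.

The per-cell-type secretion rates and circulating cell numbers that drive
the normal-cell EV pool come from external measurement compilations and are
not bundled here.  This module generates SYNTHETIC stand-in panels with the
same structure — a few dominant secreting cell types (platelets, CD4 memory
cells, monocytes) above a numerically huge but weakly secreting erythrocyte
background — and then rescales all secretion rates by one common factor so
the summed steady state matches a target total concentration (default
1e10 EVs per ml).  Calibration preserves the relative composition exactly,
so downstream percentage-contribution results depend only on the target
total and the composition structure, not on the raw draws.

Users with measured per-cell-type values should write them into the panel
config (see ``parameters.save_config``) instead of generating one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .kinetics import steady_state_count
from .parameters import CellPopulation, KineticRates, default_rates

__all__ = [
    "PanelTemplate",
    "DEFAULT_COUNT_RANGES",
    "DEFAULT_SECRETION_RANGES_PER_HOUR",
    "DEFAULT_TARGET_CONCENTRATION",
    "DEFAULT_PLASMA_VOLUME_ML",
    "generate_panel",
    "calibrate_panel",
    "reference_panel",
]

DEFAULT_TARGET_CONCENTRATION: float = 1e10  # EVs per ml of blood
DEFAULT_PLASMA_VOLUME_ML: float = 3000.0

# Whole-circulation cell numbers, [low, high].  Orders of magnitude are the
# physiological ones (~2.5e13 erythrocytes, ~1.5e12 platelets, ~2.5e9
# monocytes, ~5e9 CD4 memory T cells in an adult).
DEFAULT_COUNT_RANGES: dict[str, tuple[float, float]] = {
    "red blood cells": (1.5e13, 3.5e13),
    "platelets": (8e11, 2.5e12),
    "monocytes": (1e9, 6e9),
    "CD4 memory cells": (2e9, 1e10),
}

# Per-cell secretion, EVs/cell/hour, [low, high].  Chosen so that at range
# midpoints platelets dominate and CD4 memory cells and monocytes outrank
# erythrocytes (whose per-cell vesiculation is very low), matching the
# qualitative ranking reported for plasma EV origins.
DEFAULT_SECRETION_RANGES_PER_HOUR: dict[str, tuple[float, float]] = {
    "red blood cells": (0.01, 0.1),
    "platelets": (30.0, 120.0),
    "monocytes": (500.0, 3000.0),
    "CD4 memory cells": (500.0, 3000.0),
}


@dataclass(frozen=True)
class PanelTemplate:
    """Ranges and targets from which a synthetic panel is drawn."""

    cell_type_names: Sequence[str] = tuple(DEFAULT_COUNT_RANGES)
    count_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COUNT_RANGES)
    )
    secretion_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SECRETION_RANGES_PER_HOUR)
    )
    target_total_concentration: float = DEFAULT_TARGET_CONCENTRATION
    plasma_volume: float = DEFAULT_PLASMA_VOLUME_ML
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_total_concentration <= 0:
            raise ValueError("target total concentration must be > 0")
        if self.plasma_volume <= 0:
            raise ValueError("plasma volume must be > 0 ml")
        for name in self.cell_type_names:
            for label, ranges in (("count", self.count_ranges), ("secretion", self.secretion_ranges)):
                if name not in ranges:
                    raise ValueError(f"missing {label} range for cell type {name!r}")
                low, high = ranges[name]
                if not 0 < low <= high:
                    raise ValueError(
                        f"{label} range for {name!r} must satisfy 0 < low <= high, got [{low}, {high}]"
                    )


def _loguniform(rng: np.random.Generator, low: float, high: float) -> float:
    # Degenerate [x, x] ranges return exactly x.
    if low == high:
        return low
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def generate_panel(
    template: PanelTemplate,
    rates: KineticRates | None = None,
) -> list[CellPopulation]:
    """Draw an uncalibrated panel: log-uniform counts and secretion rates.

    Counts span orders of magnitude across cell types, hence the log-uniform
    draws.  All populations share one set of baseline clearance kinetics.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(template.seed)
    shared_rates = rates if rates is not None else default_rates()
    panel = []
    for name in template.cell_type_names:
        count = _loguniform(rng, *template.count_ranges[name])
        secretion_per_hour = _loguniform(rng, *template.secretion_ranges[name])
        panel.append(
            CellPopulation(
                name=name,
                count=count,
                secretion_rate=secretion_per_hour / 60.0,
                rates=shared_rates,
            )
        )
    return panel


def calibrate_panel(
    panel: Sequence[CellPopulation],
    target_total_concentration: float = DEFAULT_TARGET_CONCENTRATION,
    plasma_volume: float = DEFAULT_PLASMA_VOLUME_ML,
) -> list[CellPopulation]:
    """Rescale all secretion rates by one factor to hit the target pool size.

    After calibration ``sum_i N*_i = target_total_concentration *
    plasma_volume`` exactly (to floating-point); per-type composition shares
    are unchanged because the scale factor is common.
    """
    if target_total_concentration <= 0 or plasma_volume <= 0:
        raise ValueError("target concentration and plasma volume must be > 0")
    total = sum(steady_state_count(pop) for pop in panel)
    if total <= 0:
        raise ValueError("cannot calibrate a panel with zero total steady state")
    factor = (target_total_concentration * plasma_volume) / total
    return [replace(pop, secretion_rate=pop.secretion_rate * factor) for pop in panel]


def reference_panel(
    seed: int = 0,
    rates: KineticRates | None = None,
    target_total_concentration: float = DEFAULT_TARGET_CONCENTRATION,
    plasma_volume: float = DEFAULT_PLASMA_VOLUME_ML,
) -> list[CellPopulation]:
    """A calibrated synthetic default panel (generate + calibrate in one step)."""
    template = PanelTemplate(
        seed=seed,
        target_total_concentration=target_total_concentration,
        plasma_volume=plasma_volume,
    )
    panel = generate_panel(template, rates=rates)
    return calibrate_panel(panel, target_total_concentration, plasma_volume)
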