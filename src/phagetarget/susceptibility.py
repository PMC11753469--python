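"""Growth scoring, MIC calling and survival matrices from greyscale lawn data.

Bacterial growth on agar is quantified as the mean 8-bit greyscale value of a
fixed plate region minus the mean greyscale of a blank plate (background mode
near 37).  A strain "grows" at a concentration when the median blank-subtracted
value across replicates exceeds the growth threshold tau (8 = strict,
12 = lenient); the MIC is the lowest tested concentration at which the median
falls to or below tau.  Aggregating growth calls per causal gene yields the
x/n survival matrix consumed by the target-size models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalogue import SurvivalEntry

__all__ = [
    "PlateGrowthRecord",
    "GrowthCall",
    "MICResult",
    "ABOVE_RANGE",
    "STRICT_THRESHOLD",
    "LENIENT_THRESHOLD",
    "growth_values",
    "call_growth",
    "mic",
    "survival_matrix",
    "growth_calls",
]

STRICT_THRESHOLD = 8.0
LENIENT_THRESHOLD = 12.0

#: Sentinel MIC for strains still growing at the highest tested concentration.
ABOVE_RANGE = "above-range"

_ANTIBIOTICS = ("none", "chloramphenicol", "gentamicin")


@dataclass(frozen=True)
class PlateGrowthRecord:
    """One replicate greyscale measurement of a strain at one concentration."""

    strain: str
    antibiotic: str
    concentration_ug_per_ml: float
    replicate: int
    mean_greyscale: float
    blank_greyscale: float = 37.0

    def __post_init__(self) -> None:
        if self.antibiotic not in _ANTIBIOTICS:
            raise ValueError(f"unknown antibiotic {self.antibiotic!r}")
        if self.concentration_ug_per_ml < 0:
            raise ValueError("concentration must be non-negative")
        for attr in ("mean_greyscale", "blank_greyscale"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{attr} must lie in [0, 255]")

    @property
    def growth_value(self) -> float:
        """Blank-subtracted greyscale; may be negative (clamped only for calls)."""
        return self.mean_greyscale - self.blank_greyscale


@dataclass(frozen=True)
class GrowthCall:
    strain: str
    antibiotic: str
    concentration: float
    median_growth_value: float
    threshold: float
    grows: bool


@dataclass(frozen=True)
class MICResult:
    strain: str
    antibiotic: str
    mic_ug_per_ml: float | str  # a tested concentration or ABOVE_RANGE


def growth_values(
    records: Iterable[PlateGrowthRecord],
) -> dict[tuple[str, str, float], float]:
    """Median blank-subtracted growth value per (strain, antibiotic, concentration).

    Cells with no replicate simply do not appear (never imputed).
    """
    by_cell: dict[tuple[str, str, float], list[float]] = {}
    for rec in records:
        key = (rec.strain, rec.antibiotic, rec.concentration_ug_per_ml)
        by_cell.setdefault(key, []).append(rec.growth_value)
    return {key: float(np.median(vals)) for key, vals in by_cell.items()}


def call_growth(median_value: float, threshold: float = STRICT_THRESHOLD) -> bool:
    """Growth iff the median value strictly exceeds tau (equality = no growth)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return max(median_value, 0.0) > threshold


def growth_calls(
    records: Iterable[PlateGrowthRecord],
    threshold: float = STRICT_THRESHOLD,
) -> list[GrowthCall]:
    """Median growth values turned into growth calls for every measured cell."""
    calls = []
    for (strain, antibiotic, conc), med in sorted(growth_values(records).items()):
        calls.append(
            GrowthCall(strain, antibiotic, conc, med, threshold, call_growth(med, threshold))
        )
    return calls


def mic(strain_series: Sequence[GrowthCall]) -> MICResult:
    """Lowest concentration (scanning ascending) at which growth stops.

    Non-monotone profiles are resolved by this first-crossing rule; a strain
    growing at every tested concentration gets the above-range sentinel.
    """
    if not strain_series:
        raise ValueError("empty growth-call series")
    concs = [c.concentration for c in strain_series]
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValueError("concentrations must be strictly ascending")
    strains = {c.strain for c in strain_series}
    antibiotics = {c.antibiotic for c in strain_series}
    if len(strains) != 1 or len(antibiotics) != 1:
        raise ValueError("MIC series must cover a single strain and antibiotic")
    for call in strain_series:
        if not call.grows:
            return MICResult(call.strain, call.antibiotic, call.concentration)
    return MICResult(strain_series[0].strain, strain_series[0].antibiotic, ABOVE_RANGE)


def survival_matrix(
    calls: Iterable[GrowthCall],
    strain_to_gene: Mapping[str, str],
    environment_labels: Mapping[tuple[str, float], str] | None = None,
) -> list[SurvivalEntry]:
    """Aggregate growth calls into the per-gene x/n survival matrix.

    ``x`` counts strains (carrying a mutation in the gene) that grow at the
    environment's antibiotic concentration, ``n`` all strains carrying one.
    ``environment_labels`` optionally maps (antibiotic, concentration) to a
    label; the default label is ``"{antibiotic}_{concentration:g}"``.
    """
    tallies: dict[tuple[str, str], list[int]] = {}
    for call in calls:
        if call.strain not in strain_to_gene:
            raise KeyError(f"strain {call.strain!r} has no causal-gene assignment")
        gene = strain_to_gene[call.strain]
        key = (call.antibiotic, call.concentration)
        if environment_labels is not None:
            if key not in environment_labels:
                raise KeyError(f"no environment label for {key}")
            env = environment_labels[key]
        else:
            env = f"{call.antibiotic}_{call.concentration:g}"
        x_n = tallies.setdefault((gene, env), [0, 0])
        x_n[0] += int(call.grows)
        x_n[1] += 1
    return [
        SurvivalEntry(gene, env, x, n) for (gene, env), (x, n) in sorted(tallies.items())
    ]
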