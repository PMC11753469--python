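"""Generative simulator for every input the pipeline consumes.

Fluctuation cultures are simulated under the same assumptions the estimator
makes: a single founding cell grows to ``Nt`` cells, mutational events occur
uniformly over the ``Nt - 1`` cell divisions (Poisson number with mean
``m = mu*(Nt-1)``), and mutants grow at the wild-type rate, so each event
founds a clone whose final size follows ``P(K = k) = 1/(k*(k+1))`` (sampled
exactly as ``floor(1/U)``, capped at ``Nt``).  Plating thins every mutant cell
independently with probability epsilon, each clone is assigned a causal gene
categorically in proportion to the model weights, and each plated cell then
survives the antibiotic with its gene's survival fraction — the generative
statement of the target-size models.

Greyscale plate tables are emulated as a high lawn level below a strain's true
MIC and a near-blank level at or above it, with Gaussian replicate noise and a
background mode of 37.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalogue import SurvivalEntry
from .fluctuation import FluctuationExperiment
from .spectra import MutantRecord
from .susceptibility import PlateGrowthRecord
from .target_models import GeneWeightTable

__all__ = [
    "SimulationConfig",
    "SimulatedExperiment",
    "simulate_culture",
    "sample_clone_sizes",
    "plate_culture",
    "simulate_fluctuation_experiment",
    "simulate_counts",
    "simulate_plate_growth_table",
]

_PRACTICAL_M_LIMIT = 50.0


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth for one simulated fluctuation experiment.

    The defaults mirror the source assay design: 50 single-cell-founded
    cultures grown to ``Nt = 1e8`` cells, full plating, and a per-division
    mutation rate of 1e-8 (one expected mutation per culture — the regime in
    which most plates show between 1 and 100 colonies).
    """

    mu_per_division: float = 1e-8
    n_final_cells: float = 1e8
    plating_fraction: float = 1.0
    n_cultures: int = 50
    gene_weights: GeneWeightTable | None = None
    survival_fractions: tuple[SurvivalEntry, ...] = ()
    environment_label: str = "phage"
    seed: int = 0
    collect_genotypes: bool = True
    #: optional per-environment establishment probability applied to every
    #: plated mutant cell on top of its gene survival (default: no effect)
    establishment_probability: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_per_division < 0:
            raise ValueError("mu_per_division must be non-negative")
        if self.n_final_cells <= 1:
            raise ValueError("n_final_cells must exceed 1")
        if not 0.0 < self.plating_fraction <= 1.0:
            raise ValueError("plating_fraction must lie in (0, 1]")
        if self.n_cultures < 1:
            raise ValueError("n_cultures must be positive")
        if not 0.0 <= self.establishment_probability <= 1.0:
            raise ValueError("establishment_probability must lie in [0, 1]")
        m = self.mu_per_division * (self.n_final_cells - 1.0)
        if m > _PRACTICAL_M_LIMIT:
            raise ValueError(f"expected mutations per culture m = {m:.1f} too large")


@dataclass(frozen=True)
class SimulatedExperiment:
    experiment: FluctuationExperiment
    mutant_records: tuple[MutantRecord, ...]
    truth: SimulationConfig


def sample_clone_sizes(rng: np.random.Generator, n_clones: int, n_final: float) -> np.ndarray:
    """Final descendant counts of ``n_clones`` mutational events.

    Equal mutant/wild-type growth makes the clone-size law P(K = k) =
    1/(k*(k+1)); floor(1/U) with U uniform reproduces it exactly.  Sizes are
    capped at the culture size.
    """
    if n_clones == 0:
        return np.zeros(0, dtype=np.int64)
    u = rng.random(n_clones)
    sizes = np.floor(1.0 / u)
    return np.minimum(sizes, n_final).astype(np.int64)


def simulate_culture(mu: float, n_final: float, seed: int | np.random.Generator) -> np.ndarray:
    """Mutant clone sizes of one culture grown from a single cell to ``n_final``."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = mu * (n_final - 1.0)
    n_clones = int(rng.poisson(m))
    return sample_clone_sizes(rng, n_clones, n_final)


def _weights_as_arrays(
    gene_weights: GeneWeightTable | None,
    survival: Iterable[SurvivalEntry],
    environment: str,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    if gene_weights is None:
        return ["resistance"], np.array([1.0]), np.array([1.0])
    genes = list(gene_weights.weights)
    w = np.array([gene_weights.weights[g] for g in genes], dtype=float)
    if w.sum() <= 0:
        raise ValueError("gene weights sum to zero")
    surv = {e.gene: e.fraction for e in survival if e.environment_label == environment}
    s = np.array([surv.get(g, 1.0) for g in genes], dtype=float)
    return genes, w / w.sum(), s


def plate_culture(
    clone_sizes: Sequence[int],
    epsilon: float,
    gene_weights: GeneWeightTable | None,
    survival: Iterable[SurvivalEntry],
    seed: int | np.random.Generator,
    environment: str = "phage",
    establishment_probability: float = 1.0,
) -> tuple[int, list[str]]:
    """Plate one culture: thin, assign genes, apply per-gene survival.

    Returns the resistant-colony count and one gene label per colony.
    """
    if not 0.0 < epsilon <= 1.0:
        raise ValueError("epsilon must lie in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes, probs, surv = _weights_as_arrays(gene_weights, survival, environment)
    sizes = np.asarray(clone_sizes, dtype=np.int64)
    if sizes.size == 0:
        return 0, []
    gene_idx = rng.choice(len(genes), size=sizes.size, p=probs)
    p_obs = epsilon * surv[gene_idx] * establishment_probability
    colonies = rng.binomial(sizes, p_obs)
    labels: list[str] = []
    for gi, c in zip(gene_idx, colonies):
        labels.extend([genes[gi]] * int(c))
    return int(colonies.sum()), labels


def simulate_fluctuation_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Run ``n_cultures`` independent cultures under one seeded generator."""
    rng = np.random.default_rng(config.seed)
    counts: list[int] = []
    records: list[MutantRecord] = []
    for i in range(config.n_cultures):
        clones = simulate_culture(config.mu_per_division, config.n_final_cells, rng)
        count, labels = plate_culture(
            clones,
            config.plating_fraction,
            config.gene_weights,
            config.survival_fractions,
            rng,
            environment=config.environment_label,
            establishment_probability=config.establishment_probability,
        )
        counts.append(count)
        if config.collect_genotypes:
            for j, gene in enumerate(labels):
                records.append(
                    MutantRecord(
                        isolate_id=f"c{i:04d}_m{j:03d}",
                        environment_label=config.environment_label,
                        mutated_genes=(gene,),
                        causal_gene=gene,
                        lps_class="non_lps",
                    )
                )
    experiment = FluctuationExperiment(
        environment_label=config.environment_label,
        counts=tuple(counts),
        n_total_cells=config.n_final_cells,
        plating_fraction=config.plating_fraction,
    )
    return SimulatedExperiment(experiment, tuple(records), config)


def simulate_counts(
    mu: float,
    n_final: float,
    epsilon: float,
    n_cultures: int,
    rng: np.random.Generator,
    gene_probs: np.ndarray | None = None,
    survival_probs: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised colony counts for many cultures (rate-only fast path).

    ``gene_probs``/``survival_probs`` optionally mix per-clone gene assignment
    with gene-specific survival; omitted, every plated cell is kept with
    probability epsilon alone.
    """
    m = mu * (n_final - 1.0)
    n_clones = rng.poisson(m, size=n_cultures)
    total = int(n_clones.sum())
    sizes = sample_clone_sizes(rng, total, n_final)
    if gene_probs is not None:
        gi = rng.choice(len(gene_probs), size=total, p=gene_probs)
        p_obs = epsilon * survival_probs[gi]
    else:
        p_obs = np.full(total, epsilon)
    colonies = rng.binomial(sizes, p_obs) if total else np.zeros(0, dtype=np.int64)
    culture_of = np.repeat(np.arange(n_cultures), n_clones)
    return np.bincount(culture_of, weights=colonies, minlength=n_cultures).astype(np.int64)


def simulate_plate_growth_table(
    strain_mics: Mapping[str, float],
    concentrations: Sequence[float],
    noise_sd: float = 3.0,
    blank: float = 37.0,
    seed: int | np.random.Generator = 0,
    antibiotic: str = "chloramphenicol",
    n_replicates: int = 3,
    lawn_level: float = 70.0,
    no_growth_level: float = 2.0,
) -> list[PlateGrowthRecord]:
    """Greyscale plate table with a known true MIC per strain.

    Below its MIC a strain produces a uniform lawn (mean greyscale ``blank +
    lawn_level``); at or above it, a near-blank plate (``blank +
    no_growth_level``); replicate noise is Gaussian and values are clipped to
    the 8-bit range [0, 255].
    """
    if any(b <= a for a, b in zip(concentrations, list(concentrations)[1:])):
        raise ValueError("concentrations must be strictly ascending")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = []
    for strain, true_mic in strain_mics.items():
        for conc in concentrations:
            level = lawn_level if conc < true_mic else no_growth_level
            for rep in range(1, n_replicates + 1):
                grey = blank + level + rng.normal(0.0, noise_sd)
                records.append(
                    PlateGrowthRecord(
                        strain=strain,
                        antibiotic=antibiotic,
                        concentration_ug_per_ml=float(conc),
                        replicate=rep,
                        mean_greyscale=float(np.clip(grey, 0.0, 255.0)),
                        blank_greyscale=blank,
                    )
                )
    return records
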