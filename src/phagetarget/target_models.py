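"""Mutational-target-size models for phage-resistance rate prediction.

Three nested models turn the gene catalogue and the antibiotic-survival matrix
into per-environment gene weights:

* **model 1** — the probability of a resistance mutation landing in gene *g*
  is proportional to its coding length; the weight in environment *e* is
  ``w_g = (x_g/n_g) * length_g`` where ``x/n`` is the fraction of *g*-mutants
  that grow in *e*.
* **model 2** — the length is replaced by the number of mutations actually
  observed in the reference (phage-only) environment, plus a pseudo-count so
  unobserved genes keep non-zero weight: ``w_g = (x_g/n_g) * (count_g + 1)``.
* **model 3** — identical to model 2 but the survival matrix is rebuilt with
  the lenient growth threshold (greyscale 12 instead of 8).

The predicted relative resistance rate of an environment is the ratio of its
total weight to the reference total; normalised weights give the predicted
gene-wise and LPS-type mutant distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

from .catalogue import (
    CLASS_SEVERITY,
    DEFAULT_SURVIVAL_PROXIES,
    GeneRecord,
    SurvivalEntry,
    catalogue_by_name,
)

__all__ = [
    "GeneWeightTable",
    "ModelPrediction",
    "model1_weights",
    "model2_weights",
    "model3_weights",
    "predicted_relative_rate",
    "predicted_distributions",
    "round_half_up",
]

ModelId = Literal["model1", "model2", "model3"]


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties away from zero (display convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class GeneWeightTable:
    """Per-gene mutational weights for one model and environment."""

    model_id: ModelId
    environment_label: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("gene weights must be non-negative")

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights.values()))


@dataclass(frozen=True)
class ModelPrediction:
    """Relative rate and mutant-distribution prediction for one environment."""

    model_id: ModelId
    environment_label: str
    relative_rate: float | None
    gene_proportions: Mapping[str, float]
    lps_type_proportions: Mapping[str, float]


def _survival_lookup(
    survival: Iterable[SurvivalEntry],
    environment: str,
    gene_names: Iterable[str],
    proxies: Mapping[str, str] | None,
) -> dict[str, float]:
    """Survival fraction per gene in ``environment``, applying proxy profiles.

    Genes never isolated in the original screen have no measured survival; the
    default proxies map them onto the profile of the pathway-adjacent gene
    (gmhA -> gmhB, hldD -> hldE), overridable by the caller.
    """
    if proxies is None:
        proxies = DEFAULT_SURVIVAL_PROXIES
    by_gene: dict[str, float] = {}
    seen_env = False
    for entry in survival:
        if entry.environment_label == environment:
            by_gene[entry.gene] = entry.fraction
            seen_env = True
    if not seen_env:
        raise KeyError(f"no survival entries for environment {environment!r}")
    out: dict[str, float] = {}
    for name in gene_names:
        if name in by_gene:
            out[name] = by_gene[name]
        elif name in proxies and proxies[name] in by_gene:
            out[name] = by_gene[proxies[name]]
        else:
            raise KeyError(
                f"gene {name!r} has no survival entry (or proxy) in environment "
                f"{environment!r}"
            )
    return out


def model1_weights(
    genes: Iterable[GeneRecord],
    survival: Iterable[SurvivalEntry],
    environment: str,
    proxies: Mapping[str, str] | None = None,
) -> GeneWeightTable:
    """Gene-length model: ``w_g = (x_g/n_g) * coding_length_g``."""
    cat = catalogue_by_name(genes)
    frac = _survival_lookup(survival, environment, cat, proxies)
    weights = {name: frac[name] * cat[name].coding_length_bp for name in cat}
    return GeneWeightTable("model1", environment, weights)


def model2_weights(
    genes: Iterable[GeneRecord],
    observed_counts_reference: Mapping[str, int],
    survival: Iterable[SurvivalEntry],
    environment: str,
    pseudo_count: int = 1,
    proxies: Mapping[str, str] | None = None,
) -> GeneWeightTable:
    """Observed-spectrum model: ``w_g = (x_g/n_g) * (count_g + pseudo)``.

    ``observed_counts_reference`` are causal-gene counts from the phage-only
    environment; genes absent from the mapping count as zero and survive only
    through the pseudo-count.
    """
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be non-negative")
    cat = catalogue_by_name(genes)
    for gene, count in observed_counts_reference.items():
        if count < 0:
            raise ValueError(f"negative observed count for gene {gene!r}")
    frac = _survival_lookup(survival, environment, cat, proxies)
    weights = {
        name: frac[name] * (observed_counts_reference.get(name, 0) + pseudo_count)
        for name in cat
    }
    return GeneWeightTable("model2", environment, weights)


def model3_weights(
    genes: Iterable[GeneRecord],
    observed_counts_reference: Mapping[str, int],
    survival_lenient: Iterable[SurvivalEntry],
    environment: str,
    pseudo_count: int = 1,
    proxies: Mapping[str, str] | None = None,
) -> GeneWeightTable:
    """Model 2 with the survival matrix rebuilt at the lenient threshold (12)."""
    table = model2_weights(
        genes, observed_counts_reference, survival_lenient, environment,
        pseudo_count=pseudo_count, proxies=proxies,
    )
    return GeneWeightTable("model3", environment, dict(table.weights))


def predicted_relative_rate(
    weights_env: GeneWeightTable, weights_ref: GeneWeightTable
) -> float:
    """rho = total weight of the environment / total weight of the reference."""
    if weights_env.model_id != weights_ref.model_id:
        raise ValueError("relative rate requires the same model for both tables")
    if set(weights_env.weights) != set(weights_ref.weights):
        raise ValueError("relative rate requires the same gene catalogue")
    total_ref = weights_ref.total_weight
    if total_ref <= 0:
        raise ValueError("reference environment has zero total weight")
    return weights_env.total_weight / total_ref


def predicted_distributions(
    weights: GeneWeightTable,
    genes: Iterable[GeneRecord],
    relative_rate: float | None = None,
) -> ModelPrediction:
    """Normalise weights into gene-wise and LPS-type mutant proportions.

    The regulatory class (rfaH) is reported on its own, never folded into
    rough or deep rough.
    """
    cat = catalogue_by_name(genes)
    total = weights.total_weight
    if total <= 0:
        raise ValueError("cannot form proportions: total weight is zero")
    gene_props = {name: w / total for name, w in weights.weights.items()}
    class_props = {cls: 0.0 for cls in CLASS_SEVERITY}
    for name, prop in gene_props.items():
        if name not in cat:
            raise KeyError(f"gene {name!r} missing from catalogue")
        class_props[cat[name].lps_class] += prop
    return ModelPrediction(
        model_id=weights.model_id,
        environment_label=weights.environment_label,
        relative_rate=relative_rate,
        gene_proportions=gene_props,
        lps_type_proportions=class_props,
    )
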