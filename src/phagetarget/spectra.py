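"""Mutant spectra: causal-gene classification, bootstrap SDs, goodness of fit.

A resistant isolate may carry several mutations; only the one predicted to
cause the most dramatic LPS truncation is scored as causal (severity order
deep rough > regulatory > rough > non-LPS, ties broken by catalogue/pathway
order).  Per-environment gene counts form the observed mutant spectrum;
sampling uncertainty is estimated by resampling isolates with replacement
(after adding one pseudo-isolate for every gene that could confer resistance
in that environment), and model predictions are tested against observed
spectra with Pearson chi-square goodness-of-fit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .catalogue import CLASS_SEVERITY, GeneRecord, catalogue_by_name
from .target_models import ModelPrediction

__all__ = [
    "MutantRecord",
    "MutantSpectrum",
    "make_mutant_record",
    "assign_causal_gene",
    "spectrum",
    "bootstrap_spectrum",
    "gof_chisq",
]

_SEVERITY_RANK = {cls: i for i, cls in enumerate(CLASS_SEVERITY)}


@dataclass(frozen=True)
class MutantRecord:
    """One sequenced phage-resistant isolate."""

    isolate_id: str
    environment_label: str
    mutated_genes: tuple[str, ...]
    causal_gene: str
    lps_class: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "mutated_genes", tuple(self.mutated_genes))
        if not self.mutated_genes:
            raise ValueError(f"isolate {self.isolate_id}: empty mutation list")
        if self.causal_gene not in self.mutated_genes:
            raise ValueError(
                f"isolate {self.isolate_id}: causal gene not among mutated genes"
            )


@dataclass(frozen=True)
class MutantSpectrum:
    """Observed causal-gene counts for one environment."""

    environment_label: str
    counts: Mapping[str, int]
    bootstrap_sd_gene: Mapping[str, float] | None = None
    bootstrap_sd_class: Mapping[str, float] | None = None

    @property
    def n_isolates(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def proportions(self) -> dict[str, float]:
        n = self.n_isolates
        if n == 0:
            raise ValueError("spectrum has no isolates")
        return {g: c / n for g, c in self.counts.items()}


def make_mutant_record(
    isolate_id: str,
    environment_label: str,
    mutated_genes: Sequence[str],
    catalogue: Iterable[GeneRecord],
) -> MutantRecord:
    """Build a record with the causal gene and LPS class filled in."""
    genes = list(catalogue)
    causal = assign_causal_gene(mutated_genes, genes)
    cat = catalogue_by_name(genes)
    cls = cat[causal].lps_class if causal in cat else "non_lps"
    return MutantRecord(isolate_id, environment_label, tuple(mutated_genes), causal, cls)


def assign_causal_gene(
    mutated_genes: Sequence[str], catalogue: Iterable[GeneRecord]
) -> str:
    """Pick the mutation predicted to cause the most dramatic LPS change.

    Severity precedence: deep rough > regulatory > rough > non-LPS; within a
    class, the gene listed earlier in the catalogue (pathway order) wins.
    An isolate with no catalogued gene is classified non-LPS under its first
    listed gene.
    """
    if not mutated_genes:
        raise ValueError("mutated gene list is empty")
    genes = list(catalogue)
    cat_order = {g.name: i for i, g in enumerate(genes)}
    cat = catalogue_by_name(genes)
    candidates = [g for g in mutated_genes if g in cat_order]
    if not candidates:
        return mutated_genes[0]
    return min(
        candidates,
        key=lambda g: (_SEVERITY_RANK[cat[g].lps_class], cat_order[g]),
    )


def spectrum(
    mutants: Iterable[MutantRecord],
    environment: str,
    catalogue: Iterable[GeneRecord],
) -> MutantSpectrum:
    """Observed causal-gene counts in one environment, zero-filled over the catalogue."""
    counts: dict[str, int] = {g.name: 0 for g in catalogue}
    seen_env = False
    n_in_env = 0
    for rec in mutants:
        if rec.environment_label != environment:
            continue
        seen_env = True
        n_in_env += 1
        counts[rec.causal_gene] = counts.get(rec.causal_gene, 0) + 1
    if not seen_env:
        raise KeyError(f"no isolates recorded for environment {environment!r}")
    return MutantSpectrum(environment, counts)


def bootstrap_spectrum(
    spec: MutantSpectrum,
    candidate_genes: Sequence[str],
    catalogue: Iterable[GeneRecord],
    n_boot: int = 100,
    pseudo_count: int = 1,
    seed: int = 0,
) -> MutantSpectrum:
    """Bootstrap SDs of the per-gene and per-LPS-class proportions.

    The resampling pool is the observed isolates plus ``pseudo_count``
    pseudo-isolates for every candidate gene (genes able to confer resistance
    in the environment), added before sampling; each replicate redraws
    pool-size isolates with replacement.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be non-negative")
    cat = catalogue_by_name(catalogue)
    genes = list(dict.fromkeys(list(spec.counts) + list(candidate_genes)))
    pool = np.array(
        [spec.counts.get(g, 0) + (pseudo_count if g in candidate_genes else 0) for g in genes],
        dtype=float,
    )
    pool_size = int(pool.sum())
    if pool_size == 0:
        raise ValueError("empty resampling pool")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(pool_size, pool / pool_size, size=n_boot)  # (n_boot, genes)
    props = draws / pool_size
    sd_gene = dict(zip(genes, props.std(axis=0, ddof=0)))
    class_of = np.array(
        [_class_index(g, cat) for g in genes]
    )
    class_props = np.zeros((n_boot, len(CLASS_SEVERITY)))
    for j, _cls in enumerate(CLASS_SEVERITY):
        class_props[:, j] = props[:, class_of == j].sum(axis=1)
    sd_class = dict(zip(CLASS_SEVERITY, class_props.std(axis=0, ddof=0)))
    return MutantSpectrum(
        environment_label=spec.environment_label,
        counts=dict(spec.counts),
        bootstrap_sd_gene={g: float(s) for g, s in sd_gene.items()},
        bootstrap_sd_class={c: float(s) for c, s in sd_class.items()},
    )


def _class_index(gene: str, cat: Mapping[str, GeneRecord]) -> int:
    cls = cat[gene].lps_class if gene in cat else "non_lps"
    return CLASS_SEVERITY.index(cls)


def gof_chisq(
    observed: MutantSpectrum,
    predicted: ModelPrediction,
    mode: Literal["gene_wise", "lps_type"] = "gene_wise",
    catalogue: Iterable[GeneRecord] | None = None,
) -> tuple[float, float]:
    """Pearson chi-square goodness of fit of observed counts vs model proportions.

    Categories with zero expected proportion are disallowed; extend the model
    catalogue (the "added genes" variant, which includes hldD and gmhA in the
    gene-length model) so every observed category has positive expectation.
    """
    n = observed.n_isolates
    if mode == "gene_wise":
        exp_props = dict(predicted.gene_proportions)
        obs_counts = {g: observed.counts.get(g, 0) for g in exp_props}
        stray = {
            g: c for g, c in observed.counts.items() if c > 0 and g not in exp_props
        }
        if stray:
            raise ValueError(
                f"observed mutations in categories with zero expectation: "
                f"{sorted(stray)}; use the added-genes model variant"
            )
    elif mode == "lps_type":
        if catalogue is None:
            raise ValueError("lps_type mode requires the gene catalogue")
        cat = catalogue_by_name(catalogue)
        exp_props = {c: 0.0 for c in CLASS_SEVERITY}
        for g, p in predicted.lps_type_proportions.items():
            exp_props[g] = p
        obs_counts = {c: 0 for c in CLASS_SEVERITY}
        for g, c in observed.counts.items():
            cls = cat[g].lps_class if g in cat else "non_lps"
            obs_counts[cls] += c
        # drop classes absent from both observation and expectation
        for cls in list(exp_props):
            if exp_props[cls] == 0.0 and obs_counts[cls] == 0:
                del exp_props[cls], obs_counts[cls]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    cats = sorted(exp_props)
    expected = np.array([exp_props[c] for c in cats]) * n
    obs = np.array([obs_counts[c] for c in cats], dtype=float)
    if np.any(expected <= 0.0):
        bad = [c for c, e in zip(cats, expected) if e <= 0.0]
        raise ValueError(
            f"zero expected count in categories {bad}; use the added-genes "
            f"model variant to guarantee positive expectations"
        )
    total_p = expected.sum() / n
    if abs(total_p - 1.0) > 1e-8:
        raise ValueError("predicted proportions must sum to 1 over the categories")
    statistic, p_value = stats.chisquare(obs, expected)
    return float(statistic), float(p_value)
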