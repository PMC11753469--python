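"""Default gene catalogue and antibiotic-survival annotations.

The catalogue lists the LPS-pathway genes in which loss-of-function mutations
confer resistance of *E. coli* C to phage PhiX174, together with their coding
lengths (the mutational target size of each gene) and the LPS phenotype class
a knockout produces. Genes appear in biosynthetic-pathway order; that order is
also the tie-break used when classifying multi-mutation isolates.

The survival annotations record, for each gene and each phage+antibiotic
plating environment, the fraction x/n of resistant strains carrying a mutation
in that gene that still grow at the given antibiotic concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

LpsClass = Literal["rough", "deep_rough", "regulatory", "non_lps"]

#: Severity precedence used when a single isolate carries several mutations:
#: the most LPS-truncating class wins.
CLASS_SEVERITY: tuple[str, ...] = ("deep_rough", "regulatory", "rough", "non_lps")

#: Canonical plating-environment labels.
ENV_PHAGE = "phage"
ENV_PHAGE_CL1 = "phage_CL1"
ENV_PHAGE_CL2 = "phage_CL2"
ENV_PHAGE_GM1 = "phage_GM1"
ENV_PHAGE_GM2 = "phage_GM2"
DEFAULT_ENVIRONMENTS = (
    ENV_PHAGE,
    ENV_PHAGE_CL1,
    ENV_PHAGE_CL2,
    ENV_PHAGE_GM1,
    ENV_PHAGE_GM2,
)


@dataclass(frozen=True)
class GeneRecord:
    """One mutational target: a gene whose inactivation confers phage resistance."""

    name: str
    coding_length_bp: int
    lps_class: LpsClass

    def __post_init__(self) -> None:
        if self.coding_length_bp <= 0:
            raise ValueError(f"gene {self.name}: coding length must be positive")
        if self.lps_class not in CLASS_SEVERITY:
            raise ValueError(f"gene {self.name}: unknown LPS class {self.lps_class!r}")


@dataclass(frozen=True)
class SurvivalEntry:
    """Fraction x/n of mutants of a gene that grow in an environment."""

    gene: str
    environment_label: str
    numerator_x: int
    denominator_n: int

    def __post_init__(self) -> None:
        if self.denominator_n <= 0:
            raise ValueError(f"{self.gene}/{self.environment_label}: n must be positive")
        if not 0 <= self.numerator_x <= self.denominator_n:
            raise ValueError(
                f"{self.gene}/{self.environment_label}: need 0 <= x <= n, "
                f"got {self.numerator_x}/{self.denominator_n}"
            )

    @property
    def fraction(self) -> float:
        return self.numerator_x / self.denominator_n


# Default catalogue: the genes of the wild-type phage-resistance screen, with
# coding lengths in bp, in pathway order (outer core first, inner core last).
DEFAULT_GENES: tuple[GeneRecord, ...] = (
    GeneRecord("yajC", 333, "rough"),
    GeneRecord("waaW", 1026, "rough"),
    GeneRecord("galE", 1017, "rough"),
    GeneRecord("waaT", 996, "rough"),
    GeneRecord("waaO", 1017, "rough"),
    GeneRecord("rfaH", 489, "regulatory"),
    GeneRecord("waaP", 798, "deep_rough"),
    GeneRecord("waaG", 1125, "deep_rough"),
    GeneRecord("galU", 909, "deep_rough"),
    GeneRecord("waaF", 1047, "deep_rough"),
    GeneRecord("gmhB", 573, "deep_rough"),
    GeneRecord("hldE", 1434, "deep_rough"),
    GeneRecord("waaC", 972, "deep_rough"),
)

# Two additional inner-core genes observed only in the combination-environment
# screens.  Lengths are the standard E. coli annotation values; both knockouts
# are predicted deep rough.
EXTRA_GENES: tuple[GeneRecord, ...] = (
    GeneRecord("hldD", 933, "deep_rough"),
    GeneRecord("gmhA", 579, "deep_rough"),
)

EXTENDED_GENES: tuple[GeneRecord, ...] = DEFAULT_GENES + EXTRA_GENES

#: Default proxy survival profiles for genes never isolated in the original
#: screen (no direct susceptibility measurement): gmhA behaves like gmhB,
#: hldD like hldE.  Overridable wherever survival tables are consumed.
DEFAULT_SURVIVAL_PROXIES: Mapping[str, str] = {"gmhA": "gmhB", "hldD": "hldE"}

# Survival annotations per environment.  Only deviations from "all strains
# grow" (x/n = 1) are listed; genes absent from an environment's mapping are
# fully permissive there.
_SURVIVAL_DEVIATIONS: Mapping[str, Mapping[str, tuple[int, int]]] = {
    ENV_PHAGE: {},
    ENV_PHAGE_CL1: {"hldE": (3, 6), "waaC": (0, 1)},
    ENV_PHAGE_CL2: {
        "waaP": (1, 2),
        "waaG": (0, 1),
        "galU": (1, 5),
        "waaF": (0, 1),
        "gmhB": (0, 1),
        "hldE": (0, 1),
        "waaC": (0, 1),
    },
    ENV_PHAGE_GM1: {},
    ENV_PHAGE_GM2: {"waaO": (6, 7), "hldE": (1, 6), "waaC": (0, 1)},
}


def default_survival_entries(
    genes: Iterable[GeneRecord] = DEFAULT_GENES,
    environments: Iterable[str] = DEFAULT_ENVIRONMENTS,
) -> tuple[SurvivalEntry, ...]:
    """Survival matrix for the default catalogue in long (gene, env, x, n) form."""
    entries = []
    for env in environments:
        if env not in _SURVIVAL_DEVIATIONS:
            raise KeyError(f"no default survival annotations for environment {env!r}")
        deviations = _SURVIVAL_DEVIATIONS[env]
        for gene in genes:
            x, n = deviations.get(gene.name, (1, 1))
            entries.append(SurvivalEntry(gene.name, env, x, n))
    return tuple(entries)


def catalogue_by_name(genes: Iterable[GeneRecord]) -> dict[str, GeneRecord]:
    """Index a catalogue by gene name, enforcing name uniqueness."""
    out: dict[str, GeneRecord] = {}
    for g in genes:
        if g.name in out:
            raise ValueError(f"duplicate gene name {g.name!r} in catalogue")
        out[g.name] = g
    return out
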