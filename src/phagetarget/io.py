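"""Delimited-table readers/writers for every pipeline schema.

All tables are plain CSV (TSV accepted via ``sep``).  Parsing is strict:
malformed rows raise ``ValueError`` listing the offending line numbers, and
parse -> serialize -> parse is a fixed point for every schema.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalogue import GeneRecord, SurvivalEntry
from .fluctuation import FluctuationExperiment, RateComparison, RateEstimate
from .spectra import MutantRecord, MutantSpectrum, make_mutant_record
from .susceptibility import PlateGrowthRecord

__all__ = [
    "read_counts_table",
    "write_counts_table",
    "read_gene_catalogue",
    "write_gene_catalogue",
    "read_survival_table",
    "write_survival_table",
    "read_observed_counts",
    "read_mutant_table",
    "write_mutant_table",
    "read_plate_table",
    "write_plate_table",
    "write_rates_json",
    "write_json",
]

#: Count-column flags: burst plates are uncountable (right-censorable),
#: invalid plates are discarded (e.g. contamination).
BURST = "burst"
INVALID = "invalid"


def _read_csv(path: str | Path, columns: Sequence[str], sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _bad_rows(df: pd.DataFrame, mask) -> str:
    # +2: header line and 1-based numbering
    lines = [str(i + 2) for i in df.index[mask]]
    return ", ".join(lines)


def read_counts_table(path: str | Path, sep: str = ",") -> list[FluctuationExperiment]:
    """One experiment per environment from rows (environment, count, nt, epsilon).

    ``count`` is a non-negative integer or one of the flags ``burst``
    (uncountable, kept as right-censored) / ``invalid`` (dropped).
    """
    df = _read_csv(path, ["environment", "count", "nt", "epsilon"], sep)
    experiments = []
    for env, grp in df.groupby("environment", sort=True):
        counts: list[int] = []
        n_burst = 0
        bad: list[int] = []
        for idx, raw in zip(grp.index, grp["count"]):
            token = raw.strip().lower()
            if token == INVALID:
                continue
            if token == BURST:
                n_burst += 1
                continue
            try:
                value = int(token)
                if value < 0:
                    raise ValueError
            except ValueError:
                bad.append(idx)
                continue
            counts.append(value)
        if bad:
            raise ValueError(
                f"{path}: malformed count values on lines "
                f"{_bad_rows(df, df.index.isin(bad))}"
            )
        try:
            nt = float(grp["nt"].iloc[0])
            eps = float(grp["epsilon"].iloc[0])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed nt/epsilon for environment {env!r}") from exc
        if grp["nt"].nunique() > 1 or grp["epsilon"].nunique() > 1:
            raise ValueError(f"{path}: inconsistent nt/epsilon within environment {env!r}")
        experiments.append(
            FluctuationExperiment(
                environment_label=str(env),
                counts=tuple(counts),
                n_total_cells=nt,
                plating_fraction=eps,
                n_censored_high=n_burst,
            )
        )
    if not experiments:
        raise ValueError(f"{path}: no cultures parsed")
    return experiments


def write_counts_table(
    experiments: Iterable[FluctuationExperiment], path: str | Path
) -> None:
    rows = []
    for exp in experiments:
        for c in exp.counts:
            rows.append((exp.environment_label, str(c), exp.n_total_cells, exp.plating_fraction))
        for _ in range(exp.n_censored_high):
            rows.append((exp.environment_label, BURST, exp.n_total_cells, exp.plating_fraction))
    pd.DataFrame(rows, columns=["environment", "count", "nt", "epsilon"]).to_csv(
        path, index=False
    )


def read_gene_catalogue(path: str | Path, sep: str = ",") -> list[GeneRecord]:
    df = _read_csv(path, ["name", "length_bp", "lps_class"], sep)
    genes = []
    for i, row in df.iterrows():
        try:
            genes.append(GeneRecord(row["name"], int(row["length_bp"]), row["lps_class"]))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed gene row on line {i + 2}: {exc}") from exc
    return genes


def write_gene_catalogue(genes: Iterable[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(g.name, g.coding_length_bp, g.lps_class) for g in genes],
        columns=["name", "length_bp", "lps_class"],
    ).to_csv(path, index=False)


def read_survival_table(path: str | Path, sep: str = ",") -> list[SurvivalEntry]:
    df = _read_csv(path, ["gene", "environment", "x", "n"], sep)
    entries = []
    for i, row in df.iterrows():
        try:
            entries.append(
                SurvivalEntry(row["gene"], row["environment"], int(row["x"]), int(row["n"]))
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed survival row on line {i + 2}: {exc}") from exc
    return entries


def write_survival_table(entries: Iterable[SurvivalEntry], path: str | Path) -> None:
    pd.DataFrame(
        [(e.gene, e.environment_label, e.numerator_x, e.denominator_n) for e in entries],
        columns=["gene", "environment", "x", "n"],
    ).to_csv(path, index=False)


def read_observed_counts(path: str | Path, sep: str = ",") -> dict[str, int]:
    """Observed causal-gene mutation counts, rows (gene, count)."""
    df = _read_csv(path, ["gene", "count"], sep)
    out: dict[str, int] = {}
    for i, row in df.iterrows():
        try:
            value = int(row["count"])
            if value < 0:
                raise ValueError("negative")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed count on line {i + 2}") from exc
        out[row["gene"]] = value
    return out


def read_mutant_table(
    path: str | Path,
    catalogue: Iterable[GeneRecord],
    sep: str = ",",
) -> list[MutantRecord]:
    """Isolate table with semicolon-separated mutated genes.

    A ``causal_gene`` column, when present, overrides the severity-based
    classification.
    """
    genes = list(catalogue)
    df = _read_csv(path, ["isolate_id", "environment", "mutated_genes"], sep)
    records = []
    for i, row in df.iterrows():
        mutated = tuple(g.strip() for g in row["mutated_genes"].split(";") if g.strip())
        if not mutated:
            raise ValueError(f"{path}: empty mutated_genes on line {i + 2}")
        if "causal_gene" in df.columns and row.get("causal_gene", "").strip():
            causal = row["causal_gene"].strip()
            cat = {g.name: g for g in genes}
            cls = cat[causal].lps_class if causal in cat else "non_lps"
            records.append(
                MutantRecord(row["isolate_id"], row["environment"], mutated, causal, cls)
            )
        else:
            records.append(
                make_mutant_record(row["isolate_id"], row["environment"], mutated, genes)
            )
    return records


def write_mutant_table(records: Iterable[MutantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.isolate_id, r.environment_label, ";".join(r.mutated_genes), r.causal_gene)
            for r in records
        ],
        columns=["isolate_id", "environment", "mutated_genes", "causal_gene"],
    ).to_csv(path, index=False)


def read_plate_table(path: str | Path, sep: str = ",") -> list[PlateGrowthRecord]:
    df = _read_csv(
        path,
        ["strain", "antibiotic", "concentration", "replicate", "mean_greyscale", "blank_greyscale"],
        sep,
    )
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                PlateGrowthRecord(
                    strain=row["strain"],
                    antibiotic=row["antibiotic"],
                    concentration_ug_per_ml=float(row["concentration"]),
                    replicate=int(row["replicate"]),
                    mean_greyscale=float(row["mean_greyscale"]),
                    blank_greyscale=float(row["blank_greyscale"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed plate row on line {i + 2}: {exc}") from exc
    return records


def write_plate_table(records: Iterable[PlateGrowthRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (
                r.strain,
                r.antibiotic,
                r.concentration_ug_per_ml,
                r.replicate,
                r.mean_greyscale,
                r.blank_greyscale,
            )
            for r in records
        ],
        columns=["strain", "antibiotic", "concentration", "replicate", "mean_greyscale", "blank_greyscale"],
    ).to_csv(path, index=False)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(obj), indent=2, sort_keys=True) + "\n")


def write_rates_json(
    estimates: Iterable[RateEstimate],
    comparisons: Iterable[RateComparison] = (),
    path: str | Path = "rates.json",
) -> None:
    write_json(
        {
            "estimates": {e.environment_label: e for e in estimates},
            "comparisons": {c.environment_label: c for c in comparisons},
        },
        path,
    )
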