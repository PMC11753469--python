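"""End-to-end orchestration: estimate -> compare -> predict -> score spectra.

``run_pipeline`` validates the configured inputs up front, runs whichever
stages have inputs, and writes machine-readable CSV/JSON reports plus a run
manifest (config, seeds, version) from which every numeric result can be
reproduced.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__, io
from .catalogue import (
    DEFAULT_ENVIRONMENTS,
    DEFAULT_GENES,
    ENV_PHAGE,
    default_survival_entries,
)
from .fluctuation import compare_rates, estimate_rate
from .spectra import bootstrap_spectrum, gof_chisq, spectrum
from .target_models import (
    model1_weights,
    model2_weights,
    predicted_distributions,
    predicted_relative_rate,
)

log = logging.getLogger("phagetarget")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and settings for one pipeline run; file paths may be omitted to
    skip the corresponding stage (the built-in catalogue and survival
    annotations are used when no files are given)."""

    out_dir: str
    genes_path: str | None = None
    survival_path: str | None = None
    counts_path: str | None = None
    mutants_path: str | None = None
    observed_counts_path: str | None = None
    reference_environment: str = ENV_PHAGE
    models: tuple[str, ...] = ("model1", "model2")
    pseudo_count: int = 1
    n_boot: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)


def _validate_inputs(config: PipelineConfig) -> dict:
    """Parse every referenced file before any stage runs."""
    inputs: dict = {}
    inputs["genes"] = (
        io.read_gene_catalogue(config.genes_path) if config.genes_path else list(DEFAULT_GENES)
    )
    inputs["survival"] = (
        io.read_survival_table(config.survival_path)
        if config.survival_path
        else list(default_survival_entries())
    )
    inputs["experiments"] = (
        io.read_counts_table(config.counts_path) if config.counts_path else None
    )
    inputs["mutants"] = (
        io.read_mutant_table(config.mutants_path, inputs["genes"])
        if config.mutants_path
        else None
    )
    inputs["observed_counts"] = (
        io.read_observed_counts(config.observed_counts_path)
        if config.observed_counts_path
        else None
    )
    return inputs


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages with available inputs; returns the report bundle."""
    try:
        inputs = _validate_inputs(config)
    except (ValueError, KeyError, OSError) as exc:
        raise RuntimeError(f"[input-validation] {exc}") from exc
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    genes = inputs["genes"]
    survival = inputs["survival"]
    environments = sorted({e.environment_label for e in survival})

    # --- predictions (always possible) ---
    try:
        ref_w = model1_weights(genes, survival, config.reference_environment)
        predictions = {}
        for env in environments:
            w = model1_weights(genes, survival, env)
            rho = predicted_relative_rate(w, ref_w)
            predictions[env] = predicted_distributions(w, genes, relative_rate=rho)
        report["model1"] = predictions
        if inputs["observed_counts"] is not None and "model2" in config.models:
            ref2 = model2_weights(
                genes, inputs["observed_counts"], survival,
                config.reference_environment, pseudo_count=config.pseudo_count,
            )
            m2 = {}
            for env in environments:
                w = model2_weights(
                    genes, inputs["observed_counts"], survival, env,
                    pseudo_count=config.pseudo_count,
                )
                m2[env] = predicted_distributions(
                    w, genes, relative_rate=predicted_relative_rate(w, ref2)
                )
            report["model2"] = m2
    except (ValueError, KeyError) as exc:
        raise RuntimeError(f"[predict] {exc}") from exc

    # --- rate estimation ---
    if inputs["experiments"] is not None:
        try:
            estimates = [estimate_rate(e) for e in inputs["experiments"]]
            by_env = {e.environment_label: e for e in inputs["experiments"]}
            comparisons = []
            if config.reference_environment in by_env:
                ref = by_env[config.reference_environment]
                for exp in inputs["experiments"]:
                    if exp.environment_label == config.reference_environment:
                        continue
                    comparisons.append(compare_rates(exp, ref))
            report["estimates"] = estimates
            report["comparisons"] = comparisons
            io.write_rates_json(estimates, comparisons, out / "rates.json")
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"[estimate] {exc}") from exc
    else:
        log.info("no counts table configured; estimation stage skipped")

    # --- spectra ---
    if inputs["mutants"] is not None:
        try:
            spectra = {}
            candidate = [g.name for g in genes]
            envs = sorted({m.environment_label for m in inputs["mutants"]})
            for env in envs:
                spec = spectrum(inputs["mutants"], env, genes)
                spec = bootstrap_spectrum(
                    spec, candidate, genes,
                    n_boot=config.n_boot, pseudo_count=config.pseudo_count,
                    seed=config.seed,
                )
                entry: dict = {"spectrum": spec}
                if env in report["model1"]:
                    try:
                        stat, p = gof_chisq(spec, report["model1"][env], "lps_type", genes)
                        entry["gof_lps_type_model1"] = {"statistic": stat, "p_value": p}
                    except ValueError as exc:
                        entry["gof_lps_type_model1"] = {"error": str(exc)}
                spectra[env] = entry
            report["spectra"] = spectra
            io.write_json(spectra, out / "spectra.json")
        except (ValueError, KeyError) as exc:
            raise RuntimeError(f"[spectrum] {exc}") from exc
    else:
        log.info("no mutant table configured; spectrum stage skipped")

    io.write_json(report.get("model1", {}), out / "predictions_model1.json")
    if "model2" in report:
        io.write_json(report["model2"], out / "predictions_model2.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
    }
    io.write_json(manifest, out / "manifest.json")
    report["manifest"] = manifest
    return report
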