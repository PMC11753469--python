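"""Causal-gene classification, bootstrap SDs and goodness of fit."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phagetarget.catalogue import DEFAULT_GENES
from phagetarget.spectra import (
    MutantSpectrum,
    assign_causal_gene,
    bootstrap_spectrum,
    gof_chisq,
    make_mutant_record,
    spectrum,
)
from phagetarget.target_models import (
    model1_weights,
    predicted_distributions,
)
from phagetarget.catalogue import default_survival_entries


class TestCausalAssignment:
    def test_deep_rough_beats_rough(self, genes):
        assert assign_causal_gene(["galE", "hldE"], genes) == "hldE"

    def test_single_mutation(self, genes):
        assert assign_causal_gene(["waaO"], genes) == "waaO"

    def test_within_class_tie_broken_by_catalogue_order(self, genes):
        assert assign_causal_gene(["waaT", "waaW"], genes) == "waaW"
        assert assign_causal_gene(["waaW", "waaT"], genes) == "waaW"

    def test_regulatory_beats_rough_but_not_deep_rough(self, genes):
        assert assign_causal_gene(["rfaH", "galE"], genes) == "rfaH"
        assert assign_causal_gene(["rfaH", "waaC"], genes) == "waaC"

    def test_uncatalogued_isolate_falls_back_to_first_gene(self, genes):
        assert assign_causal_gene(["mysteryA", "mysteryB"], genes) == "mysteryA"

    @given(perm=st.permutations(["galE", "hldE", "waaP", "yajC"]))
    def test_permutation_invariance(self, perm):
        assert assign_causal_gene(perm, list(DEFAULT_GENES)) == "waaP"


class TestSpectrum:
    def test_counts_and_proportions_zero_filled(self, genes):
        recs = [
            make_mutant_record("i1", "phage", ["waaC"], genes),
            make_mutant_record("i2", "phage", ["waaC"], genes),
        ]
        spec = spectrum(recs, "phage", genes)
        assert spec.counts["waaC"] == 2
        assert spec.proportions["waaC"] == 1.0
        assert sum(spec.proportions.values()) == pytest.approx(1.0)
        assert spec.counts["galE"] == 0

    def test_unknown_environment_rejected(self, genes):
        recs = [make_mutant_record("i1", "phage", ["waaC"], genes)]
        with pytest.raises(KeyError):
            spectrum(recs, "mars", genes)


class TestBootstrap:
    def test_single_gene_pool_has_zero_sd(self, genes):
        spec = MutantSpectrum("phage", {"waaC": 4})
        out = bootstrap_spectrum(spec, [], genes, n_boot=50, pseudo_count=0, seed=1)
        assert out.bootstrap_sd_gene["waaC"] == 0.0

    def test_two_isolate_enumeration_oracle(self, genes):
        """Pool of 2 isolates in 2 genes: SD -> sqrt(p(1-p)/2) = 0.3536."""
        spec = MutantSpectrum("phage", {"waaC": 1, "galE": 1})
        out = bootstrap_spectrum(spec, [], genes, n_boot=20_000, pseudo_count=0, seed=3)
        assert out.bootstrap_sd_gene["waaC"] == pytest.approx(
            math.sqrt(0.125), abs=0.01
        )

    def test_pseudo_counts_enter_the_pool(self, genes):
        spec = MutantSpectrum("phage", {"waaC": 0, "galE": 0})
        out = bootstrap_spectrum(
            spec, ["waaC", "galE"], genes, n_boot=100, pseudo_count=1, seed=0
        )
        assert out.bootstrap_sd_gene["waaC"] > 0.0

    def test_empty_pool_rejected(self, genes):
        spec = MutantSpectrum("phage", {"waaC": 0})
        with pytest.raises(ValueError):
            bootstrap_spectrum(spec, [], genes, pseudo_count=0)

    def test_fixed_seed_reproducible(self, genes):
        spec = MutantSpectrum("phage", {"waaC": 3, "galE": 2, "hldE": 7})
        a = bootstrap_spectrum(spec, ["waaP"], genes, n_boot=100, seed=42)
        b = bootstrap_spectrum(spec, ["waaP"], genes, n_boot=100, seed=42)
        assert a.bootstrap_sd_gene == b.bootstrap_sd_gene
        assert a.bootstrap_sd_class == b.bootstrap_sd_class

    def test_sd_scales_as_inverse_sqrt_pool_size(self, genes):
        sds = []
        for pool in (10, 40, 160):
            spec = MutantSpectrum("phage", {"waaC": pool // 2, "galE": pool // 2})
            out = bootstrap_spectrum(spec, [], genes, n_boot=4000, pseudo_count=0, seed=7)
            sds.append(out.bootstrap_sd_gene["waaC"])
        assert sds[0] / sds[1] == pytest.approx(2.0, rel=0.15)
        assert sds[1] / sds[2] == pytest.approx(2.0, rel=0.15)


class TestGof:
    def test_exact_match_gives_zero_statistic(self, genes, survival):
        pred = predicted_distributions(model1_weights(genes, survival, "phage"), genes)
        n = 11736
        counts = {g: round(p * n) for g, p in pred.gene_proportions.items()}
        spec = MutantSpectrum("phage", counts)
        stat, p = gof_chisq(spec, pred, "gene_wise")
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_two_category_toy_matches_pearson_closed_form(self):
        # observed (8, 2) against equal expectations: chi2 = 3.6
        from phagetarget.catalogue import GeneRecord, SurvivalEntry

        pair = [GeneRecord("gA", 500, "rough"), GeneRecord("gB", 500, "deep_rough")]
        psurv = [SurvivalEntry("gA", "env", 1, 1), SurvivalEntry("gB", "env", 1, 1)]
        pred = predicted_distributions(model1_weights(pair, psurv, "env"), pair)
        spec = MutantSpectrum("env", {"gA": 8, "gB": 2})
        stat, p = gof_chisq(spec, pred, "gene_wise")
        assert stat == pytest.approx(3.6, abs=1e-10)
        assert p == pytest.approx(0.0578, abs=1e-4)

    def test_zero_expectation_demands_added_genes(self, genes, survival):
        pred = predicted_distributions(model1_weights(genes, survival, "phage_CL2"), genes)
        spec = MutantSpectrum("phage_CL2", {"waaC": 1, "galE": 5})  # waaC expected 0
        with pytest.raises(ValueError, match="added-genes"):
            gof_chisq(spec, pred, "gene_wise")

    def test_lps_type_mode_aggregates_classes(self, genes, survival):
        pred = predicted_distributions(model1_weights(genes, survival, "phage"), genes)
        spec = MutantSpectrum("phage", {"waaC": 42, "galE": 6, "rfaH": 2})
        stat, p = gof_chisq(spec, pred, "lps_type", genes)
        # independent Pearson computation over the three classes
        n = 50
        exp = {
            "rough": 4389 / 11736 * n,
            "deep_rough": 6858 / 11736 * n,
            "regulatory": 489 / 11736 * n,
            "non_lps": 0.0,
        }
        obs = {"rough": 6, "deep_rough": 42, "regulatory": 2, "non_lps": 0}
        ref = sum(
            (obs[c] - exp[c]) ** 2 / exp[c] for c in ("rough", "deep_rough", "regulatory")
        )
        assert stat == pytest.approx(ref, rel=1e-10)
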