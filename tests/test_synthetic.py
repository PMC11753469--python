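"""Generative simulator: distributional agreement with the analytic model."""

import math

import numpy as np
import pytest
from scipy import stats

from phagetarget.catalogue import DEFAULT_GENES, default_survival_entries
from phagetarget.fluctuation import lc_pmf
from phagetarget.synthetic import (
    SimulationConfig,
    plate_culture,
    sample_clone_sizes,
    simulate_counts,
    simulate_culture,
    simulate_fluctuation_experiment,
)
from phagetarget.target_models import model1_weights


def _gof_vs_pmf(counts: np.ndarray, m: float, epsilon: float, k_cap: int = 25) -> float:
    n = len(counts)
    obs = np.bincount(np.minimum(counts, k_cap), minlength=k_cap + 1)
    p = lc_pmf(m, epsilon, k_cap)
    expected = np.append(p[:k_cap], 1.0 - p[:k_cap].sum()) * n
    mask = expected >= 5.0
    expected = expected[mask] * obs[mask].sum() / expected[mask].sum()
    return stats.chisquare(obs[mask], expected).pvalue


class TestCulture:
    def test_zero_rate_never_mutates(self):
        for seed in range(5):
            assert simulate_culture(0.0, 1e8, seed).size == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_culture(-1e-9, 1e8, 0)

    def test_zero_class_probability_matches_poisson_closed_form(self, rng):
        mu, nt, n = 1e-8, float(2**27), 100_000
        m = mu * (nt - 1.0)
        n_mut = rng.poisson(m, n)
        frac_zero = np.mean(n_mut == 0)
        se = math.sqrt(math.exp(-m) * (1 - math.exp(-m)) / n)
        assert abs(frac_zero - math.exp(-m)) <= 3 * se

    def test_clone_size_law_matches_one_over_k_k_plus_one(self, rng):
        sizes = sample_clone_sizes(rng, 200_000, 1e9)
        for k in (1, 2, 5):
            p_k = np.mean(sizes == k)
            expected = 1.0 / (k * (k + 1.0))
            assert p_k == pytest.approx(expected, rel=0.05)


class TestPlating:
    def test_full_plating_full_survival_returns_all_cells(self, genes, survival):
        w = model1_weights(genes, survival, "phage")
        count, labels = plate_culture([4, 7, 1], 1.0, w, survival, seed=0, environment="phage")
        assert count == 12
        assert len(labels) == 12

    def test_zero_survival_yields_zero_colonies(self, genes):
        from phagetarget.catalogue import SurvivalEntry

        dead = [SurvivalEntry(g.name, "dead", 0, 1) for g in genes]
        w = model1_weights(genes, dead, "dead")
        # weights are all zero -> gene assignment impossible
        with pytest.raises(ValueError):
            plate_culture([5], 1.0, w, dead, seed=0, environment="dead")

    def test_zero_survival_with_positive_weights(self, genes, survival):
        from phagetarget.catalogue import SurvivalEntry

        w = model1_weights(genes, survival, "phage")
        dead = [SurvivalEntry(g.name, "phage", 0, 1) for g in genes]
        count, labels = plate_culture([5, 9], 1.0, w, dead, seed=0, environment="phage")
        assert count == 0 and labels == []

    def test_gene_label_frequencies_match_weights(self, genes, survival, rng):
        w = model1_weights(genes, survival, "phage")
        labels: list[str] = []
        while len(labels) < 10_000:
            _, lab = plate_culture([1] * 500, 1.0, w, survival, rng, environment="phage")
            labels.extend(lab)
        obs = np.array([labels.count(g.name) for g in genes], dtype=float)
        probs = np.array([w.weights[g.name] for g in genes]) / w.total_weight
        p = stats.chisquare(obs, probs * obs.sum()).pvalue
        assert p > 0.001


class TestExperiment:
    @pytest.mark.parametrize("m,epsilon", [(0.5, 1.0), (1.0, 0.5), (2.0, 0.2)])
    def test_counts_match_lea_coulson_pmf(self, m, epsilon, rng):
        counts = simulate_counts(m / (1e8 - 1), 1e8, epsilon, 100_000, rng)
        assert _gof_vs_pmf(counts, m, epsilon) > 0.01

    def test_seed_reproducibility(self):
        config = SimulationConfig(n_cultures=20, seed=99)
        a = simulate_fluctuation_experiment(config)
        b = simulate_fluctuation_experiment(config)
        assert a.experiment == b.experiment
        assert a.mutant_records == b.mutant_records

    def test_default_design_regime_counts_mostly_countable(self):
        sim = simulate_fluctuation_experiment(SimulationConfig(seed=1))
        counts = np.array(sim.experiment.counts)
        assert np.mean(counts < 100) > 0.9
        assert counts.max() >= 1

    def test_spectrum_recovery_weights_times_survival(self, genes, survival, rng):
        """Observed gene shares converge to weight*survival renormalised.

        A small culture size caps the clone-size distribution, whose heavy
        tail otherwise makes colony-weighted gene shares converge very slowly.
        """
        w = model1_weights(genes, survival, "phage")
        config = SimulationConfig(
            mu_per_division=1.0 / 63.0,
            n_final_cells=64,
            n_cultures=30_000,
            gene_weights=w,
            survival_fractions=tuple(
                e for e in survival if e.environment_label == "phage_CL2"
            ),
            environment_label="phage_CL2",
            seed=7,
        )
        sim = simulate_fluctuation_experiment(config)
        labels = [r.causal_gene for r in sim.mutant_records]
        target = {
            g.name: w.weights[g.name]
            * {e.gene: e.fraction for e in survival if e.environment_label == "phage_CL2"}[
                g.name
            ]
            for g in genes
        }
        total = sum(target.values())
        obs_galE = labels.count("galE") / len(labels)
        assert obs_galE == pytest.approx(target["galE"] / total, abs=0.03)
        assert labels.count("waaC") == 0  # survival 0


class TestPlateTables:
    def test_noise_free_tables_recover_mic_exactly(self):
        from phagetarget.susceptibility import growth_calls, mic
        from phagetarget.synthetic import simulate_plate_growth_table

        truth = {f"s{i}": float(c) for i, c in enumerate([1, 2, 3, 4], 1)}
        recs = simulate_plate_growth_table(truth, [1.0, 2.0, 3.0, 4.0], noise_sd=0.0, seed=0)
        calls = growth_calls(recs, 8.0)
        for strain, true_mic in truth.items():
            series = sorted(
                (c for c in calls if c.strain == strain), key=lambda c: c.concentration
            )
            assert mic(series).mic_ug_per_ml == true_mic

    def test_values_within_8bit_range(self):
        from phagetarget.synthetic import simulate_plate_growth_table

        recs = simulate_plate_growth_table({"s": 2.0}, [1.0, 2.0], noise_sd=50.0, seed=3)
        assert all(0.0 <= r.mean_greyscale <= 255.0 for r in recs)

    def test_mic_recovery_under_noise_across_seeds(self):
        from phagetarget.susceptibility import growth_calls, mic
        from phagetarget.synthetic import simulate_plate_growth_table

        truth = {f"s{i}": float(1 + i % 4) for i in range(20)}
        concs = [1.0, 2.0, 3.0, 4.0]
        failures = 0
        for seed in range(50):
            recs = simulate_plate_growth_table(truth, concs, noise_sd=2.0, seed=seed)
            calls = growth_calls(recs, 8.0)
            for strain, true_mic in truth.items():
                series = sorted(
                    (c for c in calls if c.strain == strain),
                    key=lambda c: c.concentration,
                )
                got = mic(series).mic_ug_per_ml
                expected = 1.0 if true_mic == 1.0 else true_mic
                failures += got != expected
        assert failures == 0
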