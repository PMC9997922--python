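"""Diversity metrics, genetic distance (with an external oracle), IBD, migration."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hexevo import metrics
from hexevo.genome import default_locus_table, sample_genotypes
from hexevo.hexgrid import BarrierMode, EpochName, EpochSpec
from hexevo import engine

from conftest import small_config


def geno(rows):
    """Build an (n, 10, 2) genotype array from per-individual locus pair lists."""
    return np.asarray(rows, dtype=np.int8)


def uniform_genotypes(n, pair):
    return np.tile(np.asarray(pair, dtype=np.int8), (n, 10, 1))


class TestHomozygosityAndFrequencies:
    def test_homozygosity_extremes_and_mean(self):
        assert metrics.per_capita_homozygosity(uniform_genotypes(5, [1, 1])) == 1.0
        assert metrics.per_capita_homozygosity(uniform_genotypes(5, [1, 2])) == 0.0
        g = np.concatenate(
            [uniform_genotypes(1, [1, 1])[:, :4], uniform_genotypes(1, [1, 2])[:, :6]],
            axis=1,
        )
        h = np.concatenate(
            [uniform_genotypes(1, [1, 1])[:, :6], uniform_genotypes(1, [1, 2])[:, :4]],
            axis=1,
        )
        assert metrics.per_capita_homozygosity(np.concatenate([g, h])) == 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            metrics.per_capita_homozygosity(np.empty((0, 10, 2), dtype=np.int8))

    def test_allele_frequencies(self):
        assert np.array_equal(
            metrics.allele_frequencies(uniform_genotypes(4, [1, 1]), 1),
            [1, 0, 0, 0, 0],
        )
        assert np.array_equal(
            metrics.allele_frequencies(uniform_genotypes(1, [1, 2]), 1),
            [0.5, 0.5, 0, 0, 0],
        )

    def test_richness(self):
        assert metrics.allelic_richness(uniform_genotypes(3, [1, 1]), 1) == 1
        g = np.concatenate(
            [uniform_genotypes(2, [1, 2]), uniform_genotypes(1, [3, 3])]
        )
        assert metrics.allelic_richness(g, 1) == 3

    def test_initial_population_richness_is_five(self):
        g = sample_genotypes(default_locus_table(), 3000, np.random.default_rng(0))
        assert all(metrics.allelic_richness(g, l) == 5 for l in range(1, 11))


class TestEvenness:
    def test_uniform_profile_is_one(self):
        assert metrics.allelic_evenness([0.2] * 5) == pytest.approx(1.0)

    def test_unequal_profile(self):
        e = metrics.allelic_evenness([0.30, 0.25, 0.20, 0.15, 0.10])
        assert round(e, 2) == 0.96

    def test_rare_profile_matches_entropy_oracle(self):
        p = np.array([0.01, 0.04, 0.15, 0.30, 0.50])
        oracle = stats.entropy(p) / np.log(5)
        e = metrics.allelic_evenness(p)
        assert e == pytest.approx(oracle, abs=1e-12)
        assert e == pytest.approx(0.7252, abs=5e-4)

    def test_fixed_allele_is_zero(self):
        assert metrics.allelic_evenness([1, 0, 0, 0, 0]) == 0.0

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            metrics.allelic_evenness([0.5, 0.5, 0.5, 0, 0])

    def test_bounds_and_uniqueness_of_extremes(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.dirichlet(np.ones(5))
            e = metrics.allelic_evenness(p)
            assert 0.0 <= e <= 1.0 + 1e-12


class TestHeterozygosityDeficit:
    def test_single_extant_allele_zero(self):
        assert metrics.heterozygosity_deficit(uniform_genotypes(5, [1, 1]), 1) == 0.0

    def test_all_homozygous_two_alleles(self):
        g = np.concatenate(
            [uniform_genotypes(5, [1, 1]), uniform_genotypes(5, [2, 2])]
        )
        assert metrics.heterozygosity_deficit(g, 1) == pytest.approx(-0.5)

    def test_hwe_sample_near_zero(self):
        """Genotypes drawn at Hardy-Weinberg proportions: deficit ~ 0."""
        rng = np.random.default_rng(2)
        p = np.array([0.30, 0.25, 0.20, 0.15, 0.10])
        n = 10_000
        g = np.sort(rng.choice(5, size=(n, 10, 2), p=p) + 1, axis=2).astype(np.int8)
        d = metrics.heterozygosity_deficit(g, 1)
        assert abs(d) < 0.02


class TestGeneticDistance:
    def test_identical_and_fully_different(self):
        a = uniform_genotypes(2, [1, 1])
        assert metrics.pairwise_genetic_distance(a)[0, 1] == 0.0
        b = np.concatenate([uniform_genotypes(1, [1, 1]), uniform_genotypes(1, [2, 2])])
        assert metrics.pairwise_genetic_distance(b)[0, 1] == 1.0

    def test_partial_difference(self):
        x = uniform_genotypes(1, [1, 1])
        y = uniform_genotypes(1, [1, 1])
        y[0, :3] = [2, 2]
        assert metrics.pairwise_genetic_distance(np.concatenate([x, y]))[0, 1] == 0.3

    def test_phase_insensitive(self):
        x = np.tile(np.array([1, 2], dtype=np.int8), (1, 10, 1))
        y = np.tile(np.array([2, 1], dtype=np.int8), (1, 10, 1))
        assert metrics.pairwise_genetic_distance(np.concatenate([x, y]))[0, 1] == 0.0

    def test_matrix_symmetric_zero_diagonal(self):
        g = sample_genotypes(default_locus_table(), 20, np.random.default_rng(3))
        d = metrics.pairwise_genetic_distance(g)
        assert np.array_equal(d, d.T)
        assert (np.diag(d) == 0).all()
        assert ((d >= 0) & (d <= 1)).all()

    def test_matches_ape_dist_gene(self, tmp_path):
        """Independent oracle: ape::dist.gene with method='percentage' on
        canonical two-allele locus strings reproduces our matrix exactly."""
        g = sample_genotypes(default_locus_table(), 8, np.random.default_rng(4))
        df = pd.DataFrame(
            {
                f"L{l + 1}": [f"{g[i, l, 0]}{g[i, l, 1]}" for i in range(len(g))]
                for l in range(10)
            }
        )
        csv = tmp_path / "geno.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "dist.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(ape))
                g <- read.csv("{csv}", colClasses = "character")
                d <- dist.gene(g, method = "percentage")
                write.csv(as.matrix(d), "{tmp_path}/dist.csv")
                """
            )
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        oracle = pd.read_csv(tmp_path / "dist.csv", index_col=0).to_numpy()
        ours = metrics.pairwise_genetic_distance(g)
        assert np.allclose(ours, oracle, atol=1e-9)


class _FakeLog:
    """Minimal log stand-in for window-based metrics."""

    def __init__(self, births, breeding, patch_labels=(1, 2)):
        self._births = births
        self._breeding = breeding
        self.patch_labels = list(patch_labels)

    def births_df(self):
        return self._births

    def breeding_df(self):
        return self._breeding


class TestMigrationAndGenerationTime:
    def test_generation_time_trivial(self):
        births = pd.DataFrame({"step": [1, 2, 3], "mother_id": [1, 2, 3],
                               "mother_age": [2, 2, 2], "patch": [1, 1, 2]})
        log = _FakeLog(births, None)
        assert metrics.generation_time(log, (1, 3)) == 2.0
        with pytest.raises(ValueError):
            metrics.generation_time(log, (10, 20))

    def test_returning_gap_crosser_is_not_a_migrant(self):
        births = pd.DataFrame({"step": [5], "mother_id": [1], "mother_age": [4],
                               "patch": [1]})
        breeding = pd.DataFrame(
            {
                "step": [5, 5, 5],
                "individual_id": [1, 2, 3],
                "patch": [1, 1, 2],
                "natal_patch": [1, 1, 1],
                "crossed_gap": [0, 1, 1],
                "female": [1, 1, 0],
            }
        )
        ms = metrics.migration_summary(_FakeLog(births, breeding), (1, 10), gen_time=4.0)
        # only individual 3 crossed a gap AND bred away from its natal patch
        assert ms.n_migrants == 1
        assert ms.migrants_per_generation == pytest.approx(1 / (10 / 4.0))

    def test_non_crosser_breeding_elsewhere_not_counted(self):
        breeding = pd.DataFrame(
            {
                "step": [1],
                "individual_id": [9],
                "patch": [2],
                "natal_patch": [1],
                "crossed_gap": [0],
                "female": [1],
            }
        )
        ms = metrics.migration_summary(_FakeLog(None, breeding), (1, 5), gen_time=5.0)
        assert ms.n_migrants == 0

    def test_isolated_run_has_zero_migrants(self, small_isolated_log):
        ms = metrics.migration_summary(small_isolated_log, (11, 40))
        assert ms.n_migrants == 0
        assert ms.migrants_per_generation == 0.0

    def test_per_patch_rates_consistent(self, small_isolated_log):
        ms = metrics.migration_summary(small_isolated_log, (11, 40))
        pp = ms.per_patch
        assert ((pp.philopatric_fraction.dropna() >= 0)
                & (pp.philopatric_fraction.dropna() <= 1)).all()
        assert (pp.philopatric_fraction.dropna() + pp.emigration_rate.dropna() <= 1 + 1e-12).all()


class TestTrajectoriesAndSampling:
    def test_totals_partition_population(self, small_continuous_log):
        df = metrics.population_trajectories(small_continuous_log)
        total = df.groupby("step")["count"].sum()
        births = small_continuous_log.births_df().groupby("step").size()
        deaths = small_continuous_log.deaths_df().groupby("step").size()
        t = 30
        assert total.loc[t] == total.loc[t - 1] + births.get(t, 0) - deaths.get(t, 0)

    def test_stratified_sample_size_and_determinism(self):
        epochs = [EpochSpec(EpochName.CONTINUOUS, 1, 15)]
        cfg = small_config(epochs, horizon=15, snapshot_steps=(15,))
        log = engine.run_replicate(cfg, 5)
        s1, m1, miss1 = metrics.sample_for_distance_matrix(log, per_patch_n=5, rng=0)
        s2, m2, miss2 = metrics.sample_for_distance_matrix(log, per_patch_n=5, rng=0)
        assert len(s1["ids"]) == 5 * 6 and m1.shape == (30, 30)
        assert np.array_equal(s1["ids"], s2["ids"]) and miss1 == [] == miss2
        s3, m3, _ = metrics.sample_for_distance_matrix(log, per_patch_n=1, rng=1)
        assert m3.shape == (6, 6)


class TestIBD:
    def test_permuted_genotypes_give_flat_profile(self):
        rng = np.random.default_rng(6)
        coords = np.column_stack([rng.integers(0, 40, 400), rng.integers(0, 40, 400)])
        g = sample_genotypes(default_locus_table(), 400, rng)
        df = metrics.ibd_correlogram(coords, g, n_bins=8, rng=1)
        ok = df.dropna()
        slope = stats.linregress(
            (ok.bin_lo + ok.bin_hi) / 2, ok.mean_genetic_distance
        ).slope
        assert abs(slope) < 5e-4

    def test_spatial_genetic_gradient_detected(self):
        # genotype changes along a line: genetic distance grows with geography
        n = 120
        coords = np.column_stack([np.arange(n), np.zeros(n, dtype=int)])
        g = np.ones((n, 10, 2), dtype=np.int8)
        g[n // 3 : 2 * n // 3, :5] = 2
        g[2 * n // 3 :, :] = 3
        df = metrics.ibd_correlogram(coords, g, n_bins=6)
        ok = df.dropna()
        slope = stats.linregress(
            (ok.bin_lo + ok.bin_hi) / 2, ok.mean_genetic_distance
        ).slope
        assert slope > 0
        assert (df.n_pairs.sum()) == n * (n - 1) // 2
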