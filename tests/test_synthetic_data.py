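import math

import numpy as np
import pytest

from popdiv import diversity
from popdiv.synthetic_data import (
    SimConfig,
    inject_missingness,
    plant_sweeps,
    sample_genotypes,
    simulate_frequencies,
    simulate_ld_haplotypes,
    write_fixture,
)
from popdiv.variant_io import MISSING, read_vcf


def _pools(truth):
    w = [s for s, l in zip(truth.sample_ids, truth.labels) if l == "weedy"]
    c = [s for s, l in zip(truth.sample_ids, truth.labels) if l == "cultivated"]
    return w, c


class TestSimConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(f_weedy=0.0)
        with pytest.raises(ValueError):
            SimConfig(n_weedy=0)
        with pytest.raises(ValueError):
            SimConfig(n_feral=2, feral_alphas=[0.5])
        with pytest.raises(ValueError):
            SimConfig(missing_max=1.5)


class TestSimulateFrequencies:
    def test_small_f_concentrates_at_ancestral(self):
        cfg = SimConfig(f_weedy=0.001, f_cultivated=0.001, n_variant_sites=2000, seed=0)
        sim = simulate_frequencies(cfg)
        for pool in sim.pool_freqs.values():
            assert np.max(np.abs(pool - sim.p_ancestral)) < 0.2
            assert np.mean(np.abs(pool - sim.p_ancestral)) < 0.02

    def test_symmetric_mean_at_half(self):
        cfg = SimConfig(f_weedy=0.5, f_cultivated=0.5, n_variant_sites=20000, seed=1)
        sim = simulate_frequencies(cfg)
        near_half = np.abs(sim.p_ancestral - 0.5) < 0.05
        assert abs(sim.pool_freqs["weedy"][near_half].mean() - 0.5) < 0.03

    def test_positions_sorted_within_chrom(self):
        cfg = SimConfig(
            chrom_lengths={"chr1": 100_000, "chr2": 50_000},
            n_variant_sites=500,
            seed=2,
        )
        sim = simulate_frequencies(cfg)
        for c in ("chr1", "chr2"):
            p = sim.pos[sim.chrom == c]
            assert np.all(np.diff(p) > 0)

    @pytest.mark.parametrize("f", [0.1, 0.3])
    def test_hudson_fst_recovers_f(self, f):
        # estimator on the simulation: per spec, 5 seeds, 20k sites, 50/pool
        errs = []
        for seed in range(5):
            cfg = SimConfig(
                n_weedy=50,
                n_cultivated=50,
                n_variant_sites=20_000,
                f_weedy=f,
                f_cultivated=f,
                seed=seed,
            )
            m, truth = sample_genotypes(simulate_frequencies(cfg), cfg)
            w, c = _pools(truth)
            errs.append(abs(diversity.fst_pair(m, w, c).fst - f))
        assert max(errs) < 0.03


class TestPlantSweeps:
    def test_full_fixation_floor(self):
        cfg = SimConfig(
            n_variant_sites=2000,
            sweep_intervals=[("chr1", 100_000, 300_000)],
            sweep_floor=1.0,
            seed=3,
        )
        sim = plant_sweeps(simulate_frequencies(cfg), cfg)
        inside = (sim.pos - 1 >= 100_000) & (sim.pos - 1 < 300_000)
        pc = sim.pool_freqs["cultivated"]
        assert np.all((pc[inside] == 0.0) | (pc[inside] == 1.0))
        m, truth = sample_genotypes(sim, cfg)
        w, c = _pools(truth)
        assert diversity.pi_over_region(m, c, ("chr1", 100_000, 300_000)) == 0.0

    def test_no_intervals_is_identity(self):
        cfg = SimConfig(n_variant_sites=500, seed=4)
        sim = simulate_frequencies(cfg)
        out = plant_sweeps(sim, cfg)
        assert np.array_equal(out.pool_freqs["cultivated"], sim.pool_freqs["cultivated"])

    def test_weedy_untouched(self):
        cfg = SimConfig(
            n_variant_sites=500,
            sweep_intervals=[("chr1", 0, 500_000)],
            seed=5,
        )
        sim = simulate_frequencies(cfg)
        out = plant_sweeps(sim, cfg)
        assert np.array_equal(out.pool_freqs["weedy"], sim.pool_freqs["weedy"])

    def test_pi_c_lower_inside_sweeps(self):
        cfg = SimConfig(
            n_variant_sites=4000,
            sweep_intervals=[("chr1", 200_000, 400_000)],
            sweep_floor=0.98,
            seed=6,
        )
        sim = plant_sweeps(simulate_frequencies(cfg), cfg)
        m, truth = sample_genotypes(sim, cfg)
        _, c = _pools(truth)
        pi_in = diversity.pi_over_region(m, c, ("chr1", 200_000, 400_000))
        pi_out = diversity.pi_over_region(m, c, ("chr1", 500_000, 1_000_000))
        assert pi_in < pi_out

    def test_interval_outside_genome_rejected(self):
        cfg = SimConfig(n_variant_sites=100, seed=0)
        cfg.sweep_intervals = [("chr1", 0, 2_000_000)]
        with pytest.raises(ValueError, match="outside genome"):
            plant_sweeps(simulate_frequencies(cfg), cfg)


class TestSampleGenotypes:
    def test_alpha_one_feral_matches_cultivated_distribution(self):
        cfg = SimConfig(
            n_weedy=5,
            n_cultivated=60,
            n_feral=60,
            feral_alphas=[1.0] * 60,
            n_variant_sites=3000,
            f_weedy=0.1,
            f_cultivated=0.3,
            seed=7,
        )
        sim = simulate_frequencies(cfg)
        m, truth = sample_genotypes(sim, cfg)
        c_idx = [i for i, l in enumerate(truth.labels) if l == "cultivated"]
        f_idx = [i for i, l in enumerate(truth.labels) if l == "feral"]
        mean_c = m.dosages[c_idx].mean(axis=0)
        mean_f = m.dosages[f_idx].mean(axis=0)
        # same expectation 2*p_c at every site
        assert np.corrcoef(mean_c, mean_f)[0, 1] > 0.95
        assert abs(mean_c.mean() - mean_f.mean()) < 0.02

    def test_alpha_half_feral_mean_midway(self):
        cfg = SimConfig(
            n_weedy=5,
            n_cultivated=5,
            n_feral=200,
            feral_alphas=[0.5] * 200,
            n_variant_sites=2000,
            f_weedy=0.1,
            f_cultivated=0.3,
            seed=8,
        )
        sim = simulate_frequencies(cfg)
        m, truth = sample_genotypes(sim, cfg)
        f_idx = [i for i, l in enumerate(truth.labels) if l == "feral"]
        expected = sim.pool_freqs["weedy"] + sim.pool_freqs["cultivated"]  # 2 * mid
        got = m.dosages[f_idx].mean(axis=0)
        assert abs((got - expected).mean()) < 0.01

    def test_true_q_rows(self):
        cfg = SimConfig(
            n_weedy=2, n_cultivated=2, n_feral=1, feral_alphas=[0.3],
            n_variant_sites=50, seed=9,
        )
        _, truth = sample_genotypes(simulate_frequencies(cfg), cfg)
        assert truth.q_true.tolist() == [
            [0.0, 1.0],
            [0.0, 1.0],
            [1.0, 0.0],
            [1.0, 0.0],
            [0.3, 0.7],
        ]

    def test_determinism(self):
        cfg = SimConfig(n_variant_sites=300, n_invariant_sites=100, seed=10)
        m1, _ = sample_genotypes(simulate_frequencies(cfg), cfg)
        m2, _ = sample_genotypes(simulate_frequencies(cfg), cfg)
        assert np.array_equal(m1.dosages, m2.dosages)
        assert np.array_equal(m1.pos, m2.pos)

    def test_invariant_sites_appended_as_zero(self):
        cfg = SimConfig(n_variant_sites=200, n_invariant_sites=150, seed=11)
        m, _ = sample_genotypes(simulate_frequencies(cfg), cfg)
        assert (~m.is_variant).sum() == 150
        assert np.all(m.dosages[:, ~m.is_variant] == 0)
        # merged coordinates still sorted
        assert np.all(np.diff(m.pos[m.chrom == "chr1"]) > 0)

    def test_bottleneck_direction(self):
        # pi_cultivated < pi_weedy whenever F_cult > F_weedy, 5 seeds
        for seed in range(5):
            cfg = SimConfig(
                n_variant_sites=20_000,
                f_weedy=0.05,
                f_cultivated=0.3,
                seed=seed,
            )
            m, truth = sample_genotypes(simulate_frequencies(cfg), cfg)
            w, c = _pools(truth)
            assert diversity.pi_over_region(m, c) < diversity.pi_over_region(m, w)


class TestLdHaplotypes:
    def test_zero_switch_rate_copies_founders(self):
        cfg = SimConfig(
            n_weedy=2,
            n_cultivated=10,
            n_variant_sites=300,
            founder_count=4,
            switch_rate=0.0,
            seed=12,
        )
        m, _ = simulate_ld_haplotypes(cfg)
        from popdiv.ld_decay import genotype_r2

        # with whole-founder haplotypes LD stays high at long range
        r2s = []
        rng = np.random.default_rng(0)
        cols = rng.choice(m.n_sites - 1, 100, replace=False)
        for j in cols:
            r2 = genotype_r2(m.dosages[2:, j], m.dosages[2:, j + 1])
            if not math.isnan(r2):
                r2s.append(r2)
        assert np.mean(r2s) > 0.3

    def test_high_switch_rate_decorrelates(self):
        cfg = SimConfig(
            n_weedy=2,
            n_cultivated=10,
            n_variant_sites=300,
            founder_count=4,
            switch_rate=1e-2,
            seed=13,
        )
        m, _ = simulate_ld_haplotypes(cfg)
        from popdiv.ld_decay import ld_decay_curve

        pool = m.sample_ids[2:]
        curve = ld_decay_curve(m, samples=pool, max_dist=200_000, bin_width=50_000)
        far = curve.mean_r2[-2:][curve.pair_count[-2:] > 0]
        assert np.nanmean(far) < 0.2

    def test_founder_count_validation(self):
        with pytest.raises(ValueError):
            simulate_ld_haplotypes(SimConfig(founder_count=1))


class TestInjectMissingness:
    def test_zero_max_identity(self):
        cfg = SimConfig(n_variant_sites=100, missing_max=0.0, seed=14)
        m, _ = sample_genotypes(simulate_frequencies(cfg), cfg)
        assert inject_missingness(m, cfg) is m

    def test_overall_fraction_near_half_of_max(self):
        cfg = SimConfig(
            n_weedy=30, n_cultivated=30, n_variant_sites=5000,
            missing_max=1.0, seed=15,
        )
        m, _ = sample_genotypes(simulate_frequencies(cfg), cfg)
        out = inject_missingness(m, cfg)
        frac = (out.dosages == MISSING).mean()
        assert abs(frac - 0.5) < 0.02  # mean of U(0,1)

    def test_surviving_calls_unaltered(self):
        cfg = SimConfig(n_variant_sites=500, missing_max=0.6, seed=16)
        m, _ = sample_genotypes(simulate_frequencies(cfg), cfg)
        out = inject_missingness(m, cfg)
        survived = out.dosages != MISSING
        assert np.array_equal(out.dosages[survived], m.dosages[survived])

    def test_seed_reproducible(self):
        cfg = SimConfig(n_variant_sites=500, missing_max=0.5, seed=17)
        m, _ = sample_genotypes(simulate_frequencies(cfg), cfg)
        o1 = inject_missingness(m, cfg)
        o2 = inject_missingness(m, cfg)
        assert np.array_equal(o1.dosages, o2.dosages)


class TestWriteFixture:
    def test_round_trip_and_truth_files(self, tmp_path):
        cfg = SimConfig(
            n_weedy=4,
            n_cultivated=4,
            n_feral=2,
            feral_alphas=[0.5, 0.9],
            n_variant_sites=200,
            n_invariant_sites=50,
            sweep_intervals=[("chr1", 100_000, 200_000), ("chr1", 500_000, 600_000)],
            missing_max=0.3,
            seed=18,
        )
        sim = plant_sweeps(simulate_frequencies(cfg), cfg)
        m, truth = sample_genotypes(sim, cfg)
        m = inject_missingness(m, cfg)
        paths = write_fixture(m, truth, tmp_path / "fix", cfg)
        m2 = read_vcf(paths["vcf"])
        assert np.array_equal(m.dosages, m2.dosages)
        assert np.array_equal(m.is_variant, m2.is_variant)
        bed_lines = [
            l for l in paths["sweeps_bed"].read_text().splitlines() if l.strip()
        ]
        assert len(bed_lines) == 2
        pop_lines = paths["populations"].read_text().splitlines()
        assert len(pop_lines) == 1 + 10

    def test_same_seed_byte_identical_vcf(self, tmp_path):
        cfg = SimConfig(n_variant_sites=150, missing_max=0.2, seed=19)

        def render(sub):
            m, truth = sample_genotypes(simulate_frequencies(cfg), cfg)
            m = inject_missingness(m, cfg)
            paths = write_fixture(m, truth, tmp_path / sub, cfg)
            return paths["vcf"].read_text()

        assert render("a") == render("b")
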