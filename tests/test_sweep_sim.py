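"""Wright–Fisher simulator: determinism, neutral expectations, sweep
conditioning, and VCF emission."""

import numpy as np
import pytest

from sweepscan.containers import PoolSpec
from sweepscan.sweep_sim import (
    SweepNotAchievedError,
    SweepSimParams,
    TwoPopParams,
    emit_vcf,
    simulate,
)
from sweepscan.vcf_ingest import polarize, read_phased_region

SMALL = dict(pop_size_haploid=50, region_bp=100_000, mu=3e-6, rho=3e-6,
             sample_haplotypes=16, burn_in_generations=300)


class TestDeterminism:
    def test_same_seed_identical_outputs(self, tmp_path):
        runs = []
        for _ in range(2):
            mat, sites, truth = simulate(SweepSimParams(seed=99, **SMALL))
            path = tmp_path / f"run{len(runs)}.vcf"
            emit_vcf(mat, sites, truth, str(path))
            runs.append((mat, path.read_bytes()))
        np.testing.assert_array_equal(runs[0][0].entries, runs[1][0].entries)
        assert runs[0][1] == runs[1][1]  # byte-identical VCFs

    def test_different_seeds_differ(self):
        a, _, _ = simulate(SweepSimParams(seed=1, **SMALL))
        b, _, _ = simulate(SweepSimParams(seed=2, **SMALL))
        assert a.n_sites != b.n_sites or not np.array_equal(a.entries, b.entries)


class TestNeutralExpectations:
    def test_zero_mutation_rate_gives_no_sites(self):
        mat, sites, _ = simulate(SweepSimParams(
            pop_size_haploid=40, region_bp=10_000, mu=0.0, rho=1e-6,
            sample_haplotypes=10, seed=3, burn_in_generations=100))
        assert mat.n_sites == 0 and len(sites) == 0

    def test_drift_is_a_martingale(self):
        # standing variant at f0 = 0.3, no mutation: the mean final population
        # frequency across replicates stays at 0.3 (absorbed runs count 0/1)
        finals = []
        for seed in range(2000):
            params = SweepSimParams(
                pop_size_haploid=50, region_bp=1_000, mu=0.0, rho=0.0,
                sample_haplotypes=2, seed=seed, burn_in_generations=50,
                standing_variants=[(500, 0.3)])
            _, _, truth = simulate(params)
            finals.append(truth.standing_final_freqs[0])
        # MC standard error ~ 0.36/sqrt(2000) ~ 0.008
        assert np.mean(finals) == pytest.approx(0.3, abs=0.03)

    def test_site_frequency_spectrum_follows_one_over_i(self):
        # aggregate folded-unfolded SFS over replicates; neutral expectation
        # for a sample of n is xi_i proportional to 1/i
        n = 8
        counts = np.zeros(n - 1)
        for seed in range(80):
            params = SweepSimParams(
                pop_size_haploid=40, region_bp=50_000, mu=1e-5, rho=1e-5,
                sample_haplotypes=n, seed=7000 + seed, burn_in_generations=400)
            mat, _, _ = simulate(params)
            c = mat.derived_counts
            counts += np.bincount(c, minlength=n)[1:n]
        got = counts / counts.sum()
        harm = np.array([1 / i for i in range(1, n)])
        want = harm / harm.sum()
        assert np.abs(got - want).max() < 0.04

    def test_sample_columns_all_segregating(self, neutral_sim):
        mat, _, _ = neutral_sim
        c = mat.derived_counts
        assert np.all((c > 0) & (c < mat.n_haplotypes))


@pytest.fixture(scope="module")
def sweep():
    return simulate(SweepSimParams(
        pop_size_haploid=100, region_bp=300_000, mu=1e-6, rho=1e-6, s=0.1,
        favored_final_freq=0.7, sample_haplotypes=20, seed=11,
        burn_in_generations=600))


class TestSweepMode:
    def test_trajectory_reaches_target(self, sweep):
        _, _, truth = sweep
        assert truth.favored_trajectory[-1] >= 0.7
        assert truth.favored_trajectory[0] == pytest.approx(0.01)

    def test_favored_site_in_sample(self, sweep):
        mat, _, truth = sweep
        j = truth.favored_site_index
        assert j is not None
        assert mat.positions[j] == truth.favored_pos
        assert truth.favored_sample_freq == mat.derived_freqs[j]

    def test_retry_budget_exhaustion_names_budget(self):
        with pytest.raises(SweepNotAchievedError, match="2 attempts"):
            simulate(SweepSimParams(
                pop_size_haploid=200, region_bp=10_000, mu=1e-7, rho=0.0, s=1e-4,
                favored_final_freq=0.99, sample_haplotypes=10, seed=5,
                burn_in_generations=20, sweep_retry_budget=2,
                sweep_generation_cap=5))

    def test_sweep_elevates_ehh_over_neutral_baseline(self, sweep):
        from sweepscan.ehh_ihs import ihh_pair

        mat, _, truth = sweep
        j = truth.favored_site_index
        rec = ihh_pair(mat, j)
        # matched-frequency neutral sites in the same replicate's flanks
        f = mat.derived_freqs
        far = np.flatnonzero(np.abs(mat.positions - truth.favored_pos) > 100_000)
        matched = [i for i in far if abs(f[i] - f[j]) < 0.1]
        vals = []
        for i in matched[:40]:
            r = ihh_pair(mat, i)
            if r.defined:
                vals.append(r.ihh1)
        assert rec.defined and rec.ihh1 > np.median(vals)


class TestParamsValidation:
    def test_sample_larger_than_population_rejected(self):
        with pytest.raises(ValueError, match="sample_haplotypes"):
            SweepSimParams(pop_size_haploid=10, sample_haplotypes=20)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            SweepSimParams(mu=-1e-9)


class TestEmitVcf:
    def test_round_trip_and_aa_truth(self, tmp_path, neutral_sim):
        mat, sites, truth = neutral_sim
        path = str(tmp_path / "sim.vcf")
        emit_vcf(mat, sites, truth, path)
        aa_col = [ln.split("\t")[7] for ln in open(path) if not ln.startswith("#")]
        assert aa_col == [f"AA={a}" for a in truth.ancestral_alleles]
        pool = PoolSpec("sim", tuple(f"pop1_s{i:03d}" for i in range(10)))
        back, rep = polarize(read_phased_region(path, "1", 1, 10**9, pool))
        np.testing.assert_array_equal(back.entries, mat.entries)
        assert rep.n_dropped == 0

    def test_bgzip_output_with_index_supports_region_query(self, tmp_path, neutral_sim):
        mat, sites, truth = neutral_sim
        path = str(tmp_path / "sim.vcf.gz")
        emit_vcf(mat, sites, truth, path, contig_length=200_000)
        pool = PoolSpec("sim", tuple(f"pop1_s{i:03d}" for i in range(10)))
        mid = int(mat.positions[mat.n_sites // 2]) + 1
        part = read_phased_region(path, "1", 1, mid, pool)
        assert 0 < part.n_sites < mat.n_sites
        np.testing.assert_array_equal(
            part.positions, mat.positions[mat.positions <= mid - 1]
        )

    def test_odd_haplotype_count_rejected(self, neutral_sim):
        from sweepscan.containers import HaplotypeMatrix

        mat, sites, truth = neutral_sim
        odd = HaplotypeMatrix(mat.entries[:5], mat.sites, "x", True)
        with pytest.raises(ValueError, match="even"):
            emit_vcf(odd, sites, truth, "/tmp/never.vcf")


class TestTwoPopMode:
    def test_labels_and_shapes(self):
        mat, sites, truth = simulate(SweepSimParams(
            pop_size_haploid=40, region_bp=100_000, mu=2e-6, rho=2e-6,
            sample_haplotypes=10, seed=21, burn_in_generations=200,
            two_pop=TwoPopParams(split_generations=200, migration=0.02)))
        assert mat.n_haplotypes == 20
        assert truth.pop_labels == ["pop1"] * 10 + ["pop2"] * 10

    def test_sweep_and_two_pop_exclusive(self):
        with pytest.raises(ValueError, match="mutually exclusive"):
            simulate(SweepSimParams(
                pop_size_haploid=40, region_bp=100_000, s=0.1,
                sample_haplotypes=10, seed=1, burn_in_generations=10,
                two_pop=TwoPopParams(10, 0.01)))
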