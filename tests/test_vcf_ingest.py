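"""VCF ingestion, polarization, and score-table round trips."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.containers import HaplotypeMatrix, PoolSpec, make_sites
from sweepscan.vcf_ingest import (
    UnphasedGenotypeError,
    load_pools,
    polarize,
    read_phased_region,
    read_score_table,
    write_score_table,
)

HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=100000>
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
"""


def write_vcf(tmp_path, body, name="t.vcf"):
    path = tmp_path / name
    path.write_text(HEADER + body)
    return str(path)


POOL = PoolSpec("pool", ("s1", "s2", "s3"))


class TestReadPhasedRegion:
    def test_five_snvs_give_6x5_matrix(self, tmp_path):
        body = "".join(
            f"1\t{pos}\t.\tA\tT\t.\tPASS\tAA=A\tGT\t0|1\t1|1\t0|0\n"
            for pos in (10, 20, 30, 40, 50)
        )
        mat = read_phased_region(write_vcf(tmp_path, body), "1", 1, 1000, POOL)
        assert mat.entries.shape == (6, 5)
        # row order follows pool sample order, two haplotypes per diploid
        np.testing.assert_array_equal(mat.entries[:, 0], [0, 1, 1, 1, 0, 0])

    def test_empty_region_gives_zero_columns(self, tmp_path):
        body = "1\t5000\t.\tA\tT\t.\tPASS\tAA=A\tGT\t0|1\t1|1\t0|0\n"
        mat = read_phased_region(write_vcf(tmp_path, body), "1", 1, 100, POOL)
        assert mat.entries.shape == (6, 0)
        assert len(mat.sites) == 0

    def test_region_is_one_based_closed(self, tmp_path):
        body = "1\t10\t.\tA\tT\t.\tPASS\tAA=A\tGT\t0|1\t0|0\t0|0\n" \
               "1\t20\t.\tC\tG\t.\tPASS\tAA=C\tGT\t0|1\t0|0\t0|0\n"
        mat = read_phased_region(write_vcf(tmp_path, body), "1", 10, 19, POOL)
        assert mat.positions.tolist() == [9]  # internal 0-based

    def test_multiallelic_and_indels_rejected(self, tmp_path):
        body = (
            "1\t10\t.\tA\tT,G\t.\tPASS\tAA=A\tGT\t0|1\t0|2\t0|0\n"
            "1\t20\t.\tAT\tA\t.\tPASS\tAA=A\tGT\t0|1\t0|0\t0|0\n"
            "1\t30\t.\tC\tG\t.\tPASS\tAA=C\tGT\t0|1\t0|0\t0|0\n"
        )
        mat = read_phased_region(write_vcf(tmp_path, body), "1", 1, 1000, POOL)
        assert mat.positions.tolist() == [29]

    def test_unphased_genotype_is_hard_error_naming_sample(self, tmp_path):
        body = "1\t10\t.\tA\tT\t.\tPASS\tAA=A\tGT\t0|1\t0/1\t0|0\n"
        with pytest.raises(UnphasedGenotypeError, match=r"s2 at 1:10"):
            read_phased_region(write_vcf(tmp_path, body), "1", 1, 1000, POOL)

    def test_missing_sample_is_hard_error(self, tmp_path):
        body = "1\t10\t.\tA\tT\t.\tPASS\tAA=A\tGT\t0|1\t0|1\t0|0\n"
        bad = PoolSpec("pool", ("s1", "sX"))
        with pytest.raises(KeyError, match="sX"):
            read_phased_region(write_vcf(tmp_path, body), "1", 1, 1000, bad)

    def test_column_sums_equal_alt_counts(self, tmp_path, neutral_sim):
        from sweepscan.sweep_sim import emit_vcf

        mat, sites, truth = neutral_sim
        vcf = str(tmp_path / "sim.vcf")
        emit_vcf(mat, sites, truth, vcf)
        pool = PoolSpec("sim", tuple(f"pop1_s{i:03d}" for i in range(10)))
        raw = read_phased_region(vcf, "1", 1, 10**9, pool)
        # before polarization 1 codes ALT; ALT count = derived count where
        # REF is ancestral, else n - derived count
        ref_is_anc = sites["ref"].to_numpy() == sites["aa"].to_numpy()
        want = np.where(ref_is_anc, mat.derived_counts, 20 - mat.derived_counts)
        np.testing.assert_array_equal(raw.derived_counts, want)


class TestPolarize:
    def _matrix(self, aa):
        entries = np.array([[0, 0, 1], [1, 0, 1], [1, 1, 0], [0, 1, 0]], dtype=np.uint8)
        sites = make_sites("1", [10, 20, 30], ref=["A", "C", "G"], alt=["T", "G", "A"], aa=aa)
        return HaplotypeMatrix(entries, sites, "p", polarized=False)

    def test_aa_ref_unchanged_aa_alt_flipped(self):
        out, rep = polarize(self._matrix(["A", "g", "A"]))  # lower case accepted
        np.testing.assert_array_equal(out.entries[:, 0], [0, 1, 1, 0])  # AA=REF
        np.testing.assert_array_equal(out.entries[:, 1], [1, 1, 0, 0])  # AA=ALT flipped
        assert out.sites.loc[1, "ref"] == "G" and out.sites.loc[1, "alt"] == "C"
        assert rep.n_flipped == 2 and rep.n_dropped == 0

    def test_missing_and_mismatching_aa_dropped(self):
        out, rep = polarize(self._matrix([None, "T", "A"]))
        assert out.n_sites == 1
        assert rep.n_missing_aa == 1 and rep.n_mismatch_aa == 1
        assert [r[2] for r in rep.dropped] == ["missing_aa", "mismatch_aa"]

    def test_ten_site_fixture_drop_accounting(self, rng):
        entries = random_polymorphic(rng)
        aa = ["A"] * 10
        aa[2] = aa[7] = None       # missing
        aa[5] = "C"                # matches neither A nor T
        sites = make_sites("1", np.arange(10) * 10, ref=["A"] * 10, alt=["T"] * 10, aa=aa)
        mat = HaplotypeMatrix(entries, sites, "p", polarized=False)
        out, rep = polarize(mat)
        assert out.n_sites == 7 and len(rep.dropped) == 3

    def test_pool_monomorphic_columns_dropped(self):
        entries = np.array([[1, 1], [1, 0]], dtype=np.uint8)
        sites = make_sites("1", [10, 20], ref=["A", "A"], alt=["T", "T"], aa=["A", "A"])
        out, rep = polarize(HaplotypeMatrix(entries, sites, "p"))
        assert out.n_sites == 1 and rep.n_monomorphic == 1

    def test_double_polarization_with_swapped_aa_restores(self):
        mat = self._matrix(["A", "G", "A"])
        once, _ = polarize(mat)
        # relabel: declare the ancestral allele to be the current derived one
        swapped = once.sites.copy()
        swapped["aa"] = swapped["alt"]
        twice, _ = polarize(HaplotypeMatrix(once.entries, swapped, "p"))
        np.testing.assert_array_equal(twice.entries, 1 - once.entries)


def random_polymorphic(rng):
    from .conftest import random_polymorphic_matrix

    return random_polymorphic_matrix(rng, 4, 10)


class TestScoreTable:
    def _track(self):
        return pd.DataFrame(
            {
                "chrom": ["1", "1", "2"],
                "pos0": [99, 9, 49],
                "stat_name": "iSAFE",
                "raw_score": [0.5, 1.25, 0.125],
                "zscore": [0.1, 2.0, -1.0],
                "pvalue": [0.4602, 0.0228, 0.8413],
                "neglog10p": [0.337, 1.642, 0.075],
            }
        )

    def test_round_trip_preserves_scores(self, tmp_path):
        path = str(tmp_path / "scores.tsv")
        write_score_table(self._track(), path, header_comment="cfg=deadbeef")
        back = read_score_table(path)
        assert back["pos"].tolist() == [10, 100, 50]  # 1-based, sorted
        merged = back.sort_values("raw_score").reset_index(drop=True)
        orig = self._track().sort_values("raw_score").reset_index(drop=True)
        np.testing.assert_allclose(merged["raw_score"], orig["raw_score"], atol=1e-12)
        np.testing.assert_allclose(merged["zscore"], orig["zscore"], atol=1e-12)

    def test_empty_track_writes_header_only(self, tmp_path):
        path = str(tmp_path / "empty.tsv")
        write_score_table(self._track().iloc[:0], path)
        lines = open(path).read().splitlines()
        assert len(lines) == 1 and lines[0].startswith("chrom\tpos")


def test_load_pools_yaml_and_json(tmp_path):
    y = tmp_path / "pools.yaml"
    y.write_text("fleckvieh: [s1, s2]\nchbi: [s3]\n")
    pools = load_pools(str(y))
    assert pools["fleckvieh"].sample_ids == ("s1", "s2")
    j = tmp_path / "pools.json"
    j.write_text('{"a": ["x"]}')
    assert load_pools(str(j))["a"].sample_ids == ("x",)
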