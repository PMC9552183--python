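"""Phased-VCF ingestion, ancestral polarization, and score-table I/O.

The scan statistics (SAFE/iSAFE, iHS) need haplotypes coded 0 = ancestral /
1 = derived.  Ingestion is two-stage and lossless-first:

1. :func:`read_phased_region` pulls a pool's phased genotypes for a region
   into a :class:`~sweepscan.containers.HaplotypeMatrix` coded against ALT.
2. :func:`polarize` recodes to derived using the INFO/AA ancestral-allele tag,
   dropping sites whose ancestral state is missing or matches neither allele,
   and sites monomorphic within the pool (the statistics are undefined there).

Missingness and unphased genotypes are hard errors: the statistics assume a
fully phased matrix and silently imputing would corrupt haplotype structure.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import SITE_COLUMNS, HaplotypeMatrix, PoolSpec

SCORE_COLUMNS = ["chrom", "pos", "stat_name", "raw_score", "zscore", "pvalue", "neglog10p"]


class UnphasedGenotypeError(ValueError):
    pass


@dataclass
class PolarizationReport:
    """Bookkeeping from :func:`polarize`: what was flipped and what was dropped."""

    n_input: int = 0
    n_kept: int = 0
    n_flipped: int = 0
    n_missing_aa: int = 0
    n_mismatch_aa: int = 0
    n_monomorphic: int = 0
    dropped: list = field(default_factory=list)  # (chrom, pos0, reason)

    @property
    def n_dropped(self) -> int:
        return self.n_missing_aa + self.n_mismatch_aa + self.n_monomorphic


def load_pools(path: str) -> dict[str, PoolSpec]:
    """Read a pool file (YAML or JSON mapping pool_id -> list of sample names)."""
    with open(path) as fh:
        text = fh.read()
    if path.endswith((".yaml", ".yml")):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValueError(f"pool file {path} must map pool_id -> sample list")
    return {pid: PoolSpec(pool_id=pid, sample_ids=tuple(samples)) for pid, samples in raw.items()}


def _open_pool_vcf(vcf_path: str, pool: PoolSpec) -> tuple[VCF, np.ndarray]:
    """Open a VCF restricted to the pool, returning the VCF handle and the
    permutation mapping VCF sample order back to pool order."""
    header = VCF(vcf_path)
    missing = [s for s in pool.sample_ids if s not in header.samples]
    header.close()
    if missing:
        raise KeyError(
            f"pool {pool.pool_id!r}: samples absent from VCF header: {', '.join(missing)}"
        )
    vcf = VCF(vcf_path, samples=list(pool.sample_ids), gts012=False, lazy=True)
    order = np.array([vcf.samples.index(s) for s in pool.sample_ids], dtype=np.int64)
    return vcf, order


def read_phased_region(
    vcf_path: str,
    chrom: str,
    start: int,
    end: int,
    pool: PoolSpec,
) -> HaplotypeMatrix:
    """Read phased biallelic SNVs in ``chrom:[start, end]`` (1-based, closed)
    for one pool into an ALT-coded haplotype matrix.

    Two haplotype rows per diploid sample, ordered as ``pool.sample_ids``
    (hapA then hapB per sample).  Multiallelic and non-SNV records are
    rejected (skipped); an unphased genotype is a hard error.
    """
    vcf, order = _open_pool_vcf(vcf_path, pool)
    try:
        if os.path.exists(vcf_path + ".tbi") or os.path.exists(vcf_path + ".csi"):
            it = vcf(f"{chrom}:{start}-{end}")
        else:  # no index: stream and filter
            it = (v for v in vcf if v.CHROM == chrom and start <= v.POS <= end)
        cols: list[np.ndarray] = []
        rows = []
        for v in it:
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                continue  # multiallelic / indel: rejected
            gts = np.asarray(v.genotype.array(), dtype=np.int64)[order]
            if np.any(gts[:, :2] < 0):
                bad = pool.sample_ids[int(np.argmax((gts[:, :2] < 0).any(axis=1)))]
                raise UnphasedGenotypeError(
                    f"missing genotype for sample {bad} at {v.CHROM}:{v.POS}"
                )
            if np.any(gts[:, 2] == 0):
                bad = pool.sample_ids[int(np.argmax(gts[:, 2] == 0))]
                raise UnphasedGenotypeError(
                    f"unphased genotype for sample {bad} at {v.CHROM}:{v.POS}"
                )
            aa = v.INFO.get("AA")
            aa = aa.upper() if isinstance(aa, str) and aa.strip(".") else None
            rows.append((v.CHROM, v.POS - 1, v.REF, v.ALT[0], aa))
            cols.append(gts[:, :2].reshape(-1).astype(np.uint8))
    finally:
        vcf.close()

    n_hap = 2 * len(pool.sample_ids)
    labels = [f"{s}_{h}" for s in pool.sample_ids for h in ("A", "B")]
    if not cols:
        entries = np.zeros((n_hap, 0), dtype=np.uint8)
        sites = pd.DataFrame({c: [] for c in SITE_COLUMNS})
        sites["pos0"] = sites["pos0"].astype(np.int64)
    else:
        entries = np.column_stack(cols)
        sites = pd.DataFrame(rows, columns=list(SITE_COLUMNS))
    return HaplotypeMatrix(
        entries=entries,
        sites=sites,
        pool_id=pool.pool_id,
        polarized=False,
        haplotype_labels=labels,
    )


def polarize(matrix: HaplotypeMatrix) -> tuple[HaplotypeMatrix, PolarizationReport]:
    """Recode an ALT-coded matrix to derived-allele coding using INFO/AA.

    AA == REF keeps the column; AA == ALT flips it (ref/alt roles swap in the
    derived encoding); AA missing or matching neither allele drops the site.
    Columns monomorphic within the pool are dropped afterwards since the
    haplotype statistics are undefined at derived frequencies 0 and 1.
    The AA comparison is case-insensitive (lower case marks low-confidence
    ancestral calls in common pipelines and is accepted).
    """
    rep = PolarizationReport(n_input=matrix.n_sites)
    if matrix.n_sites == 0:
        out = HaplotypeMatrix(
            matrix.entries.copy(), matrix.sites.copy(), matrix.pool_id, True,
            list(matrix.haplotype_labels),
        )
        return out, rep

    ref = matrix.sites["ref"].str.upper().to_numpy()
    alt = matrix.sites["alt"].str.upper().to_numpy()
    aa_raw = matrix.sites["aa"].to_numpy(dtype=object)
    aa = np.array([a.upper() if isinstance(a, str) else "" for a in aa_raw])

    is_ref = aa == ref
    is_alt = aa == alt
    missing = aa == ""
    mismatch = ~(is_ref | is_alt | missing)

    entries = matrix.entries.copy()
    entries[:, is_alt] = 1 - entries[:, is_alt]
    sites = matrix.sites.copy()
    # flipped sites: the derived allele is what the VCF called REF
    sites.loc[is_alt, ["ref", "alt"]] = sites.loc[is_alt, ["alt", "ref"]].to_numpy()

    counts = entries.sum(axis=0)
    mono = (counts == 0) | (counts == matrix.n_haplotypes)
    keep = (is_ref | is_alt) & ~mono

    rep.n_flipped = int(np.count_nonzero(is_alt & ~mono))
    rep.n_missing_aa = int(np.count_nonzero(missing))
    rep.n_mismatch_aa = int(np.count_nonzero(mismatch))
    rep.n_monomorphic = int(np.count_nonzero((is_ref | is_alt) & mono))
    rep.n_kept = int(np.count_nonzero(keep))
    for i in np.flatnonzero(~keep):
        reason = (
            "missing_aa" if missing[i]
            else "mismatch_aa" if mismatch[i]
            else "monomorphic_in_pool"
        )
        rep.dropped.append((sites.iloc[i]["chrom"], int(sites.iloc[i]["pos0"]), reason))

    out = HaplotypeMatrix(
        entries=entries[:, keep],
        sites=sites.loc[keep].reset_index(drop=True),
        pool_id=matrix.pool_id,
        polarized=True,
        haplotype_labels=list(matrix.haplotype_labels),
    )
    return out, rep


# ---------------------------------------------------------------------------
# score-table / BED output
# ---------------------------------------------------------------------------

def write_score_table(track: pd.DataFrame, out_path: str, header_comment: str | None = None) -> None:
    """Write a score track as TSV (columns chrom, pos [1-based], stat_name,
    raw_score, zscore, pvalue, neglog10p), sorted by (chrom, pos)."""
    df = track.copy()
    if "pos" not in df.columns and "pos0" in df.columns:
        df["pos"] = df["pos0"] + 1
    for col in SCORE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[SCORE_COLUMNS].sort_values(["chrom", "pos"], kind="mergesort")
    with open(out_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_score_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_significant_bed(track: pd.DataFrame, out_path: str, header_comment: str | None = None) -> None:
    """Export significant records as BED (0-based half-open single-bp features,
    or the window interval for window tracks)."""
    sig = track[track.get("significant", pd.Series(False, index=track.index)).astype(bool)]
    with open(out_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for _, r in sig.iterrows():
            if "window_start" in sig.columns:
                start, end = int(r["window_start"]), int(r["window_end"])
            else:
                start = int(r["pos0"]) if "pos0" in sig.columns else int(r["pos"]) - 1
                end = start + 1
            name = r.get("stat_name", "score")
            fh.write(f"{r['chrom']}\t{start}\t{end}\t{name}\t{r['neglog10p']:.6g}\n")
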