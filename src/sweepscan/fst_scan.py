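"""Two-population Weir–Cockerham Fst, per site and in 10-kb windows.

Per site the 1984 variance components are computed from the two pools'
diploid sample sizes, allele frequencies and observed heterozygote
proportions (diploids are reconstituted by pairing consecutive haplotype
rows, i.e. the two phased haplotypes of each sample):

    theta = a / (a + b + c)

with a the among-population component and b, c the between/within-individual
components.  theta is undefined (NaN) where a + b + c <= 0 — in particular
where both pools are monomorphic for the same allele — and such sites are
excluded from window aggregates.  Negative per-site estimates are retained
unclamped: clamping would bias window averages upward.

Windows tile each chromosome with a fixed span (default 10 kb) anchored at
coordinate 0.  Both window aggregates are emitted: the unweighted mean of
per-site theta (the default carried to the significance step) and the
weighted ratio of sums  sum(a) / sum(a+b+c)  (the standard genome-scan
estimator, less noisy for sparse windows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import HaplotypeMatrix

DEFAULT_WINDOW_BP = 10_000


@dataclass(frozen=True)
class SiteFst:
    chrom: str
    pos0: int
    a_comp: float
    bc_comp: float  # b + c

    @property
    def theta(self) -> float:
        denom = self.a_comp + self.bc_comp
        return self.a_comp / denom if denom > 0 else float("nan")


def _diploid_summaries(matrix: HaplotypeMatrix | np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    """(n_diploids, alt/derived allele freq per site, observed het proportion
    per site), pairing consecutive haplotype rows into diploids."""
    X = matrix.entries if isinstance(matrix, HaplotypeMatrix) else np.asarray(matrix)
    X = X.astype(np.int64, copy=False)
    n_hap = X.shape[0]
    if n_hap < 2 or n_hap % 2:
        raise ValueError("need an even number (>= 2) of haplotypes to form diploids")
    h1, h2 = X[0::2], X[1::2]
    n_dip = n_hap // 2
    p = (h1 + h2).sum(axis=0) / n_hap
    het = (h1 != h2).sum(axis=0) / n_dip
    return n_dip, p, het


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Weir–Cockerham (1984) a, b, c for r = 2 populations (vectorized)."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    return a, b, c


def wc_fst_site(geno_pop1, geno_pop2, chrom: str = ".", pos0: int = 0) -> SiteFst:
    """theta at one biallelic site from diploid genotype counts.

    ``geno_popX`` is (n_hom_ref, n_het, n_hom_alt).
    """
    out = []
    for counts in (geno_pop1, geno_pop2):
        n00, n01, n11 = (int(x) for x in counts)
        n = n00 + n01 + n11
        if n < 1:
            raise ValueError("each pool needs at least one called genotype")
        out.append((n, (2 * n11 + n01) / (2 * n), n01 / n))
    (n1, p1, h1), (n2, p2, h2) = out
    a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
    return SiteFst(chrom=chrom, pos0=pos0, a_comp=float(a), bc_comp=float(b + c))


def fst_sites(matrix_a: HaplotypeMatrix, matrix_b: HaplotypeMatrix) -> pd.DataFrame:
    """Per-site Weir–Cockerham components and theta for two pools read over
    the same region (site tables must match positionally).

    The allele orientation (ALT vs derived) is irrelevant: theta is invariant
    to swapping the allele labels, so unpolarized matrices are fine — what
    matters is that both pools use the same coding, which sharing one VCF
    guarantees.
    """
    if matrix_a.n_sites != matrix_b.n_sites or not np.array_equal(
        matrix_a.positions, matrix_b.positions
    ):
        raise ValueError("pool matrices cover different site sets")
    n1, p1, h1 = _diploid_summaries(matrix_a)
    n2, p2, h2 = _diploid_summaries(matrix_b)
    a, b, c = _wc_components(float(n1), p1, h1, float(n2), p2, h2)
    bc = b + c
    denom = a + bc
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom > 0, a / denom, np.nan)
    return pd.DataFrame(
        {
            "chrom": matrix_a.sites["chrom"].to_numpy(),
            "pos0": matrix_a.positions,
            "a_comp": a,
            "bc_comp": bc,
            "theta": theta,
        }
    )


def windowed_fst(sites: pd.DataFrame, window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Aggregate per-site Fst components into fixed non-overlapping windows
    anchored at coordinate 0.  Sites with undefined theta are excluded; empty
    windows are omitted.  ``n_sites`` counts contributing sites."""
    df = sites.dropna(subset=["theta"]).copy()
    if df.empty:
        return pd.DataFrame(
            columns=["chrom", "window_start", "window_end", "n_sites", "fst_weighted", "fst_mean"]
        )
    df["window_start"] = (df["pos0"] // window_bp) * window_bp
    df["abc"] = df["a_comp"] + df["bc_comp"]
    out = (
        df.groupby(["chrom", "window_start"], sort=True)
        .agg(
            n_sites=("theta", "size"),
            sum_a=("a_comp", "sum"),
            sum_abc=("abc", "sum"),
            fst_mean=("theta", "mean"),
        )
        .reset_index()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fst_weighted"] = np.where(out["sum_abc"] > 0, out["sum_a"] / out["sum_abc"], np.nan)
    out["window_end"] = out["window_start"] + window_bp
    return out[
        ["chrom", "window_start", "window_end", "n_sites", "fst_weighted", "fst_mean"]
    ]
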