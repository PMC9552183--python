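"""SAFE and iSAFE: ranking candidate favored mutations within a population.

Both statistics are functions of a polarized haplotype matrix only.  With
``c_j`` the derived-allele count at site *j*, each haplotype *h* gets a
haplotype allele frequency (HAF) score

    HAF(h) = sum of c_j over the sites where h carries the derived allele,

so putative carriers of a favored allele accumulate large HAF.  Haplotypes are
"distinct" iff their HAF scores differ.  For a site *e* with derived frequency
``f`` in (0, 1):

    k(e)   = (# distinct haplotypes carrying e) / (# distinct haplotypes),
    phi(e) = (sum of HAF over carriers of e) / (sum of HAF over all),
    SAFE(e) = (phi - k) / sqrt(f (1 - f)).

A hard sweep inflates phi (carriers hold most of the HAF mass) while
collapsing carriers onto few distinct haplotypes (small k), so the favored
mutation maximizes SAFE.  Because every haplotype becomes distinct in large
regions, iSAFE rescues power by rescoring in half-overlapped windows of a
fixed number of SNPs (default 300) and combining windows:

    psi(e, w) = max(0, SAFE of e evaluated within window w, inserting e's
                column into w when e lies outside it),
    delta     = the per-window best-SAFE sites,
    alpha(w)  = sum_{e in delta} psi(e, w), normalized over windows,
    iSAFE(e)  = sum_w psi(e, w) * alpha(w).

Genome scans run iSAFE independently on non-overlapping chunks (default 4 Mb,
never above the method's 5 Mb span) and concatenate the per-site scores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import HaplotypeMatrix, PoolSpec

MAX_CHUNK_BP = 5_000_000  # the method is specified for regions up to 5 Mb


def haf_scores(matrix: HaplotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-haplotype HAF score: sum of derived-allele counts over the sites
    where the haplotype carries the derived allele."""
    X = matrix.entries if isinstance(matrix, HaplotypeMatrix) else np.asarray(matrix)
    X = X.astype(np.int64, copy=False)
    if X.size == 0:
        return np.zeros(X.shape[0], dtype=np.int64)
    counts = X.sum(axis=0)
    return X @ counts


def _distinct_counts(Hmat: np.ndarray, carrier_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise (# distinct values among carriers, # distinct values overall).

    ``Hmat`` is (n_hap, n_sites) of non-negative ints; ``carrier_mask`` same
    shape, boolean.
    """
    S = np.sort(Hmat, axis=0)
    d_total = 1 + (np.diff(S, axis=0) != 0).sum(axis=0)
    # sentinel -1 sorts below all HAF values (HAF >= 0)
    Sc = np.sort(np.where(carrier_mask, Hmat, -1), axis=0)
    prev = np.vstack([np.full((1, Sc.shape[1]), -2, dtype=Sc.dtype), Sc[:-1]])
    d_carrier = ((Sc > -1) & (Sc != prev)).sum(axis=0)
    return d_carrier, d_total


def safe_scores(
    matrix: HaplotypeMatrix | np.ndarray,
    denominator: str = "sqrt",
) -> pd.DataFrame:
    """SAFE score per site of a polarized, all-polymorphic matrix.

    Returns a DataFrame with columns ``f``, ``k``, ``phi``, ``safe``.
    ``denominator="sqrt"`` uses (phi - k)/sqrt(f(1-f)) (the standard,
    variance-normalized form); ``denominator="linear"`` divides by f(1-f)
    instead, for comparison with the formula as typeset.
    """
    X = matrix.entries if isinstance(matrix, HaplotypeMatrix) else np.asarray(matrix)
    X = X.astype(np.int64, copy=False)
    n, m = X.shape
    if n < 2:
        raise ValueError("SAFE needs at least 2 haplotypes")
    counts = X.sum(axis=0)
    if np.any(counts == 0) or np.any(counts == n):
        raise ValueError("matrix has monomorphic columns; polarize/filter first")
    H = X @ counts
    total_haf = int(H.sum())
    if total_haf == 0:
        raise ValueError("total HAF is zero (no derived alleles anywhere)")
    f = counts / n
    phi = (X * H[:, None]).sum(axis=0) / total_haf
    d_carrier, d_total = _distinct_counts(
        np.broadcast_to(H[:, None], X.shape), X.astype(bool)
    )
    k = d_carrier / d_total
    if denominator == "sqrt":
        safe = (phi - k) / np.sqrt(f * (1.0 - f))
    elif denominator == "linear":
        safe = (phi - k) / (f * (1.0 - f))
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return pd.DataFrame({"f": f, "k": k, "phi": phi, "safe": safe})


def _window_starts(m: int, window: int, step: int) -> list[tuple[int, int]]:
    """Half-overlapped windows of `window` sites; a trailing partial window is
    retained rather than dropped (no blind spot at chunk edges)."""
    if m <= window:
        return [(0, m)]
    out = []
    for s in range(0, m, step):
        e = min(s + window, m)
        out.append((s, e))
        if e == m:
            break
    return out


def _window_psi(
    X: np.ndarray, counts: np.ndarray, f: np.ndarray, lo: int, hi: int, denominator: str
) -> np.ndarray:
    """psi(e, w) for one window w = [lo, hi) and every site e of the chunk.

    For e inside w this is its plain within-window SAFE (clamped at 0); for e
    outside, e's column is inserted into the window's submatrix, HAFs are
    recomputed, and SAFE is evaluated there.
    """
    n, m = X.shape
    Hw = X[:, lo:hi] @ counts[lo:hi]  # within-window HAF per haplotype
    add = counts.copy()
    add[lo:hi] = 0  # insertion applies only to out-of-window sites
    Hmat = Hw[:, None] + X * add[None, :]
    carrier = X.astype(bool)
    tot = Hmat.sum(axis=0)
    phi = (Hmat * X).sum(axis=0) / tot
    d_carrier, d_total = _distinct_counts(Hmat, carrier)
    k = d_carrier / d_total
    if denominator == "sqrt":
        safe = (phi - k) / np.sqrt(f * (1.0 - f))
    else:
        safe = (phi - k) / (f * (1.0 - f))
    return np.maximum(safe, 0.0)


def isafe_scores(
    matrix: HaplotypeMatrix | np.ndarray,
    window_snps: int = 300,
    denominator: str = "sqrt",
) -> np.ndarray:
    """iSAFE score per site.

    Windows are half-overlapped spans of ``window_snps`` consecutive sites
    (step = window_snps // 2).  When the chunk has no more than
    ``window_snps`` sites a single window is used and iSAFE reduces to
    max(0, SAFE).  When two sites tie for a window's best SAFE the lower
    position wins; the per-window best sites are deduplicated before the
    window weights are computed.
    """
    X = matrix.entries if isinstance(matrix, HaplotypeMatrix) else np.asarray(matrix)
    X = X.astype(np.int64, copy=False)
    n, m = X.shape
    if m < 2:
        warnings.warn("fewer than 2 sites: iSAFE not computed", stacklevel=2)
        return np.zeros(m)
    counts = X.sum(axis=0)
    f = counts / n

    windows = _window_starts(m, window_snps, max(1, window_snps // 2))
    if len(windows) == 1:
        safe = safe_scores(X, denominator=denominator)["safe"].to_numpy()
        return np.maximum(safe, 0.0)

    psi = np.empty((m, len(windows)))
    delta: list[int] = []
    for j, (lo, hi) in enumerate(windows):
        psi[:, j] = _window_psi(X, counts, f, lo, hi, denominator)
        # within-window argmax; np.argmax takes the first (lowest position) on ties
        delta.append(lo + int(np.argmax(psi[lo:hi, j])))
    delta = sorted(set(delta))

    alpha = psi[delta, :].sum(axis=0)
    total = alpha.sum()
    if total <= 0:  # every SAFE score non-positive: no signal anywhere
        return np.zeros(m)
    alpha /= total
    return psi @ alpha


def genome_scan_isafe(
    vcf_path: str,
    pool: PoolSpec,
    chunk_bp: int = 4_000_000,
    window_snps: int = 300,
    denominator: str = "sqrt",
    chroms: list[str] | None = None,
) -> pd.DataFrame:
    """Chunked genome-wide iSAFE scan for one pool.

    Each chromosome is partitioned into non-overlapping ``chunk_bp`` chunks
    (anchored at coordinate 0); iSAFE runs per chunk on the pool's polarized
    haplotypes and the per-site scores are concatenated.  ``chunk_bp`` may not
    exceed the method's 5 Mb maximum span.
    """
    from cyvcf2 import VCF

    from .vcf_ingest import polarize, read_phased_region

    if chunk_bp > MAX_CHUNK_BP:
        raise ValueError(f"chunk_bp={chunk_bp} exceeds the method's 5 Mb maximum span")

    header = VCF(vcf_path)
    lengths = dict(zip(header.seqnames, header.seqlens))
    header.close()
    if chroms is None:
        chroms = list(lengths)

    frames = []
    for chrom in chroms:
        length = lengths[chrom]
        for chunk_start in range(0, length, chunk_bp):
            chunk_end = min(chunk_start + chunk_bp, length)
            mat = read_phased_region(vcf_path, chrom, chunk_start + 1, chunk_end, pool)
            mat, _ = polarize(mat)
            if mat.n_sites == 0:
                continue
            if mat.n_sites < 2:
                scores = np.zeros(mat.n_sites)
            else:
                scores = isafe_scores(mat, window_snps=window_snps, denominator=denominator)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos0": mat.positions,
                        "stat_name": "iSAFE",
                        "raw_score": scores,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos0", "stat_name", "raw_score"])
    return pd.concat(frames, ignore_index=True)
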