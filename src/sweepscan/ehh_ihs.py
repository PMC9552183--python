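"""Extended haplotype homozygosity (EHH), integrated EHH (iHH), and iHS.

For a core site and core allele, EHH at a flanking marker x is the
probability that two randomly drawn carriers of the core allele are identical
over the whole stretch from the core to x:

    EHH(x) = sum_g C(n_g, 2) / C(n_core, 2)

where the n_g are the sizes of the identity groups the carriers fall into.
iHH integrates the EHH curve over genetic distance (trapezoid rule, upstream
plus downstream), with physical gaps converted at a flat map rate (default
1 cM per Mb).  The statistic

    iHS_raw = ln(iHH_derived / iHH_ancestral)

is positive when derived-allele haplotypes are unusually long, the signature
of a recent sweep on the derived allele.

Numerical policy: curves start at the core with EHH = 1, stop once EHH falls
below ``cutoff`` (the first sub-cutoff point is kept, so the terminal decay
segment contributes to the integral), stop without extending across physical
gaps larger than ``max_gap_bp`` (unmodelled recombination deserts), and are
never extrapolated past the last computed marker.

The inner loops are numba-compiled; a pure-Python oracle in the test suite
cross-checks them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .containers import HaplotypeMatrix

DEFAULT_EHH_CUTOFF = 0.05
DEFAULT_MAX_GAP_BP = 200_000


@dataclass
class EhhCurve:
    core_site: int
    core_allele: int
    direction: str  # "up" (increasing position) or "down"
    marker_indices: np.ndarray  # includes the core as first element
    ehh_values: np.ndarray  # EHH at each marker; 1.0 at the core


@dataclass
class IhsRecord:
    site_index: int
    ihh0: float
    ihh1: float
    ihs_raw: float
    defined: bool = True
    reason: str = ""


@njit(cache=True)
def _ehh_extend(X, pos0, core, allele, step, cutoff, max_gap_bp, out_idx, out_ehh):  # pragma: no cover
    """Fill out_idx/out_ehh with the EHH curve from `core` in direction `step`
    (+1/-1); returns the number of points written (>= 1: the core itself).
    Returns 0 when fewer than 2 haplotypes carry the core allele."""
    n, m = X.shape
    nc = 0
    for h in range(n):
        if X[h, core] == allele:
            nc += 1
    if nc < 2:
        return 0
    carriers = np.empty(nc, np.int64)
    t = 0
    for h in range(n):
        if X[h, core] == allele:
            carriers[t] = h
            t += 1
    npairs = nc * (nc - 1) // 2
    grp = np.zeros(nc, np.int64)
    out_idx[0] = core
    out_ehh[0] = 1.0
    k = 1
    j = core + step
    prev = core
    key = np.empty(nc, np.int64)
    newgrp = np.empty(nc, np.int64)
    while 0 <= j < m:
        gap = pos0[j] - pos0[prev]
        if gap < 0:
            gap = -gap
        if gap > max_gap_bp:
            break
        for t in range(nc):
            key[t] = grp[t] * 2 + X[carriers[t], j]
        order = np.argsort(key, kind="mergesort")
        g = 0
        run = 1
        pairs = 0
        newgrp[order[0]] = 0
        for t in range(1, nc):
            if key[order[t]] != key[order[t - 1]]:
                pairs += run * (run - 1) // 2
                g += 1
                run = 1
            else:
                run += 1
            newgrp[order[t]] = g
        pairs += run * (run - 1) // 2
        ehh = pairs / npairs
        out_idx[k] = j
        out_ehh[k] = ehh
        k += 1
        for t in range(nc):
            grp[t] = newgrp[t]
        if ehh < cutoff:
            break
        prev = j
        j += step
    return k


@njit(cache=True)
def _trapz_cm(out_idx, out_ehh, k, pos0, cm_per_mb):  # pragma: no cover
    s = 0.0
    for t in range(1, k):
        gap = pos0[out_idx[t]] - pos0[out_idx[t - 1]]
        if gap < 0:
            gap = -gap
        s += 0.5 * (out_ehh[t] + out_ehh[t - 1]) * (gap / 1.0e6) * cm_per_mb
    return s


@njit(cache=True)
def _ihh_one_allele(X, pos0, core, allele, cutoff, max_gap_bp, cm_per_mb, idx_buf, ehh_buf):  # pragma: no cover
    """iHH for one core allele: upstream + downstream integrals.
    Returns -1.0 when the allele has < 2 carriers."""
    total = 0.0
    for step in (-1, 1):
        k = _ehh_extend(X, pos0, core, allele, step, cutoff, max_gap_bp, idx_buf, ehh_buf)
        if k == 0:
            return -1.0
        total += _trapz_cm(idx_buf, ehh_buf, k, pos0, cm_per_mb)
    return total


@njit(cache=True)
def _ihs_scan_kernel(X, pos0, targets, cutoff, max_gap_bp, cm_per_mb):  # pragma: no cover
    m = X.shape[1]
    nt = targets.shape[0]
    ihh0 = np.empty(nt)
    ihh1 = np.empty(nt)
    status = np.zeros(nt, np.int64)  # 0 ok; 1 few carriers; 2 zero integral
    idx_buf = np.empty(m, np.int64)
    ehh_buf = np.empty(m)
    for i in range(nt):
        e = targets[i]
        a0 = _ihh_one_allele(X, pos0, e, 0, cutoff, max_gap_bp, cm_per_mb, idx_buf, ehh_buf)
        a1 = _ihh_one_allele(X, pos0, e, 1, cutoff, max_gap_bp, cm_per_mb, idx_buf, ehh_buf)
        ihh0[i] = a0
        ihh1[i] = a1
        if a0 < 0.0 or a1 < 0.0:
            status[i] = 1
        elif a0 == 0.0 or a1 == 0.0:
            status[i] = 2
    return ihh0, ihh1, status


def ehh(
    matrix: HaplotypeMatrix | np.ndarray,
    core: int,
    allele: int,
    direction: str,
    cutoff: float = DEFAULT_EHH_CUTOFF,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> EhhCurve:
    """EHH decay curve from a core site for one core allele and direction.

    Raises ``ValueError`` when fewer than 2 haplotypes carry the core allele
    (EHH is a pairwise probability and needs at least one pair).
    """
    X, pos0 = _as_arrays(matrix)
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    step = 1 if direction == "up" else -1
    idx_buf = np.empty(X.shape[1], np.int64)
    ehh_buf = np.empty(X.shape[1])
    k = _ehh_extend(X, pos0, core, allele, step, cutoff, max_gap_bp, idx_buf, ehh_buf)
    if k == 0:
        raise ValueError(f"fewer than 2 haplotypes carry allele {allele} at site {core}")
    return EhhCurve(
        core_site=core,
        core_allele=allele,
        direction=direction,
        marker_indices=idx_buf[:k].copy(),
        ehh_values=ehh_buf[:k].copy(),
    )


def ihh_pair(
    matrix: HaplotypeMatrix | np.ndarray,
    core: int,
    map_rate_cm_per_mb: float = 1.0,
    cutoff: float = DEFAULT_EHH_CUTOFF,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> IhsRecord:
    """iHH for both core alleles at one site, and the raw iHS = ln(iHH1/iHH0).

    Undefined records (either allele with < 2 carriers, or a zero integral)
    are flagged rather than raised; they are excluded from standardization.
    """
    X, pos0 = _as_arrays(matrix)
    idx_buf = np.empty(X.shape[1], np.int64)
    ehh_buf = np.empty(X.shape[1])
    a0 = _ihh_one_allele(X, pos0, core, 0, cutoff, max_gap_bp, map_rate_cm_per_mb, idx_buf, ehh_buf)
    a1 = _ihh_one_allele(X, pos0, core, 1, cutoff, max_gap_bp, map_rate_cm_per_mb, idx_buf, ehh_buf)
    if a0 < 0 or a1 < 0:
        return IhsRecord(core, max(a0, 0.0), max(a1, 0.0), np.nan, False, "few_carriers")
    if a0 == 0 or a1 == 0:
        return IhsRecord(core, a0, a1, np.nan, False, "zero_integral")
    return IhsRecord(core, a0, a1, float(np.log(a1 / a0)))


def ihs_scan(
    matrix: HaplotypeMatrix,
    maf_min: float = 0.05,
    map_rate_cm_per_mb: float = 1.0,
    cutoff: float = DEFAULT_EHH_CUTOFF,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    return_skipped: bool = False,
):
    """Raw iHS for every site with derived frequency in [maf_min, 1 - maf_min].

    Returns a score-track DataFrame (chrom, pos0, stat_name, raw_score, ihh0,
    ihh1); with ``return_skipped=True`` also a DataFrame of skipped sites with
    reason codes (maf_filter, few_carriers, zero_integral).
    """
    if not matrix.polarized:
        raise ValueError("ihs_scan requires a polarized matrix")
    X, pos0 = _as_arrays(matrix)
    n, m = X.shape
    f = X.sum(axis=0) / n
    eligible = (f >= maf_min) & (f <= 1.0 - maf_min)
    targets = np.flatnonzero(eligible).astype(np.int64)
    if targets.size:
        ihh0, ihh1, status = _ihs_scan_kernel(
            X, pos0, targets, cutoff, max_gap_bp, map_rate_cm_per_mb
        )
    else:
        ihh0 = ihh1 = np.empty(0)
        status = np.empty(0, np.int64)
    ok = status == 0
    sites = matrix.sites
    track = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy()[targets[ok]],
            "pos0": pos0[targets[ok]],
            "stat_name": "iHS",
            "raw_score": np.log(ihh1[ok] / ihh0[ok]),
            "ihh0": ihh0[ok],
            "ihh1": ihh1[ok],
        }
    )
    if not return_skipped:
        return track
    reasons = []
    for j in np.flatnonzero(~eligible):
        reasons.append((sites["chrom"].iloc[j], int(pos0[j]), "maf_filter"))
    code = {1: "few_carriers", 2: "zero_integral"}
    for t, st in zip(targets[~ok], status[~ok]):
        reasons.append((sites["chrom"].iloc[int(t)], int(pos0[int(t)]), code[int(st)]))
    skipped = pd.DataFrame(reasons, columns=["chrom", "pos0", "reason"])
    return track, skipped


def standardize_by_frequency(track: pd.DataFrame, freqs: np.ndarray, n_bins: int = 20) -> pd.DataFrame:
    """Classical frequency-bin standardization of raw iHS (optional mode; the
    default pipeline standardizes genome-wide instead).  ``freqs`` gives the
    derived-allele frequency of each track record."""
    track = track.copy()
    bins = np.clip((np.asarray(freqs) * n_bins).astype(int), 0, n_bins - 1)
    z = np.full(len(track), np.nan)
    raw = track["raw_score"].to_numpy()
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = raw[sel].mean(), raw[sel].std(ddof=0)
        if sd > 0:
            z[sel] = (raw[sel] - mu) / sd
    track["zscore_freqbin"] = z
    return track


def _as_arrays(matrix) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(matrix, HaplotypeMatrix):
        return matrix.entries, matrix.positions
    X = np.asarray(matrix, dtype=np.uint8)
    return X, np.arange(X.shape[1], dtype=np.int64)
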