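"""Genome-wide significance: normal right-tail p-values, thresholding, and
gene-interval annotation.

Raw scores are standardized against the track's own genome-wide moments
(one mean/SD per pool and test across all autosomes jointly) and converted to
one-sided upper-tail p-values of the standard normal:

    z = (raw - mean) / sd,    p = P(Z >= z) = Phi_bar(z),
    -log10(p) >= 7.301  (i.e. p <= 5.00e-8)  declares significance.

The phrase "right-tail probability density function" is interpreted as the
upper-tail *probability* (survival function) — a density value is not a
probability and cannot yield p-values; ``mode="pdf"`` keeps the literal
density reading available for forensic comparison only.

Note the rule is one-sided throughout: strongly *negative* scores (e.g. long
ancestral haplotypes under iHS) are never flagged by this procedure.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy.stats import norm

GENOME_WIDE_THRESHOLD = 7.301  # -log10(p); p = 5.00e-8
P_FLOOR = 1e-300


def right_tail_p(track: pd.DataFrame, mode: str = "sf") -> pd.DataFrame:
    """Attach zscore, pvalue, neglog10p to a score track (``raw_score``).

    The track's own finite raw scores define the standardization moments;
    a degenerate track (fewer than 2 finite scores, or zero SD) is a hard
    error.  p-values are floored at 1e-300 before the log transform; floored
    records carry ``p_floored = True``.
    """
    track = track.copy()
    raw = track["raw_score"].to_numpy(dtype=float)
    finite = np.isfinite(raw)
    if finite.sum() < 2:
        raise ValueError("track needs at least 2 finite raw scores")
    mu = raw[finite].mean()
    sd = raw[finite].std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate track: zero standard deviation")
    z = (raw - mu) / sd
    if mode == "sf":
        p = norm.sf(z)
    elif mode == "pdf":  # forensic mode: the literal "density" reading
        p = norm.pdf(z)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    floored = p < P_FLOOR
    p = np.clip(p, P_FLOOR, None)
    track["zscore"] = z
    track["pvalue"] = p
    track["neglog10p"] = -np.log10(p)
    track["p_floored"] = floored
    return track


def apply_threshold(track: pd.DataFrame, neglog10p_min: float = GENOME_WIDE_THRESHOLD) -> pd.DataFrame:
    """Flag records with neglog10p >= threshold (inclusive boundary)."""
    track = track.copy()
    track["significant"] = track["neglog10p"] >= neglog10p_min
    return track


def significance_summary(track: pd.DataFrame) -> dict:
    sig = track[track["significant"]]
    per_chrom = sig.groupby("chrom").size().to_dict() if len(sig) else {}
    return {"n_total": int(len(track)), "n_significant": int(len(sig)), "per_chrom": per_chrom}


# ---------------------------------------------------------------------------
# gene intervals
# ---------------------------------------------------------------------------

def load_gene_intervals(path: str, dialect: str | None = None) -> pd.DataFrame:
    """Load gene intervals from BED (0-based half-open) or GFF3 (1-based
    closed; ``gene`` features only).  Dialect is auto-detected from the
    extension and can be overridden.  Returns columns chrom, start0, end0,
    gene_id, gene_name with half-open coordinates."""
    if dialect is None:
        low = path.lower()
        dialect = "gff" if low.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")) else "bed"
    rows = []
    if dialect == "bed":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: BED line has fewer than 3 columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: non-integer BED coordinates") from exc
                if start >= end:
                    raise ValueError(f"{path}:{ln}: degenerate interval {start}>={end}")
                name = parts[3] if len(parts) > 3 else f"feature_{ln}"
                rows.append((parts[0], start, end, name, name))
    elif dialect == "gff":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ValueError(f"{path}:{ln}: GFF3 line must have 9 columns")
                if parts[2] != "gene":
                    continue
                try:
                    start1, end1 = int(parts[3]), int(parts[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: non-integer GFF coordinates") from exc
                if start1 > end1:
                    raise ValueError(f"{path}:{ln}: degenerate interval {start1}>{end1}")
                attrs = parts[8]
                gid = _gff_attr(attrs, "ID") or _gff_attr(attrs, "gene_id") or f"gene_{ln}"
                gname = _gff_attr(attrs, "Name") or gid
                rows.append((parts[0], start1 - 1, end1, gid, gname))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.DataFrame(rows, columns=["chrom", "start0", "end0", "gene_id", "gene_name"])
    return df.sort_values(["chrom", "start0"], kind="mergesort").reset_index(drop=True)


def _gff_attr(attrs: str, key: str) -> str | None:
    m = re.search(rf"(?:^|;)\s*{key}=([^;]+)", attrs)
    return m.group(1) if m else None


def annotate_features(track: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Label every record genic/intergenic by interval overlap.

    Site records overlap a gene when pos0 lies in [start0, end0); window
    records when [window_start, window_end) intersects it.  Overlapping gene
    ids are attached (comma-joined) for significant records.
    """
    track = track.copy()
    if "window_start" in track.columns:
        rec_start = track["window_start"].to_numpy(dtype=np.int64)
        rec_end = track["window_end"].to_numpy(dtype=np.int64)
    else:
        rec_start = track["pos0"].to_numpy(dtype=np.int64)
        rec_end = rec_start + 1
    chroms = track["chrom"].astype(str).to_numpy()
    genic = np.zeros(len(track), dtype=bool)
    gene_ids = np.array([""] * len(track), dtype=object)
    want_ids = track["significant"].to_numpy(dtype=bool) if "significant" in track.columns \
        else np.ones(len(track), dtype=bool)
    for chrom, gsub in genes.groupby("chrom"):
        sel = np.flatnonzero(chroms == str(chrom))
        if sel.size == 0:
            continue
        starts = gsub["start0"].to_numpy(dtype=np.int64)
        ends = gsub["end0"].to_numpy(dtype=np.int64)
        ids = gsub["gene_id"].to_numpy(dtype=object)
        # genes sorted by start; running max of ends handles nested intervals
        cummax_end = np.maximum.accumulate(ends)
        for i in sel:
            s, e = rec_start[i], rec_end[i]
            j = np.searchsorted(starts, e)  # genes with start < record end
            if j == 0 or cummax_end[j - 1] <= s:
                continue
            hit = (starts[:j] < e) & (ends[:j] > s)
            if hit.any():
                genic[i] = True
                if want_ids[i]:
                    gene_ids[i] = ",".join(ids[:j][hit])
    track["genic"] = genic
    track["gene_ids"] = gene_ids
    return track
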