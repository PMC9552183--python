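"""Core in-memory containers shared across the scan modules.

The central object is :class:`HaplotypeMatrix`: a fully phased 0/1 matrix with
one row per haplotype and one column per biallelic SNV, together with a site
table (pandas DataFrame).  Before polarization a 1 encodes the VCF ALT allele;
after :func:`sweepscan.vcf_ingest.polarize` a 1 encodes the *derived* allele.

Internal coordinates are 0-based half-open (column ``pos0``); conversion to the
1-based VCF/TSV convention happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every site table carries, in order.
SITE_COLUMNS = ("chrom", "pos0", "ref", "alt", "aa")


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNV.

    ``pos0`` is the 0-based coordinate; ``derived_count`` counts haplotypes
    carrying the derived allele (only meaningful after polarization).
    """

    chrom: str
    pos0: int
    ref_allele: str
    alt_allele: str
    ancestral_allele: str | None
    derived_count: int
    n_haplotypes: int

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt ({self.ref_allele}) at {self.chrom}:{self.pos0 + 1}")
        if not 0 <= self.derived_count <= self.n_haplotypes:
            raise ValueError(
                f"derived_count {self.derived_count} outside [0, {self.n_haplotypes}]"
            )


@dataclass(frozen=True)
class PoolSpec:
    """A named set of VCF samples analyzed together as one population."""

    pool_id: str
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) == 0:
            raise ValueError(f"pool {self.pool_id!r} has no samples")
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))


@dataclass
class HaplotypeMatrix:
    """Phased haplotype-by-site 0/1 matrix plus its site table.

    Parameters
    ----------
    entries
        ``(n_haplotypes, n_sites)`` uint8 array; no missing values.
    sites
        DataFrame with columns :data:`SITE_COLUMNS`, one row per column of
        ``entries``, sorted by ``pos0``.
    pool_id
        Label of the pool the haplotypes belong to.
    polarized
        True once 1 means "derived" rather than "ALT".
    """

    entries: np.ndarray
    sites: pd.DataFrame
    pool_id: str = "pool"
    polarized: bool = False
    haplotype_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = np.ascontiguousarray(self.entries, dtype=np.uint8)
        if self.entries.ndim != 2:
            raise ValueError("entries must be 2-D (haplotypes x sites)")
        if len(self.sites) != self.entries.shape[1]:
            raise ValueError(
                f"{len(self.sites)} site rows vs {self.entries.shape[1]} matrix columns"
            )
        pos = self.sites["pos0"].to_numpy()
        if len(pos) > 1 and np.any(np.diff(pos) <= 0):
            raise ValueError("site positions must be strictly increasing")

    # -- basic geometry -------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_sites(self) -> int:
        return self.entries.shape[1]

    @property
    def positions(self) -> np.ndarray:
        """0-based physical positions, one per column."""
        return self.sites["pos0"].to_numpy(dtype=np.int64)

    @property
    def derived_counts(self) -> np.ndarray:
        """Per-site count of 1-alleles (derived once polarized)."""
        return self.entries.sum(axis=0, dtype=np.int64)

    @property
    def derived_freqs(self) -> np.ndarray:
        return self.derived_counts / self.n_haplotypes

    # -- manipulation ---------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "HaplotypeMatrix":
        """Subset columns (bool mask or integer index), keeping order."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HaplotypeMatrix(
            entries=self.entries[:, idx],
            sites=self.sites.iloc[idx].reset_index(drop=True),
            pool_id=self.pool_id,
            polarized=self.polarized,
            haplotype_labels=list(self.haplotype_labels),
        )

    def site_records(self) -> list[SiteRecord]:
        counts = self.derived_counts
        return [
            SiteRecord(
                chrom=row.chrom,
                pos0=int(row.pos0),
                ref_allele=row.ref,
                alt_allele=row.alt,
                ancestral_allele=row.aa,
                derived_count=int(counts[i]),
                n_haplotypes=self.n_haplotypes,
            )
            for i, row in enumerate(self.sites.itertuples(index=False))
        ]


def make_sites(
    chrom,
    pos0,
    ref=None,
    alt=None,
    aa=None,
) -> pd.DataFrame:
    """Assemble a site table; scalar ``chrom`` is broadcast."""
    pos0 = np.asarray(pos0, dtype=np.int64)
    n = len(pos0)
    def _col(x, default):
        if x is None:
            return [default] * n
        return list(x)
    return pd.DataFrame(
        {
            "chrom": [chrom] * n if np.isscalar(chrom) else list(chrom),
            "pos0": pos0,
            "ref": _col(ref, "A"),
            "alt": _col(alt, "T"),
            "aa": _col(aa, None),
        }
    )
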