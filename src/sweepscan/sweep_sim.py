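"""Forward-in-time Wright–Fisher haplotype simulator with recombination.

This is the package's synthetic-data generator.  It emulates the structure of
the scan input — phased biallelic SNVs with known ancestral alleles over a
multi-megabase region, for pools of a few dozen haplotypes — under three
regimes: a neutral null, a hard selective sweep with a known favored site
conditioned to reach a target frequency, and a two-deme island model for the
differentiation (Fst) statistics.

Model choices (deliberately minimal — the consuming statistics see only
haplotypes):

* haploid reproduction, fitness 1 + s per favored-allele copy;
* single-crossover recombination: each offspring recombines with probability
  ``min(1, rho * region_bp)``, at a uniform breakpoint;
* infinite-sites mutation at unique uniform bp positions, Poisson
  ``mu * region_bp`` per genome per generation; fixed and lost sites are
  pruned (they leave no trace in a VCF of segregating sites);
* sweeps start from a single de-novo copy and are retried from the same
  standing variation until the favored allele reaches the target frequency;
* the two-deme mode splits one burn-in population into two demes of the full
  size each, exchanging migrants at a per-generation fraction ``m``, so the
  equilibrium differentiation follows E[Fst] = 1 / (1 + 4 N m).

The default scale (200 haploids, ~2 Mb, mu tuned to ~10^3–10^4 segregating
sites in a 20-haplotype sample) runs in seconds per replicate on one CPU;
population-scaled rates stand in for genome-scale diversity that desk-scale
N cannot otherwise reach.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import HaplotypeMatrix, make_sites

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class TwoPopParams:
    """Island-model mode: generations simulated after the split, and the
    per-generation fraction of individuals whose parent is drawn from the
    other deme."""

    split_generations: int
    migration: float


@dataclass
class SweepSimParams:
    pop_size_haploid: int = 200
    region_bp: int = 2_000_000
    mu: float = 5e-7  # per bp per generation (population-scaled)
    rho: float = 5e-7  # per bp per generation per meiosis; default mu/rho = 1
    s: float = 0.0
    favored_pos: int | None = None  # defaults to the region midpoint in sweep mode
    favored_final_freq: float = 0.7
    sample_haplotypes: int = 20  # per deme in two-pop mode
    seed: int = 0
    burn_in_generations: int | None = None  # defaults to 8 * pop_size_haploid
    sweep_retry_budget: int = 1000
    sweep_generation_cap: int | None = None  # defaults to max(600, 40/s)
    standing_variants: list | None = None  # [(pos_bp, freq), ...] seeded at start
    p_ref_is_derived: float = 0.2  # fraction of sites where the VCF REF is the derived base
    two_pop: TwoPopParams | None = None

    def __post_init__(self) -> None:
        if self.sample_haplotypes > self.pop_size_haploid:
            raise ValueError("sample_haplotypes exceeds pop_size_haploid")
        if not 0.0 <= self.favored_final_freq <= 1.0:
            raise ValueError("favored_final_freq outside [0, 1]")
        if min(self.mu, self.rho) < 0 or self.region_bp <= 0:
            raise ValueError("rates must be >= 0 and region_bp > 0")

    @property
    def burn_in(self) -> int:
        return (
            self.burn_in_generations
            if self.burn_in_generations is not None
            else 8 * self.pop_size_haploid
        )


@dataclass
class SimTruth:
    favored_pos: int | None = None
    favored_site_index: int | None = None  # column in the sampled matrix, if segregating
    favored_trajectory: list = field(default_factory=list)  # per-generation pop frequency
    favored_sample_freq: float | None = None
    pop_labels: list = field(default_factory=list)  # per sampled haplotype
    ancestral_alleles: list = field(default_factory=list)  # per emitted site
    standing_final_freqs: list = field(default_factory=list)
    n_retries: int = 0

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "favored_pos": self.favored_pos,
                    "favored_site_index": self.favored_site_index,
                    "favored_trajectory": self.favored_trajectory,
                    "favored_sample_freq": self.favored_sample_freq,
                    "pop_labels": self.pop_labels,
                    "ancestral_alleles": self.ancestral_alleles,
                    "standing_final_freqs": self.standing_final_freqs,
                    "n_retries": self.n_retries,
                },
                fh,
                indent=1,
            )


class SweepNotAchievedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

class _State:
    __slots__ = ("pop", "positions")

    def __init__(self, pop: np.ndarray, positions: np.ndarray):
        self.pop = pop  # (n_rows, n_seg_sites) uint8
        self.positions = positions  # int64, strictly increasing

    def copy(self) -> "_State":
        return _State(self.pop.copy(), self.positions.copy())

    def freq_at(self, pos: int) -> float:
        j = np.searchsorted(self.positions, pos)
        if j < len(self.positions) and self.positions[j] == pos:
            return float(self.pop[:, j].sum()) / self.pop.shape[0]
        return 0.0


def _choose_parents(rng, rows: np.ndarray, size: int, s: float, fav: np.ndarray | None) -> np.ndarray:
    """Indices into `rows` of `size` parents, fitness 1 + s per favored copy."""
    if s == 0.0 or fav is None:
        return rows[rng.integers(0, len(rows), size)]
    w = 1.0 + s * fav[rows]
    return rows[rng.choice(len(rows), size, p=w / w.sum())]


def _generation(state: _State, rng, params: SweepSimParams, demes: list[np.ndarray],
                migration: float, select: bool,
                protect: np.ndarray | None = None) -> _State:
    """One discrete Wright–Fisher generation over all demes."""
    pop, positions = state.pop, state.positions
    n_rows = pop.shape[0]
    L = params.region_bp
    p_rec = min(1.0, params.rho * L)

    fav = None
    if select and params.favored_pos is not None:
        j = np.searchsorted(positions, params.favored_pos)
        if j < len(positions) and positions[j] == params.favored_pos:
            fav = pop[:, j].astype(np.float64)

    parent1 = np.empty(n_rows, dtype=np.int64)
    parent_deme = np.empty(n_rows, dtype=np.int64)
    for d, rows in enumerate(demes):
        src = np.full(len(rows), d)
        if len(demes) == 2 and migration > 0.0:
            src[rng.random(len(rows)) < migration] = 1 - d
        parent_deme[rows] = src
        for sd in np.unique(src):
            sel = rows[src == sd]
            parent1[sel] = _choose_parents(rng, demes[sd], len(sel), params.s if select else 0.0, fav)

    child = pop[parent1]

    if p_rec > 0.0 and positions.size:
        rec = np.flatnonzero(rng.random(n_rows) < p_rec)
        if rec.size:
            cuts = np.searchsorted(positions, rng.integers(0, L, rec.size))
            parent2 = np.empty(rec.size, dtype=np.int64)
            pd_rec = parent_deme[rec]
            for sd in range(len(demes)):
                sel = pd_rec == sd
                if sel.any():
                    parent2[sel] = _choose_parents(
                        rng, demes[sd], int(sel.sum()), params.s if select else 0.0, fav
                    )
            for t in range(rec.size):
                c = cuts[t]
                child[rec[t], c:] = pop[parent2[t], c:]

    n_mut = rng.poisson(params.mu * L * n_rows)
    cand = np.empty(0, dtype=np.int64)
    owners = np.empty(0, dtype=np.int64)
    if n_mut:
        cand = np.unique(rng.integers(0, L, n_mut))
        if positions.size:
            cand = cand[~np.isin(cand, positions, assume_unique=True)]
        owners = rng.integers(0, n_rows, cand.size)

    # drop fixed/lost columns and splice in the new mutations in one rebuild
    counts = child.sum(axis=0, dtype=np.int64)
    keep = (counts > 0) & (counts < n_rows)
    if protect is not None and positions.size:
        # tracked sites (favored, standing variants) stay visible even when
        # absorbed, so their final frequencies (0 or 1) remain observable
        j = np.searchsorted(positions, protect)
        ok = (j < positions.size) & (positions[np.minimum(j, positions.size - 1)] == protect)
        keep[j[ok]] = True
    kept_idx = np.flatnonzero(keep)
    all_pos = np.concatenate([positions[kept_idx], cand])
    src = np.concatenate([kept_idx, -1 - np.arange(cand.size)])  # negative = new column
    order = np.argsort(all_pos, kind="mergesort")
    all_pos = all_pos[order]
    src = src[order]
    out = np.empty((n_rows, src.size), dtype=np.uint8)
    old_sel = src >= 0
    out[:, old_sel] = child[:, src[old_sel]]
    new_cols = np.flatnonzero(~old_sel)
    if new_cols.size:
        out[:, new_cols] = 0
        out[owners[-1 - src[new_cols]], new_cols] = 1
    return _State(out, all_pos)


def _seed_standing(params: SweepSimParams, rng) -> _State:
    n = params.pop_size_haploid
    if not params.standing_variants:
        return _State(np.zeros((n, 0), dtype=np.uint8), np.empty(0, dtype=np.int64))
    entries = []
    pos = []
    for p_bp, freq in sorted(params.standing_variants):
        col = np.zeros(n, dtype=np.uint8)
        k = int(round(freq * n))
        col[rng.choice(n, k, replace=False)] = 1
        entries.append(col)
        pos.append(p_bp)
    return _State(np.column_stack(entries), np.asarray(pos, dtype=np.int64))


def _run_sweep_phase(state: _State, rng, params: SweepSimParams, demes) -> tuple[_State, list, int]:
    """Introduce the favored allele and select until it reaches the target
    frequency; retry from the same standing variation within the budget."""
    fav_pos = params.favored_pos if params.favored_pos is not None else params.region_bp // 2
    params.favored_pos = fav_pos
    cap = params.sweep_generation_cap or max(600, int(40.0 / params.s))
    tracked = sorted({p for p, _ in (params.standing_variants or [])} | {fav_pos})
    protect = np.asarray(tracked, dtype=np.int64)
    base = state
    for attempt in range(params.sweep_retry_budget):
        st = base.copy()
        # de-novo favored mutation on one random haplotype
        j = np.searchsorted(st.positions, fav_pos)
        if j < len(st.positions) and st.positions[j] == fav_pos:
            st.positions = np.delete(st.positions, j)  # evict a colliding neutral site
            st.pop = np.delete(st.pop, j, axis=1)
            j = np.searchsorted(st.positions, fav_pos)
        col = np.zeros(st.pop.shape[0], dtype=np.uint8)
        col[rng.integers(0, st.pop.shape[0])] = 1
        st = _State(
            np.insert(st.pop, j, col, axis=1),
            np.insert(st.positions, j, fav_pos),
        )
        traj = [1.0 / st.pop.shape[0]]
        for _ in range(cap):
            st = _generation(st, rng, params, demes, 0.0, select=True, protect=protect)
            f = st.freq_at(fav_pos)
            traj.append(f)
            if f == 0.0:
                break
            if f >= params.favored_final_freq:
                return st, traj, attempt
    raise SweepNotAchievedError(
        f"favored allele failed to reach {params.favored_final_freq} within "
        f"{params.sweep_retry_budget} attempts"
    )


def simulate(params: SweepSimParams) -> tuple[HaplotypeMatrix, pd.DataFrame, SimTruth]:
    """Run the simulator; returns the sampled, derived-coded haplotype matrix
    (columns segregating in the sample only), its site table, and the truth.
    Deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n = params.pop_size_haploid
    truth = SimTruth()

    state = _seed_standing(params, rng)
    tracked = np.asarray(sorted(p for p, _ in (params.standing_variants or [])), dtype=np.int64)
    protect = tracked if tracked.size else None
    demes = [np.arange(n)]
    for _ in range(params.burn_in):
        state = _generation(state, rng, params, demes, 0.0, select=False, protect=protect)

    if params.two_pop is not None:
        # split: both demes draw their first post-split parents from the
        # ancestral pool, then evolve side by side with migration
        state = _State(np.vstack([state.pop, state.pop]), state.positions)
        demes = [np.arange(n), np.arange(n, 2 * n)]
        for _ in range(params.two_pop.split_generations):
            state = _generation(state, rng, params, demes, params.two_pop.migration,
                                select=False, protect=protect)

    if params.s > 0.0:
        if params.two_pop is not None:
            raise ValueError("sweep mode and two-pop mode are mutually exclusive")
        state, traj, retries = _run_sweep_phase(state, rng, params, demes)
        truth.favored_pos = params.favored_pos
        truth.favored_trajectory = [float(x) for x in traj]
        truth.n_retries = retries

    if params.standing_variants:
        truth.standing_final_freqs = [state.freq_at(p) for p, _ in sorted(params.standing_variants)]

    # ---- sample haplotypes -------------------------------------------
    rows = []
    labels = []
    for d, deme_rows in enumerate(demes):
        pick = rng.choice(deme_rows, params.sample_haplotypes, replace=False)
        rows.append(np.sort(pick))
        labels += [f"pop{d + 1}"] * params.sample_haplotypes
    sample = state.pop[np.concatenate(rows)]
    counts = sample.sum(axis=0, dtype=np.int64)
    seg = (counts > 0) & (counts < sample.shape[0])
    sample = sample[:, seg]
    positions = state.positions[seg]

    # ---- allele bases -------------------------------------------------
    m = positions.size
    anc_idx = rng.integers(0, 4, m)
    der_idx = (anc_idx + rng.integers(1, 4, m)) % 4
    anc, der = _BASES[anc_idx], _BASES[der_idx]
    ref_is_derived = rng.random(m) < params.p_ref_is_derived
    ref = np.where(ref_is_derived, der, anc)
    alt = np.where(ref_is_derived, anc, der)
    sites = make_sites("1", positions, ref=ref, alt=alt, aa=anc)
    # the matrix itself is derived-coded: in the derived encoding ref/alt name
    # the ancestral and derived bases
    sites_derived = sites.copy()
    sites_derived["ref"] = anc
    sites_derived["alt"] = der

    if truth.favored_pos is not None:
        j = int(np.searchsorted(positions, truth.favored_pos))
        if j < m and positions[j] == truth.favored_pos:
            truth.favored_site_index = j
            truth.favored_sample_freq = float(counts[seg][j]) / sample.shape[0]
    truth.pop_labels = labels
    truth.ancestral_alleles = [str(b) for b in anc]

    n_samples = sample.shape[0] // 2
    matrix = HaplotypeMatrix(
        entries=sample,
        sites=sites_derived,
        pool_id="sim",
        polarized=True,
        haplotype_labels=[f"{labels[2 * i]}_s{i:03d}_{h}" for i in range(n_samples) for h in "AB"],
    )
    matrix.sites.attrs["vcf_ref"] = ref
    matrix.sites.attrs["vcf_alt"] = alt
    return matrix, sites, truth


# ---------------------------------------------------------------------------
# VCF emission
# ---------------------------------------------------------------------------

def emit_vcf(
    matrix: HaplotypeMatrix,
    sites: pd.DataFrame,
    truth: SimTruth,
    out_path: str,
    contig_length: int | None = None,
) -> None:
    """Write the sampled haplotypes as a phased VCF with INFO/AA truth.

    ``sites`` carries the VCF REF/ALT orientation (REF may be the derived
    base); the matrix is derived-coded, so genotypes are recoded against REF.
    Diploid samples pair consecutive haplotypes.  Output is deterministic:
    identical inputs give byte-identical files.  A ``.gz`` path is
    bgzip-compressed and tabix-indexed.
    """
    n_hap = matrix.n_haplotypes
    if n_hap % 2:
        raise ValueError("need an even number of haplotypes to form diploids")
    n_samples = n_hap // 2
    labels = truth.pop_labels or ["pop1"] * n_hap
    sample_names = [f"{labels[2 * i]}_s{i:03d}" for i in range(n_samples)]
    if contig_length is None:
        contig_length = int(sites["pos0"].max()) + 2 if len(sites) else 1

    aa = sites["aa"].to_numpy()
    ref = sites["ref"].to_numpy()
    gt_is_ref_anc = ref == aa  # else REF is the derived base and coding flips

    header = [
        "##fileformat=VCFv4.2",
        "##source=sweepscan-sim",
        f"##contig=<ID=1,length={contig_length}>",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names),
    ]
    plain_path = out_path[:-3] if out_path.endswith(".gz") else out_path
    with open(plain_path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        X = matrix.entries
        for j in range(len(sites)):
            row = sites.iloc[j]
            col = X[:, j] if gt_is_ref_anc[j] else 1 - X[:, j]
            gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_samples))
            fh.write(
                f"1\t{int(row.pos0) + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"AA={aa[j]}\tGT\t{gts}\n"
            )
    if out_path.endswith(".gz"):
        import pysam

        pysam.tabix_compress(plain_path, out_path, force=True)
        pysam.tabix_index(out_path, preset="vcf", force=True)
        import os

        os.remove(plain_path)
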