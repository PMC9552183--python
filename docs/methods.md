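# Methods

This note documents the statistical procedures implemented in `sweepscan`,
the assumptions behind them, the tunable parameters and their defaults, what
the bundled simulator does and does not emulate, and the package's known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Input model

All statistics consume a fully phased haplotype-by-site 0/1 matrix per pool,
derived from a biallelic-SNV VCF with an `INFO/AA` ancestral-allele tag.
Polarization recodes 1 = derived: columns whose AA equals ALT are
bit-flipped (ref/alt roles swap), columns with missing or third-allele AA are
dropped and counted, and columns monomorphic *within the pool* are dropped
because every within-pool statistic is undefined at derived frequency 0 or 1.
The AA comparison is case-insensitive: lower-case calls (the usual encoding
of low-confidence ancestral states) are accepted. No missingness is
tolerated — an unphased or missing genotype is a hard error naming the sample
and position, since silently imputing would fabricate haplotype structure.

Internally all coordinates are 0-based half-open; VCF (1-based) and GFF
(1-based closed) conventions are converted at the I/O boundary. Genome
windows and chunks are anchored at coordinate 0.

## SAFE and iSAFE

Definitions are given in the README. Implementation decisions that the
one-line definitions leave open:

* **Normalization.** The SAFE denominator is `sqrt(f(1-f))`, the
  variance-normalized form of the statistic; a `denominator="linear"` switch
  divides by `f(1-f)` instead for comparison.
* **Distinctness.** Haplotypes are distinct iff their HAF scores differ;
  HAF ties collapse to one distinct haplotype. This is the literal "distinct
  by HAF" convention; with more than a few dozen segregating sites ties are
  rare and `k(e)` approaches the carrier fraction.
* **Insertion semantics.** `ψ(e,w)` for a site outside window *w* is
  computed by appending *e*'s column to *w*'s submatrix and recomputing HAF,
  carriers, φ and k within that augmented window (frequency *f* is the
  sample-wide frequency of *e*, a property of the site, not of the window).
  For *e* inside *w* the plain within-window SAFE is used — the column is
  never counted twice.
* **δ and α.** Each window contributes its argmax-SAFE site to δ (lowest
  position wins ties, making output deterministic); δ is de-duplicated before
  the window weights α are formed, so a site topping two overlapping windows
  is not double-weighted. If every SAFE score in a chunk is non-positive all
  iSAFE scores are 0 (no normalizable window mass).
* **Windows.** Half-overlapped windows of 300 SNPs (step 150). A trailing
  partial window is retained rather than dropped so chunk edges are covered.
  Chunks ≤ 300 SNPs reduce to a single window and `iSAFE = max(0, SAFE)`.
* **Chunking.** Genome scans partition each chromosome into non-overlapping
  4-Mb chunks; requesting chunks above the method's 5-Mb specified span is an
  error. Sweeps at chunk boundaries remain detectable in the adjacent chunk
  because every chunk is scored independently.

## EHH, iHH, iHS

EHH at marker *x* for a core allele is the probability that two random
carriers are identical over the stretch core→*x*:
`Σ_g C(n_g,2) / C(n_core,2)` over the identity groups *g*. Numerical policy:

* curves start at the core with EHH = 1 and are truncated once EHH drops
  below `ehh_cutoff` (default **0.05**); the first sub-cutoff point is kept,
  so the final decay segment contributes to the integral;
* physical gaps above `max_gap_bp` (default **200 kb**) terminate the
  extension on that side — otherwise unmodelled recombination deserts
  dominate the integral;
* no extrapolation beyond the last computed marker;
* iHH is the trapezoidal integral over genetic distance with a flat map of
  `map_rate_cm_per_mb` (default **1 cM/Mb**, the conventional stand-in when
  no genetic map is available).

Sites enter the iHS scan when the derived frequency lies in
`[maf_min, 1 − maf_min]` (default **0.05**); sites where either core allele
has fewer than 2 carriers, or where either integral is zero, are flagged with
a reason code and excluded from standardization. The classical
frequency-bin standardization is available (`standardize_by_frequency`) but
is **off** in the pipeline: the default significance path standardizes raw
iHS genome-wide, which preserves the sign convention (positive = long derived
haplotypes) and matches a single genome-wide mean ± SD per pool. The inner
loops are numba-compiled; the test suite checks them against a brute-force
pairwise-identity oracle.

## Weir–Cockerham Fst

Per-site 1984 variance components for two pools are computed from diploid
sample sizes, allele frequencies and observed heterozygote proportions;
diploids are reconstituted by pairing consecutive haplotype rows (the two
phased haplotypes of each sample). `θ = a/(a+b+c)`, undefined where the
denominator is ≤ 0 (e.g. both pools fixed for the same allele); undefined
sites are excluded from windows. Negative per-site estimates are retained
unclamped. Windows tile chromosomes at 10 kb; both the unweighted mean of
per-site θ (the default aggregate carried into the significance step, the
literal "averaged" reading) and the weighted ratio of sums Σa/Σ(a+b+c) are
emitted — the weighted form is the better-behaved estimator for sparse
windows and is the one compared against island-model theory in the tests.
Allele orientation is irrelevant (θ is label-swap invariant), so Fst runs on
unpolarized matrices.

## Significance

Each track (one pool, one test) is standardized by its own genome-wide
moments — one mean and SD across all chromosomes jointly — and converted to
one-sided upper-tail p-values of the standard normal (survival function).
"Right-tail density" is deliberately read as the upper-tail *probability*:
a density value is not a probability; a strict-density mode exists behind a
flag for forensic comparison only. p-values are floored at 1e-300 before the
log transform and flagged when floored. The genome-wide threshold is
`−log₁₀(p) ≥ 7.301` (inclusive), i.e. p ≤ 5.00×10⁻⁸, corresponding to
z ≈ 5.326. The rule is one-sided: strongly negative scores (long ancestral
haplotypes under iHS) are never flagged. Gene annotation is plain interval
overlap against BED (0-based half-open) or GFF3 `gene` features (1-based
closed), auto-detected by extension and overridable.

## The simulator: what it emulates, and what it does not

Forward-in-time haploid Wright–Fisher with single-crossover recombination
(probability `min(1, ρ·L)` per meiosis, uniform breakpoint), infinite-sites
mutation at unique bp positions, fitness `1 + s` per favored-allele copy,
retry-based conditioning of sweeps on reaching the target frequency (budget
1000, from the same standing variation), and a two-deme island mode (one
burn-in population split into two full-size demes exchanging a fraction *m*
of parents per generation). Diploids exist only at VCF emission, where
consecutive haplotypes are paired; the VCF carries the true ancestral base in
`INFO/AA`, and the REF allele is the derived base at a random 20% of sites so
that polarization is genuinely exercised.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `pop_size_haploid` | 200 | largest N whose 8N-generation burn-in runs in seconds per replicate on one CPU |
| `region_bp` | 2 Mb | mid-range of the 1–4 Mb scan-chunk scale |
| `mu` | 5×10⁻⁷ /bp/gen | population-scaled so a 20-haplotype sample segregates ~1.4×10³ sites over 2 Mb (the 10³–10⁴ working band) |
| `rho` | 5×10⁻⁷ /bp/gen | μ/ρ = 1, the genome-wide mammalian ratio (~1e-8 each); also the largest ρ for which the single-crossover model is internally consistent (ρ·L = 1) |
| burn-in | 8 N generations | several coalescent timescales past the ~2N expected TMRCA |
| `favored_final_freq` | 0.7 | intermediate-to-high frequency, the regime the favored-site ranking targets |
| `p_ref_is_derived` | 0.2 | minority of sites where a reference genome carries the derived allele |

The generator emulates: equilibrium neutral diversity (the site-frequency
spectrum tests against the 1/i expectation), drift (frequency martingale),
hard-sweep haplotype structure with a known driver, island-model
differentiation matching `1/(1+4Nm)` (for two haploid demes of size N,
within-deme pair coalescence time is 2N and between-deme pairs add 1/(2m),
giving exactly that equilibrium Fst). It does **not** emulate: demographic
history (bottlenecks, growth, admixture — all present in real cattle),
variable recombination/mutation maps, gene conversion, background selection,
genotyping/phasing error, or genome-scale contiguity. A green test therefore
establishes correctness of the statistics on idealized equilibrium input,
not robustness to real-data pathologies.

**Scaling caveat (important).** Desk-scale forward simulation forces
population-scaled per-generation rates while the selection coefficient is
used unscaled. Two consequences: the effective selection strength is
α = 2Ns = 20 at the defaults (a weak-to-moderate sweep; published sweep
benchmarks typically sit at α in the hundreds), and sweeps last hundreds of
generations during which the scaled mutation process deposits young variants
on the sweeping haplotypes — noise that real (unscaled) populations do not
produce at this magnitude. The μ/ρ = 1 default keeps that artifact at its
realistic relative size, but it cannot remove the α limitation.

## Known limitations

* **Favored-site localization at 20 haplotypes.** With pools of 20
  haplotypes and α = 2Ns = 20, the favored site's iSAFE rank lands in the
  top few percent of sites, not the absolute top-20: intra-sweep hitchhikers
  sharing most of the favored site's carrier set are statistically almost
  indistinguishable at this sample size, and the statistic's power declines
  as the favored allele's *sample* frequency (binomially dispersed around
  the conditioning target with SD ≈ 0.10) approaches fixation. The
  acceptance suite states the strong top-20 claim as written and records the
  achieved proportions as frozen regression baselines; iSAFE does localize
  the driver more often than raw SAFE, and more tightly (lower rank) in the
  clear majority of replicates.
* One-sided significance means sweeps on the *ancestral* allele's background
  are invisible by design.
* The iSAFE candidate list δ holds one site per window; richer candidate
  sets (top-k per window) are not implemented.
* Fst is strictly two-pool; multi-population estimators and haplotype-based
  differentiation are out of scope.
* The flat 1 cM/Mb map makes iHH values comparable only within a run; real
  map variation would require an external genetic map, which the interface
  does not currently accept.
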