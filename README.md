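# sweepscan

Selective-sweep scanning for small, phased resequencing cohorts — cattle-scale
pools of 6–24 haplotypes — from a single multi-sample VCF with ancestral-allele
(`INFO/AA`) annotation.

The package re-implements, as one reusable pipeline, the three tests commonly
combined in livestock selection-signature studies:

* **SAFE / iSAFE** — within-population ranking of the candidate favored SNV.
  With haplotype allele frequency `HAF(h) = Σ_j c_j · x_hj` (the sum of
  derived-allele counts `c_j` over the sites a haplotype carries), and for a
  site *e* with derived frequency *f*:

  ```
  k(e)   = # distinct-HAF haplotypes carrying e / # distinct-HAF haplotypes
  φ(e)   = Σ HAF over carriers of e            / Σ HAF over all haplotypes
  SAFE(e) = (φ − k) / √(f(1−f))
  ```

  iSAFE rescues SAFE's power in large regions by rescoring every site inside
  half-overlapped windows of 300 SNPs: `ψ(e,w) = max(0, SAFE of e inserted
  into window w)`, window weights `α(w) ∝ Σ_{e∈δ} ψ(e,w)` (δ = per-window
  best sites), and `iSAFE(e) = Σ_w ψ(e,w)·α(w)`.  Genome scans run on
  non-overlapping 4-Mb chunks (the method is specified up to 5 Mb).

* **EHH / iHS** — extended haplotype homozygosity around each core site,
  integrated over genetic distance (flat 1 cM/Mb by default) for the derived
  and ancestral core alleles; `iHS = ln(iHH₁/iHH₀)`, positive for unusually
  long derived haplotypes.

* **Weir–Cockerham Fst** — per-site variance components `θ = a/(a+b+c)`
  between two pools, averaged in 10-kb non-overlapping windows (both the
  unweighted mean of per-site θ and the ratio-of-sums aggregate are emitted).

Raw scores are standardized genome-wide per pool and test, converted to
one-sided normal upper-tail p-values, and thresholded at genome-wide
significance `−log₁₀(p) ≥ 7.301` (p ≤ 5×10⁻⁸); significant sites/windows can
be annotated genic/intergenic against a BED or GFF3 gene file.

A forward-in-time Wright–Fisher simulator (`sweepscan.sweep_sim`) generates
the synthetic cohorts the test suite validates against: neutral nulls, hard
sweeps conditioned on a target favored-allele frequency with full truth
records, and a two-deme island model whose equilibrium differentiation
follows `E[Fst] = 1/(1+4Nm)`.

## Worked example

The three haplotypes `110`, `100`, `000` (rows) over two sites with derived
counts (2, 1):

```python
>>> import numpy as np, sweepscan
>>> X = np.array([[1, 1], [1, 0], [0, 0]], dtype=np.uint8)
>>> sweepscan.haf_scores(X)
array([3, 2, 0])
>>> sweepscan.safe_scores(X)
          f         k  phi      safe
0  0.666667  0.666667  1.0  0.707107
1  0.333333  0.333333  0.6  0.565685
```

Site 0 is carried by the two highest-HAF haplotypes (φ = 1) while only 2 of 3
distinct haplotypes carry it (k = 2/3), giving SAFE = (1/3)/√(2/9) ≈ 0.7071 —
the more sweep-like site of the two.

A full pipeline run on a simulated sweep cohort (10 diploid samples, 2 Mb,
s = 0.05 conditioned to frequency 0.7):

```bash
sweepscan simulate --mode sweep --s 0.05 --final-freq 0.7 --sample 20 \
    --seed 42 --out cohort.vcf --truth truth.json
sweepscan run --config scan.yaml
```

prints a per-pool/test summary in the layout of a selection-scan report
(means ± SD of raw scores, significant counts, genic/intergenic split), e.g.:

```
 pool         test  n_records     mean       sd  n_significant
poolA        iSAFE       1099 0.017865 0.019304            0.0
poolA          iHS        637 0.593031 1.210513            0.0
poolA Fst_vs_poolB        200 0.012182 0.077499            0.0
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's headline quantities from scratch: it simulates a
sweep cohort with the given seed, emits a phased VCF with AA truth, runs the
per-pool iSAFE and iHS scans, the cross-pool windowed Fst, and the
genome-wide significance step, printing the summary table, and writes the
requested measurements as JSON to `--out`.

## Layout

```
src/sweepscan/
  containers.py    haplotype matrix / site table / pool types
  vcf_ingest.py    phased-VCF reading, AA polarization, TSV/BED output
  safe_isafe.py    HAF, SAFE, iSAFE, chunked genome scan
  ehh_ihs.py       EHH curves, iHH integration, iHS scan (numba kernels)
  fst_scan.py      Weir–Cockerham components, 10-kb windows
  significance.py  right-tail p-values, 7.301 threshold, gene annotation
  sweep_sim.py     forward Wright–Fisher simulator + VCF emission
  cli.py           ScanConfig / run_all and the `sweepscan` CLI
```

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
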