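# Methods

## Model and procedure

hijackscan scores each expressed gene for evidence that a structural
rearrangement has repositioned an active enhancer into its regulatory
neighborhood in at least one sample of a cohort. The unit of evidence is the
(gene, candidate sample) pair; candidacy is purely geometric (a breakend in
the gene's extended TAD, or within a fallback window), and the score is a
weighted sum of four components described in the README. The design
assumptions are:

- enhancer–promoter contacts are confined to TADs, so TAD co-membership
  after the rearrangement is a usable proxy for regulatory contact;
- true events produce *strong* overexpression relative to samples without
  nearby breakpoints, typically from one allele only;
- amplification-driven overexpression is a dosage effect and is removed by
  the 2/CN correction before outlier scoring;
- each breakend pair can be interpreted independently. Complex nested
  rearrangements (chromothripsis with clustered breakpoints) can route an
  enhancer through several junctions; those paths are not traversed, which
  can miss enhancers (the score is then conservative for such events).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `w_overexpression, w_ase, w_enhancer, w_deletion` | 4, 2, 1, 1 | component weights in the combined score |
| `tad_extension_bp` | 80,000 | pad around TADs, absorbing imprecise boundary calls |
| `fallback_window_bp` | 1,500,000 | gene-centered search window when no TAD overlaps; also caps enhancer traversal without a boundary |
| `min_tpm_expressed` | 1 | a gene is considered only if some sample exceeds this TPM |
| `sigma_floor` | 0.3 | added to the reference SD so uniform reference expression cannot produce unbounded t |
| `ase_cn_low / ase_cn_high` | 2 / 4 | outside this CN range allelic fractions are uninformative and S_ase = 0 |
| `bb_concentration` | 10 | beta-binomial concentration s (α = p·s, β = (1−p)·s) shared by all three mixture components |
| `mono_means / bi_mean` | 0.02, 0.98 / 0.5 | component means of the monoallelic mixture and the biallelic model |
| `llr_clamp` | 20 | per-SNP cap so one ultra-deep SNP cannot dominate |
| `deletion_cn_threshold` | 1.5 | "gene deleted" operationalized as CN below this (covers integer CN ≤ 1 and subclonal losses) |
| `min_reference_samples` | 5 | genes with fewer references are skipped; μ and σ would be unstable |
| `niter` | 50 | null resampling iterations; null size = niter × n(null-eligible genes) |

Natural logarithms are used throughout; any other base would only rescale
scores jointly with the weights, and ln keeps the −2 ln 3 anchor at t = 0
conventional. Sums written over n SNPs or n enhancers have exactly n terms.

## Numerical and procedural choices

- **Coordinates.** Intervals are 0-based half-open (BED); breakend and SNP
  positions are 1-based (VCF). Conversion happens once at read time.
  Chromosome names are normalized (`chr` stripped, X/Y/MT upper-cased).
- **Reference distribution.** μ and σ are the mean and *population* SD
  (divisor n) of ln(0.5 + CN-corrected TPM) over reference samples. With the
  +0.3 floor the estimator choice is immaterial in practice; it is fixed for
  reproducibility.
- **Gene copy number** is that of the maximally overlapping segment (not a
  length-weighted mean — robust to segment fragmentation), 2 when uncovered,
  ties broken toward the leftmost segment. The 2/CN denominator is floored
  at 1 so CN = 0 calls cannot blow up the correction. Fractional CN calls
  are used as-is.
- **ASE.** The mixture weights are ½/½, keeping the llr symmetric in
  (ref, alt). Records with zero total coverage are dropped; duplicate SNP
  rows are collapsed by summing. Genes with no usable SNPs score S_ase = 0,
  which does not preclude detection through the other components.
- **Enhancer traversal.** For a qualifying junction (one end in the gene's
  search region with the gene body on its retained flank, partner end
  outside), enhancers are collected on the partner's retained flank from the
  junction to the first TAD boundary in that direction (derivative-TAD
  proxy), capped at `fallback_window_bp` when no boundary exists. Enhancers
  inside the gene's own search region never count (no self-hijack), and each
  enhancer counts once across junctions. Unknown breakend orientation is
  resolved by trying both flanks and taking the union (conservative toward
  sensitivity).
- **Null and p-values.** Pseudo-candidates are scored with the full stack:
  overexpression against the remaining references, their observed ASE and
  deletion status, enhancer 0 (they carry no qualifying breakends by
  construction). Genes enter the null only if 3 pseudo-candidates still
  leave ≥ `min_reference_samples` references. The null pool is shared across
  genes. p-values use the add-one convention (1 + #{null ≥ obs})/(1 + N), so
  p > 0 always and BH is well defined; ties count toward the numerator.
  Aggregation sums all candidate scores, including negative ones, as the
  gene formula states. One master seed; per-iteration generators derive from
  (seed, iteration), so the stage is bit-reproducible and order-independent.
- **BH** is implemented as the definitional step-up min-over-suffix, capped
  at 1, applied only to genes with ≥ 1 true candidate (only these are
  tested).
- **Reporting.** Ordering is total and deterministic (FDR, then score
  descending, then gene_id). The FDR threshold (default 0.2) controls only
  the `significant` flag. The manifest excludes timestamps, so identical
  inputs + seed give byte-identical outputs.

## Synthetic cohorts

The simulator tiles a 4-chromosome genome into ~1 Mb TADs (one gene per
TAD, plus donor TADs used by injections) and emulates:

- log-normal baseline expression with per-sample noise; ~30% of genes
  silent (noise < 0.5 TPM) — the prerequisite state for a detectable
  hijacking event;
- **hijack injections**: a silent gene gains TPM 100–200 in one sample, a
  gene-retaining junction into an enhancer-bearing donor TAD (enrichment
  ≥ 5), and monoallelic allelic counts (2 SNPs × 30 reads, 97% major
  allele);
- **amplification decoys**: CN 6 segments with 3× expression and balanced
  alleles. They carry no junctions — they model dosage-driven
  overexpression contaminating the reference pool, which the 2/CN
  correction must neutralize (their t-values are pulled toward 0);
- **breakpoint decoys**: in-TAD junctions with unchanged expression, in 1–3
  samples per decoy gene, matching the 1–3 pseudo-candidate multiplicity of
  the null resampler so observed and resampled aggregations are
  exchangeable under the null;
- balanced (biallelic) allelic counts on all other expressed gene/sample
  pairs.

Default sizes (30 samples × 200 genes; 300 × 40 for the null-calibration
cohort) keep a full scan with niter = 50 in the low seconds on one CPU while
leaving ≥ 250 tested genes for the uniformity check.

What passing these tests does *not* show: real cohorts have unequal SNP
coverage and density, subclonal copy number, clustered/complex breakpoints,
TADs from a non-matching cell type, and expression dispersion that varies
per gene — none of which the generator emulates. Recovery rates on the
synthetic cohorts are upper bounds on real-data sensitivity.

## Known limitations

- A candidate pair whose ASE is gated to 0 (e.g. CN > 4) competes against a
  pooled null whose pseudo-candidates mostly carry negative biallelic ASE;
  in cohorts with dense allelic coverage this can make such genes look
  anti-conservatively significant despite negative scores. Inspect the
  per-sample component table before trusting a hit whose ASE was gated.
- The pooled (rather than per-gene) null assumes gene scores are comparable
  across genes after the σ-floored standardization.
- Genes absent from the expression matrix or the annotation are silently
  untested; silencer hijacking and fusion-driven activation are annotated
  (fusions) or out of scope, not modeled.
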