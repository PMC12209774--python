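"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the scan assumes in real
cohorts: genes sit one per TAD on a small multi-chromosome genome; most
genes have log-normal baseline expression and a fraction are silent
(noise below 0.5 TPM); injected hijacking events give a silent gene strong
monoallelic overexpression in one sample together with a junction joining
its TAD to a donor TAD carrying a strong enhancer on the retained flank;
amplification decoys couple copy-number gain with proportional biallelic
overexpression, contaminating the reference pool unless expression is
CN-corrected; breakpoint decoys place in-TAD junctions (in 1-3 samples
per decoy gene, the candidate multiplicity typical of real cohorts) with no
expression change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io_model import (
    AllelicSnpCount,
    Breakend,
    CohortBundle,
    CopyNumberSegment,
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    InputError,
    ScanConfig,
    ScoredEnhancer,
    SIDE_LEFT,
    SIDE_RIGHT,
    write_allelic_counts,
    write_breakends,
    write_cna,
    write_enhancers,
    write_expression,
    write_fusions,
    write_gene_annotation,
    write_tads,
)


@dataclass
class SimulationSpec:
    """Generative parameters for a synthetic cohort.

    Defaults describe a modest cohort (30 samples, 200 genes) with five
    hijacking events (TPM 100-200, two SNPs of depth 30 at a 97% major
    allele), five amplification decoys (CN 6 with 3x expression and
    balanced alleles) and ten breakpoint decoys.
    """

    n_samples: int = 30
    n_genes: int = 200
    n_chromosomes: int = 4
    tad_size_mean: int = 1_000_000
    gene_length: int = 20_000
    expr_log_mean: float = 2.0
    expr_log_sd: float = 1.0
    silent_fraction: float = 0.3
    silent_noise_tpm: float = 0.45
    sample_noise_sd: float = 0.25
    n_hijack_events: int = 5
    hijack_tpm_range: tuple = (100.0, 200.0)
    snps_per_gene: int = 2
    allelic_depth: int = 30
    monoallelic_fraction: float = 0.97
    n_amplification_decoys: int = 5
    amplification_cn: float = 6.0
    amplification_fold: float = 3.0
    n_breakpoint_decoys: int = 10
    breakpoint_decoy_max_samples: int = 3
    enhancer_density: float = 0.3
    enhancer_log_mean: float = 1.0
    enhancer_log_sd: float = 0.5
    donor_enhancer_log_mean: float = 2.0
    hijack_min_enrichment: float = 5.0
    rng_seed: int = 0

    def __post_init__(self):
        counts = (self.n_samples, self.n_genes, self.n_chromosomes,
                  self.n_hijack_events, self.n_amplification_decoys,
                  self.n_breakpoint_decoys, self.snps_per_gene)
        if any(c < 0 for c in counts):
            raise InputError("simulation counts must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown simulation spec keys: {sorted(unknown)}")
        if "hijack_tpm_range" in d:
            d = dict(d, hijack_tpm_range=tuple(d["hijack_tpm_range"]))
        return cls(**d)


@dataclass
class GroundTruth:
    hijacked: list = field(default_factory=list)   # (gene_id, sample_id)
    decoys: dict = field(default_factory=dict)     # class -> [(gene_id, sample_id)]

    def all_decoy_pairs(self) -> set:
        return {pair for pairs in self.decoys.values() for pair in pairs}


def _tile_genome(spec: SimulationSpec, rng: np.random.Generator):
    """TADs laid consecutively per chromosome, round-robin assignment."""
    n_tads = spec.n_genes + spec.n_hijack_events
    sizes = rng.integers(int(0.8 * spec.tad_size_mean),
                         int(1.2 * spec.tad_size_mean), size=n_tads)
    cursors = {str(c + 1): 0 for c in range(spec.n_chromosomes)}
    tads = []
    for i in range(n_tads):
        chrom = str(i % spec.n_chromosomes + 1)
        start = cursors[chrom]
        end = start + int(sizes[i])
        cursors[chrom] = end
        tads.append(GenomicInterval(chrom, start, end))
    return tads


def simulate_cohort(spec: SimulationSpec):
    """Build a (CohortBundle, GroundTruth) pair from the spec, reproducibly."""
    rng = np.random.default_rng(spec.rng_seed)
    tads = _tile_genome(spec, rng)
    gene_tads = tads[:spec.n_genes]
    donor_pool = list(tads[spec.n_genes:])

    genes = []
    for i, tad in enumerate(gene_tads):
        mid = (tad.start + tad.end) // 2
        body = GenomicInterval(tad.chrom, mid - spec.gene_length // 2,
                               mid + spec.gene_length // 2)
        genes.append(GeneAnnotation(gene_id=f"G{i:04d}", name=f"GENE{i:04d}", body=body))

    samples = [f"S{j:03d}" for j in range(spec.n_samples)]

    n_silent = int(round(spec.silent_fraction * spec.n_genes))
    if spec.n_hijack_events > n_silent:
        raise InputError(
            f"cannot place {spec.n_hijack_events} hijack events with only "
            f"{n_silent} silent genes"
        )
    silent_rows = set(rng.choice(spec.n_genes, size=n_silent, replace=False).tolist()) \
        if n_silent else set()

    # baseline expression
    tpm = np.empty((spec.n_genes, spec.n_samples))
    base = np.exp(rng.normal(spec.expr_log_mean, spec.expr_log_sd, size=spec.n_genes))
    for g in range(spec.n_genes):
        if g in silent_rows:
            tpm[g] = rng.uniform(0.0, spec.silent_noise_tpm, size=spec.n_samples)
        else:
            tpm[g] = base[g] * np.exp(rng.normal(0.0, spec.sample_noise_sd,
                                                 size=spec.n_samples))

    breakends, cna, enhancers = [], [], []
    truth = GroundTruth(decoys={"amplification": [], "breakpoint": []})

    # ambient enhancers, log-normal enrichment so rank weighting sees ties rarely
    n_ambient = int(round(spec.enhancer_density * len(tads)))
    for _ in range(n_ambient):
        tad = tads[int(rng.integers(len(tads)))]
        lo = tad.start + 10_000
        hi = tad.end - 12_000
        start = int(rng.integers(lo, hi))
        enhancers.append(ScoredEnhancer(
            region=GenomicInterval(tad.chrom, start, start + 2_000),
            enrichment=float(np.exp(rng.normal(spec.enhancer_log_mean,
                                               spec.enhancer_log_sd))),
        ))

    # hijack events: silent gene joined (gene-retaining) to an enhancer donor TAD
    silent_list = sorted(silent_rows)
    hijack_rows = (rng.choice(silent_list, size=spec.n_hijack_events,
                              replace=False).tolist()
                   if spec.n_hijack_events else [])
    used_donors = set()
    for g in hijack_rows:
        gene = genes[g]
        s = int(rng.integers(spec.n_samples))
        tpm[g, s] = float(rng.uniform(*spec.hijack_tpm_range))
        donor = None
        for di, cand in enumerate(donor_pool):
            if di in used_donors:
                continue
            if cand.chrom != gene.body.chrom or donor is None:
                donor = (di, cand)
                if cand.chrom != gene.body.chrom:
                    break
        di, donor_tad = donor
        used_donors.add(di)
        pos_a = gene.body.end + 5_000            # 1-based, right of the gene, in-TAD
        pos_b = donor_tad.start + 100_001        # 1-based, left edge of donor TAD
        breakends.append(Breakend(
            sample_id=samples[s],
            chrom_a=gene.body.chrom, pos_a=pos_a, side_a=SIDE_LEFT,
            chrom_b=donor_tad.chrom, pos_b=pos_b, side_b=SIDE_RIGHT,
            sv_class="translocation",
        ).normalized())
        enh_start = donor_tad.start + 150_000    # on the retained flank of pos_b
        enhancers.append(ScoredEnhancer(
            region=GenomicInterval(donor_tad.chrom, enh_start, enh_start + 2_000),
            enrichment=float(max(np.exp(rng.normal(spec.donor_enhancer_log_mean,
                                                   spec.enhancer_log_sd)),
                                 spec.hijack_min_enrichment)),
        ))
        truth.hijacked.append((gene.gene_id, samples[s]))

    # amplification decoys: CN gain + proportional expression, balanced alleles
    expressed_rows = [g for g in range(spec.n_genes) if g not in silent_rows]
    picked = rng.choice(expressed_rows, size=spec.n_amplification_decoys,
                        replace=False).tolist() if spec.n_amplification_decoys else []
    for g in picked:
        gene = genes[g]
        s = int(rng.integers(spec.n_samples))
        tpm[g, s] *= spec.amplification_fold
        seg = GenomicInterval(gene.body.chrom, gene.body.start - 100_000,
                              gene.body.end + 100_000)
        cna.append(CopyNumberSegment(sample_id=samples[s], region=seg,
                                     copy_number=spec.amplification_cn))
        truth.decoys["amplification"].append((gene.gene_id, samples[s]))

    # breakpoint decoys: in-TAD junctions, 1-3 samples each, expression untouched
    remaining = [g for g in expressed_rows if g not in set(picked)]
    if spec.n_breakpoint_decoys > len(remaining):
        raise InputError("not enough expressed genes for the breakpoint decoys")
    bp_rows = rng.choice(remaining, size=spec.n_breakpoint_decoys,
                         replace=False).tolist() if spec.n_breakpoint_decoys else []
    for g in bp_rows:
        gene = genes[g]
        tad = gene_tads[g]
        u = int(rng.integers(1, spec.breakpoint_decoy_max_samples + 1))
        for s in rng.choice(spec.n_samples, size=u, replace=False).tolist():
            breakends.append(Breakend(
                sample_id=samples[s],
                chrom_a=tad.chrom, pos_a=tad.start + 150_001, side_a=SIDE_LEFT,
                chrom_b=tad.chrom, pos_b=tad.end - 150_000, side_b=SIDE_RIGHT,
                sv_class="inversion",
            ).normalized())
            truth.decoys["breakpoint"].append((gene.gene_id, samples[s]))

    # allelic counts: biallelic on expressed genes, monoallelic at hijack pairs
    hijack_pairs = set(truth.hijacked)
    allelic = []
    for g in range(spec.n_genes):
        gene = genes[g]
        positions = [gene.body.start + 1_000 * (i + 1)
                     for i in range(spec.snps_per_gene)]
        for s, sample in enumerate(samples):
            if (gene.gene_id, sample) in hijack_pairs:
                p_major = spec.monoallelic_fraction
            elif g not in silent_rows:
                p_major = 0.5
            else:
                continue  # silent, unexpressed: no RNA coverage
            for pos in positions:
                ref = int(rng.binomial(spec.allelic_depth, p_major))
                allelic.append(AllelicSnpCount(
                    sample_id=sample, gene_id=gene.gene_id, chrom=gene.body.chrom,
                    pos=pos, ref_count=ref, alt_count=spec.allelic_depth - ref,
                ))

    expression = ExpressionMatrix(genes=[g.gene_id for g in genes],
                                  samples=samples, tpm=tpm)
    bundle = CohortBundle(
        expression=expression, breakends=breakends, genes=genes,
        cna=cna or None, allelic=allelic or None, tads=tads,
        enhancers=enhancers or None, fusions=None,
        config=ScanConfig(rng_seed=spec.rng_seed),
    )
    return bundle, truth


def write_cohort(bundle: CohortBundle, out_dir,
                 truth: Optional[GroundTruth] = None) -> dict:
    """Write every cohort input in the dialects the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "breakends": out / "breakends.tsv",
        "genes": out / "genes.tsv",
        "tads": out / "tads.bed",
    }
    write_expression(bundle.expression, paths["expression"])
    write_breakends(bundle.breakends, paths["breakends"])
    write_gene_annotation(bundle.genes, paths["genes"])
    write_tads(bundle.tads or [], paths["tads"])
    if bundle.cna:
        paths["cna"] = out / "cna.tsv"
        write_cna(bundle.cna, paths["cna"])
    if bundle.allelic:
        paths["allelic"] = out / "allelic_counts.tsv"
        write_allelic_counts(bundle.allelic, paths["allelic"])
    if bundle.enhancers:
        paths["enhancers"] = out / "enhancers.bed"
        write_enhancers(bundle.enhancers, paths["enhancers"])
    if bundle.fusions:
        paths["fusions"] = out / "fusions.tsv"
        write_fusions(bundle.fusions, paths["fusions"])
    if truth is not None:
        paths["ground_truth"] = out / "ground_truth.tsv"
        with open(paths["ground_truth"], "w") as fh:
            fh.write("gene_id\tsample\tclass\n")
            for gene_id, sample in truth.hijacked:
                fh.write(f"{gene_id}\t{sample}\thijack\n")
            for cls, pairs in sorted(truth.decoys.items()):
                for gene_id, sample in pairs:
                    fh.write(f"{gene_id}\t{sample}\t{cls}\n")
    return paths
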