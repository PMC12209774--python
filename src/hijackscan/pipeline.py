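"""End-to-end orchestration: filter -> partition -> score -> FDR.

`build_context` precomputes everything per-(gene, sample) that both the
observed scoring pass and the null resampler need (copy numbers, corrected
log expression, ASE scores, deletion indicators, neighborhoods and sample
partitions), so the niter resampling iterations are cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import candidates as cand
from . import fdr as fdrmod
from . import scoring
from .io_model import CohortBundle, filter_expressed_genes

logger = logging.getLogger("hijackscan")


@dataclass
class ScoringContext:
    """Precomputed per-cohort arrays over expressed genes x samples."""

    bundle: CohortBundle
    genes: list                # expressed GeneAnnotation, expression order
    samples: list
    sample_index: dict
    logexpr: np.ndarray        # ln(0.5 + CN-corrected TPM)
    cn: np.ndarray             # gene copy number per (gene, sample)
    deleted: np.ndarray        # deletion indicator per (gene, sample)
    ase: dict                  # (gene_id, sample_id) -> (s_ase, n_snps)
    neighborhoods: dict        # gene_id -> GeneNeighborhood
    partitions: dict           # gene_id -> SamplePartition
    ref_idx: dict              # gene_id -> np.ndarray of reference sample columns
    cand_idx: dict             # gene_id -> np.ndarray of candidate sample columns


def _copy_number_matrix(genes, samples, cna) -> np.ndarray:
    cn = np.full((len(genes), len(samples)), 2.0)
    if not cna:
        return cn
    by_sample = {}
    for seg in cna:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    sample_index = {s: j for j, s in enumerate(samples)}
    for sample_id, segs in by_sample.items():
        j = sample_index[sample_id]
        for i, gene in enumerate(genes):
            best_ov, best_cn = 0, 2.0
            for seg in segs:
                ov = seg.region.overlap(gene.body)
                if ov > best_ov:
                    best_ov, best_cn = ov, seg.copy_number
            cn[i, j] = best_cn
    return cn


def _ase_lookup(bundle: CohortBundle, genes, sample_index, cn, config) -> dict:
    """Precompute (s_ase, n_snps) for every (gene, sample) pair with data."""
    out = {}
    if not bundle.allelic:
        return out
    gene_row = {g.gene_id: i for i, g in enumerate(genes)}
    gene_by_id = {g.gene_id: g for g in genes}
    groups = {}
    for rec in bundle.allelic:
        groups.setdefault((rec.gene_id, rec.sample_id), []).append(rec)
    # vectorize llr over the full table, then sum per group
    keys = list(groups)
    flat_ref, flat_alt, offsets = [], [], [0]
    for key in keys:
        snps = groups[key]
        flat_ref.extend(s.ref_count for s in snps)
        flat_alt.extend(s.alt_count for s in snps)
        offsets.append(offsets[-1] + len(snps))
    if not keys:
        return out
    llr = scoring.snp_llr_array(flat_ref, flat_alt, config)
    for idx, (gene_id, sample_id) in enumerate(keys):
        gene = gene_by_id.get(gene_id)
        if gene is None:  # allelic data for a non-expressed/unknown gene
            continue
        n = offsets[idx + 1] - offsets[idx]
        gcn = cn[gene_row[gene_id], sample_index[sample_id]]
        if (gcn < config.ase_cn_low or gcn > config.ase_cn_high
                or gene.is_sex_chrom or gene.is_imprinted):
            out[(gene_id, sample_id)] = (0.0, 0)
        else:
            out[(gene_id, sample_id)] = (
                float(llr[offsets[idx]:offsets[idx + 1]].sum() / (n + 2)), n)
    return out


def build_context(bundle: CohortBundle) -> ScoringContext:
    config = bundle.config
    expressed_ids = set(filter_expressed_genes(bundle.expression, config.min_tpm_expressed))
    gene_by_id = bundle.gene_by_id
    genes, rows = [], []
    n_unannotated = 0
    for i, gid in enumerate(bundle.expression.genes):
        if gid not in expressed_ids:
            continue
        if gid not in gene_by_id:
            n_unannotated += 1
            continue
        genes.append(gene_by_id[gid])
        rows.append(i)
    if n_unannotated:
        logger.warning("%d expressed genes lack annotation and are skipped", n_unannotated)
    samples = list(bundle.expression.samples)
    sample_index = {s: j for j, s in enumerate(samples)}

    cn = _copy_number_matrix(genes, samples, bundle.cna)
    tpm = bundle.expression.tpm[rows, :]
    corrected = tpm * 2.0 / np.maximum(cn, 1.0)
    logexpr = scoring.log_expression(corrected)
    deleted = (cn < config.deletion_cn_threshold).astype(int)

    ase = _ase_lookup(bundle, genes, sample_index, cn, config)

    neighborhoods, partitions, ref_idx, cand_idx = {}, {}, {}, {}
    for gene in genes:
        nb = cand.build_neighborhood(gene, bundle.tads, config)
        part = cand.partition_samples(gene, nb, bundle.breakends, samples)
        neighborhoods[gene.gene_id] = nb
        partitions[gene.gene_id] = part
        ref_idx[gene.gene_id] = np.array(
            sorted(sample_index[s] for s in part.reference_samples), dtype=int)
        cand_idx[gene.gene_id] = np.array(
            sorted(sample_index[s] for s in part.candidate_samples), dtype=int)

    return ScoringContext(
        bundle=bundle, genes=genes, samples=samples, sample_index=sample_index,
        logexpr=logexpr, cn=cn, deleted=deleted, ase=ase,
        neighborhoods=neighborhoods, partitions=partitions,
        ref_idx=ref_idx, cand_idx=cand_idx,
    )


def score_observed(ctx: ScoringContext) -> list:
    """GeneScore for every expressed gene with >= 1 candidate and enough
    references, in expression order."""
    config = ctx.bundle.config
    bnd_by_sample = {}
    for b in ctx.bundle.breakends:
        bnd_by_sample.setdefault(b.sample_id, []).append(b)
    out = []
    for row, gene in enumerate(ctx.genes):
        gid = gene.gene_id
        part = ctx.partitions[gid]
        if not cand.eligible_for_scoring(part, config):
            continue
        ref = ctx.ref_idx[gid]
        vals = ctx.logexpr[row, ref]
        mu = float(vals.mean())
        sigma = float(vals.std())
        sample_scores = []
        for j in ctx.cand_idx[gid]:
            sample_id = ctx.samples[j]
            t = (float(ctx.logexpr[row, j]) - mu) / (sigma + config.sigma_floor)
            s_ovx = scoring._score_from_t(t)
            s_ase, n_snps = ctx.ase.get((gid, sample_id), (0.0, 0))
            hijacked = scoring.hijacked_enhancers(
                gene, ctx.neighborhoods[gid], bnd_by_sample.get(sample_id, []),
                ctx.bundle.enhancers, ctx.bundle.tads, config)
            s_enh = scoring.enhancer_score(hijacked)
            sample_scores.append(scoring.combine_sample_score(
                gid, sample_id, s_ovx, t, s_ase, n_snps, s_enh, hijacked,
                int(ctx.deleted[row, j]), config))
        out.append(scoring.aggregate_gene_score(sample_scores))
    return out


def run_scan(bundle: CohortBundle, seed: Optional[int] = None) -> tuple:
    """Full scan: returns (results, null_score_set, context).

    ``results`` is a list of :class:`hijackscan.fdr.GeneResult`, one per
    tested gene (>= 1 candidate sample), unsorted; the report layer orders
    and annotates them.
    """
    config = bundle.config
    if seed is None:
        seed = config.rng_seed
    ctx = build_context(bundle)
    observed = score_observed(ctx)
    null = fdrmod.build_null(ctx, config, master_seed=seed)
    pvals = fdrmod.empirical_pvalues([g.aggregated for g in observed], null)
    fdrs = fdrmod.bh_correct(pvals) if len(observed) else np.array([])
    results = [
        fdrmod.GeneResult(gene_id=g.gene_id, score=g, p_value=float(p), fdr=float(q))
        for g, p, q in zip(observed, pvals, fdrs)
    ]
    logger.info("scanned %d expressed genes, tested %d, null size %d",
                len(ctx.genes), len(results), len(null.scores))
    return results, null, ctx
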