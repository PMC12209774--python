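"""Per-(gene, sample) score components and their combination.

The combined score for a candidate sample is a weighted sum of four
components:

* overexpression — how far the sample's copy-number-corrected, log-scaled
  TPM lies above the reference-sample distribution, on a damped scale;
* allele-specific expression (ASE) — a beta-binomial log-likelihood ratio
  of monoallelic vs biallelic expression at heterozygous SNPs;
* enhancer — rank-weighted total enrichment of enhancers repositioned into
  the gene's TAD by the rearrangement;
* deletion — a fixed penalty when the gene itself is lost in the sample,
  since a hijacking rearrangement should not delete the gene it activates.

Sample scores are aggregated per gene with a shrinking factor that rewards
recurrence across samples.  Natural logarithms are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import betabinom

from .candidates import GeneNeighborhood, point_in_regions
from .io_model import (
    AllelicSnpCount,
    Breakend,
    GeneAnnotation,
    GenomicInterval,
    ScanConfig,
    ScoredEnhancer,
    SIDE_LEFT,
    SIDE_RIGHT,
)

LN2 = math.log(2.0)


@dataclass
class ReferenceDistribution:
    """Mean/SD of ln(0.5 + corrected TPM) over reference samples."""

    gene_id: str
    mu: float
    sigma: float
    n_ref: int


@dataclass
class SampleScore:
    gene_id: str
    sample_id: str
    s_overexpression: float
    t_value: float
    s_ase: float
    n_snps: int
    s_enhancer: float
    hijacked_enhancers: list
    deleted: int
    combined: float


@dataclass
class GeneScore:
    gene_id: str
    sample_scores: list
    n_candidates: int
    aggregated: float


# ---------------------------------------------------------------------------
# Overexpression
# ---------------------------------------------------------------------------

def log_expression(tpm_corrected) -> np.ndarray:
    """The log transform applied before outlier scoring: ln(0.5 + E)."""
    return np.log(0.5 + np.asarray(tpm_corrected, dtype=float))


def reference_distribution(gene_id: str, corrected_tpm: Sequence[float]) -> ReferenceDistribution:
    """Population mean/SD of log-scale expression over reference samples."""
    vals = log_expression(corrected_tpm)
    return ReferenceDistribution(
        gene_id=gene_id,
        mu=float(np.mean(vals)),
        sigma=float(np.std(vals)),  # population SD; the +sigma_floor dominates anyway
        n_ref=len(vals),
    )


def overexpression_score(e_corrected: float, ref: ReferenceDistribution,
                         config: ScanConfig) -> tuple:
    """Damped z-like outlier score of a candidate's expression.

    t = (ln(0.5+E) - mu) / (sigma + floor); the score is ln(t-1) above
    t = 2 and -2 ln(3-t) below, continuous (0) at t = 2 and increasingly
    negative as expression approaches or falls below the reference mean.
    """
    e = math.log(0.5 + e_corrected)
    t = (e - ref.mu) / (ref.sigma + config.sigma_floor)
    return _score_from_t(t), t


def _score_from_t(t: float) -> float:
    if t > 2.0:
        return math.log(t - 1.0)
    return -2.0 * math.log(3.0 - t)


# ---------------------------------------------------------------------------
# Allele-specific expression
# ---------------------------------------------------------------------------

def _bb_logpmf(k, n, mean: float, conc: float):
    return betabinom.logpmf(k, n, mean * conc, (1.0 - mean) * conc)


def snp_llr_array(ref_counts, alt_counts, config: ScanConfig) -> np.ndarray:
    """Vectorized per-SNP log-likelihood ratio, monoallelic vs biallelic.

    Monoallelic model: equal mixture of two beta-binomials with means near 0
    and 1 (allowing slight leakage from the silent allele); biallelic model:
    one beta-binomial centred on 1/2.  Positive values support monoallelic
    expression.  Clamped to +/- ``llr_clamp`` so no single ultra-deep SNP
    dominates the gene score.
    """
    k = np.asarray(ref_counts, dtype=int)
    n = k + np.asarray(alt_counts, dtype=int)
    lo, hi = config.mono_means
    s = config.bb_concentration
    l_mono = np.logaddexp(_bb_logpmf(k, n, hi, s), _bb_logpmf(k, n, lo, s)) - LN2
    l_bi = _bb_logpmf(k, n, config.bi_mean, s)
    return np.clip(l_mono - l_bi, -config.llr_clamp, config.llr_clamp)


def snp_llr(ref_count: int, alt_count: int, config: ScanConfig) -> float:
    return float(snp_llr_array([ref_count], [alt_count], config)[0])


def ase_score(snps: Sequence[AllelicSnpCount], gene_cn: float,
              gene: GeneAnnotation, config: ScanConfig) -> tuple:
    """(S_ase, n_snps) for one gene in one sample: (sum llr_i) / (n + 2).

    Gated to 0 when the gene's copy number lies outside [cn_low, cn_high]
    (allelic fractions are then uninformative about hijacking), on sex
    chromosomes, for imprinted genes, or without allelic data.
    """
    if (gene_cn < config.ase_cn_low or gene_cn > config.ase_cn_high
            or gene.is_sex_chrom or gene.is_imprinted or not snps):
        return 0.0, 0
    llrs = snp_llr_array([s.ref_count for s in snps],
                         [s.alt_count for s in snps], config)
    n = len(snps)
    return float(llrs.sum() / (n + 2)), n


# ---------------------------------------------------------------------------
# Enhancer hijacking geometry
# ---------------------------------------------------------------------------

def _retained_window(chrom: str, pos: int, side: str,
                     tads: Optional[Sequence[GenomicInterval]],
                     config: ScanConfig) -> GenomicInterval:
    """Genomic window on the retained side of a junction end, up to the
    nearest TAD boundary in that direction (capped at the fallback window)."""
    boundaries = sorted(
        {b for t in (tads or []) if t.chrom == chrom for b in (t.start, t.end)}
    )
    p0 = pos - 1  # 0-based
    if side == SIDE_RIGHT:
        nxt = [b for b in boundaries if b >= p0 + 1]
        hi = nxt[0] if nxt else p0 + config.fallback_window_bp
        return GenomicInterval(chrom, p0, max(hi, p0 + 1))
    prev = [b for b in boundaries if b <= p0]
    lo = prev[-1] if prev else max(0, p0 - config.fallback_window_bp)
    return GenomicInterval(chrom, min(lo, p0), p0 + 1)


def _gene_on_retained_side(gene: GeneAnnotation, chrom: str, pos: int, side: str) -> bool:
    if gene.body.chrom != chrom:
        return False
    if side == SIDE_LEFT:
        return gene.body.end <= pos  # whole body at coordinates <= pos
    return gene.body.start >= pos - 1  # whole body at coordinates >= pos


def hijacked_enhancers(gene: GeneAnnotation,
                       neighborhood: GeneNeighborhood,
                       sample_breakends: Sequence[Breakend],
                       enhancers: Optional[Sequence[ScoredEnhancer]],
                       tads: Optional[Sequence[GenomicInterval]],
                       config: ScanConfig) -> list:
    """Enhancers likely brought into the gene's TAD by the sample's junctions.

    Each breakend pair is considered independently: one end must lie inside
    the gene's search region with the gene body on its retained flank (the
    derivative allele carries the gene), and the partner end must lie outside
    the search region.  Enhancers on the retained flank of the partner end
    are collected up to the first TAD boundary in that direction.  Enhancers
    already inside the gene's own search region are never counted (no
    self-hijack), and each enhancer is kept once across breakends.  Ends
    with unknown orientation are tried in both orientations.
    """
    if not enhancers:
        return []
    collected = {}
    for bnd in sample_breakends:
        (ca, pa, sa), (cb, pb, sb) = bnd.ends
        for (c_in, p_in, s_in), (c_out, p_out, s_out) in (
            ((ca, pa, sa), (cb, pb, sb)),
            ((cb, pb, sb), (ca, pa, sa)),
        ):
            if not point_in_regions(c_in, p_in, neighborhood.search_regions):
                continue
            if point_in_regions(c_out, p_out, neighborhood.search_regions):
                continue  # intra-region junction cannot import new enhancers
            in_sides = (s_in,) if s_in is not None else (SIDE_LEFT, SIDE_RIGHT)
            if not any(_gene_on_retained_side(gene, c_in, p_in, s) for s in in_sides):
                continue
            out_sides = (s_out,) if s_out is not None else (SIDE_LEFT, SIDE_RIGHT)
            for s in out_sides:
                window = _retained_window(c_out, p_out, s, tads, config)
                for enh in enhancers:
                    if enh.region.overlap(window) <= 0:
                        continue
                    if any(enh.region.overlap(r) > 0 for r in neighborhood.search_regions):
                        continue
                    key = (enh.region.chrom, enh.region.start, enh.region.end)
                    collected[key] = enh
    return list(collected.values())


def enhancer_score(hijacked: Sequence[ScoredEnhancer]) -> float:
    """Rank-weighted sum of enrichments: sum_i E_i / (i+1), strongest first."""
    scores = sorted((e.enrichment for e in hijacked), reverse=True)
    return float(sum(e / (i + 1) for i, e in enumerate(scores)))


# ---------------------------------------------------------------------------
# Deletion penalty, combination, aggregation
# ---------------------------------------------------------------------------

def deletion_indicator(gene_cn: float, config: ScanConfig) -> int:
    """1 when the gene is deleted in the sample (CN below threshold)."""
    return 1 if gene_cn < config.deletion_cn_threshold else 0


def combine_sample_score(gene_id: str, sample_id: str,
                         s_overexpression: float, t_value: float,
                         s_ase: float, n_snps: int,
                         s_enhancer: float, hijacked: Sequence[ScoredEnhancer],
                         deleted: int, config: ScanConfig) -> SampleScore:
    combined = (config.w_overexpression * s_overexpression
                + config.w_ase * s_ase
                + config.w_enhancer * s_enhancer
                - config.w_deletion * deleted)
    return SampleScore(
        gene_id=gene_id, sample_id=sample_id,
        s_overexpression=s_overexpression, t_value=t_value,
        s_ase=s_ase, n_snps=n_snps,
        s_enhancer=s_enhancer, hijacked_enhancers=list(hijacked),
        deleted=deleted, combined=combined,
    )


def aggregate_scores(scores: Sequence[float]) -> float:
    """Gene-level aggregation 5 * sum(S_i) / (n + 4): equals the sample score
    at n = 1 and rewards recurrent activation across samples."""
    n = len(scores)
    if n == 0:
        raise ValueError("aggregate_scores requires at least one sample score")
    return 5.0 * float(sum(scores)) / (n + 4)


def aggregate_gene_score(sample_scores: Sequence[SampleScore]) -> GeneScore:
    if not sample_scores:
        raise ValueError("aggregate_gene_score requires at least one sample score")
    gene_id = sample_scores[0].gene_id
    return GeneScore(
        gene_id=gene_id,
        sample_scores=list(sample_scores),
        n_candidates=len(sample_scores),
        aggregated=aggregate_scores([s.combined for s in sample_scores]),
    )
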