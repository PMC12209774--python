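"""Partition cohort samples into candidate and reference samples per gene.

A sample is a *candidate* for a gene when at least one of its breakend ends
falls inside the gene's search region: every TAD overlapping the gene body,
extended by a fixed pad on both sides to absorb imprecise TAD boundaries, or
a fixed window around the gene when no TAD overlaps it.  All remaining
samples are *references* and define the null expression distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .io_model import (
    Breakend,
    GeneAnnotation,
    GenomicInterval,
    ScanConfig,
)

logger = logging.getLogger("hijackscan")


@dataclass
class GeneNeighborhood:
    gene_id: str
    search_regions: list  # GenomicInterval
    used_fallback: bool


@dataclass
class SamplePartition:
    gene_id: str
    candidate_samples: set
    reference_samples: set


def build_neighborhood(gene: GeneAnnotation,
                       tads: Optional[Sequence[GenomicInterval]],
                       config: ScanConfig) -> GeneNeighborhood:
    """Search regions for a gene: extended overlapping TADs, or a fallback window.

    TAD membership is any overlap with the gene body.  Each overlapping TAD is
    extended by ``tad_extension_bp`` on both sides (clipped at 0).  When no
    TAD overlaps (or no TADs are given), a single window of the gene body
    padded by ``fallback_window_bp`` is used.
    """
    regions = []
    if tads:
        regions = [t.expanded(config.tad_extension_bp)
                   for t in tads if t.overlap(gene.body) > 0]
    if regions:
        return GeneNeighborhood(gene.gene_id, regions, used_fallback=False)
    return GeneNeighborhood(
        gene.gene_id,
        [gene.body.expanded(config.fallback_window_bp)],
        used_fallback=True,
    )


def point_in_regions(chrom: str, pos_1based: int,
                     regions: Sequence[GenomicInterval]) -> bool:
    return any(r.contains_point(chrom, pos_1based) for r in regions)


def partition_samples(gene: GeneAnnotation,
                      neighborhood: GeneNeighborhood,
                      breakends: Sequence[Breakend],
                      all_samples: Sequence[str]) -> SamplePartition:
    """Split the cohort into candidate and reference samples for one gene.

    Both ends of every breakend pair are tested independently, so a sample
    whose junction partner lands in the gene's TAD is a candidate even when
    the anchor end is elsewhere.
    """
    candidates = set()
    for bnd in breakends:
        if bnd.sample_id in candidates:
            continue
        for chrom, pos, _side in bnd.ends:
            if point_in_regions(chrom, pos, neighborhood.search_regions):
                candidates.add(bnd.sample_id)
                break
    references = set(all_samples) - candidates
    return SamplePartition(gene.gene_id, candidates, references)


def eligible_for_scoring(partition: SamplePartition, config: ScanConfig) -> bool:
    """A gene is scored only with >= 1 candidate and enough references."""
    ok = (len(partition.candidate_samples) >= 1
          and len(partition.reference_samples) >= config.min_reference_samples)
    if not ok:
        logger.debug(
            "gene %s skipped: %d candidates, %d references (need >= 1 and >= %d)",
            partition.gene_id, len(partition.candidate_samples),
            len(partition.reference_samples), config.min_reference_samples,
        )
    return ok
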