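"""Empirical null, p-values and Benjamini-Hochberg FDR.

The gene scores have arbitrary scale, so significance is calibrated against
an empirical null: for each gene, its true candidate samples are set aside
and 1-3 randomly chosen reference samples are scored as pseudo-candidates
with the full scoring stack (overexpression against the remaining
references, observed ASE and copy number, enhancer score 0 because these
samples carry no qualifying breakends).  Repeating this ``niter`` times
yields a pooled list of niter x ngenes null gene scores, from which an
add-one empirical p-value is computed per gene, followed by BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .scoring import GeneScore


@dataclass
class NullScoreSet:
    scores: np.ndarray  # length niter * n_null_eligible_genes
    niter: int
    master_seed: int
    n_genes: int
    k_values: Optional[np.ndarray] = None  # pseudo-candidate count per null score

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass
class GeneResult:
    gene_id: str
    score: GeneScore
    p_value: float
    fdr: float
    fusion_annotations: list = field(default_factory=list)  # (sample_id, partner, role)


def null_eligible_gene_rows(ctx, config) -> list:
    """Rows of genes with enough references that 3 pseudo-candidates still
    leave >= min_reference_samples references for mu/sigma."""
    need = config.min_reference_samples + 3
    return [row for row, g in enumerate(ctx.genes)
            if len(ctx.ref_idx[g.gene_id]) >= need]


def build_null(ctx, config, master_seed: Optional[int] = None) -> NullScoreSet:
    """Pooled null gene scores from pseudo-candidate resampling.

    ``ctx`` is the precomputed scoring context of a cohort (see
    :mod:`hijackscan.pipeline`).  One master seed; per-iteration generators
    are derived from (seed, iteration) so results are reproducible and
    independent of evaluation order.
    """
    if master_seed is None:
        master_seed = config.rng_seed
    rows = null_eligible_gene_rows(ctx, config)
    if not rows:
        raise ValueError("no genes have enough reference samples to build a null")

    # per-gene reference summaries for O(k) mu/sigma updates
    per_gene = []
    for row in rows:
        gid = ctx.genes[row].gene_id
        ref = ctx.ref_idx[gid]
        vals = ctx.logexpr[row, ref]
        ase = np.array([ctx.ase.get((gid, ctx.samples[j]), (0.0, 0))[0] for j in ref])
        dele = ctx.deleted[row, ref].astype(float)
        per_gene.append((vals, vals.sum(), np.square(vals).sum(), ase, dele))

    w_ovx, w_ase, w_del = config.w_overexpression, config.w_ase, config.w_deletion
    floor = config.sigma_floor
    scores = np.empty(config.niter * len(rows))
    k_values = np.empty(config.niter * len(rows), dtype=int)
    pos = 0
    for it in range(config.niter):
        rng = np.random.default_rng([master_seed, it])
        for vals, total, total_sq, ase, dele in per_gene:
            n = len(vals)
            k = int(rng.integers(1, 4))
            chosen = rng.choice(n, size=k, replace=False)
            vc = vals[chosen]
            n_rem = n - k
            mu = (total - vc.sum()) / n_rem
            var = max((total_sq - np.square(vc).sum()) / n_rem - mu * mu, 0.0)
            t = (vc - mu) / (np.sqrt(var) + floor)
            s_ovx = np.where(t > 2.0, np.log(np.maximum(t - 1.0, 1e-300)),
                             -2.0 * np.log(3.0 - np.minimum(t, 2.0)))
            combined = w_ovx * s_ovx + w_ase * ase[chosen] - w_del * dele[chosen]
            scores[pos] = 5.0 * combined.sum() / (k + 4)
            k_values[pos] = k
            pos += 1
    return NullScoreSet(scores=scores, niter=config.niter,
                        master_seed=master_seed, n_genes=len(rows),
                        k_values=k_values)


def empirical_pvalues(observed: Sequence[float], null: NullScoreSet) -> np.ndarray:
    """Add-one empirical p: (1 + #{null >= observed}) / (1 + N), ties in."""
    pool = np.sort(null.scores)
    big_n = len(pool)
    if big_n == 0:
        raise ValueError("empty null score set")
    obs = np.asarray(observed, dtype=float)
    n_ge = big_n - np.searchsorted(pool, obs, side="left")
    return (1.0 + n_ge) / (1.0 + big_n)


def bh_correct(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.  Implemented directly so
    the adjustment is the definitional arithmetic, bit for bit (scipy's
    ``false_discovery_control`` serves as a cross-check in the test suite).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out
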