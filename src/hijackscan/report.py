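"""Fusion annotation, ranked result tables and the run manifest.

A fusion transcript whose 3' partner is a candidate gene points to a
monoallelic-overexpression mechanism distinct from enhancer hijacking, so
candidates are annotated with — never filtered by — their fusion status.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .fdr import GeneResult
from .io_model import CohortBundle, FusionCall, ScanConfig

logger = logging.getLogger("hijackscan")

NO_FUSION = "no fusion detected"


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte."""

    config: dict
    inputs: dict          # logical name -> {path, sha256} for files given
    n_samples: int = 0
    n_genes_total: int = 0
    n_genes_expressed: int = 0
    n_genes_tested: int = 0
    seed: int = 0
    version: str = __version__
    extra: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        payload = {
            "tool": "hijackscan",
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "inputs": self.inputs,
            "counts": {
                "samples": self.n_samples,
                "genes_total": self.n_genes_total,
                "genes_expressed": self.n_genes_expressed,
                "genes_tested": self.n_genes_tested,
            },
            **({"extra": self.extra} if self.extra else {}),
        }
        return yaml.safe_dump(payload, sort_keys=True)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def annotate_fusions(results: Sequence[GeneResult],
                     fusions: Optional[Sequence[FusionCall]]) -> list:
    """Attach fusion status: for each candidate sample of each result gene,
    record the partner gene and whether the candidate is the 5' or 3' member."""
    fus_by_sample = {}
    for f in fusions or []:
        fus_by_sample.setdefault(f.sample_id, []).append(f)
    for res in results:
        annotations = []
        for ss in res.score.sample_scores:
            for f in fus_by_sample.get(ss.sample_id, []):
                if f.gene5 == res.gene_id:
                    annotations.append((ss.sample_id, f.gene3, "5prime"))
                elif f.gene3 == res.gene_id:
                    annotations.append((ss.sample_id, f.gene5, "3prime"))
        res.fusion_annotations = annotations
    return list(results)


def _fusion_text(res: GeneResult) -> str:
    if not res.fusion_annotations:
        return NO_FUSION
    parts = [
        f"{sample}:{'3prime-partner-of' if role == '3prime' else '5prime-partner-of'}:{partner}"
        for sample, partner, role in sorted(res.fusion_annotations)
    ]
    return ";".join(parts)


def sort_results(results: Sequence[GeneResult]) -> list:
    """Total, deterministic order: FDR asc, aggregated score desc, gene_id."""
    return sorted(results, key=lambda r: (r.fdr, -r.score.aggregated, r.gene_id))


def _fmt(x: float) -> str:
    return f"{x:.6g}"


GENE_COLUMNS = ["gene_id", "name", "chrom", "score", "p_value", "fdr",
                "n_candidates", "candidate_samples", "significant", "fusion"]
DETAIL_COLUMNS = ["gene_id", "sample_id", "combined", "s_overexpression", "t",
                  "s_ase", "n_snps", "s_enhancer", "n_hijacked_enhancers", "deleted"]


def write_results(results: Sequence[GeneResult], out_dir, bundle: CohortBundle,
                  manifest: RunManifest, fdr_threshold: float = 0.2) -> dict:
    """Write gene-level and per-sample TSVs plus the YAML manifest.

    The FDR threshold only sets the ``significant`` flag column; every tested
    gene is always written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene_by_id = bundle.gene_by_id
    ordered = sort_results(results)

    gene_path = out / "gene_results.tsv"
    with open(gene_path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for r in ordered:
            g = gene_by_id[r.gene_id]
            cand = ",".join(sorted(s.sample_id for s in r.score.sample_scores))
            fh.write("\t".join([
                r.gene_id, g.name, g.body.chrom,
                _fmt(r.score.aggregated), _fmt(r.p_value), _fmt(r.fdr),
                str(r.score.n_candidates), cand,
                "yes" if r.fdr < fdr_threshold else "no",
                _fusion_text(r),
            ]) + "\n")

    detail_path = out / "sample_scores.tsv"
    with open(detail_path, "w") as fh:
        fh.write("\t".join(DETAIL_COLUMNS) + "\n")
        for r in ordered:
            for ss in sorted(r.score.sample_scores, key=lambda s: s.sample_id):
                fh.write("\t".join([
                    ss.gene_id, ss.sample_id, _fmt(ss.combined),
                    _fmt(ss.s_overexpression), _fmt(ss.t_value),
                    _fmt(ss.s_ase), str(ss.n_snps), _fmt(ss.s_enhancer),
                    str(len(ss.hijacked_enhancers)), str(ss.deleted),
                ]) + "\n")

    manifest_path = out / "run_manifest.yaml"
    manifest_path.write_text(manifest.to_yaml())

    if not results:
        logger.warning("no genes were tested; wrote header-only result tables")
    n_sig = sum(1 for r in ordered if r.fdr < fdr_threshold)
    logger.info("wrote %d tested genes (%d at FDR < %s) to %s",
                len(ordered), n_sig, fdr_threshold, out)
    return {"gene_results": gene_path, "sample_scores": detail_path,
            "manifest": manifest_path}


def build_manifest(config: ScanConfig, input_paths: dict, seed: int,
                   n_samples: int, n_genes_total: int, n_genes_expressed: int,
                   n_genes_tested: int) -> RunManifest:
    inputs = {
        name: {"path": str(p), "sha256": file_checksum(p)}
        for name, p in input_paths.items() if p is not None
    }
    return RunManifest(
        config=config.to_dict(), inputs=inputs, seed=seed,
        n_samples=n_samples, n_genes_total=n_genes_total,
        n_genes_expressed=n_genes_expressed, n_genes_tested=n_genes_tested,
    )
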