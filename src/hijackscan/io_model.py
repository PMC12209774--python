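"""Shared domain types, tabular readers/writers and coordinate conventions.

Coordinate dialects
-------------------
Intervals (TADs, enhancers, copy-number segments, gene bodies) are stored
0-based half-open, BED style.  Point positions (breakend junctions,
heterozygous SNPs) are 1-based, VCF style.  Conversion happens once at read
time; all internal geometry works on half-open intervals.  Chromosome names
are normalized by stripping a leading ``chr`` and upper-casing X/Y/MT, so
mixed-reference inputs compare equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hijackscan")

SEX_CHROMS = {"X", "Y"}

#: breakend side retained on the derivative allele: coordinates <= pos
SIDE_LEFT = "left"
#: coordinates >= pos retained
SIDE_RIGHT = "right"


class InputError(ValueError):
    """Raised when an input file violates the format contract."""


def normalize_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in {"X", "Y", "MT", "M"}:
        c = "MT" if c.upper() in {"MT", "M"} else c.upper()
    if not c:
        raise InputError("empty chromosome name")
    return c


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a normalized chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise InputError("interval with empty chromosome")
        if self.end <= self.start:
            raise InputError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos_1based: int) -> bool:
        return self.chrom == chrom and self.start < pos_1based <= self.end

    def expanded(self, pad: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, max(0, self.start - pad), self.end + pad)


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    name: str
    body: GenomicInterval
    is_sex_chrom: bool = False
    is_imprinted: bool = False


@dataclass(frozen=True)
class Breakend:
    """One oriented SV junction: two ends, each with a retained side.

    ``side_* == "left"`` means coordinates <= pos survive on the derivative
    allele at that end; ``"right"`` means coordinates >= pos survive.  A side
    of ``None`` records an unknown/ambiguous orientation (both are tried
    downstream).
    """

    sample_id: str
    chrom_a: str
    pos_a: int
    side_a: Optional[str]
    chrom_b: str
    pos_b: int
    side_b: Optional[str]
    sv_class: Optional[str] = None

    def __post_init__(self):
        if self.pos_a < 1 or self.pos_b < 1:
            raise InputError("breakend positions are 1-based and must be >= 1")
        for s in (self.side_a, self.side_b):
            if s not in (SIDE_LEFT, SIDE_RIGHT, None):
                raise InputError(f"invalid breakend side {s!r}")

    def normalized(self) -> "Breakend":
        """Order intrachromosomal ends ascending by position."""
        if self.chrom_a == self.chrom_b and self.pos_b < self.pos_a:
            return replace(
                self,
                chrom_a=self.chrom_b, pos_a=self.pos_b, side_a=self.side_b,
                chrom_b=self.chrom_a, pos_b=self.pos_a, side_b=self.side_a,
            )
        return self

    @property
    def ends(self):
        return ((self.chrom_a, self.pos_a, self.side_a),
                (self.chrom_b, self.pos_b, self.side_b))


@dataclass(frozen=True)
class CopyNumberSegment:
    sample_id: str
    region: GenomicInterval
    copy_number: float

    def __post_init__(self):
        if self.copy_number < 0:
            raise InputError("copy number must be >= 0")


@dataclass
class ExpressionMatrix:
    """TPM expression, genes x samples."""

    genes: list
    samples: list
    tpm: np.ndarray

    def __post_init__(self):
        self.tpm = np.asarray(self.tpm, dtype=float)
        if self.tpm.shape != (len(self.genes), len(self.samples)):
            raise InputError("expression matrix shape does not match labels")
        if len(set(self.genes)) != len(self.genes):
            raise InputError("duplicate gene IDs in expression matrix")
        if len(set(self.samples)) != len(self.samples):
            raise InputError("duplicate sample IDs in expression matrix")
        if np.any(self.tpm < 0) or np.any(~np.isfinite(self.tpm)):
            raise InputError("expression values must be finite and >= 0")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.tpm[self._gene_index[gene_id]]

    def value(self, gene_id: str, sample_id: str) -> float:
        return float(self.tpm[self._gene_index[gene_id], self._sample_index[sample_id]])


@dataclass(frozen=True)
class AllelicSnpCount:
    sample_id: str
    gene_id: str
    chrom: str
    pos: int  # 1-based
    ref_count: int
    alt_count: int

    def __post_init__(self):
        if self.ref_count < 0 or self.alt_count < 0:
            raise InputError("allelic counts must be >= 0")
        if self.ref_count + self.alt_count < 1:
            raise InputError("allelic record with zero total coverage")


@dataclass(frozen=True)
class ScoredEnhancer:
    region: GenomicInterval
    enrichment: float

    def __post_init__(self):
        if self.enrichment < 0:
            raise InputError("enhancer enrichment must be >= 0")


@dataclass(frozen=True)
class FusionCall:
    sample_id: str
    gene5: str
    gene3: str

    def __post_init__(self):
        if self.gene5 == self.gene3:
            raise InputError("fusion partners must differ")


@dataclass
class ScanConfig:
    """Tunable parameters of the scan.

    Weights follow the combined score S = w_ovx*S_ovx + w_ase*S_ase +
    w_enh*S_enh - w_del*1_deleted.  ``bb_concentration`` is the beta-binomial
    concentration s (alpha = mean*s, beta = (1-mean)*s) shared by the
    monoallelic mixture components and the biallelic null.
    """

    w_overexpression: float = 4.0
    w_ase: float = 2.0
    w_enhancer: float = 1.0
    w_deletion: float = 1.0
    niter: int = 50
    tad_extension_bp: int = 80_000
    fallback_window_bp: int = 1_500_000
    min_tpm_expressed: float = 1.0
    sigma_floor: float = 0.3
    ase_cn_low: float = 2.0
    ase_cn_high: float = 4.0
    bb_concentration: float = 10.0
    mono_means: tuple = (0.02, 0.98)
    bi_mean: float = 0.5
    llr_clamp: float = 20.0
    deletion_cn_threshold: float = 1.5
    min_reference_samples: int = 5
    rng_seed: int = 0

    def __post_init__(self):
        for w in (self.w_overexpression, self.w_ase, self.w_enhancer, self.w_deletion):
            if w < 0:
                raise InputError("score weights must be >= 0")
        if self.niter < 1:
            raise InputError("niter must be >= 1")
        if self.tad_extension_bp < 0 or self.fallback_window_bp <= 0:
            raise InputError("windows must be positive")
        lo, hi = self.mono_means
        if not np.isclose(lo + hi, 1.0):
            raise InputError("mono_means must be symmetric about 0.5")

    @classmethod
    def from_dict(cls, d: dict) -> "ScanConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "mono_means" in d:
            d = dict(d, mono_means=tuple(d["mono_means"]))
        return cls(**d)

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in self.__dataclass_fields__}
        out["mono_means"] = list(self.mono_means)
        return out


@dataclass
class CohortBundle:
    """All per-cohort inputs, keyed by sample and gene."""

    expression: ExpressionMatrix
    breakends: list
    genes: list
    cna: Optional[list] = None
    allelic: Optional[list] = None
    tads: Optional[list] = None
    enhancers: Optional[list] = None
    fusions: Optional[list] = None
    config: ScanConfig = field(default_factory=ScanConfig)

    def __post_init__(self):
        samples = set(self.expression.samples)
        offenders = []
        for name, records in (("breakends", self.breakends),
                              ("cna", self.cna or []),
                              ("allelic", self.allelic or []),
                              ("fusions", self.fusions or [])):
            for r in records:
                if r.sample_id not in samples:
                    offenders.append((name, r.sample_id))
        if offenders:
            uniq = sorted({f"{n}:{s}" for n, s in offenders})
            raise InputError(
                "sample IDs absent from expression matrix: " + ", ".join(uniq)
            )
        if len(samples) < 10:
            logger.warning(
                "cohort has only %d samples; the method is designed for >= 10 "
                "samples and works best on large cohorts", len(samples)
            )

    @property
    def gene_by_id(self) -> dict:
        return {g.gene_id: g for g in self.genes}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, **kw)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error wording varies
        raise InputError(f"failed to parse {path}: {exc}") from exc


def _numeric(series: pd.Series, what: str, path) -> np.ndarray:
    vals = pd.to_numeric(series, errors="coerce")
    if vals.isna().any():
        bad = series[vals.isna()].iloc[0]
        raise InputError(f"{path}: malformed numeric {what}: {bad!r}")
    return vals.to_numpy()


def read_expression(path) -> ExpressionMatrix:
    """Read a TPM matrix: header = sample IDs, first column = gene_id."""
    with open(path) as fh:  # pandas mangles duplicate header names; check raw
        raw_header = fh.readline().rstrip("\n").split("\t")
    if len(set(raw_header[1:])) != len(raw_header[1:]):
        raise InputError(f"{path}: duplicate sample IDs in header")
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expression matrix needs a gene column and >= 1 sample")
    gene_col = df.columns[0]
    genes = df[gene_col].tolist()
    samples = list(df.columns[1:])
    dup_g = {g for g in genes if genes.count(g) > 1}
    if dup_g:
        raise InputError(f"{path}: duplicate gene IDs: {sorted(dup_g)}")
    body = np.column_stack([_numeric(df[s], f"TPM in column {s}", path) for s in samples])
    if np.any(body < 0):
        raise InputError(f"{path}: negative expression value")
    return ExpressionMatrix(genes=genes, samples=samples, tpm=body)


_SIDE_TOKENS = {"+": SIDE_LEFT, "-": SIDE_RIGHT, "−": SIDE_RIGHT, ".": None}


def read_breakends(path) -> list:
    """Read paired breakends: sample, chrom1, pos1, side1, chrom2, pos2, side2[, sv_class].

    Side tokens: ``+`` = left flank retained, ``-`` = right flank retained,
    ``.`` = unknown orientation.
    """
    df = _read_tsv(path)
    need = ["sample", "chrom1", "pos1", "side1", "chrom2", "pos2", "side2"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing breakend columns {missing}")
    out = []
    pos1 = _numeric(df["pos1"], "pos1", path).astype(int)
    pos2 = _numeric(df["pos2"], "pos2", path).astype(int)
    for i, row in df.iterrows():
        sides = []
        for col in ("side1", "side2"):
            tok = str(row[col]).strip()
            if tok not in _SIDE_TOKENS:
                raise InputError(f"{path}: unknown side token {tok!r} in row {i}")
            sides.append(_SIDE_TOKENS[tok])
        sv = row.get("sv_class")
        bnd = Breakend(
            sample_id=str(row["sample"]),
            chrom_a=normalize_chrom(row["chrom1"]), pos_a=int(pos1[i]), side_a=sides[0],
            chrom_b=normalize_chrom(row["chrom2"]), pos_b=int(pos2[i]), side_b=sides[1],
            sv_class=None if sv is None or pd.isna(sv) else str(sv),
        ).normalized()
        out.append(bnd)
    return out


def read_cna(path) -> list:
    """Read copy-number segments: sample, chrom, start, end, copy_number (half-open)."""
    df = _read_tsv(path)
    need = ["sample", "chrom", "start", "end", "copy_number"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing CNA columns {missing}")
    start = _numeric(df["start"], "start", path).astype(int)
    end = _numeric(df["end"], "end", path).astype(int)
    cn = _numeric(df["copy_number"], "copy_number", path)
    segs = [
        CopyNumberSegment(
            sample_id=str(df["sample"].iloc[i]),
            region=GenomicInterval(normalize_chrom(df["chrom"].iloc[i]),
                                   int(start[i]), int(end[i])),
            copy_number=float(cn[i]),
        )
        for i in range(len(df))
    ]
    by_sample = {}
    for s in segs:
        by_sample.setdefault((s.sample_id, s.region.chrom), []).append(s)
    for (sample, chrom), group in by_sample.items():
        group = sorted(group, key=lambda s: s.region.start)
        for a, b in zip(group, group[1:]):
            if a.region.end > b.region.start:
                raise InputError(
                    f"{path}: overlapping CNA segments for sample {sample} on {chrom}: "
                    f"{a.region.start}-{a.region.end} and {b.region.start}-{b.region.end}"
                )
    return segs


def read_allelic_counts(path) -> list:
    """Read RNA-seq allelic counts at heterozygous SNPs.

    Records with ref+alt == 0 are dropped with a warning; duplicate
    (sample, chrom, pos) rows are collapsed by summing counts.
    """
    df = _read_tsv(path)
    need = ["sample", "gene_id", "chrom", "pos", "ref_count", "alt_count"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing allelic-count columns {missing}")
    pos = _numeric(df["pos"], "pos", path).astype(int)
    ref = _numeric(df["ref_count"], "ref_count", path).astype(int)
    alt = _numeric(df["alt_count"], "alt_count", path).astype(int)
    merged = {}
    n_dropped = n_dup = 0
    for i in range(len(df)):
        if ref[i] + alt[i] == 0:
            n_dropped += 1
            continue
        key = (str(df["sample"].iloc[i]), normalize_chrom(df["chrom"].iloc[i]), int(pos[i]))
        if key in merged:
            n_dup += 1
            prev = merged[key]
            merged[key] = replace(prev, ref_count=prev.ref_count + int(ref[i]),
                                  alt_count=prev.alt_count + int(alt[i]))
        else:
            merged[key] = AllelicSnpCount(
                sample_id=key[0], gene_id=str(df["gene_id"].iloc[i]),
                chrom=key[1], pos=key[2],
                ref_count=int(ref[i]), alt_count=int(alt[i]),
            )
    if n_dropped:
        logger.warning("%s: dropped %d SNP rows with zero coverage", path, n_dropped)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate SNP rows by summing counts", path, n_dup)
    return list(merged.values())


def read_tads(path) -> list:
    """Read TADs from BED3 (0-based half-open, headerless)."""
    df = _read_tsv(path, header=None)
    if df.shape[1] < 3:
        raise InputError(f"{path}: BED3 requires >= 3 columns")
    start = _numeric(df[1], "start", path).astype(int)
    end = _numeric(df[2], "end", path).astype(int)
    return [
        GenomicInterval(normalize_chrom(df[0].iloc[i]), int(start[i]), int(end[i]))
        for i in range(len(df))
    ]


def read_enhancers(path) -> list:
    """Read scored enhancers from BED4 with column 4 = enrichment."""
    df = _read_tsv(path, header=None)
    if df.shape[1] < 4:
        raise InputError(f"{path}: enhancer BED requires 4 columns (chrom,start,end,enrichment)")
    start = _numeric(df[1], "start", path).astype(int)
    end = _numeric(df[2], "end", path).astype(int)
    score = _numeric(df[3], "enrichment", path)
    return [
        ScoredEnhancer(
            region=GenomicInterval(normalize_chrom(df[0].iloc[i]), int(start[i]), int(end[i])),
            enrichment=float(score[i]),
        )
        for i in range(len(df))
    ]


def read_fusions(path) -> list:
    df = _read_tsv(path)
    need = ["sample", "gene5", "gene3"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing fusion columns {missing}")
    return [
        FusionCall(sample_id=str(r["sample"]), gene5=str(r["gene5"]), gene3=str(r["gene3"]))
        for _, r in df.iterrows()
    ]


def read_gene_annotation(path, imprinted: Optional[Iterable[str]] = None) -> list:
    """Read gene bodies: gene_id, name, chrom, start, end (half-open)."""
    df = _read_tsv(path)
    need = ["gene_id", "name", "chrom", "start", "end"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing gene annotation columns {missing}")
    if df["gene_id"].duplicated().any():
        dups = df["gene_id"][df["gene_id"].duplicated()].tolist()
        raise InputError(f"{path}: duplicate gene IDs: {dups}")
    imprinted = set(imprinted or ())
    start = _numeric(df["start"], "start", path).astype(int)
    end = _numeric(df["end"], "end", path).astype(int)
    genes = []
    for i, row in df.iterrows():
        chrom = normalize_chrom(row["chrom"])
        genes.append(GeneAnnotation(
            gene_id=str(row["gene_id"]), name=str(row["name"]),
            body=GenomicInterval(chrom, int(start[i]), int(end[i])),
            is_sex_chrom=chrom in SEX_CHROMS,
            is_imprinted=str(row["gene_id"]) in imprinted,
        ))
    return genes


def read_imprinted(path) -> set:
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


# ---------------------------------------------------------------------------
# Writers (round-trip counterparts of the readers)
# ---------------------------------------------------------------------------

_SIDE_OUT = {SIDE_LEFT: "+", SIDE_RIGHT: "-", None: "."}


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(matrix.tpm, index=matrix.genes, columns=matrix.samples)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_breakends(breakends: Sequence[Breakend], path) -> None:
    rows = [
        {"sample": b.sample_id, "chrom1": b.chrom_a, "pos1": b.pos_a,
         "side1": _SIDE_OUT[b.side_a], "chrom2": b.chrom_b, "pos2": b.pos_b,
         "side2": _SIDE_OUT[b.side_b], "sv_class": b.sv_class or ""}
        for b in breakends
    ]
    cols = ["sample", "chrom1", "pos1", "side1", "chrom2", "pos2", "side2", "sv_class"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_cna(segments: Sequence[CopyNumberSegment], path) -> None:
    rows = [
        {"sample": s.sample_id, "chrom": s.region.chrom, "start": s.region.start,
         "end": s.region.end, "copy_number": s.copy_number}
        for s in segments
    ]
    cols = ["sample", "chrom", "start", "end", "copy_number"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_allelic_counts(counts: Sequence[AllelicSnpCount], path) -> None:
    rows = [
        {"sample": c.sample_id, "gene_id": c.gene_id, "chrom": c.chrom, "pos": c.pos,
         "ref_count": c.ref_count, "alt_count": c.alt_count}
        for c in counts
    ]
    cols = ["sample", "gene_id", "chrom", "pos", "ref_count", "alt_count"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_tads(tads: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for t in tads:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")


def write_enhancers(enhancers: Sequence[ScoredEnhancer], path) -> None:
    with open(path, "w") as fh:
        for e in enhancers:
            fh.write(f"{e.region.chrom}\t{e.region.start}\t{e.region.end}\t{e.enrichment:.6g}\n")


def write_fusions(fusions: Sequence[FusionCall], path) -> None:
    rows = [{"sample": f.sample_id, "gene5": f.gene5, "gene3": f.gene3} for f in fusions]
    pd.DataFrame(rows, columns=["sample", "gene5", "gene3"]).to_csv(path, sep="\t", index=False)


def write_gene_annotation(genes: Sequence[GeneAnnotation], path) -> None:
    rows = [
        {"gene_id": g.gene_id, "name": g.name, "chrom": g.body.chrom,
         "start": g.body.start, "end": g.body.end}
        for g in genes
    ]
    cols = ["gene_id", "name", "chrom", "start", "end"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Copy-number lookup/correction and expression filtering
# ---------------------------------------------------------------------------

def gene_copy_number(gene: GeneAnnotation, sample_id: str,
                     cna: Optional[Sequence[CopyNumberSegment]]) -> float:
    """Copy number of the segment maximally overlapping the gene body.

    Returns 2 (diploid) when no segment overlaps or no CNA data are provided.
    Ties on overlap break toward the leftmost segment for determinism.
    """
    if not cna:
        return 2.0
    best, best_ov = None, 0
    for seg in cna:
        if seg.sample_id != sample_id:
            continue
        ov = seg.region.overlap(gene.body)
        if ov > best_ov or (ov == best_ov and ov > 0 and best is not None
                            and seg.region.start < best.region.start):
            best, best_ov = seg, ov
    return best.copy_number if best is not None else 2.0


def copy_number_correct(tpm: float, cn: float) -> float:
    """Scale TPM by 2/CN to remove dosage effects; CN floored at 1."""
    return tpm * 2.0 / max(cn, 1.0)


def filter_expressed_genes(expr: ExpressionMatrix, threshold: float = 1.0) -> list:
    """Gene IDs whose maximum TPM across samples strictly exceeds threshold."""
    keep = expr.tpm.max(axis=1) > threshold
    return [g for g, k in zip(expr.genes, keep) if k]


def merge_enhancer_rankings(lists: Sequence[Sequence[ScoredEnhancer]]) -> list:
    """Merge enhancer rankings from several datasets by averaging scores.

    Enhancers are matched across datasets by >= 50% reciprocal overlap; the
    merged enrichment is the arithmetic mean over all datasets, with datasets
    lacking the enhancer contributing 0.
    """
    if not lists:
        raise InputError("merge_enhancer_rankings requires at least one list")
    n = len(lists)
    clusters = []  # (region, [scores])
    for lst in lists:
        for enh in lst:
            best_i, best_ov = None, 0
            for i, (region, _) in enumerate(clusters):
                ov = region.overlap(enh.region)
                if (ov >= 0.5 * len(region) and ov >= 0.5 * len(enh.region)
                        and ov > best_ov):
                    best_i, best_ov = i, ov
            if best_i is None:
                clusters.append((enh.region, [enh.enrichment]))
            else:
                clusters[best_i][1].append(enh.enrichment)
    return [ScoredEnhancer(region=r, enrichment=sum(scores) / n) for r, scores in clusters]
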