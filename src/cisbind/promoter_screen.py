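"""Promoter extraction, motif occurrence scanning and the expression filter.

Co-regulated gene sets are selected from a gene x condition fold-change
table (genes at least 2-fold induced over the untreated control count as
up-regulated).  Promoters are the 1,000 nt upstream of the transcription
start site when known, otherwise of the ATG start codon.  A candidate
cis-sequence is kept by the in-silico expression filter when, ranking all
conditions by the enrichment of motif-containing genes among each
condition's up-regulated set, at least two drought-associated conditions
appear among the top three.

Enrichment is scored with the hypergeometric tail probability of drawing at
least the observed number of motif-containing genes among a condition's
up-regulated genes; gene-level presence/absence feeds the test, so repeated
hits within one promoter count once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .motif_model import IUPACPattern, iupac_scan

_RC = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GeneAnnotation:
    gene_id: str
    chrom: str
    strand: str
    atg: int  # 1-based
    tss: int | None = None  # 1-based, optional

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: invalid strand")
        if self.atg <= 0 or (self.tss is not None and self.tss <= 0):
            raise ValidationError(f"{self.gene_id}: coordinates must be "
                                  "positive")

    @property
    def anchor(self) -> int:
        return self.tss if self.tss is not None else self.atg


@dataclass
class Condition:
    condition_id: str
    tissue: str = ""
    timepoint: str = ""
    is_drought: bool = False


@dataclass
class ExpressionMatrix:
    """Positive fold-change ratios (treatment / control), genes x conditions."""

    genes: list[str]
    conditions: list[Condition]
    fold_change: np.ndarray

    def __post_init__(self):
        self.fold_change = np.asarray(self.fold_change, dtype=float)
        if self.fold_change.shape != (len(self.genes), len(self.conditions)):
            raise ValidationError("fold_change shape mismatch")
        if not np.all(np.isfinite(self.fold_change)):
            raise ValidationError("fold changes must be finite")
        if np.any(self.fold_change <= 0):
            raise ValidationError("fold changes must be > 0")

    def condition_index(self, condition_id: str) -> int:
        for i, c in enumerate(self.conditions):
            if c.condition_id == condition_id:
                return i
        raise KeyError(condition_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fold_change, index=self.genes,
                            columns=[c.condition_id for c in self.conditions])


@dataclass
class GeneSet:
    label: str
    gene_ids: frozenset

    def __post_init__(self):
        self.gene_ids = frozenset(self.gene_ids)


@dataclass
class Occurrence:
    pattern_id: str
    gene_id: str
    position: int  # 0-based start on the forward promoter sequence
    strand: str
    matched: str


@dataclass
class OccurrenceTable:
    rows: list[Occurrence]

    @property
    def genes_with_hits(self) -> frozenset:
        return frozenset(r.gene_id for r in self.rows)

    def __len__(self):
        return len(self.rows)


@dataclass
class PromoterRecord:
    gene_id: str
    sequence: str
    truncated: bool = False

    def __len__(self):
        return len(self.sequence)


# ---------------------------------------------------------------------------

def select_upregulated(expr: ExpressionMatrix, condition_id: str,
                       fold_min: float = 2.0,
                       fold_max: float | None = None) -> GeneSet:
    """Genes induced at least ``fold_min``-fold (and below ``fold_max``
    when given) in one condition; the lower bound is inclusive."""
    if fold_min <= 0:
        raise ValidationError("fold_min must be > 0")
    col = expr.fold_change[:, expr.condition_index(condition_id)]
    keep = col >= fold_min
    if fold_max is not None:
        keep &= col < fold_max
    return GeneSet(label=condition_id,
                   gene_ids=frozenset(g for g, k in zip(expr.genes, keep)
                                      if k))


def extract_upstream(genome: dict[str, str], ann: GeneAnnotation,
                     length: int = 1000) -> PromoterRecord:
    """The ``length`` bases 5' of the TSS (or ATG fallback), stranded.

    The anchor base itself is excluded; windows running off the contig edge
    are truncated, never padded, and flagged.
    """
    if ann.chrom not in genome:
        raise ValidationError(f"{ann.gene_id}: contig {ann.chrom!r} unknown")
    contig = genome[ann.chrom].upper()
    anchor = ann.anchor
    if not (1 <= anchor <= len(contig)):
        raise ValidationError(f"{ann.gene_id}: anchor {anchor} off contig")
    if ann.strand == "+":
        start = max(0, anchor - 1 - length)
        seq = contig[start:anchor - 1]
        truncated = anchor - 1 - length < 0
    else:
        end = min(len(contig), anchor + length)
        seq = contig[anchor:end].translate(_RC)[::-1]
        truncated = anchor + length > len(contig)
    return PromoterRecord(gene_id=ann.gene_id, sequence=seq,
                          truncated=truncated)


def scan_promoters(query: IUPACPattern | str,
                   promoters: list[PromoterRecord],
                   both_strands: bool = True) -> OccurrenceTable:
    """Exhaustive occurrence table of a (degenerate) pattern in promoters."""
    if not promoters:
        raise ValidationError("no promoters to scan")
    if isinstance(query, str):
        query = IUPACPattern(query)
    rows = []
    for prom in promoters:
        for start, strand in iupac_scan(query, prom.sequence, both_strands):
            rows.append(Occurrence(
                pattern_id=query.pattern, gene_id=prom.gene_id,
                position=start, strand=strand,
                matched=prom.sequence[start:start + len(query)]))
    return OccurrenceTable(rows=rows)


def rank_conditions(occ: OccurrenceTable, expr: ExpressionMatrix,
                    fold_min: float = 2.0) -> list[tuple[str, float]]:
    """Conditions ranked by hypergeometric enrichment of motif-containing
    genes among each condition's up-regulated set (most enriched first).

    Ties break toward the larger overlap with the up-regulated set, then
    by condition id.
    """
    hit_genes = occ.genes_with_hits
    unknown = hit_genes - set(expr.genes)
    if unknown:
        raise ValidationError(
            f"occurrence genes missing from expression matrix: "
            f"{sorted(unknown)}")
    M = len(expr.genes)
    N = len(hit_genes)
    scored = []
    for cond in expr.conditions:
        up = select_upregulated(expr, cond.condition_id, fold_min).gene_ids
        k = len(hit_genes & up)
        score = float(hypergeom.sf(k - 1, M, len(up), N)) if N else 1.0
        scored.append((cond.condition_id, score, k))
    scored.sort(key=lambda t: (t[1], -t[2], t[0]))
    return [(cid, score) for cid, score, _ in scored]


def drought_filter(ranked: list[tuple[str, float]],
                   labels: dict[str, bool], top_n: int = 3,
                   min_drought: int = 2) -> bool:
    """True when at least ``min_drought`` of the ``top_n`` best-ranked
    conditions are drought-associated."""
    if not ranked:
        raise ValidationError("empty ranking")
    if top_n < min_drought:
        raise ValidationError("top_n must be >= min_drought")
    top = [cid for cid, _ in ranked[:top_n]]
    return sum(bool(labels.get(cid, False)) for cid in top) >= min_drought


# ---------------------------------------------------------------------------
# File I/O helpers
# ---------------------------------------------------------------------------

def read_expression_tsv(path) -> ExpressionMatrix:
    """Expression TSV with a '#condition' metadata header block.

    Header lines: ``#condition<TAB>id<TAB>tissue<TAB>timepoint<TAB>is_drought``
    followed by a TSV with a 'gene' column and one column per condition.
    """
    conditions = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#condition\t"):
            _, cid, tissue, timepoint, drought = line.split("\t")
            conditions.append(Condition(
                condition_id=cid, tissue=tissue, timepoint=timepoint,
                is_drought=drought.lower() in ("1", "true", "yes")))
            body_start = i + 1
        elif line.startswith("#"):
            body_start = i + 1
        else:
            break
    header = lines[body_start].split("\t")
    if header[0] != "gene":
        raise ValidationError("expression table must start with a 'gene' "
                              "column")
    order = {c.condition_id: i for i, c in enumerate(conditions)}
    col_idx = [order[c] for c in header[1:]]
    genes, values = [], []
    for line in lines[body_start + 1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        genes.append(fields[0])
        row = np.empty(len(conditions))
        for ci, v in zip(col_idx, fields[1:]):
            row[ci] = float(v)
        values.append(row)
    return ExpressionMatrix(genes=genes, conditions=conditions,
                            fold_change=np.array(values))


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        for c in expr.conditions:
            fh.write(f"#condition\t{c.condition_id}\t{c.tissue}\t"
                     f"{c.timepoint}\t{int(c.is_drought)}\n")
        fh.write("gene\t" + "\t".join(c.condition_id
                                      for c in expr.conditions) + "\n")
        for g, row in zip(expr.genes, expr.fold_change):
            fh.write(g + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_annotation_tsv(path) -> list[GeneAnnotation]:
    """Gene annotation TSV: gene_id, chrom, strand, tss (may be empty), atg."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            tss = f[idx["tss"]].strip()
            out.append(GeneAnnotation(
                gene_id=f[idx["gene_id"]], chrom=f[idx["chrom"]],
                strand=f[idx["strand"]],
                tss=int(tss) if tss else None, atg=int(f[idx["atg"]])))
    return out


def read_annotation_gff3(path) -> list[GeneAnnotation]:
    """Gene annotations from GFF3 ``gene`` features.

    The ATG anchor falls back to the gene start (strand-aware); a
    ``five_prime_UTR`` child, when present, pushes the TSS upstream of it.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="merge")
    out = []
    for gene in db.features_of_type("gene"):
        strand = gene.strand if gene.strand in ("+", "-") else "+"
        tss = gene.start if strand == "+" else gene.end
        atg = tss
        cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        if cds:
            atg = cds[0].start if strand == "+" else cds[-1].end
        out.append(GeneAnnotation(gene_id=gene.id, chrom=gene.seqid,
                                  strand=strand, tss=tss, atg=atg))
    return out
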