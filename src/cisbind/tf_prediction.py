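"""Cis-sequence to transcription-factor prediction engine.

The prediction chain mirrors how annotated motif-TF repositories are used
in practice: a query cis-sequence (or motif) is aligned against every motif
in an annotated database; motifs similar beyond an E-value threshold point
to their cognate TFs; each such TF is transferred to the target proteome by
local protein alignment; and candidates whose DNA-contacting interface
residues are poorly conserved are discarded.  The default thresholds are
the ones commonly used for this kind of screen: motif E-value 1e-3,
homology E-value 1e-10, interface similarity 50%.

Homology search is exact Smith-Waterman local alignment (BLOSUM62, gap
open 11 / extend 1) with Karlin-Altschul-style E-values using the
conventional gapped-BLOSUM62 constants (lambda = 0.267, K = 0.041); it is
deterministic and needs no external search tool.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ValidationError
from .motif_model import (CisSequence, NucleotideMotif, motif_from_sequences,
                          read_motifs)
from .motif_compare import (MotifAlignment, NullModel, align_motifs,
                            build_null, motif_evalue)
from .structure_interface import (InterfaceAnnotation, SubstitutionMatrix,
                                  blosum62, interface_similarity)


@dataclass
class TFRecord:
    tf_id: str
    name: str
    family: str
    species: str
    protein_seq: str
    motif_ids: list[str]
    interface: InterfaceAnnotation | None = None

    def __post_init__(self):
        if not self.protein_seq:
            raise ValidationError(f"TF {self.tf_id}: empty protein sequence")


@dataclass
class MotifTFDatabase:
    """Motifs linked to the TFs they were experimentally derived from."""

    motifs: list[NucleotideMotif]
    tfs: list[TFRecord]
    links: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        motif_ids = {m.id for m in self.motifs}
        tf_ids = {t.tf_id for t in self.tfs}
        if not self.links:
            self.links = {}
            for tf in self.tfs:
                for mid in tf.motif_ids:
                    self.links.setdefault(mid, []).append(tf.tf_id)
        dangling = []
        for tf in self.tfs:
            dangling.extend(m for m in tf.motif_ids if m not in motif_ids)
        for mid, tids in self.links.items():
            if mid not in motif_ids:
                dangling.append(mid)
            dangling.extend(t for t in tids if t not in tf_ids)
        if dangling:
            raise ValidationError(
                f"dangling database links: {sorted(set(dangling))}")
        for mid, tids in self.links.items():
            for tid in tids:
                tf = self.tf(tid)
                if mid not in tf.motif_ids:
                    raise ValidationError(
                        f"link {mid} -> {tid} not mirrored in TF record")

    def motif(self, motif_id: str) -> NucleotideMotif:
        for m in self.motifs:
            if m.id == motif_id:
                return m
        raise KeyError(motif_id)

    def tf(self, tf_id: str) -> TFRecord:
        for t in self.tfs:
            if t.tf_id == tf_id:
                return t
        raise KeyError(tf_id)


@dataclass
class Proteome:
    """Target protein set; the search space for homology transfer."""

    entries: dict[str, tuple[str, str]]  # id -> (description, sequence)

    def __post_init__(self):
        for pid, (_, seq) in self.entries.items():
            if not seq:
                raise ValidationError(f"protein {pid}: empty sequence")

    @property
    def total_residues(self) -> int:
        return sum(len(seq) for _, seq in self.entries.values())

    def __len__(self):
        return len(self.entries)


@dataclass
class PredictionParams:
    stamp_evalue_max: float = 1e-3
    blast_evalue_max: float = 1e-10
    interface_min: float = 50.0
    require_interface: bool = True

    def __post_init__(self):
        if (self.stamp_evalue_max <= 0 or self.blast_evalue_max <= 0
                or self.interface_min < 0):
            raise ValidationError("thresholds must be positive")


@dataclass
class ProteinAlignment:
    """One local alignment path with its score statistics."""

    query_id: str
    target_id: str
    aligned_pairs: list[tuple[int, int]]  # (query index, target index)
    raw_score: float
    bit_score: float = 0.0
    e_value: float = math.inf

    def query_to_target(self) -> dict[int, int]:
        return dict(self.aligned_pairs)


@dataclass
class Prediction:
    """One query -> database motif -> database TF -> candidate chain."""

    query_id: str
    db_motif_id: str
    motif_evalue: float
    db_tf_id: str
    candidate_protein_id: str
    homology_evalue: float
    interface_similarity: float | None
    passed_filters: bool

    @property
    def rank_key(self) -> tuple[float, float]:
        return (self.motif_evalue, self.homology_evalue)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _format_from_path(path) -> str:
    suffix = Path(path).suffix.lower()
    return {".meme": "meme", ".jaspar": "jaspar", ".pfm": "jaspar"}.get(
        suffix, "transfac")


def load_proteome(fasta_path) -> Proteome:
    entries = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        entries[rec.id] = (rec.description, str(rec.seq).upper())
    return Proteome(entries=entries)


def load_database(motif_path, tf_table_path, protein_fasta_path,
                  interface_json_path=None) -> MotifTFDatabase:
    """Assemble a motif-TF database from its on-disk parts.

    The TF table is a TSV with columns tf_id, name, family, species,
    motif_ids (semicolon-separated); protein sequences come from a FASTA
    keyed by tf_id; interface annotations from an optional JSON mapping
    tf_id to a list of 0-based positions.
    """
    motifs = read_motifs(motif_path, _format_from_path(motif_path))
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(protein_fasta_path), "fasta")}
    interfaces = {}
    if interface_json_path is not None:
        with open(interface_json_path) as fh:
            interfaces = json.load(fh)
    tfs = []
    with open(tf_table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            tf_id = fields[idx["tf_id"]]
            if tf_id not in seqs:
                raise ValidationError(f"TF {tf_id}: no protein sequence "
                                      "in FASTA")
            iface = None
            if tf_id in interfaces:
                iface = InterfaceAnnotation(
                    tf_id=tf_id, positions=tuple(interfaces[tf_id]))
            tfs.append(TFRecord(
                tf_id=tf_id, name=fields[idx["name"]],
                family=fields[idx["family"]], species=fields[idx["species"]],
                protein_seq=seqs[tf_id],
                motif_ids=[m for m in fields[idx["motif_ids"]].split(";")
                           if m],
                interface=iface))
    return MotifTFDatabase(motifs=motifs, tfs=tfs)


# ---------------------------------------------------------------------------
# Motif search
# ---------------------------------------------------------------------------

def search_similar_motifs(query: NucleotideMotif, db: MotifTFDatabase,
                          params: PredictionParams | None = None,
                          null: NullModel | None = None,
                          seed: int = 0
                          ) -> list[tuple[str, MotifAlignment, float]]:
    """Database motifs similar to the query, ascending E-value."""
    if params is None:
        params = PredictionParams()
    if null is None:
        null = build_null(db.motifs, query.width, seed=seed)
    hits = []
    for m in db.motifs:
        mo = min(5, query.width, m.width)
        aln = align_motifs(query, m, min_overlap=mo)
        e = motif_evalue(aln, null, db_size=len(db.motifs))
        if e <= params.stamp_evalue_max:
            aln.e_value = e
            hits.append((m.id, aln, e))
    hits.sort(key=lambda h: (h[2], h[0]))
    return hits


# ---------------------------------------------------------------------------
# Protein homology
# ---------------------------------------------------------------------------

_AA = set("ACDEFGHIKLMNPQRSTVWYBZX*")


def _make_aligner(matrix_name: str = "BLOSUM62", gap_open: int = 11,
                  gap_extend: int = 1) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # first gap position costs open + extend, as in BLAST's 11/1 scheme
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_protein(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _AA
    if bad:
        raise ValidationError(f"non-amino-acid characters: {sorted(bad)}")
    return seq


def local_protein_align(a: str, b: str, matrix: str = "BLOSUM62",
                        gap_open: int = 11, gap_extend: int = 1,
                        query_id: str = "", target_id: str = ""
                        ) -> ProteinAlignment:
    """Optimal Smith-Waterman local alignment of two protein sequences."""
    a, b = _check_protein(a), _check_protein(b)
    if not a or not b:
        raise ValidationError("empty protein sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return ProteinAlignment(query_id=query_id, target_id=target_id,
                                aligned_pairs=[], raw_score=0.0)
    aln = next(iter(aligner.align(a, b)))
    pairs = []
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        pairs.extend(zip(range(qs, qe), range(ts, te)))
    return ProteinAlignment(query_id=query_id, target_id=target_id,
                            aligned_pairs=pairs, raw_score=float(score))


def protein_evalue(aln: ProteinAlignment, query_len: int, db_residues: int,
                   lambda_: float = 0.267, K: float = 0.041) -> float:
    """Karlin-Altschul-style expectation: E = K * m * n * exp(-lambda * S)."""
    if query_len <= 0 or db_residues <= 0:
        raise ValidationError("lengths must be positive")
    return K * query_len * db_residues * math.exp(-lambda_ * aln.raw_score)


def find_homologs(tf: TFRecord, proteome: Proteome,
                  params: PredictionParams | None = None,
                  matrix: SubstitutionMatrix | None = None
                  ) -> list[tuple[str, ProteinAlignment, float | None]]:
    """Proteome members homologous to a database TF, ascending E-value.

    When the TF carries an interface annotation and ``require_interface``
    is on, candidates whose interface similarity falls below
    ``interface_min`` are dropped; TFs without an annotation pass the
    filter with similarity recorded as absent.
    """
    if params is None:
        params = PredictionParams()
    if matrix is None:
        matrix = blosum62()
    aligner = _make_aligner()
    n = proteome.total_residues
    m = len(tf.protein_seq)
    out = []
    for pid, (_, seq) in proteome.entries.items():
        score = aligner.score(tf.protein_seq, seq)
        quick = ProteinAlignment(query_id=tf.tf_id, target_id=pid,
                                 aligned_pairs=[], raw_score=float(score))
        e = protein_evalue(quick, m, n)
        if e > params.blast_evalue_max:
            continue
        aln = local_protein_align(tf.protein_seq, seq, query_id=tf.tf_id,
                                  target_id=pid)
        aln.e_value = e
        aln.bit_score = (0.267 * aln.raw_score - math.log(0.041)) / math.log(2)
        iface_sim: float | None = None
        if tf.interface is not None and tf.interface.positions:
            iface_sim = interface_similarity(tf.protein_seq, seq,
                                             tf.interface, aln, matrix)
            if params.require_interface and iface_sim < params.interface_min:
                continue
        out.append((pid, aln, iface_sim))
    out.sort(key=lambda h: (h[1].e_value, h[0]))
    return out


# ---------------------------------------------------------------------------
# End-to-end prediction
# ---------------------------------------------------------------------------

def as_query_motif(query: CisSequence | NucleotideMotif | str
                   ) -> NucleotideMotif:
    """Coerce a query to a motif; a bare cis-sequence becomes a single-copy
    column-pure matrix."""
    if isinstance(query, NucleotideMotif):
        return query
    if isinstance(query, CisSequence):
        return motif_from_sequences([query.element],
                                    id=f"seq{query.seq_nr}")
    return motif_from_sequences([str(query)], id=str(query))


def predict_tfs(query: CisSequence | NucleotideMotif | str,
                db: MotifTFDatabase, proteome: Proteome,
                params: PredictionParams | None = None, seed: int = 0,
                null: NullModel | None = None) -> list[Prediction]:
    """Full prediction chain for one query.

    Results are deduplicated per candidate protein, keeping the chain with
    the best (motif E-value, homology E-value) rank key, and sorted by that
    key.
    """
    if params is None:
        params = PredictionParams()
    qmotif = as_query_motif(query)
    if null is None:
        null = build_null(db.motifs, qmotif.width, seed=seed)
    hits = search_similar_motifs(qmotif, db, params, null)
    best: dict[str, Prediction] = {}
    homolog_cache: dict[str, list] = {}
    for motif_id, aln, m_e in hits:
        for tf_id in db.links.get(motif_id, []):
            if tf_id not in homolog_cache:
                homolog_cache[tf_id] = find_homologs(db.tf(tf_id), proteome,
                                                     params)
            for pid, paln, iface in homolog_cache[tf_id]:
                pred = Prediction(
                    query_id=qmotif.id, db_motif_id=motif_id,
                    motif_evalue=m_e, db_tf_id=tf_id,
                    candidate_protein_id=pid,
                    homology_evalue=paln.e_value,
                    interface_similarity=iface, passed_filters=True)
                prev = best.get(pid)
                if prev is None or pred.rank_key < prev.rank_key:
                    best[pid] = pred
    return sorted(best.values(), key=lambda p: (p.rank_key,
                                                p.candidate_protein_id))


def predictions_to_table(predictions: list[Prediction]) -> list[dict]:
    rows = []
    for p in predictions:
        rows.append({
            "query_id": p.query_id, "db_motif_id": p.db_motif_id,
            "motif_evalue": f"{p.motif_evalue:.3g}",
            "db_tf_id": p.db_tf_id,
            "candidate_protein_id": p.candidate_protein_id,
            "homology_evalue": f"{p.homology_evalue:.3g}",
            "interface_similarity": (
                "" if p.interface_similarity is None
                else f"{p.interface_similarity:.1f}"),
            "passed_filters": str(p.passed_filters).lower(),
        })
    return rows
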