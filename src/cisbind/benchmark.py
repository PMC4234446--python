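"""Gold-standard handling and benchmarking of TF predictions.

The packaged gold standard transcribes a yeast one-hybrid screen of 15
cis-sequences (plus one screened sequence with no table entries of its
own): for each screened sequence, the TF genes whose products activated
transcription from it but not from its mutated version.  TF identity is
the locus identifier, not a protein isoform, because the screen reports
loci.

A cis-element is *predictable* when the motif-TF database holds at least
one motif significantly similar to it whose cognate TF is homologous to at
least one experimentally verified interactor.  Prediction quality is
summarised per element (gold hits among predicted candidates) and overall
(sensitivity over all gold TFs, specificity over a configured candidate
universe, and the number of predictions made per validated TF).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from itertools import product

from .errors import ValidationError
from .motif_model import CisSequence, motif_from_sequences
from .motif_compare import NullModel, build_null
from .tf_prediction import (MotifTFDatabase, PredictionParams, Prediction,
                            Proteome, find_homologs, local_protein_align,
                            protein_evalue, predict_tfs,
                            search_similar_motifs)

_FIXTURE = "table3_gold_standard.tsv"
_CIS_FIXTURE = "table1_cis_sequences.tsv"


@dataclass
class GoldStandardEntry:
    motif_group: str
    screened_seq: str
    mutated_seq: str | None = None
    tf_gene_id: str | None = None
    family: str | None = None
    tf_name: str | None = None
    flagged: bool = False

    def __post_init__(self):
        if (self.mutated_seq and
                len(self.mutated_seq) != len(self.screened_seq)):
            raise ValidationError(
                f"{self.screened_seq}: mutated sequence length mismatch")


@dataclass
class GoldStandard:
    entries: list[GoldStandardEntry]

    @property
    def elements(self) -> list[str]:
        seen = []
        for e in self.entries:
            if e.screened_seq not in seen:
                seen.append(e.screened_seq)
        return seen

    def entries_for(self, element: str) -> list[GoldStandardEntry]:
        if element not in self.elements:
            raise KeyError(element)
        return [e for e in self.entries
                if e.screened_seq == element and e.tf_gene_id]

    def tf_ids_for(self, element: str) -> set[str]:
        return {e.tf_gene_id for e in self.entries_for(element)}

    @property
    def groups(self) -> set[str]:
        return {e.motif_group for e in self.entries}


@dataclass
class ElementReport:
    element: str
    predictable: bool
    n_gold: int
    n_predictions: int
    n_true_positive: int


@dataclass
class BenchmarkReport:
    per_element: list[ElementReport]
    sensitivity: float
    specificity: float
    predictions_per_validated: float | None
    params: PredictionParams


@dataclass
class OverlapStats:
    set_a_size: int
    set_b_size: int
    intersection: int
    union: int
    pct_of_a: float
    pct_of_union: float


# ---------------------------------------------------------------------------

def load_gold_standard(path=None) -> GoldStandard:
    """Read the gold-standard TSV (packaged fixture by default)."""
    if path is None:
        ref = resources.files("cisbind.fixtures").joinpath(_FIXTURE)
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    entries = []
    lines = text.splitlines()
    header = lines[0].split("\t")
    idx = {c: i for i, c in enumerate(header)}
    required = ("motif_group", "screened_seq")
    for col in required:
        if col not in idx:
            raise ValidationError(f"gold standard lacks column {col!r}")

    def get(fields, col):
        i = idx.get(col)
        if i is None or i >= len(fields):
            return None
        return fields[i].strip() or None

    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            entries.append(GoldStandardEntry(
                motif_group=fields[idx["motif_group"]],
                flagged=bool(get(fields, "flagged")),
                screened_seq=fields[idx["screened_seq"]],
                mutated_seq=get(fields, "mutated_seq"),
                tf_gene_id=get(fields, "tf_gene_id"),
                family=get(fields, "family"),
                tf_name=get(fields, "tf_name")))
        except (ValidationError, IndexError) as exc:
            raise ValidationError(f"line {ln}: {exc}") from exc
    return GoldStandard(entries=entries)


def load_cis_sequences(path=None) -> list[CisSequence]:
    """The screened cis-sequences with their provenance (packaged fixture
    by default).  Rows with several upstream positions keep the first."""
    if path is None:
        text = resources.files("cisbind.fixtures").joinpath(
            _CIS_FIXTURE).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = text.splitlines()
    idx = {c: i for i, c in enumerate(lines[0].split("\t"))}
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        position = int(f[idx["position"]].split("/")[0])
        out.append(CisSequence(
            seq_nr=f[idx["seq_nr"]], element=f[idx["element"]],
            motif_group=f[idx["motif_group"]], query_id=f[idx["query_id"]],
            gene=f[idx["gene"]], position=position))
    return out


def family_counts(gold: GoldStandard, element: str) -> dict[str, int]:
    """Distinct interacting TF genes per family for one element."""
    counts: dict[str, set] = {}
    for e in gold.entries_for(element):
        counts.setdefault(e.family or "unknown", set()).add(e.tf_gene_id)
    return {fam: len(ids) for fam, ids in sorted(counts.items())}


def overlap_stats(gold: GoldStandard, elem_a: str, elem_b: str,
                  family: str | None = None) -> OverlapStats:
    """Set algebra on the distinct TF genes of two elements.

    ``pct_of_a`` is the share of element A's TFs also found with element B;
    ``pct_of_union`` the share of the union common to both.  Percentages
    are rounded to one decimal.
    """
    def ids(elem):
        return {e.tf_gene_id for e in gold.entries_for(elem)
                if family is None or e.family == family}

    a, b = ids(elem_a), ids(elem_b)
    inter, union = a & b, a | b
    return OverlapStats(
        set_a_size=len(a), set_b_size=len(b),
        intersection=len(inter), union=len(union),
        pct_of_a=round(100.0 * len(inter) / len(a), 1) if a else 0.0,
        pct_of_union=(round(100.0 * len(inter) / len(union), 1)
                      if union else 0.0))


# ---------------------------------------------------------------------------

def classify_predictable(element: str, db: MotifTFDatabase,
                         gold: GoldStandard,
                         params: PredictionParams | None = None,
                         null: NullModel | None = None,
                         gold_proteins: dict[str, str] | None = None,
                         seed: int = 0) -> bool:
    """Whether the database could in principle have found this element's TFs.

    True when some database motif aligns to the element below the motif
    E-value threshold and its cognate TF is homologous (below the homology
    E-value threshold) to at least one gold TF.  Elements with no gold TFs
    are unpredictable by convention.  Gold TF protein sequences are taken
    from ``gold_proteins`` or, failing that, from same-id database records.
    """
    if params is None:
        params = PredictionParams()
    gold_ids = gold.tf_ids_for(element)
    if not gold_ids:
        return False
    if gold_proteins is None:
        gold_proteins = {}
    seqs = {}
    for gid in gold_ids:
        if gid in gold_proteins:
            seqs[gid] = gold_proteins[gid]
        else:
            try:
                seqs[gid] = db.tf(gid).protein_seq
            except KeyError:
                continue
    if not seqs:
        return False
    query = motif_from_sequences([element], id=element)
    if null is None:
        null = build_null(db.motifs, query.width, seed=seed)
    hits = search_similar_motifs(query, db, params, null)
    n_res = sum(len(s) for s in seqs.values())
    for motif_id, _, _ in hits:
        for tf_id in db.links.get(motif_id, []):
            tf = db.tf(tf_id)
            for gid, gseq in seqs.items():
                aln = local_protein_align(tf.protein_seq, gseq)
                e = protein_evalue(aln, len(tf.protein_seq), n_res)
                if e <= params.blast_evalue_max:
                    return True
    return False


def evaluate_predictions(predictions: dict[str, list[Prediction]],
                         gold: GoldStandard, db: MotifTFDatabase,
                         universe: set[str] | None = None,
                         params: PredictionParams | None = None,
                         predictable: dict[str, bool] | None = None
                         ) -> BenchmarkReport:
    """Confusion-matrix summary of per-element predictions against gold.

    A true positive is a predicted candidate whose identifier equals a
    gold TF gene for that element.  Sensitivity pools all gold TFs of
    elements with at least one gold entry; specificity pools, per element,
    the candidate ``universe`` (default: the database TF list, standing in
    for the cloned TF library a screen draws from) minus that element's
    gold TFs.
    """
    if params is None:
        params = PredictionParams()
    if universe is None:
        universe = {tf.tf_id for tf in db.tfs}
    per_element = []
    tp_total = fn_total = fp_total = tn_total = 0
    n_predictions_total = 0
    for element in gold.elements:
        gold_ids = gold.tf_ids_for(element)
        preds = predictions.get(element, [])
        pred_ids = {p.candidate_protein_id for p in preds}
        tp = len(pred_ids & gold_ids)
        per_element.append(ElementReport(
            element=element,
            predictable=(predictable or {}).get(element, bool(gold_ids)),
            n_gold=len(gold_ids), n_predictions=len(preds),
            n_true_positive=tp))
        n_predictions_total += len(preds)
        if gold_ids:
            tp_total += tp
            fn_total += len(gold_ids - pred_ids)
        negatives = universe - gold_ids
        fp = len(pred_ids & negatives)
        fp_total += fp
        tn_total += len(negatives) - fp
    sensitivity = (tp_total / (tp_total + fn_total)
                   if tp_total + fn_total else 0.0)
    specificity = (tn_total / (tn_total + fp_total)
                   if tn_total + fp_total else 1.0)
    ppv = (n_predictions_total / tp_total) if tp_total else None
    return BenchmarkReport(per_element=per_element, sensitivity=sensitivity,
                           specificity=specificity,
                           predictions_per_validated=ppv, params=params)


def parameter_sweep(grid: dict[str, list], db: MotifTFDatabase,
                    proteome: Proteome, gold: GoldStandard,
                    queries: dict[str, object],
                    universe: set[str] | None = None,
                    seed: int = 0
                    ) -> list[tuple[PredictionParams, BenchmarkReport]]:
    """One benchmark report per point of a threshold grid.

    ``grid`` maps PredictionParams field names to candidate values;
    ``queries`` maps gold elements to their query motifs.
    """
    if not grid:
        raise ValidationError("empty parameter grid")
    names = sorted(grid)
    out = []
    null_cache: dict[int, NullModel] = {}
    for values in product(*(grid[n] for n in names)):
        params = replace(PredictionParams(), **dict(zip(names, values)))
        preds = {}
        for element, query in queries.items():
            from .tf_prediction import as_query_motif
            w = as_query_motif(query).width
            if w not in null_cache:
                null_cache[w] = build_null(db.motifs, w, seed=seed)
            preds[element] = predict_tfs(query, db, proteome, params,
                                         seed=seed, null=null_cache[w])
        out.append((params, evaluate_predictions(preds, gold, db, universe,
                                                 params)))
    return out
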