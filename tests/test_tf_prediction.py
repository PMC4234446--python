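import math

import numpy as np
import pytest

import _oracles
from cisbind.errors import ValidationError
from cisbind.motif_model import NucleotideMotif, motif_from_sequences
from cisbind.motif_compare import build_null
from cisbind.structure_interface import InterfaceAnnotation, blosum62
from cisbind.tf_prediction import (MotifTFDatabase, PredictionParams,
                                   Proteome, TFRecord, find_homologs,
                                   load_database, local_protein_align,
                                   predict_tfs, protein_evalue,
                                   search_similar_motifs)
from cisbind.synthetic_data import SynthConfig, generate_database, \
    write_dataset

_B62 = blosum62()


def _negative_partner(aa):
    """An amino acid scoring <= 0 against ``aa`` under BLOSUM62."""
    for cand in "ACDEFGHIKLMNPQRSTVWY":
        if cand != aa and _B62.score(aa, cand) <= 0:
            return cand
    raise AssertionError(f"no dissimilar partner for {aa}")


class TestDatabaseLoading:
    def test_synthetic_dataset_round_trips(self, tmp_path, small_synth):
        cfg, db, proteome, truth = small_synth
        paths = write_dataset(tmp_path, db, proteome, truth)
        back = load_database(paths["motifs"], paths["tf_table"],
                            paths["tf_proteins"], paths["interfaces"])
        assert [m.id for m in back.motifs] == [m.id for m in db.motifs]
        assert [t.tf_id for t in back.tfs] == [t.tf_id for t in db.tfs]
        for ours, theirs in zip(db.tfs, back.tfs):
            assert ours.protein_seq == theirs.protein_seq
            assert ours.interface.positions == theirs.interface.positions
        assert back.links == db.links

    def test_small_consistent_database_loads(self):
        m = motif_from_sequences(["ACGTA"] * 3, id="m1")
        tf = TFRecord(tf_id="t1", name="t1", family="bHLH", species="x",
                      protein_seq="MKRL", motif_ids=["m1"])
        db = MotifTFDatabase(motifs=[m], tfs=[tf])
        assert db.links == {"m1": ["t1"]}

    def test_dangling_motif_link_names_offender(self):
        tf = TFRecord(tf_id="t1", name="t1", family="bHLH", species="x",
                      protein_seq="MKRL", motif_ids=["missing_motif"])
        with pytest.raises(ValidationError, match="missing_motif"):
            MotifTFDatabase(motifs=[], tfs=[tf])


@pytest.fixture(scope="module")
def db(small_synth):
    return small_synth[1]


class TestSearchSimilarMotifs:
    def test_database_motif_query_finds_itself_first(self, db):
        query = db.motifs[0]
        null = build_null(db.motifs, query.width, seed=7)
        hits = search_similar_motifs(query, db, null=null)
        assert hits and hits[0][0] == query.id

    def test_uninformative_query_finds_nothing(self, db):
        flat = NucleotideMotif(id="flat", counts=np.ones((10, 4)))
        null = build_null(db.motifs, 10, seed=7)
        assert search_similar_motifs(flat, db, null=null) == []

    def test_relaxing_threshold_gives_superset(self, db):
        query = db.motifs[3]
        null = build_null(db.motifs, query.width, seed=7)
        strict = search_similar_motifs(
            query, db, PredictionParams(stamp_evalue_max=1e-3), null)
        loose = search_similar_motifs(
            query, db, PredictionParams(stamp_evalue_max=1.0), null)
        assert {h[0] for h in strict} <= {h[0] for h in loose}


class TestLocalProteinAlign:
    def test_identical_peptide_scores_diagonal_sum(self):
        pep = "MKRLWQSAEN"
        aln = local_protein_align(pep, pep)
        expected = sum(_B62.score(a, a) for a in pep)
        assert aln.raw_score == expected
        assert aln.aligned_pairs == [(i, i) for i in range(len(pep))]

    def test_nonpositive_pair_gives_empty_alignment(self):
        aln = local_protein_align("A", "G")  # BLOSUM62 A/G scores 0
        assert aln.raw_score == 0 and aln.aligned_pairs == []

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValidationError):
            local_protein_align("MKRL1", "MKRL")

    @pytest.mark.parametrize("trial", range(25))
    def test_score_matches_independent_dp(self, trial):
        rng = np.random.default_rng(7000 + trial)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aas, size=30))
        b = "".join(rng.choice(aas, size=30))
        ours = local_protein_align(a, b).raw_score
        assert ours == pytest.approx(_oracles.smith_waterman_score(a, b))


class TestProteinEvalue:
    def _zero(self):
        from cisbind.tf_prediction import ProteinAlignment
        return ProteinAlignment("q", "t", [], raw_score=0.0)

    def test_zero_score_limit(self):
        assert protein_evalue(self._zero(), 100, 1000) == \
            pytest.approx(0.041 * 100 * 1000)

    def test_identical_100mer_is_highly_significant(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        aln = local_protein_align(seq, seq)
        assert protein_evalue(aln, 100, 10 ** 5) < 1e-10

    def test_linear_in_database_size(self):
        e1 = protein_evalue(self._zero(), 50, 1000)
        e2 = protein_evalue(self._zero(), 50, 2000)
        assert e2 == pytest.approx(2 * e1)

    def test_monotone_decreasing_in_score(self):
        from cisbind.tf_prediction import ProteinAlignment
        es = [protein_evalue(ProteinAlignment("q", "t", [], raw_score=s),
                             100, 1000) for s in (0, 50, 100, 200)]
        assert es == sorted(es, reverse=True)


class TestFindHomologs:
    def _tf(self, seq, iface_positions=None):
        iface = None
        if iface_positions is not None:
            iface = InterfaceAnnotation(tf_id="t1",
                                        positions=iface_positions)
        return TFRecord(tf_id="t1", name="t1", family="fam", species="x",
                        protein_seq=seq, motif_ids=[], interface=iface)

    def test_self_hit_has_full_interface_similarity(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        tf = self._tf(seq, iface_positions=(10, 20, 30))
        proteome = Proteome(entries={"self": ("desc", seq)})
        hits = find_homologs(tf, proteome)
        assert hits and hits[0][0] == "self" and hits[0][2] == 100.0

    def test_interface_filter_rejects_mutated_interface(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        iface = tuple(range(10, 40))
        mutated = list(seq)
        for pos in iface:
            mutated[pos] = _negative_partner(seq[pos])
        mutated = "".join(mutated)
        tf = self._tf(seq, iface_positions=iface)
        proteome = Proteome(entries={"hom": ("desc", mutated)})
        # homologous overall (3/4 of the protein identical) ...
        aln = local_protein_align(seq, mutated)
        assert protein_evalue(aln, len(seq), len(mutated)) < 1e-10
        # ... but rejected by the interface-conservation filter
        assert find_homologs(tf, proteome) == []
        relaxed = PredictionParams(require_interface=False)
        kept = find_homologs(tf, proteome, relaxed)
        assert [h[0] for h in kept] == ["hom"]
        assert kept[0][2] == 0.0

    def test_unannotated_tf_passes_with_absent_similarity(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        tf = self._tf(seq, iface_positions=None)
        hits = find_homologs(tf, Proteome(entries={"p": ("d", seq)}))
        assert hits[0][2] is None


class TestPredictTfs:
    def test_planted_homolog_recovered(self, small_synth):
        cfg, db, proteome, truth = small_synth
        fam = "fam1"
        null = build_null(db.motifs, cfg.motif_width, seed=cfg.seed)
        preds = predict_tfs(truth.family_motifs[fam], db, proteome,
                            seed=cfg.seed, null=null)
        assert preds
        fam_homs = set(truth.family_homologs[fam])
        assert any(p.candidate_protein_id in fam_homs for p in preds)

    def test_database_motif_query_returns_cognate_tf_first(self, small_synth):
        cfg, db, proteome, truth = small_synth
        motif = db.motifs[0]
        null = build_null(db.motifs, motif.width, seed=cfg.seed)
        preds = predict_tfs(motif, db, proteome, seed=cfg.seed, null=null)
        cognate = db.links[motif.id][0]
        assert preds[0].candidate_protein_id == truth.homolog_of[cognate]

    def test_empty_proteome_is_not_an_error(self, small_synth):
        cfg, db, _, truth = small_synth
        null = build_null(db.motifs, cfg.motif_width, seed=cfg.seed)
        preds = predict_tfs(truth.family_motifs["fam1"], db,
                            Proteome(entries={}), seed=cfg.seed, null=null)
        assert preds == []

    def test_tightening_thresholds_never_adds_predictions(self, small_synth):
        cfg, db, proteome, truth = small_synth
        null = build_null(db.motifs, cfg.motif_width, seed=cfg.seed)
        query = truth.family_motifs["fam2"]
        base = PredictionParams()
        baseline = {p.candidate_protein_id for p in predict_tfs(
            query, db, proteome, base, seed=cfg.seed, null=null)}
        tighter = [
            PredictionParams(stamp_evalue_max=1e-6),
            PredictionParams(blast_evalue_max=1e-30),
            PredictionParams(interface_min=90.0),
        ]
        for params in tighter:
            subset = {p.candidate_protein_id for p in predict_tfs(
                query, db, proteome, params, seed=cfg.seed, null=null)}
            assert subset <= baseline

    def test_all_returned_predictions_satisfy_thresholds(self, small_synth):
        cfg, db, proteome, truth = small_synth
        null = build_null(db.motifs, cfg.motif_width, seed=cfg.seed)
        params = PredictionParams()
        for fam in list(truth.family_motifs)[:2]:
            for p in predict_tfs(truth.family_motifs[fam], db, proteome,
                                 params, seed=cfg.seed, null=null):
                assert p.motif_evalue <= params.stamp_evalue_max
                assert p.homology_evalue <= params.blast_evalue_max
                if p.interface_similarity is not None:
                    assert p.interface_similarity >= params.interface_min
                assert p.passed_filters
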