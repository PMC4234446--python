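import math

import numpy as np
import pytest

from cisbind.errors import ValidationError
from cisbind.promoter_screen import (Condition, ExpressionMatrix,
                                     GeneAnnotation, PromoterRecord,
                                     drought_filter, extract_upstream,
                                     rank_conditions, read_expression_tsv,
                                     scan_promoters, select_upregulated,
                                     write_expression_tsv)
from cisbind.synthetic_data import SynthConfig, generate_expression_matrix, \
    generate_promoter_set


def _expr(genes, conditions, values):
    return ExpressionMatrix(genes=genes, conditions=conditions,
                            fold_change=np.array(values, dtype=float))


class TestSelectUpregulated:
    @pytest.fixture
    def expr(self):
        conds = [Condition("c1", is_drought=True), Condition("c2")]
        return _expr(["g1", "g2", "g3"], conds,
                     [[2.0, 1.0], [12.0, 1.0], [1.0, 3.0]])

    def test_twofold_boundary_is_inclusive(self, expr):
        assert "g1" in select_upregulated(expr, "c1").gene_ids

    def test_upper_bound_excludes(self, expr):
        sel = select_upregulated(expr, "c1", fold_min=2, fold_max=10)
        assert sel.gene_ids == {"g1"}

    def test_unresponsive_genes_give_empty_set(self):
        expr = _expr(["g1"], [Condition("c1")], [[1.0]])
        assert select_upregulated(expr, "c1").gene_ids == frozenset()

    def test_nonpositive_threshold_rejected(self, expr):
        with pytest.raises(ValidationError):
            select_upregulated(expr, "c1", fold_min=0)


class TestExtractUpstream:
    @pytest.fixture
    def genome(self, rng):
        return {"chr1": "".join(rng.choice(list("ACGT"), size=3000))}

    def test_plus_strand_window(self, genome):
        ann = GeneAnnotation(gene_id="g", chrom="chr1", strand="+",
                             tss=2001, atg=2101)
        prom = extract_upstream(genome, ann)
        assert prom.sequence == genome["chr1"][1000:2000]
        assert not prom.truncated

    def test_minus_strand_is_reverse_complement(self, genome):
        ann = GeneAnnotation(gene_id="g", chrom="chr1", strand="-",
                             tss=1000, atg=900)
        prom = extract_upstream(genome, ann)
        window = genome["chr1"][1000:2000]
        rc = window.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert prom.sequence == rc

    def test_contig_edge_truncates_and_flags(self, genome):
        ann = GeneAnnotation(gene_id="g", chrom="chr1", strand="+",
                             tss=500, atg=600)
        prom = extract_upstream(genome, ann)
        assert len(prom) == 499 and prom.truncated

    def test_atg_fallback_when_tss_unknown(self, genome):
        ann = GeneAnnotation(gene_id="g", chrom="chr1", strand="+",
                             tss=None, atg=1501)
        prom = extract_upstream(genome, ann, length=500)
        assert prom.sequence == genome["chr1"][1000:1500]

    def test_mirrored_annotations_give_reverse_complements(self, genome):
        plus = extract_upstream(genome, GeneAnnotation(
            gene_id="g", chrom="chr1", strand="+", tss=2001, atg=2101))
        minus = extract_upstream(genome, GeneAnnotation(
            gene_id="g", chrom="chr1", strand="-", tss=1000, atg=900))
        rc = minus.sequence.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert plus.sequence == rc

    def test_off_contig_gene_rejected(self, genome):
        ann = GeneAnnotation(gene_id="g", chrom="chr1", strand="+",
                             tss=9999, atg=9999)
        with pytest.raises(ValidationError):
            extract_upstream(genome, ann)


class TestScanPromoters:
    def test_single_occurrence_at_correct_offset(self):
        prom = PromoterRecord(gene_id="g1",
                              sequence="A" * 100 + "CACCTAAC" + "G" * 50)
        occ = scan_promoters("CACCTAAC", [prom], both_strands=False)
        assert len(occ) == 1
        assert (occ.rows[0].position, occ.rows[0].strand) == (100, "+")

    def test_upstream_coordinate_maps_to_offset(self, rng):
        # a site at upstream position -26 of a 1,000-bp promoter sits at
        # 0-based offset 974
        seq = list(rng.choice(list("ACGT"), size=1000))
        site = "ACCAAACAT"
        seq[974:974 + len(site)] = list(site)
        occ = scan_promoters(site, [PromoterRecord("g", "".join(seq))])
        assert 974 in [r.position for r in occ.rows]

    def test_absent_pattern_gives_empty_table(self):
        occ = scan_promoters("TTTTTTTT", [PromoterRecord("g", "ACGC" * 30)])
        assert len(occ) == 0

    def test_no_promoters_rejected(self):
        with pytest.raises(ValidationError):
            scan_promoters("ACGT", [])


class TestRankConditions:
    def _instance(self):
        genes = [f"g{i}" for i in range(20)]
        conds = [Condition("c1", is_drought=True),
                 Condition("c2", is_drought=True), Condition("c3")]
        fc = np.ones((20, 3))
        fc[:5, 0] = 4.0        # c1 up-regulates exactly the motif genes
        fc[10:15, 1] = 4.0     # c2 up-regulates unrelated genes
        fc[:10, 2] = 4.0       # c3 up-regulates a superset
        expr = _expr(genes, conds, fc)
        proms = [PromoterRecord(g, "A" * 50 + ("CACCTAAC" if i < 5 else "")
                                + "G" * 20) for i, g in enumerate(genes)]
        occ = scan_promoters("CACCTAAC", proms)
        return expr, occ

    def test_exclusive_condition_ranks_first(self):
        expr, occ = self._instance()
        ranked = rank_conditions(occ, expr)
        assert ranked[0][0] == "c1"

    def test_scores_match_exact_hypergeometric_enumeration(self):
        expr, occ = self._instance()
        ranked = dict(rank_conditions(occ, expr))
        # brute-force tail: P(X >= k) enumerated from binomial coefficients
        M, N = 20, 5  # population, motif-containing genes
        for cid, n_up, k in (("c1", 5, 5), ("c2", 5, 0), ("c3", 10, 5)):
            tail = sum(math.comb(n_up, x) * math.comb(M - n_up, N - x)
                       for x in range(k, min(N, n_up) + 1)) / math.comb(M, N)
            assert ranked[cid] == pytest.approx(tail, rel=1e-12)

    def test_ubiquitous_motif_ties_break_by_condition_id(self):
        genes = ["g1", "g2"]
        conds = [Condition("cB"), Condition("cA")]
        expr = _expr(genes, conds, [[3.0, 3.0], [3.0, 3.0]])
        proms = [PromoterRecord(g, "AACACCTAACAA") for g in genes]
        occ = scan_promoters("CACCTAAC", proms)
        ranked = rank_conditions(occ, expr)
        assert [cid for cid, _ in ranked] == ["cA", "cB"]

    def test_score_invariant_to_gene_order(self):
        expr, occ = self._instance()
        ranked = rank_conditions(occ, expr)
        perm = np.random.default_rng(0).permutation(len(expr.genes))
        expr2 = ExpressionMatrix(
            genes=[expr.genes[i] for i in perm],
            conditions=expr.conditions,
            fold_change=expr.fold_change[perm])
        assert ranked == rank_conditions(occ, expr2)


class TestDroughtFilter:
    LABELS = {"d1": True, "d2": True, "c1": False, "c2": False}

    def _ranked(self, order):
        return [(cid, 0.1 * i) for i, cid in enumerate(order)]

    def test_two_drought_in_top3_passes(self):
        assert drought_filter(self._ranked(["d1", "d2", "c1", "c2"]),
                              self.LABELS)

    def test_one_drought_in_top3_fails(self):
        assert not drought_filter(self._ranked(["d1", "c1", "c2", "d2"]),
                                  self.LABELS)

    def test_boundary_is_inclusive(self):
        assert drought_filter(self._ranked(["c1", "d1", "d2", "c2"]),
                              self.LABELS)

    def test_monotone_in_min_drought(self):
        ranked = self._ranked(["d1", "d2", "c1"])
        results = [drought_filter(ranked, self.LABELS, 3, k)
                   for k in (1, 2, 3)]
        # once it fails for some k it fails for all larger k
        assert results == sorted(results, reverse=True)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            drought_filter(self._ranked(["d1"]), self.LABELS, top_n=1,
                           min_drought=2)
        with pytest.raises(ValidationError):
            drought_filter([], self.LABELS)


class TestEndToEndDroughtRecovery:
    def test_planted_drought_motif_passes_filter(self, sharp_motif):
        """A motif planted only in drought-up genes is flagged drought-
        responsive by the ranking + filter chain."""
        cfg = SynthConfig(seed=11, n_promoters=40, planted_fraction=0.5)
        promoters, truth = generate_promoter_set(cfg, sharp_motif)
        expr = generate_expression_matrix(
            cfg, [p.gene_id for p in promoters], set(truth.drought_up))
        occ = scan_promoters(sharp_motif.consensus(), promoters)
        ranked = rank_conditions(occ, expr)
        labels = {c.condition_id: c.is_drought for c in expr.conditions}
        assert drought_filter(ranked, labels)


class TestExpressionIO:
    def test_round_trip(self, tmp_path):
        conds = [Condition("c1", "roots", "6h", True),
                 Condition("c2", "shoots", "1h", False)]
        expr = _expr(["g1", "g2"], conds, [[2.5, 1.0], [0.5, 3.25]])
        path = tmp_path / "expr.tsv"
        write_expression_tsv(expr, path)
        back = read_expression_tsv(path)
        assert back.genes == expr.genes
        assert [c.condition_id for c in back.conditions] == ["c1", "c2"]
        assert back.conditions[0].is_drought
        assert np.allclose(back.fold_change, expr.fold_change)


class TestGff3Annotation:
    def test_gene_features_parsed(self, tmp_path):
        from cisbind.promoter_screen import read_annotation_gff3
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\ttest\tgene\t2001\t3000\t.\t+\t.\tID=gene1\n"
            "chr1\ttest\tmRNA\t2001\t3000\t.\t+\t.\tID=rna1;Parent=gene1\n"
            "chr1\ttest\tCDS\t2101\t2900\t.\t+\t0\tID=cds1;Parent=rna1\n"
            "chr1\ttest\tgene\t5000\t6000\t.\t-\t.\tID=gene2\n")
        anns = {a.gene_id: a for a in read_annotation_gff3(gff)}
        assert anns["gene1"].tss == 2001 and anns["gene1"].atg == 2101
        assert anns["gene2"].strand == "-" and anns["gene2"].tss == 6000
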