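"""Novel-gene calling (start selection, ORF bounds) and gene-model auditing."""

import pytest

from protegap.genome_db import CILIATE_CODE, GeneModel, reverse_complement, translate
from protegap.mapping_grouping import GenomicMapping, PeptideEvidence, UNIQUENESS_GSSP
from protegap.novel_genes import (ERR_INTRON_BOUNDARY, ERR_INTRON_CODING,
                                  ERR_START, ERR_STOP, GsspLocus,
                                  call_novel_gene, classify_mapping_against_model,
                                  cluster_gssps, gc_content)


def _mapping(contig, strand, start, end, entry="e"):
    return GenomicMapping(contig, strand, ((start, end),), entry, spliced=False)


def _gssp(seq, mappings):
    return PeptideEvidence(sequence=seq, psm_count=1, best_score=10.0,
                           matched_entry_ids={"e"}, origins={"six_frame"},
                           parents={}, uniqueness=UNIQUENESS_GSSP,
                           genomic_mappings=list(mappings))


class TestGcContent:
    @pytest.mark.parametrize("dna,expected", [
        ("ATGC", 0.5), ("AAAA", 0.0), ("GGCC", 1.0), ("ANGN", 0.5),
    ])
    def test_fraction(self, dna, expected):
        assert gc_content(dna) == pytest.approx(expected)

    def test_all_n_is_undefined(self):
        assert gc_content("NNNN") is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")


class TestClusterGssps:
    def test_nearby_same_frame_mappings_merge(self):
        ev = [_gssp("AAAAAK", [_mapping("c", "+", 102, 120)]),
              _gssp("CCCCCK", [_mapping("c", "+", 168, 186)])]
        novel, audit = cluster_gssps(ev, [], max_gap=300)
        assert len(novel) == 1 and audit == []
        assert novel[0].unique_gssps == {"AAAAAK", "CCCCCK"}

    def test_opposite_strands_stay_apart(self):
        ev = [_gssp("AAAAAK", [_mapping("c", "+", 100, 118)]),
              _gssp("CCCCCK", [_mapping("c", "-", 120, 138)])]
        novel, audit = cluster_gssps(ev, [], max_gap=300)
        assert len(novel) == 2

    def test_locus_in_annotated_frame_routed_to_audit(self):
        model = GeneModel("g", "c", "+", ((99, 300),))
        ev = [_gssp("AAAAAK", [_mapping("c", "+", 120, 138)])]
        novel, audit = cluster_gssps(ev, [model], max_gap=300)
        assert novel == [] and len(audit) == 1

    def test_out_of_frame_overlap_is_not_routed(self):
        model = GeneModel("g", "c", "+", ((100, 301),))  # phase 1
        ev = [_gssp("AAAAAK", [_mapping("c", "+", 120, 138)])]  # phase 0
        novel, audit = cluster_gssps(ev, [model], max_gap=300)
        assert len(novel) == 1 and audit == []


def _locus(contig_seq, strand, peptide_spans, peptides):
    maps = [(p, _mapping("c", strand, s, e)) for p, (s, e) in
            zip(peptides, peptide_spans)]
    start = min(s for s, _ in peptide_spans)
    end = max(e for _, e in peptide_spans)
    key = ("+", start % 3) if strand == "+" else ("-", end % 3)
    return GsspLocus("c", strand, key, start, end, maps)


class TestCallNovelGene:
    # reading-orientation layout: pad | TGA | ATG | body | TGA | pad
    BODY = "AAAGCTAAAGCTAAAGCTAAAGCTAAAGCTAAAGCTAAAGCT"  # 14 codons, no start/stop

    def _contig(self, upstream="TGAATG"):
        return "CCTCCTCCT" + upstream[:3] + upstream[3:] + self.BODY + "TGA" + "CCTCCTCCT"

    def test_single_gssp_locus_rejected(self):
        seq = self._contig()
        locus = _locus(seq, "+", [(15, 33)], ["KAKAKA"])
        assert call_novel_gene(locus, {"c": seq}) is None

    def test_canonical_start_and_exact_orf(self):
        seq = self._contig()  # TGA at 9, ATG at 12, body 15..57, stop 57..60
        locus = _locus(seq, "+", [(15, 33), (33, 51)], ["pepA", "pepB"])
        call = call_novel_gene(locus, {"c": seq})
        assert call.start_class == "canonical_ATG"
        assert call.orf_interval == (12, 60)
        assert call.start_codon == "ATG"
        assert call.protein_sequence == translate(seq[12:57], CILIATE_CODE, 1)

    def test_alternative_start_when_no_atg(self):
        # TGA | GTG | AAA | evidence...: GTG is the most upstream candidate
        seq = "CCTCCTCCT" + "TGA" + "GTG" + "AAA" + self.BODY + "TGA" + "CCT"
        locus = _locus(seq, "+", [(18, 36), (36, 54)], ["pepA", "pepB"])
        call = call_novel_gene(locus, {"c": seq})
        assert call.start_class == "alternative"
        assert call.start_codon == "GTG"
        assert call.orf_interval[0] == 12

    def test_noncanonical_start_is_evidence_bounded(self):
        # stop immediately before the first peptide, no ATG/GTG/CTG/TTG
        seq = "CCTCCTCCT" + "TGA" + "AAT" + self.BODY + "TGA" + "CCT"
        locus = _locus(seq, "+", [(12, 30), (30, 48)], ["pepA", "pepB"])
        call = call_novel_gene(locus, {"c": seq})
        assert call.start_class == "noncanonical"
        assert call.start_codon == "AAT"
        assert call.orf_interval[0] == 12

    def test_minus_strand_call_mirrors_plus(self):
        seq = self._contig()
        rc = reverse_complement(seq)
        L = len(seq)
        locus = _locus(rc, "-", [(L - 33, L - 15), (L - 51, L - 33)],
                       ["pepA", "pepB"])
        call = call_novel_gene(locus, {"c": rc})
        assert call.strand == "-"
        assert call.orf_interval == (L - 60, L - 12)
        assert call.start_class == "canonical_ATG"

    def test_partial_flag_at_contig_edge(self):
        # no downstream stop before the contig ends
        seq = "TGA" + "ATG" + self.BODY
        locus = _locus(seq, "+", [(6, 24), (24, 42)], ["pepA", "pepB"])
        call = call_novel_gene(locus, {"c": seq})
        assert call.partial

    def test_protein_contains_supporting_peptides(self, noise_free_study):
        study, result = noise_free_study
        assert result.novel_calls
        for call in result.novel_calls:
            for pep in call.supporting_gssps:
                assert pep in call.protein_sequence


class TestErrorClassification:
    """Directed micro-cases on a hand-built single-exon '+' model."""

    MODEL = GeneModel("g", "c", "+", ((30, 90),))
    SEQ = "A" * 150  # stop-free in every frame

    def classify(self, start, end, seq=None):
        return classify_mapping_against_model(
            _mapping("c", "+", start, end), self.MODEL, seq or self.SEQ)

    def test_peptide_crossing_start_in_frame(self):
        assert self.classify(24, 45) == [ERR_START]

    def test_peptide_wholly_upstream_with_clear_reading(self):
        assert self.classify(9, 24) == [ERR_START]

    def test_out_of_frame_peptide_ignored(self):
        assert self.classify(25, 46) == []

    def test_peptide_crossing_stop_in_frame(self):
        assert self.classify(84, 105) == [ERR_STOP]

    def test_peptide_wholly_downstream_with_no_annotated_stop(self):
        assert self.classify(93, 111) == [ERR_STOP]

    def test_genomic_stop_at_annotated_terminus_blocks_downstream_evidence(self):
        seq = "A" * 87 + "TGA" + "A" * 60
        assert self.classify(93, 111, seq) == []

    def test_interior_peptide_yields_no_record(self):
        assert self.classify(36, 57) == []

    def test_intron_boundary_and_intron_coding(self):
        model = GeneModel("g2", "c", "+", ((30, 60), (90, 120)))
        seq = "A" * 150
        donor = classify_mapping_against_model(_mapping("c", "+", 54, 75), model, seq)
        assert ERR_INTRON_BOUNDARY in donor
        acceptor = classify_mapping_against_model(_mapping("c", "+", 81, 99), model, seq)
        assert ERR_INTRON_BOUNDARY in acceptor
        inside = classify_mapping_against_model(_mapping("c", "+", 63, 84), model, seq)
        assert inside == [ERR_INTRON_CODING]

    def test_spliced_mapping_never_flagged(self):
        model = GeneModel("g2", "c", "+", ((30, 60), (90, 120)))
        spliced = GenomicMapping("c", "+", ((54, 60), (90, 105)), "e", spliced=True)
        assert classify_mapping_against_model(spliced, model, self.SEQ) == []
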