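"""Translation, six-frame database construction, and FASTA/GFF3 round-trips."""

import numpy as np
import pytest
from Bio.Seq import Seq

from protegap.genome_db import (CILIATE_CODE, STANDARD_CODE, Contig,
                                InvalidSequenceError, ProteinEntry,
                                build_database, read_gene_models_gff3,
                                reverse_complement, reverse_decoy,
                                six_frame_entries, transcript_entries,
                                translate, write_gene_models_gff3)
from protegap.synthetic_data import SyntheticConfig, generate_genome


def _random_contig(rng, n):
    return Contig("c", "".join(rng.choice(list("ACGT"), size=n)))


class TestGeneticCode:
    def test_ciliate_code_reassigns_taa_tag_to_glutamine(self):
        assert CILIATE_CODE.codon_to_aa["TAA"] == "Q"
        assert CILIATE_CODE.codon_to_aa["TAG"] == "Q"
        assert CILIATE_CODE.stop_codons == {"TGA"}

    def test_tables_cover_all_64_codons(self):
        for code in (CILIATE_CODE, STANDARD_CODE):
            assert len(code.codon_to_aa) == 64
            assert code.stop_codons == {c for c, aa in code.codon_to_aa.items()
                                        if aa == "*"}


class TestTranslate:
    @pytest.mark.parametrize("dna,code,expected", [
        ("ATGAAATAA", CILIATE_CODE, "MKQ"),
        ("ATGAAATGA", CILIATE_CODE, "MK*"),
        ("ATGAAATAA", STANDARD_CODE, "MK*"),
    ])
    def test_codon_by_codon(self, dna, code, expected):
        assert translate(dna, code, 1) == expected

    def test_frames_shift_and_drop_partial_codons(self):
        dna = "AATGAAA"
        assert translate(dna, CILIATE_CODE, 2) == "MK"  # offset 1, 6 nt left
        assert len(translate(dna, CILIATE_CODE, 1)) == 2

    def test_n_codons_become_x(self):
        assert translate("ATGANA", CILIATE_CODE, 1) == "MX"

    def test_empty_and_invalid_inputs_rejected(self):
        with pytest.raises(InvalidSequenceError):
            translate("", CILIATE_CODE, 1)
        with pytest.raises(InvalidSequenceError):
            translate("ATGRRR", CILIATE_CODE, 1)

    def test_agrees_with_biopython_table6(self, rng):
        for _ in range(20):
            dna = "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 300))))
            n = (len(dna) // 3) * 3
            assert translate(dna, CILIATE_CODE, 1) == str(Seq(dna[:n]).translate(table=6))


def _brute_force_six_frame(contig, code, min_len):
    """Independent oracle: translate every frame codon-by-codon, split on stops."""
    out = []
    L = len(contig.sequence)
    for strand, seq in (("+", contig.sequence), ("-", reverse_complement(contig.sequence))):
        for offset in range(3):
            aa = "".join(code.aa(seq[i:i + 3])
                         for i in range(offset, len(seq) - 2, 3))
            for chunk in aa.split("*"):
                if len(chunk) >= min_len:
                    out.append((strand, offset + 1, chunk))
    return sorted(out)


class TestSixFrame:
    def test_matches_brute_force_oracle_on_random_contigs(self, rng):
        for _ in range(30):
            contig = _random_contig(rng, int(rng.integers(60, 2000)))
            got = sorted((e.provenance.strand, abs(e.provenance.frame), e.sequence)
                         for e in six_frame_entries(contig, CILIATE_CODE, 20))
            assert got == _brute_force_six_frame(contig, CILIATE_CODE, 20)

    def test_short_stretch_filtered_long_kept(self):
        # frame +1: 25 stop-free codons, stop, 19 codons, stop
        dna = "AAA" * 25 + "TGA" + "AAA" * 19 + "TGA"
        seqs = [e.sequence for e in six_frame_entries(Contig("c", dna), CILIATE_CODE, 20)
                if e.provenance.frame == 1]
        assert seqs == ["K" * 25]

    def test_all_a_contig_frame1(self):
        entries = six_frame_entries(Contig("c", "A" * 120), CILIATE_CODE, 20)
        plus1 = [e for e in entries if e.provenance.frame == 1]
        assert len(plus1) == 1
        assert plus1[0].sequence == "K" * 40
        assert (plus1[0].provenance.start, plus1[0].provenance.end) == (0, 120)

    def test_strand_symmetry(self, rng):
        for _ in range(10):
            contig = _random_contig(rng, int(rng.integers(100, 800)))
            rc = Contig("c", reverse_complement(contig.sequence))
            fwd = sorted(e.sequence for e in six_frame_entries(contig, CILIATE_CODE, 10))
            rev = sorted(e.sequence for e in six_frame_entries(rc, CILIATE_CODE, 10))
            assert fwd == rev

    def test_entries_stop_free_and_long_enough(self, rng):
        contig = _random_contig(rng, 1500)
        for e in six_frame_entries(contig, CILIATE_CODE, 20):
            assert "*" not in e.sequence
            assert len(e.sequence) >= 20

    def test_minus_strand_provenance_round_trips(self, rng):
        contig = _random_contig(rng, 900)
        for e in six_frame_entries(contig, CILIATE_CODE, 10):
            p = e.provenance
            sub = contig.sequence[p.start:p.end]
            if p.strand == "-":
                sub = reverse_complement(sub)
            assert translate(sub, CILIATE_CODE, 1) == e.sequence


class TestTranscriptEntries:
    def test_frame1_entry_equals_annotated_protein(self):
        cfg = SyntheticConfig(seed=3, n_annotated_genes=8, n_hidden_genes=0,
                              n_error_genes={}, intron_rate=1.0)
        study = generate_genome(cfg)
        by_tid = dict(study.transcripts)
        for model in study.annotated_models:
            prot = model.protein(study.contigs[model.contig_id], CILIATE_CODE)
            entries = transcript_entries([(model.gene_id, by_tid[f"{model.gene_id}.t1"])],
                                         CILIATE_CODE, 20)
            frame1 = [e.sequence for e in entries if e.provenance.frame == 1]
            assert prot in frame1

    def test_sub_20mer_frames_filtered(self):
        # 59 nt, frame 1 stop-free -> 19 aa, below the length floor
        entries = transcript_entries([("t1", "AAA" * 19 + "AA")], CILIATE_CODE, 20)
        assert [e for e in entries if e.provenance.frame == 1] == []

    def test_empty_input_and_duplicate_ids(self):
        assert transcript_entries([], CILIATE_CODE) == []
        with pytest.raises(ValueError):
            transcript_entries([("t", "AAAGGG"), ("t", "AAAGGG")], CILIATE_CODE)


class TestBuildDatabase:
    def test_counts_and_decoys(self):
        ref = [ProteinEntry(f"r{i}", "MKAAAAAK", "reference") for i in range(2)]
        six = [ProteinEntry(f"s{i}", "LLLLLLK", "six_frame") for i in range(3)]
        con = [ProteinEntry("c0", "GGGGGGR", "contaminant")]
        db = build_database(ref, six, [], con, with_decoys=True)
        assert len(db) == 12
        assert db.origin_counts["decoy"] == 6

    def test_decoy_is_full_reversal(self):
        entry = ProteinEntry("e", "PEPTIDEK", "reference")
        assert reverse_decoy(entry).sequence == "KEDITPEP"

    def test_empty_database_allowed_id_collision_rejected(self):
        assert len(build_database()) == 0
        dup = [ProteinEntry("x", "AAAK", "reference"),
               ProteinEntry("x", "CCCK", "reference")]
        with pytest.raises(ValueError):
            build_database(reference=dup, with_decoys=False)


class TestGff3RoundTrip:
    def test_models_survive_write_read(self, tmp_path):
        cfg = SyntheticConfig(seed=5, n_annotated_genes=12, n_hidden_genes=0)
        study = generate_genome(cfg)
        path = tmp_path / "ann.gff3"
        write_gene_models_gff3(path, study.annotated_models)
        back = {m.gene_id: m for m in read_gene_models_gff3(path)}
        assert len(back) == len(study.annotated_models)
        for m in study.annotated_models:
            r = back[m.gene_id]
            assert (r.contig_id, r.strand, tuple(r.exons)) == \
                   (m.contig_id, m.strand, tuple(m.exons))
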