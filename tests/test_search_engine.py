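"""Fragment ladders, open-search scoring and recovery, target-decoy FDR."""

import numpy as np
import pytest

from protegap.digestion_mass import (DEFAULT_MASSES, Peptide, build_peptide_index,
                                     mz, peptide_mass)
from protegap.genome_db import ProteinEntry, build_database
from protegap.search_engine import (PSM, Spectrum, annotate_q_values,
                                    open_search, peptide_fdr, protein_fdr,
                                    read_mgf, score_match, theoretical_ions,
                                    write_mgf)

PHOSPHO = 79.966331


def _ladder_spectrum(sid, seq, charge=2, delta=0.0, mod_pos=None, extra=()):
    """Clean b/y ladder spectrum of a peptide, optionally with a shift planted."""
    mods = ((mod_pos, "mod", delta),) if mod_pos is not None else ()
    pep = Peptide(seq, modifications=mods)
    b, y = theoretical_ions(pep)
    peaks = np.concatenate([b, y, np.array(extra, dtype=float)]) if len(extra) \
        else np.concatenate([b, y])
    inten = np.full(len(peaks), 100.0)
    pmz = mz(peptide_mass(pep), charge)
    return Spectrum(sid, pmz, charge, peaks, inten)


class TestTheoreticalIons:
    def test_ag_ladder_values(self):
        b, y = theoretical_ions("AG")
        assert b[0] == pytest.approx(72.0444, abs=1e-3)
        assert y[0] == pytest.approx(76.0393, abs=1e-3)
        # the full-length ion equals the protonated precursor
        assert peptide_mass("AG") + DEFAULT_MASSES.proton == pytest.approx(
            147.0764, abs=1e-3)

    def test_modification_shift_localizes_to_prefix_ions(self):
        p = Peptide("AG", modifications=((0, "acetyl", 42.010565),))
        b, y = theoretical_ions(p)
        b0, y0 = theoretical_ions("AG")
        assert b[0] == pytest.approx(b0[0] + 42.0106, abs=1e-3)
        assert y[0] == pytest.approx(y0[0], abs=1e-9)

    def test_single_residue_rejected(self):
        with pytest.raises(ValueError):
            theoretical_ions("K")


class TestScoreMatch:
    def test_full_ladder_scores_peaks_plus_full_intensity(self):
        s = _ladder_spectrum("s", "PEPTIDEK")
        ms = score_match(s, "PEPTIDEK", 20.0, 0.0)
        assert ms.matched_peaks == 14
        assert ms.intensity_fraction == pytest.approx(1.0)
        assert ms.score == pytest.approx(15.0)

    def test_empty_peak_list_scores_zero(self):
        s = Spectrum("s", 500.0, 2, np.array([]), np.array([]))
        assert score_match(s, "PEPTIDEK", 20.0, 0.0).score == 0.0

    def test_unrelated_peptide_scores_low(self):
        s = _ladder_spectrum("s", "PEPTIDEK")
        # without a shift, chance matches are bounded by the shared C-terminal
        # y1 ion; the free delta placement can add about one more alignment
        assert score_match(s, "GGGGGGK", 20.0, 0.0,
                           unmodified_tol=1e9).score < 2
        delta = peptide_mass("PEPTIDEK") - peptide_mass("GGGGGGK")
        assert score_match(s, "GGGGGGK", 20.0, delta).score < 4

    def test_shifted_series_recovers_modified_ladder(self):
        s = _ladder_spectrum("s", "AAASAAAK", delta=PHOSPHO, mod_pos=3)
        ms = score_match(s, "AAASAAAK", 20.0, PHOSPHO)
        assert ms.matched_peaks == 14
        assert ms.mod_position == 3


def _toy_index(rng, n_prot=20):
    aas = list("ADEFGHIKLNQRSTVY")
    prots = []
    for i in range(n_prot):
        seq = "".join(rng.choice(aas, size=60))
        prots.append(ProteinEntry(f"P{i:03d}", seq, "reference"))
    db = build_database(reference=prots, with_decoys=True)
    return db, build_peptide_index(db)


class TestOpenSearch:
    def test_self_recovery_on_clean_spectra(self, rng):
        db, index = _toy_index(rng)
        peptides = [ip.sequence for ip in index.peptides if not ip.decoy_only][:100]
        spectra = [_ladder_spectrum(f"s{i}", seq) for i, seq in enumerate(peptides)]
        psms = {p.spectrum_id: p for p in open_search(spectra, index)}
        recovered = sum(1 for i, seq in enumerate(peptides)
                        if f"s{i}" in psms and psms[f"s{i}"].peptide == seq)
        assert recovered >= 0.99 * len(peptides)
        for p in psms.values():
            assert abs(p.delta_mass) < 0.02

    def test_phospho_shift_recovered(self, rng):
        db, index = _toy_index(rng)
        seq = next(ip.sequence for ip in index.peptides
                   if not ip.decoy_only and "S" in ip.sequence[1:-1])
        site = seq.index("S", 1)
        s = _ladder_spectrum("mod", seq, delta=PHOSPHO, mod_pos=site)
        (psm,) = open_search([s], index)
        assert psm.peptide == seq
        assert psm.delta_mass == pytest.approx(PHOSPHO, abs=0.01)

    def test_unmatchable_spectrum_yields_no_psm(self, rng):
        db, index = _toy_index(rng, n_prot=3)
        s = Spectrum("junk", 5000.0, 2, np.array([4000.0, 4100.0]),
                     np.array([1.0, 1.0]))
        assert open_search([s], index) == []

    def test_out_of_range_charge_skipped_with_warning(self, rng):
        db, index = _toy_index(rng, n_prot=3)
        seq = next(ip.sequence for ip in index.peptides if not ip.decoy_only)
        s = _ladder_spectrum("z8", seq, charge=2)
        s.charge = 8
        with pytest.warns(UserWarning, match="charge"):
            assert open_search([s], index) == []

    def test_determinism(self, rng):
        db, index = _toy_index(rng)
        peptides = [ip.sequence for ip in index.peptides if not ip.decoy_only][:30]
        spectra = [_ladder_spectrum(f"s{i}", seq, extra=[300.123, 301.456])
                   for i, seq in enumerate(peptides)]
        a = open_search(spectra, index)
        b = open_search(spectra, index)
        assert [(p.spectrum_id, p.peptide, p.score) for p in a] == \
               [(p.spectrum_id, p.peptide, p.score) for p in b]


def _psm(i, score, decoy):
    return PSM(spectrum_id=f"s{i}", peptide=f"PEP{i}", neutral_precursor_mass=1000.0,
               delta_mass=0.0, score=score, matched_peaks=5, intensity_fraction=0.5,
               is_decoy=decoy)


class TestPeptideFdr:
    def test_decoy_ratio_at_one_percent(self):
        # 100 targets then 1 decoy: estimated FDR at that depth is 1/100
        psms = [_psm(i, 1000 - i, False) for i in range(100)]
        psms.append(_psm(100, 899.5, True))
        ranked = annotate_q_values(psms)
        assert ranked[-1].q_value == pytest.approx(0.01)
        accepted = peptide_fdr(psms, threshold=0.01)
        assert len(accepted) == 100
        assert all(not p.is_decoy for p in accepted)

    def test_q_values_monotone_in_rank(self):
        rng = np.random.default_rng(1)
        psms = [_psm(i, float(rng.uniform(0, 100)), bool(rng.random() < 0.3))
                for i in range(200)]
        ranked = annotate_q_values(psms)
        qs = [p.q_value for p in ranked]
        assert qs == sorted(qs)

    def test_empty_and_all_decoy_inputs(self):
        assert peptide_fdr([]) == []
        assert peptide_fdr([_psm(i, 10 - i, True) for i in range(5)]) == []

    def test_threshold_zero_keeps_only_psms_above_every_decoy(self):
        psms = [_psm(0, 10, False), _psm(1, 9, True), _psm(2, 8, False)]
        accepted = peptide_fdr(psms, threshold=0.0)
        assert [p.spectrum_id for p in accepted] == ["s0"]


class _Group:
    def __init__(self, gid, score, decoy):
        self.group_id = gid
        self.score = score
        self.is_decoy = decoy
        self.q_value = None


class TestProteinFdr:
    def test_ratio_estimator_and_decoy_removal(self):
        groups = [_Group(f"g{i}", 1000 - i, False) for i in range(200)]
        groups += [_Group("d1", 500.5, True), _Group("d2", 400.5, True)]
        accepted = protein_fdr(groups, threshold=0.01)
        assert len(accepted) == 200
        assert all(not g.is_decoy for g in accepted)

    def test_single_target_no_decoys(self):
        (g,) = protein_fdr([_Group("g", 5.0, False)], threshold=0.01)
        assert g.q_value == 0.0

    def test_decoy_only_group_excluded(self):
        assert protein_fdr([_Group("d", 5.0, True)], threshold=0.01) == []


class TestMgfIO:
    def test_round_trip(self, tmp_path, rng):
        spectra = [_ladder_spectrum(f"sp{i}", "PEPTIDEK", charge=2 + i)
                   for i in range(3)]
        path = tmp_path / "test.mgf"
        write_mgf(path, spectra)
        back = read_mgf(path)
        assert [s.spectrum_id for s in back] == [s.spectrum_id for s in spectra]
        for a, b in zip(spectra, back):
            assert b.charge == a.charge
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-4)
            np.testing.assert_allclose(b.peaks_mz, a.peaks_mz, atol=1e-4)
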