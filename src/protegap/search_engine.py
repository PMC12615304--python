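"""Simplified open-search spectrum identification with target-decoy FDR.

The open search allows an unconstrained precursor mass difference (the
"delta") between the observed neutral mass and the unmodified theoretical
peptide mass, so modified peptides are identified without predefining
modification types.  The scorer is a documented shared-peak count plus
matched-intensity fraction — deliberately simple; it only needs to rank the
generating peptide first and to give decoys the same score distribution as
false targets so the decoy-ratio FDR estimate is calibrated.

A fragment-ion index over the unshifted b/y ladders provides fast candidate
preselection (modified spectra still share at least the untouched half of
their ladder with the unshifted ions); the survivors are scored exactly,
with the delta placed at every residue position and the best placement kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .digestion_mass import (DEFAULT_MASSES, MassConstants, Peptide, PeptideIndex,
                             neutral_mass, peptide_mass, ppm_window)


@dataclass
class Spectrum:
    """One MS/MS spectrum; peaks are kept sorted by m/z."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray

    def __post_init__(self):
        self.peaks_mz = np.asarray(self.peaks_mz, dtype=float)
        self.peaks_intensity = np.asarray(self.peaks_intensity, dtype=float)
        if self.peaks_mz.shape != self.peaks_intensity.shape:
            raise ValueError("peak m/z and intensity arrays differ in length")
        if np.any(self.peaks_intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.peaks_mz, kind="stable")
        self.peaks_mz = self.peaks_mz[order]
        self.peaks_intensity = self.peaks_intensity[order]

    def neutral_mass(self, constants: MassConstants = DEFAULT_MASSES) -> float:
        return neutral_mass(self.precursor_mz, self.charge, constants)


@dataclass
class PSM:
    spectrum_id: str
    peptide: str
    neutral_precursor_mass: float
    delta_mass: float
    score: float
    matched_peaks: int
    intensity_fraction: float
    is_decoy: bool
    mod_position: Optional[int] = None   # best delta placement, None if unmodified
    parents: tuple = ()                  # (entry_id, offset, missed) of matched entries
    q_value: Optional[float] = None


# ---------------------------------------------------------------------------
# Theoretical fragments and placement-aware matching
# ---------------------------------------------------------------------------

def residue_mass_array(sequence: str, constants: MassConstants = DEFAULT_MASSES,
                       modifications: Sequence = ()) -> np.ndarray:
    arr = np.array([constants.residue(aa) for aa in sequence], dtype=float)
    for pos, _name, shift in modifications:
        arr[pos] += shift
    return arr


def theoretical_ions(p, constants: MassConstants = DEFAULT_MASSES,
                     frag_charge: int = 1) -> tuple:
    """Singly-protonated (or ``frag_charge``) b- and y-ion m/z ladders.

    b_i covers the first i residues, y_i the last i, for i = 1..len-1.
    Modification shifts are applied at their recorded positions.
    """
    if isinstance(p, Peptide):
        seq, mods = p.sequence, p.modifications
    else:
        seq, mods = p, ()
    if len(seq) < 2:
        raise ValueError("peptide too short for fragmentation")
    res = residue_mass_array(seq, constants, mods)
    prefix = np.cumsum(res)[:-1]
    suffix = np.cumsum(res[::-1])[:-1]
    z = frag_charge
    b = (prefix + z * constants.proton) / z
    y = (suffix + constants.water + z * constants.proton) / z
    return b, y


def _ion_matched(ions: np.ndarray, peaks_mz: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Boolean per ion: does any peak lie within tol_ppm of it?"""
    tol = ions * tol_ppm * 1e-6
    lo = np.searchsorted(peaks_mz, ions - tol, side="left")
    hi = np.searchsorted(peaks_mz, ions + tol, side="right")
    return hi > lo


def placement_ion_counts(peaks_mz: np.ndarray, sequence: str, delta: float,
                         frag_tol_ppm: float = 20.0,
                         constants: MassConstants = DEFAULT_MASSES) -> np.ndarray:
    """Matched-ion count for the delta placed at each residue position.

    Placing the shift at residue t moves b_i for i > t and y_i for i >= L-t.
    Returned array has one entry per position t = 0..L-1.
    """
    b, y = theoretical_ions(sequence, constants)
    L = len(sequence)
    mbU = _ion_matched(b, peaks_mz, frag_tol_ppm).astype(int)
    mbS = _ion_matched(b + delta, peaks_mz, frag_tol_ppm).astype(int)
    myU = _ion_matched(y, peaks_mz, frag_tol_ppm).astype(int)
    myS = _ion_matched(y + delta, peaks_mz, frag_tol_ppm).astype(int)
    # prefix sums; cb[k] = number matched among first k ions
    cbU, cbS = np.concatenate([[0], np.cumsum(mbU)]), np.concatenate([[0], np.cumsum(mbS)])
    cyU, cyS = np.concatenate([[0], np.cumsum(myU)]), np.concatenate([[0], np.cumsum(myS)])
    t = np.arange(L)
    nb = L - 1
    # b_i unshifted for i <= t (i ranges 1..L-1, array index i-1)
    b_counts = cbU[np.minimum(t, nb)] + (cbS[nb] - cbS[np.minimum(t, nb)])
    # y_i unshifted for i < L-t, i.e. first (L-1-t) ions capped to [0, nb]
    ky = np.clip(L - 1 - t, 0, nb)
    y_counts = cyU[ky] + (cyS[nb] - cyS[ky])
    return b_counts + y_counts


def _peak_level_match(spectrum: Spectrum, ions: np.ndarray, frag_tol_ppm: float) -> tuple:
    """(#matched peaks, matched intensity fraction) against an ion set."""
    if len(spectrum.peaks_mz) == 0:
        return 0, 0.0
    matched = np.zeros(len(spectrum.peaks_mz), dtype=bool)
    tol = ions * frag_tol_ppm * 1e-6
    lo = np.searchsorted(spectrum.peaks_mz, ions - tol, side="left")
    hi = np.searchsorted(spectrum.peaks_mz, ions + tol, side="right")
    for a, b in zip(lo, hi):
        if b > a:
            matched[a:b] = True
    n = int(matched.sum())
    total = float(spectrum.peaks_intensity.sum())
    frac = float(spectrum.peaks_intensity[matched].sum() / total) if total > 0 else 0.0
    return n, frac


@dataclass(frozen=True)
class MatchScore:
    score: float
    matched_peaks: int
    intensity_fraction: float
    mod_position: Optional[int]
    #: fraction of the peptide's own predicted ions that found a peak —
    #: a parsimony signal used only to break score ties
    theoretical_fraction: float = 0.0


def score_match(spectrum: Spectrum, peptide, frag_tol_ppm: float = 20.0,
                delta: float = 0.0,
                constants: MassConstants = DEFAULT_MASSES,
                unmodified_tol: Optional[float] = None) -> MatchScore:
    """Shared-peak + intensity-fraction score of one spectrum/peptide pair.

    If ``delta`` exceeds the fragment tolerance it is attributed to a single
    residue position (shifting the ions that contain it); the placement with
    the most matched ions wins, ties going to the lowest position.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if len(spectrum.peaks_mz) == 0:
        return MatchScore(0.0, 0, 0.0, None, 0.0)
    b, y = theoretical_ions(peptide, constants)
    if unmodified_tol is None:
        # a delta within the precursor tolerance is measurement error, not a
        # modification; estimate the peptide mass from its residues
        unmodified_tol = (sum(constants.residue(aa) for aa in seq)
                          + constants.water) * 20.0 * 1e-6
    if abs(delta) <= unmodified_tol:
        ions = np.concatenate([b, y])
        pos = None
    else:
        counts = placement_ion_counts(spectrum.peaks_mz, seq, delta, frag_tol_ppm, constants)
        pos = int(np.argmax(counts))  # argmax returns lowest index on ties
        L = len(seq)
        ions = np.concatenate([
            np.where(np.arange(1, L) > pos, b + delta, b),
            np.where(np.arange(1, L) >= L - pos, y + delta, y),
        ])
    n, frac = _peak_level_match(spectrum, ions, frag_tol_ppm)
    theo = float(_ion_matched(ions, spectrum.peaks_mz, frag_tol_ppm).sum() / len(ions))
    return MatchScore(float(n + frac), n, frac, pos, theo)


# ---------------------------------------------------------------------------
# Fragment-ion index and open search
# ---------------------------------------------------------------------------

@dataclass
class FragmentIndex:
    """Sorted unshifted b/y ion m/z values over an entire peptide index."""

    ion_mz: np.ndarray
    ion_pep: np.ndarray
    n_peptides: int

    @classmethod
    def build(cls, index: PeptideIndex,
              constants: MassConstants = DEFAULT_MASSES) -> "FragmentIndex":
        mzs, ids = [], []
        for i, ip in enumerate(index.peptides):
            b, y = theoretical_ions(ip.sequence, constants)
            ions = np.concatenate([b, y])
            mzs.append(ions)
            ids.append(np.full(len(ions), i, dtype=np.int32))
        ion_mz = np.concatenate(mzs) if mzs else np.empty(0)
        ion_pep = np.concatenate(ids) if ids else np.empty(0, dtype=np.int32)
        order = np.argsort(ion_mz, kind="stable")
        return cls(ion_mz[order], ion_pep[order], len(index))

    def candidate_counts(self, peaks_mz: np.ndarray, frag_tol_ppm: float) -> np.ndarray:
        """Per-peptide count of spectrum peaks matching an unshifted ion."""
        counts = np.zeros(self.n_peptides, dtype=np.int32)
        if len(self.ion_mz) == 0 or len(peaks_mz) == 0:
            return counts
        tol = peaks_mz * frag_tol_ppm * 1e-6
        lo = np.searchsorted(self.ion_mz, peaks_mz - tol, side="left")
        hi = np.searchsorted(self.ion_mz, peaks_mz + tol, side="right")
        hits = [self.ion_pep[a:b] for a, b in zip(lo, hi) if b > a]
        if hits:
            # a peptide is counted once per peak even if two of its ions match
            for h in hits:
                counts[np.unique(h)] += 1
        return counts


def open_search(spectra: Sequence, index: PeptideIndex,
                precursor_window: tuple = (-500.0, 500.0),
                frag_tol_ppm: float = 20.0, precursor_tol_ppm: float = 20.0,
                top_k: int = 50, min_matched_peaks: int = 1,
                constants: MassConstants = DEFAULT_MASSES,
                fragment_index: Optional[FragmentIndex] = None) -> list:
    """Best peptide-spectrum match per spectrum under an open precursor window.

    Candidates are peptides whose unmodified mass lies within
    ``precursor_window`` of the spectrum's neutral mass (the narrow ppm window
    for unmodified matches is a subset of this).  Candidates are preselected
    by unshifted shared-ion count, then scored exactly with the delta placed
    at its best position.  Ties break by (score, smaller \\|delta\\|,
    lexicographic peptide), making the result deterministic.
    """
    if fragment_index is None:
        fragment_index = FragmentIndex.build(index, constants)
    w_lo, w_hi = precursor_window
    psms = []
    for spectrum in spectra:
        if not 2 <= spectrum.charge <= 6:
            warnings.warn(f"spectrum {spectrum.spectrum_id}: charge {spectrum.charge} "
                          "outside [2,6], skipped")
            continue
        nm = spectrum.neutral_mass(constants)
        i, j = index.mass_range(nm - w_hi, nm - w_lo)
        if j <= i:
            continue
        counts = fragment_index.candidate_counts(spectrum.peaks_mz, frag_tol_ppm)
        window_counts = counts[i:j]
        nonzero = np.nonzero(window_counts)[0]
        if len(nonzero) == 0:
            continue
        if len(nonzero) > top_k:
            part = np.argpartition(window_counts[nonzero], -top_k)[-top_k:]
            nonzero = nonzero[part]
        best = None
        for k in sorted(nonzero + i):
            ip = index.peptides[k]
            delta = nm - ip.mass
            ms = score_match(spectrum, ip.sequence, frag_tol_ppm, delta, constants,
                             unmodified_tol=ip.mass * precursor_tol_ppm * 1e-6)
            if ms.matched_peaks < min_matched_peaks:
                continue
            # between equal-scoring candidates prefer the one whose own ion
            # ladder is more completely explained (parsimony), then the
            # smaller mass shift, then lexicographic order
            key = (-ms.score, -ms.theoretical_fraction, abs(delta), ip.sequence)
            if best is None or key < best[0]:
                best = (key, ip, delta, ms)
        if best is None:
            continue
        _, ip, delta, ms = best
        psms.append(PSM(
            spectrum_id=spectrum.spectrum_id,
            peptide=ip.sequence,
            neutral_precursor_mass=nm,
            delta_mass=delta,
            score=ms.score,
            matched_peaks=ms.matched_peaks,
            intensity_fraction=ms.intensity_fraction,
            is_decoy=bool(ip.decoy_only),
            mod_position=ms.mod_position,
            parents=tuple(ip.parents),
        ))
    return psms


# ---------------------------------------------------------------------------
# Target-decoy FDR
# ---------------------------------------------------------------------------

def _rank_key(psm: PSM) -> tuple:
    return (-psm.score, abs(psm.delta_mass), psm.peptide, psm.spectrum_id)


def annotate_q_values(psms: Sequence, plus_one: bool = False) -> list:
    """Rank PSMs and set decoy-ratio q-values (running minimum from the bottom)."""
    ranked = sorted(psms, key=_rank_key)
    n_decoy = n_target = 0
    fdrs = []
    for psm in ranked:
        if psm.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        d = n_decoy + (1 if plus_one else 0)
        fdrs.append(d / n_target if n_target else float("inf"))
    q = float("inf")
    for idx in range(len(ranked) - 1, -1, -1):
        q = min(q, fdrs[idx])
        ranked[idx].q_value = q
    return ranked


def peptide_fdr(psms: Sequence, threshold: float = 0.01,
                plus_one: bool = False) -> list:
    """Accepted target PSMs at the decoy-estimated FDR threshold.

    Decoys participate in the estimate and are removed from the accepted set
    afterwards.  All input PSMs get their ``q_value`` set as a side effect.
    """
    ranked = annotate_q_values(psms, plus_one=plus_one)
    return [p for p in ranked if p.q_value <= threshold and not p.is_decoy]


def protein_fdr(groups: Sequence, threshold: float = 0.01,
                plus_one: bool = False) -> list:
    """Group-level decoy-ratio FDR over objects with .score and .is_decoy."""
    ranked = sorted(groups, key=lambda g: (-g.score, getattr(g, "group_id", "")))
    n_decoy = n_target = 0
    fdrs = []
    for g in ranked:
        if g.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        d = n_decoy + (1 if plus_one else 0)
        fdrs.append(d / n_target if n_target else float("inf"))
    q = float("inf")
    for idx in range(len(ranked) - 1, -1, -1):
        q = min(q, fdrs[idx])
        ranked[idx].q_value = q
    return [g for g in ranked if g.q_value <= threshold and not g.is_decoy]


# ---------------------------------------------------------------------------
# MGF I/O and PSM tables
# ---------------------------------------------------------------------------

def read_mgf(path) -> list:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for rec in reader:
            params = rec["params"]
            charge = int(params["charge"][0])
            spectra.append(Spectrum(
                spectrum_id=str(params.get("title", f"scan{len(spectra)}")),
                precursor_mz=float(params["pepmass"][0]),
                charge=charge,
                peaks_mz=rec["m/z array"],
                peaks_intensity=rec["intensity array"],
            ))
    return spectra


def write_mgf(path, spectra: Sequence) -> None:
    records = [{
        "params": {"title": s.spectrum_id, "pepmass": s.precursor_mz,
                   "charge": f"{s.charge}+"},
        "m/z array": s.peaks_mz,
        "intensity array": s.peaks_intensity,
    } for s in spectra]
    _mgf.write(records, str(path), file_mode="w")


def write_psm_tsv(path, psms: Sequence) -> None:
    with open(path, "w") as fh:
        fh.write("spectrum_id\tpeptide\tproteins\tprecursor_mass\tdelta_mass\t"
                 "score\tis_decoy\tq_value\n")
        for p in psms:
            prot = ";".join(par[0] for par in p.parents)
            q = "" if p.q_value is None else f"{p.q_value:.6g}"
            fh.write(f"{p.spectrum_id}\t{p.peptide}\t{prot}\t{p.neutral_precursor_mass:.5f}\t"
                     f"{p.delta_mass:.5f}\t{p.score:.4f}\t{int(p.is_decoy)}\t{q}\n")
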