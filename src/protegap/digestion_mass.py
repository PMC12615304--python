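"""In-silico tryptic digestion and monoisotopic mass arithmetic.

Trypsin cleaves C-terminal to K or R except before proline (Keil rule).  The
digest enumerates all peptides with up to ``max_missed`` internal cleavage
sites, recording the parent entry and offset so identified peptides can be
mapped back to proteins and the genome.  Masses are standard monoisotopic
values; carbamidomethylation of cysteine (+57.021464 Da) is applied as a
fixed modification by default, mirroring iodoacetamide alkylation.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pyteomics import mass as _pmass

from .genome_db import ORIGIN_DECOY, SearchDatabase

WATER = 18.0105646863
PROTON = 1.00727646688
CARBAMIDOMETHYL = 57.021464

_STD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MassConstants:
    """Monoisotopic residue masses plus fixed-modification shifts per residue."""

    residue_masses: dict = field(default_factory=lambda: {aa: _pmass.std_aa_mass[aa] for aa in _STD_AA})
    fixed_mods: dict = field(default_factory=lambda: {"C": CARBAMIDOMETHYL})
    water: float = WATER
    proton: float = PROTON

    def residue(self, aa: str) -> float:
        try:
            return self.residue_masses[aa] + self.fixed_mods.get(aa, 0.0)
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None


DEFAULT_MASSES = MassConstants()
#: Without the fixed cysteine carbamidomethylation.
UNMODIFIED_MASSES = MassConstants(fixed_mods={})


@dataclass(frozen=True)
class Peptide:
    sequence: str
    parent_entry_id: Optional[str] = None
    start_in_parent: int = 0
    missed_cleavages: int = 0
    modifications: tuple = ()  # of (position 0-based, name, mass shift Da)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty peptide")
        for pos, _name, _shift in self.modifications:
            if not 0 <= pos < len(self.sequence):
                raise ValueError("modification position outside peptide")

    @property
    def matchable(self) -> bool:
        """X (ambiguous translation) residues make a peptide non-matchable."""
        return "X" not in self.sequence


def cleavage_sites(sequence: str) -> list:
    """Positions after which trypsin cleaves (K/R not followed by P)."""
    return [i + 1 for i in range(len(sequence) - 1)
            if sequence[i] in "KR" and sequence[i + 1] != "P"]


def digest(entry_or_sequence, max_missed: int = 2, min_len: int = 6,
           max_len: int = 60) -> list:
    """Fully tryptic peptides of a protein with 0..max_missed missed cleavages."""
    if hasattr(entry_or_sequence, "sequence"):
        seq = entry_or_sequence.sequence
        parent = entry_or_sequence.entry_id
    else:
        seq = entry_or_sequence
        parent = None
    if not seq:
        raise ValueError("empty protein sequence")
    bounds = [0] + cleavage_sites(seq) + [len(seq)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            s, e = bounds[i], bounds[j]
            if not (min_len <= e - s <= max_len):
                continue
            peptides.append(Peptide(sequence=seq[s:e], parent_entry_id=parent,
                                    start_in_parent=s, missed_cleavages=j - i - 1))
    return peptides


def peptide_mass(p, constants: MassConstants = DEFAULT_MASSES) -> float:
    """Neutral monoisotopic mass: residues + water + modification shifts."""
    seq = p.sequence if isinstance(p, Peptide) else p
    if "X" in seq:
        raise ValueError("cannot compute mass of X-containing peptide")
    total = sum(constants.residue(aa) for aa in seq) + constants.water
    if isinstance(p, Peptide):
        total += sum(shift for _pos, _name, shift in p.modifications)
    return total


def mz(neutral_mass: float, charge: int, constants: MassConstants = DEFAULT_MASSES) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * constants.proton) / charge


def neutral_mass(precursor_mz: float, charge: int,
                 constants: MassConstants = DEFAULT_MASSES) -> float:
    return precursor_mz * charge - charge * constants.proton


def ppm_window(mass_da: float, tol_ppm: float = 20.0) -> tuple:
    if mass_da <= 0:
        raise ValueError("mass must be positive")
    half = mass_da * tol_ppm * 1e-6
    return (mass_da - half, mass_da + half)


# ---------------------------------------------------------------------------
# Peptide index
# ---------------------------------------------------------------------------

@dataclass
class IndexedPeptide:
    sequence: str
    mass: float
    parents: list            # of (entry_id, start_in_parent, missed_cleavages)
    decoy_only: bool         # True if every parent is a decoy entry


@dataclass
class PeptideIndex:
    """Deduplicated peptide sequences from a search database, sorted by mass.

    A sequence shared by a target and a decoy entry counts as target
    (``decoy_only`` False), the standard resolution of reversal collisions.
    """

    peptides: list
    constants: MassConstants = field(default_factory=lambda: DEFAULT_MASSES)
    masses: np.ndarray = field(init=False)
    is_decoy: np.ndarray = field(init=False)

    def __post_init__(self):
        self.peptides.sort(key=lambda ip: (ip.mass, ip.sequence))
        self.masses = np.array([ip.mass for ip in self.peptides], dtype=float)
        self.is_decoy = np.array([ip.decoy_only for ip in self.peptides], dtype=bool)

    def __len__(self):
        return len(self.peptides)

    def mass_range(self, lo: float, hi: float) -> tuple:
        """Index slice [i, j) of peptides with mass in [lo, hi]."""
        i = bisect.bisect_left(self.masses, lo)
        j = bisect.bisect_right(self.masses, hi)
        return i, j

    def find(self, sequence: str) -> Optional[IndexedPeptide]:
        m = peptide_mass(sequence, self.constants)
        i, j = self.mass_range(m - 1e-6, m + 1e-6)
        for ip in self.peptides[i:j]:
            if ip.sequence == sequence:
                return ip
        return None


def build_peptide_index(db: SearchDatabase, max_missed: int = 2, min_len: int = 6,
                        max_len: int = 60,
                        constants: MassConstants = DEFAULT_MASSES) -> PeptideIndex:
    by_seq: dict = {}
    for entry in db.entries:
        for pep in digest(entry, max_missed=max_missed, min_len=min_len, max_len=max_len):
            if not pep.matchable:
                continue
            rec = by_seq.get(pep.sequence)
            if rec is None:
                rec = by_seq[pep.sequence] = IndexedPeptide(
                    sequence=pep.sequence,
                    mass=peptide_mass(pep, constants),
                    parents=[], decoy_only=True)
            rec.parents.append((entry.entry_id, pep.start_in_parent, pep.missed_cleavages))
            if entry.origin != ORIGIN_DECOY:
                rec.decoy_only = False
    return PeptideIndex(list(by_seq.values()), constants=constants)


def write_peptide_index_tsv(path, index: PeptideIndex) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tmass\tdecoy_only\tparents\tpositions\n")
        for ip in index.peptides:
            parents = ";".join(p[0] for p in ip.parents)
            positions = ";".join(str(p[1]) for p in ip.parents)
            fh.write(f"{ip.sequence}\t{ip.mass:.6f}\t{int(ip.decoy_only)}\t{parents}\t{positions}\n")
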