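"""Open-search delta-mass annotation against a PTM catalog, site
localization, and per-type summaries.

The default catalog ships 30 common eukaryotic modifications with Unimod
monoisotopic masses.  Delta matching uses the precursor-scale tolerance
(ppm of the peptide mass), consistent with the search; near-isobaric pairs
(e.g. trimethyl 42.04695 vs acetyl 42.010565, 0.0364 Da apart) are flagged
and resolvable at 20 ppm for peptides up to ~1800 Da.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import pandas as pd

from .digestion_mass import DEFAULT_MASSES, MassConstants, peptide_mass
from .search_engine import PSM, Spectrum, placement_ion_counts

POSITION_ANYWHERE = "anywhere"
POSITION_PROTEIN_NTERM = "protein_nterm"
POSITION_PEPTIDE_NTERM = "peptide_nterm"

#: Reference window (Da) used only to flag near-isobaric catalog pairs,
#: corresponding to 20 ppm at a 1000 Da peptide.
NEAR_ISOBARIC_REFERENCE_DA = 0.02


@dataclass(frozen=True)
class Modification:
    name: str
    mass: float
    residues: frozenset
    position: str = POSITION_ANYWHERE


@dataclass
class ModificationCatalog:
    entries: list
    by_name: dict = field(init=False)
    near_isobaric: set = field(init=False)

    def __post_init__(self):
        names = [m.name for m in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate modification names in catalog")
        self.by_name = {m.name: m for m in self.entries}
        self.near_isobaric = set()
        for i, a in enumerate(self.entries):
            for b in self.entries[i + 1:]:
                if abs(a.mass - b.mass) < 2 * NEAR_ISOBARIC_REFERENCE_DA:
                    self.near_isobaric.add(frozenset((a.name, b.name)))

    def __len__(self):
        return len(self.entries)


def load_catalog(path=None) -> ModificationCatalog:
    """Load a catalog TSV (name, mass, residues, position); default: bundled 30."""
    if path is None:
        ref = importlib.resources.files("protegap") / "data" / "modifications.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    entries = [Modification(row["name"], float(row["mass"]),
                            frozenset(str(row["residues"])), str(row["position"]))
               for _, row in df.iterrows()]
    return ModificationCatalog(entries)


# ---------------------------------------------------------------------------
# Delta matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeltaMatch:
    status: str                     # unmodified | matched | ambiguous | none
    names: tuple = ()
    within_tolerance: tuple = ()    # all catalog names that qualified
    #: False when a second catalog entry sits so close to the winner that
    #: precursor error could flip the assignment (near-isobaric pair)
    resolved: bool = True


def match_delta(delta: float, catalog: ModificationCatalog, pep_mass: float,
                tol_ppm: float = 20.0) -> DeltaMatch:
    """Assign a precursor mass delta to the nearest catalog entry.

    Tolerance scales with the peptide mass (ppm of the unmodified mass).  A
    delta within tolerance of zero is unmodified; exact distance ties are
    reported as ambiguous with both names.
    """
    tol = pep_mass * tol_ppm * 1e-6
    if abs(delta) <= tol:
        return DeltaMatch("unmodified")
    qualified = sorted((abs(delta - m.mass), m.name) for m in catalog.entries
                       if abs(delta - m.mass) <= tol)
    if not qualified:
        return DeltaMatch("none")
    names_within = tuple(name for _d, name in qualified)
    best_d = qualified[0][0]
    tied = tuple(name for d, name in qualified if abs(d - best_d) < 1e-9)
    if len(tied) > 1:
        return DeltaMatch("ambiguous", tied, names_within, resolved=False)
    resolved = (len(qualified) == 1
                or qualified[1][0] - best_d >= NEAR_ISOBARIC_REFERENCE_DA)
    return DeltaMatch("matched", (qualified[0][1],), names_within, resolved)


# ---------------------------------------------------------------------------
# Site localization
# ---------------------------------------------------------------------------

def compatible_positions(sequence: str, mod: Modification,
                         peptide_is_protein_nterm: bool = False) -> list:
    if mod.position == POSITION_PEPTIDE_NTERM:
        candidates = [0]
    elif mod.position == POSITION_PROTEIN_NTERM:
        candidates = [0] if peptide_is_protein_nterm else []
    else:
        candidates = range(len(sequence))
    return [i for i in candidates if sequence[i] in mod.residues]


def localize_site(spectrum: Spectrum, sequence: str, mod: Modification,
                  frag_tol_ppm: float = 20.0,
                  constants: MassConstants = DEFAULT_MASSES,
                  peptide_is_protein_nterm: bool = False) -> Optional[tuple]:
    """(site position, confident) for one modification on one spectrum.

    The delta is placed at every specificity-compatible position and the
    fragment-match count compared; the winner must lead by at least one
    matched ion to be confident.  Ties resolve to the lowest position,
    flagged not confident.  Returns None if no residue is compatible.
    """
    positions = compatible_positions(sequence, mod, peptide_is_protein_nterm)
    if not positions:
        return None
    counts = placement_ion_counts(spectrum.peaks_mz, sequence, mod.mass,
                                  frag_tol_ppm, constants)
    scored = sorted((int(-counts[p]), p) for p in positions)
    best_neg, best_pos = scored[0]
    if len(scored) == 1:
        return best_pos, True
    runner_neg = scored[1][0]
    confident = (runner_neg - best_neg) >= 1
    return best_pos, confident


# ---------------------------------------------------------------------------
# PSM-level assignment and summaries
# ---------------------------------------------------------------------------

@dataclass
class PTMAssignment:
    spectrum_id: str
    peptide: str
    modification: str
    ambiguous_with: tuple
    site_position: Optional[int]
    protein_id: Optional[str]
    protein_site: Optional[int]      # 1-based residue coordinate
    residue: Optional[str]
    localization_confident: bool


def assign_ptms(psms: Sequence, spectra_by_id: Dict[str, Spectrum],
                catalog: ModificationCatalog, tol_ppm: float = 20.0,
                frag_tol_ppm: float = 20.0,
                constants: MassConstants = DEFAULT_MASSES,
                anchor_of_entry: Optional[Dict[str, str]] = None) -> list:
    """Annotate accepted modified PSMs with a PTM type and site.

    ``anchor_of_entry`` maps database entry ids to their protein-group anchor
    so sites deduplicate per group; without it the lexicographically first
    matched entry is the protein coordinate system.
    """
    assignments = []
    for psm in psms:
        pm = peptide_mass(psm.peptide, constants)
        dm = match_delta(psm.delta_mass, catalog, pm, tol_ppm)
        if dm.status in ("unmodified", "none"):
            continue
        names = dm.names if dm.status == "ambiguous" else (dm.names[0],)
        spectrum = spectra_by_id.get(psm.spectrum_id)
        for name in names:
            mod = catalog.by_name[name]
            site = None
            confident = False
            if spectrum is not None:
                loc = localize_site(spectrum, psm.peptide, mod, frag_tol_ppm, constants)
                if loc is None:
                    continue
                site, confident = loc
            protein_id = protein_site = residue = None
            if psm.parents and site is not None:
                entry_id, offset, _missed = sorted(psm.parents)[0]
                if anchor_of_entry:
                    protein_id = anchor_of_entry.get(entry_id, entry_id)
                else:
                    protein_id = entry_id
                protein_site = offset + site + 1
                residue = psm.peptide[site]
            assignments.append(PTMAssignment(
                spectrum_id=psm.spectrum_id, peptide=psm.peptide,
                modification=name,
                ambiguous_with=tuple(n for n in names if n != name),
                site_position=site, protein_id=protein_id,
                protein_site=protein_site, residue=residue,
                localization_confident=bool(confident and dm.status == "matched"
                                            and dm.resolved),
            ))
    return assignments


def summarize_ptms(assignments: Sequence) -> pd.DataFrame:
    """Per modification type: distinct proteins, unique sites, spectra.

    Sites deduplicate by (protein, residue coordinate, type); spectra count
    PSMs.  An ambiguous PSM contributes to each of its tied types.
    """
    rows: Dict[str, dict] = {}
    for a in assignments:
        rec = rows.setdefault(a.modification,
                              {"proteins": set(), "sites": set(), "spectra": 0})
        rec["spectra"] += 1
        if a.protein_id is not None:
            rec["proteins"].add(a.protein_id)
            rec["sites"].add((a.protein_id, a.protein_site))
    out = pd.DataFrame(
        [(name, len(r["proteins"]), len(r["sites"]), r["spectra"])
         for name, r in sorted(rows.items())],
        columns=["modification", "n_proteins", "n_sites", "n_spectra"])
    return out


def write_site_table_tsv(path, assignments: Sequence) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tposition\tresidue\tmodification\tspectrum\tconfident\n")
        for a in assignments:
            fh.write(f"{a.protein_id or ''}\t{a.protein_site or ''}\t{a.residue or ''}\t"
                     f"{a.modification}\t{a.spectrum_id}\t{int(a.localization_confident)}\n")
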