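"""Peptide-level evidence: GSSP classification, parsimony protein grouping,
coverage statistics, and peptide-to-genome mapping.

A genome search-specific peptide (GSSP) is a confidently identified peptide
whose matches are confined to the proteogenomic part of the database
(six-frame or transcript entries) — it matches no annotated reference
protein and no contaminant.  GSSPs are the evidence units for novel-gene
calling and gene-model auditing downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

from .genome_db import (CILIATE_CODE, ORIGIN_CONTAMINANT, ORIGIN_DECOY,
                        ORIGIN_REFERENCE, ORIGIN_SIX_FRAME, ORIGIN_TRANSCRIPT,
                        GeneModel, GeneticCode, GenomicProvenance, SearchDatabase,
                        reverse_complement, translate)

UNIQUENESS_REFERENCE = "reference_matched"
UNIQUENESS_GSSP = "gssp"


@dataclass
class GenomicMapping:
    """A peptide's genomic footprint: one interval if contiguous, several
    when projected across splice junctions."""

    contig_id: str
    strand: str
    intervals: tuple                 # genomic 0-based half-open, sorted
    entry_id: str
    spliced: bool                    # True when projected through a gene model

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def contiguous(self) -> bool:
        return len(self.intervals) == 1

    @property
    def frame_key(self) -> tuple:
        """(strand, codon phase) — equal for mappings read in the same frame.

        On '+' the codon phase is start mod 3; on '-' codons are anchored at
        the interval end, so end mod 3 identifies the frame.
        """
        if self.strand == "+":
            return ("+", self.start % 3)
        return ("-", self.end % 3)


@dataclass
class PeptideEvidence:
    sequence: str
    psm_count: int
    best_score: float
    matched_entry_ids: set
    origins: set
    parents: dict                    # entry_id -> sorted tuple of offsets
    uniqueness: str = UNIQUENESS_REFERENCE
    is_contaminant_only: bool = False
    genomic_mappings: list = field(default_factory=list)


@dataclass
class ProteinGroup:
    group_id: str
    member_entry_ids: tuple
    anchor_entry: str
    peptides: frozenset
    unique_peptides: set = field(default_factory=set)
    shared_peptides: set = field(default_factory=set)
    spectral_count: int = 0
    coverage_fraction: float = 0.0
    score: float = 0.0
    is_decoy: bool = False
    q_value: Optional[float] = None


# ---------------------------------------------------------------------------
# Evidence aggregation and GSSP classification
# ---------------------------------------------------------------------------

def assign_peptides(accepted_psms: Sequence, database: SearchDatabase,
                    decoy_side: bool = False) -> list:
    """Aggregate accepted PSMs per peptide sequence and classify uniqueness.

    With ``decoy_side`` the aggregation runs over decoy matches instead
    (used to build competing decoy protein groups for protein-level FDR).
    """
    by_seq: Dict[str, PeptideEvidence] = {}
    for psm in accepted_psms:
        parents = {}
        for entry_id, offset, _missed in psm.parents:
            origin = database.by_id[entry_id].origin
            if (origin == ORIGIN_DECOY) != decoy_side:
                continue
            parents.setdefault(entry_id, set()).add(offset)
        if not parents:
            raise RuntimeError(f"accepted peptide {psm.peptide} matches no database entry")
        ev = by_seq.get(psm.peptide)
        if ev is None:
            ev = by_seq[psm.peptide] = PeptideEvidence(
                sequence=psm.peptide, psm_count=0, best_score=0.0,
                matched_entry_ids=set(), origins=set(), parents={})
        ev.psm_count += 1
        ev.best_score = max(ev.best_score, psm.score)
        for entry_id, offsets in parents.items():
            ev.matched_entry_ids.add(entry_id)
            ev.origins.add(database.by_id[entry_id].origin)
            ev.parents.setdefault(entry_id, set()).update(offsets)
    evidence = sorted(by_seq.values(), key=lambda e: e.sequence)
    for ev in evidence:
        ev.parents = {k: tuple(sorted(v)) for k, v in sorted(ev.parents.items())}
        if ev.origins & {ORIGIN_REFERENCE, ORIGIN_CONTAMINANT}:
            ev.uniqueness = UNIQUENESS_REFERENCE
            ev.is_contaminant_only = ev.origins <= {ORIGIN_CONTAMINANT}
        else:
            ev.uniqueness = UNIQUENESS_GSSP
    return evidence


# ---------------------------------------------------------------------------
# Parsimony protein grouping
# ---------------------------------------------------------------------------

def group_proteins(evidence: Sequence, database: SearchDatabase,
                   is_decoy: bool = False) -> list:
    """Greedy parsimony grouping of matched entries.

    Entries with identical peptide sets merge into one group; entries whose
    peptide set is a strict subset of an existing group's set are subsumed.
    Entries are processed by descending peptide count, then lexicographic id,
    so the outcome is order-independent and deterministic.  Shared-peptide
    spectral counts go to the peptide's anchor group only (its first group in
    processing order).
    """
    entry_peps: Dict[str, set] = {}
    for ev in evidence:
        for entry_id in ev.matched_entry_ids:
            entry_peps.setdefault(entry_id, set()).add(ev.sequence)
    ev_by_seq = {ev.sequence: ev for ev in evidence}

    order = sorted(entry_peps, key=lambda eid: (-len(entry_peps[eid]), eid))
    groups: list = []
    for entry_id in order:
        peps = frozenset(entry_peps[entry_id])
        home = None
        for g in groups:
            if peps <= g.peptides:
                home = g
                break
        if home is None:
            groups.append(ProteinGroup(
                group_id=f"{'DECOYGRP' if is_decoy else 'GRP'}{len(groups) + 1:05d}",
                member_entry_ids=(entry_id,),
                anchor_entry=entry_id,
                peptides=peps,
                is_decoy=is_decoy,
            ))
        else:
            home.member_entry_ids = tuple(list(home.member_entry_ids) + [entry_id])

    membership: Dict[str, list] = {}
    for g in groups:
        for pep in g.peptides:
            membership.setdefault(pep, []).append(g)
    for pep, gs in membership.items():
        ev = ev_by_seq[pep]
        home = gs[0]  # groups were created in processing order
        home.spectral_count += ev.psm_count
        if len(gs) == 1:
            gs[0].unique_peptides.add(pep)
        else:
            for g in gs:
                g.shared_peptides.add(pep)
    for g in groups:
        g.score = max((ev_by_seq[p].best_score for p in g.peptides), default=0.0)
        g.coverage_fraction = coverage_stats(g, evidence, database)[0]
    return groups


def prefer_reference_anchors(groups: Sequence, evidence: Sequence,
                             database: SearchDatabase) -> None:
    """Re-anchor groups on an annotated accession where one is a member.

    Six-frame stretches containing an annotated gene share its peptides and
    would otherwise sometimes win the anchor by id order; reporting the
    annotated accession keeps group ids stable and quantifiable per gene.
    Coverage is recomputed against the new anchor.
    """
    for g in groups:
        refs = sorted(eid for eid in g.member_entry_ids
                      if database.by_id[eid].origin == ORIGIN_REFERENCE)
        if refs and g.anchor_entry not in refs:
            g.anchor_entry = refs[0]
            g.coverage_fraction = coverage_stats(g, evidence, database)[0]


def coverage_stats(group: ProteinGroup, evidence: Sequence,
                   database: SearchDatabase) -> tuple:
    """(coverage fraction of the anchor, unique peptide count, PSM count)."""
    anchor = database.by_id[group.anchor_entry]
    intervals = []
    psm_count = 0
    for ev in evidence:
        if ev.sequence not in group.peptides:
            continue
        psm_count += ev.psm_count
        for offset in ev.parents.get(group.anchor_entry, ()):
            intervals.append((offset, offset + len(ev.sequence)))
    covered = 0
    last_end = 0
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            covered += e - s
            last_end = e
    coverage = covered / len(anchor.sequence) if anchor.sequence else 0.0
    return coverage, len(group.peptides), psm_count


# ---------------------------------------------------------------------------
# Peptide-to-genome mapping
# ---------------------------------------------------------------------------

def project_through_gene_model(model: GeneModel, aa_offset: int,
                               aa_length: int) -> tuple:
    """Genomic intervals of a peptide at ``aa_offset`` in a model's protein.

    Splice-aware: the peptide's CDS range is walked through the exons in
    reading order; minus-strand genes read from the genomic right edge.
    """
    nt_start = model.cds_frame_offset + 3 * aa_offset
    nt_end = nt_start + 3 * aa_length
    intervals = []
    pos = 0
    for (s, e) in model.reading_exons():
        w = e - s
        a, b = max(nt_start - pos, 0), min(nt_end - pos, w)
        if b > a:
            if model.strand == "+":
                intervals.append((s + a, s + b))
            else:
                intervals.append((e - b, e - a))
        pos += w
    if sum(e - s for s, e in intervals) != 3 * aa_length:
        raise ValueError("peptide extends beyond the gene model's CDS")
    return tuple(sorted(intervals))


def map_peptide_to_genome(evidence: Sequence, database: SearchDatabase,
                          gene_models: Dict[str, GeneModel]) -> None:
    """Attach genomic mappings to each evidence record (in place).

    Six-frame matches map by provenance arithmetic (3 nt per residue,
    strand-aware); reference matches are projected through their gene model's
    exons; transcript matches carry no genomic provenance and are skipped.
    """
    for ev in evidence:
        mappings = []
        for entry_id, offsets in ev.parents.items():
            entry = database.by_id[entry_id]
            L = 3 * len(ev.sequence)
            if isinstance(entry.provenance, GenomicProvenance):
                p = entry.provenance
                for off in offsets:
                    if p.strand == "+":
                        iv = (p.start + 3 * off, p.start + 3 * off + L)
                    else:
                        iv = (p.end - 3 * off - L, p.end - 3 * off)
                    mappings.append(GenomicMapping(p.contig_id, p.strand, (iv,),
                                                   entry_id, spliced=False))
            elif entry.origin == ORIGIN_REFERENCE:
                model = gene_models.get(entry_id)
                if model is None:
                    warnings.warn(f"no gene model for reference entry {entry_id}; "
                                  "mapping skipped")
                    continue
                for off in offsets:
                    intervals = project_through_gene_model(model, off, len(ev.sequence))
                    mappings.append(GenomicMapping(model.contig_id, model.strand,
                                                   intervals, entry_id, spliced=True))
        ev.genomic_mappings = mappings


def extract_mapped_peptide(mapping: GenomicMapping, contigs: Dict[str, str],
                           code: GeneticCode = CILIATE_CODE) -> str:
    """Re-translate a genomic mapping; round-trips to the peptide sequence."""
    seq = contigs[mapping.contig_id]
    cds = "".join(seq[s:e] for s, e in mapping.intervals)
    if mapping.strand == "-":
        cds = reverse_complement(cds)
    return translate(cds, code, 1)


def write_evidence_tsv(path, evidence: Sequence) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tpsm_count\tuniqueness\tcontaminant_only\tentries\tmappings\n")
        for ev in evidence:
            maps = ";".join(
                f"{m.contig_id}:{m.strand}:" + ",".join(f"{s}-{e}" for s, e in m.intervals)
                for m in ev.genomic_mappings)
            fh.write(f"{ev.sequence}\t{ev.psm_count}\t{ev.uniqueness}\t"
                     f"{int(ev.is_contaminant_only)}\t"
                     f"{';'.join(sorted(ev.matched_entry_ids))}\t{maps}\n")


def write_groups_tsv(path, groups: Sequence) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tanchor\tmembers\tn_peptides\tunique_peptides\t"
                 "spectral_count\tcoverage\tscore\tq_value\n")
        for g in groups:
            q = "" if g.q_value is None else f"{g.q_value:.6g}"
            fh.write(f"{g.group_id}\t{g.anchor_entry}\t{';'.join(g.member_entry_ids)}\t"
                     f"{len(g.peptides)}\t{len(g.unique_peptides)}\t{g.spectral_count}\t"
                     f"{g.coverage_fraction:.4f}\t{g.score:.4f}\t{q}\n")


def write_mappings_bed(path, evidence: Sequence) -> None:
    """GSSP genomic mappings as BED12-lite (one line per mapping)."""
    with open(path, "w") as fh:
        for ev in evidence:
            for m in ev.genomic_mappings:
                fh.write(f"{m.contig_id}\t{m.start}\t{m.end}\t{ev.sequence}\t"
                         f"{ev.psm_count}\t{m.strand}\n")
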