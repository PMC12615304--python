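"""Novel-gene calling from GSSP clusters and peptide-level gene-model auditing.

Novel genes are called from clusters of genome search-specific peptides that
lie outside every annotated reading frame: the locus is extended upstream
in-frame to the nearest stop codon, the initiation codon is chosen (ATG
preferred, then GTG/CTG/TTG; otherwise the call is evidence-bounded and
flagged noncanonical), and the ORF runs to the first in-frame stop.

The audit detects four peptide-diagnosable annotation error classes:
peptides crossing the annotated start or stop in frame (start/stop errors),
peptides translated contiguously across an annotated exon-intron boundary
(intron boundary errors), and peptides wholly inside an annotated intron in
frame with the flanking CDS (introns that are actually coding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

from .genome_db import CILIATE_CODE, STOP, GeneModel, GeneticCode, reverse_complement, translate
from .mapping_grouping import GenomicMapping, PeptideEvidence, UNIQUENESS_GSSP

CANONICAL_START = "ATG"
ALTERNATIVE_STARTS = ("GTG", "CTG", "TTG")

START_CLASS_CANONICAL = "canonical_ATG"
START_CLASS_ALTERNATIVE = "alternative"
START_CLASS_NONCANONICAL = "noncanonical"

ERR_START = "start_error"
ERR_STOP = "stop_error"
ERR_INTRON_BOUNDARY = "intron_boundary_error"
ERR_INTRON_CODING = "intron_coding"
ERROR_CATEGORIES = (ERR_START, ERR_STOP, ERR_INTRON_BOUNDARY, ERR_INTRON_CODING)


@dataclass
class GsspLocus:
    contig_id: str
    strand: str
    frame_key: tuple
    start: int
    end: int
    peptides: list            # of (sequence, GenomicMapping)

    @property
    def unique_gssps(self) -> set:
        return {seq for seq, _m in self.peptides}


@dataclass
class NovelGeneCall:
    call_id: str
    contig_id: str
    strand: str
    frame_key: tuple
    supporting_gssps: frozenset
    orf_interval: tuple        # genomic, 0-based half-open, stop codon included
    protein_sequence: str
    start_codon: str
    start_class: str
    gc_content: Optional[float]
    partial: bool = False


@dataclass
class GeneModelError:
    gene_id: str
    category: str
    evidence_peptides: set
    description: str


# ---------------------------------------------------------------------------
# Reading-frame geometry of annotated models
# ---------------------------------------------------------------------------

def reading_exon_phases(model: GeneModel) -> list:
    """Per reading-order exon: (genomic interval, frame_key of its codons).

    frame_key follows :class:`GenomicMapping`: ('+', codon start mod 3) on the
    forward strand, ('-', codon end mod 3) on the reverse strand.
    """
    out = []
    before = -model.cds_frame_offset
    for (s, e) in model.reading_exons():
        if model.strand == "+":
            key = ("+", (s - before) % 3)
        else:
            key = ("-", (e + before) % 3)
        out.append(((s, e), key))
        before += e - s
    return out


def gene_frame_keys(model: GeneModel) -> set:
    return {key for _iv, key in reading_exon_phases(model)}


# ---------------------------------------------------------------------------
# GSSP clustering
# ---------------------------------------------------------------------------

def cluster_gssps(evidence: Sequence, gene_models: Sequence,
                  max_gap: int = 300) -> tuple:
    """Cluster contiguous GSSP mappings into candidate loci.

    Returns (novel_loci, audit_loci): loci overlapping an annotated gene in
    the same reading frame are routed to the gene-model audit instead of
    novel-gene calling.
    """
    items: Dict[tuple, list] = {}
    for ev in evidence:
        if ev.uniqueness != UNIQUENESS_GSSP:
            continue
        for m in ev.genomic_mappings:
            if not m.contiguous:
                continue
            items.setdefault((m.contig_id, m.frame_key), []).append((ev.sequence, m))

    loci = []
    for (contig_id, frame_key), peps in sorted(items.items()):
        peps.sort(key=lambda t: (t[1].start, t[0]))
        current = None
        for seq, m in peps:
            if current is not None and m.start - current.end <= max_gap:
                current.end = max(current.end, m.end)
                current.peptides.append((seq, m))
            else:
                current = GsspLocus(contig_id, frame_key[0], frame_key, m.start,
                                    m.end, [(seq, m)])
                loci.append(current)

    novel, audit = [], []
    models_by_contig: Dict[str, list] = {}
    for model in gene_models:
        models_by_contig.setdefault(model.contig_id, []).append(model)
    for locus in loci:
        overlaps = False
        for model in models_by_contig.get(locus.contig_id, ()):
            gs, ge = model.span
            if (model.strand == locus.strand and gs < locus.end and locus.start < ge
                    and locus.frame_key in gene_frame_keys(model)):
                overlaps = True
                break
        (audit if overlaps else novel).append(locus)
    return novel, audit


# ---------------------------------------------------------------------------
# Novel-gene calling
# ---------------------------------------------------------------------------

def gc_content(dna: str) -> Optional[float]:
    """(G+C) / (A+C+G+T); N is excluded from both counts; all-N is undefined."""
    if not dna:
        raise ValueError("empty sequence")
    counted = [b for b in dna if b != "N"]
    if not counted:
        return None
    gc = sum(1 for b in counted if b in "GC")
    return gc / len(counted)


def call_novel_gene(locus: GsspLocus, contigs: Dict[str, str],
                    code: GeneticCode = CILIATE_CODE,
                    min_unique_gssps: int = 2,
                    call_id: Optional[str] = None) -> Optional[NovelGeneCall]:
    """Infer the ORF behind a GSSP locus; None if support is below threshold.

    All coordinates are handled in "reading space" (the reverse complement
    for minus-strand loci) and converted back at the end.
    """
    if len(locus.unique_gssps) < min_unique_gssps:
        return None
    genome_seq = contigs[locus.contig_id]
    L = len(genome_seq)
    if locus.strand == "+":
        reading = genome_seq
        r_start, r_end = locus.start, locus.end
    else:
        reading = reverse_complement(genome_seq)
        r_start, r_end = L - locus.end, L - locus.start

    def codon(pos):
        return reading[pos:pos + 3]

    # upstream in-frame to the nearest stop
    upstream = r_start
    while upstream - 3 >= 0 and codon(upstream - 3) not in code.stop_codons:
        upstream -= 3
    # candidate starts between the stop and the first peptide, ATG preferred
    start_pos, start_class = None, None
    for wanted, cls in ((CANONICAL_START, START_CLASS_CANONICAL),
                        (None, START_CLASS_ALTERNATIVE)):
        for pos in range(upstream, r_start + 1, 3):
            c = codon(pos)
            if (wanted and c == wanted) or (wanted is None and c in ALTERNATIVE_STARTS):
                start_pos, start_class = pos, cls
                break
        if start_pos is not None:
            break
    if start_pos is None:
        # evidence-bounded: report the codon at the most upstream
        # evidence-consistent position, no extension past the peptide
        start_pos, start_class = r_start, START_CLASS_NONCANONICAL

    # downstream to the first in-frame stop (stop codon included in the ORF)
    pos = r_end
    partial = False
    while True:
        if pos + 3 > len(reading):
            partial = True
            break
        if codon(pos) in code.stop_codons:
            pos += 3
            break
        pos += 3
    orf_r = (start_pos, pos)
    orf_dna = reading[orf_r[0]:orf_r[1]]
    protein = translate(orf_dna, code, 1) if len(orf_dna) >= 3 else ""
    if protein.endswith(STOP):
        protein = protein[:-1]
    if locus.strand == "+":
        orf_interval = orf_r
    else:
        orf_interval = (L - orf_r[1], L - orf_r[0])
    return NovelGeneCall(
        call_id=call_id or f"NOVEL|{locus.contig_id}|{locus.strand}|{orf_interval[0]}",
        contig_id=locus.contig_id,
        strand=locus.strand,
        frame_key=locus.frame_key,
        supporting_gssps=frozenset(locus.unique_gssps),
        orf_interval=orf_interval,
        protein_sequence=protein,
        start_codon=orf_dna[:3],
        start_class=start_class,
        gc_content=gc_content(orf_dna) if orf_dna else None,
        partial=partial,
    )


# ---------------------------------------------------------------------------
# Gene-model error audit
# ---------------------------------------------------------------------------

#: Non-crossing boundary evidence must lie within this many nt of the
#: annotated boundary (matches the GSSP clustering gap).
MAX_BOUNDARY_EVIDENCE_GAP = 300


def _stop_free_reading(contig_seq: str, strand: str, code: GeneticCode,
                       left: int, right: int) -> bool:
    """No stop codon between two codon-aligned genomic positions, read on
    ``strand`` (codons anchored at ``left`` on '+', at ``right`` on '-')."""
    if right - left > MAX_BOUNDARY_EVIDENCE_GAP:
        return False
    if (right - left) % 3 != 0 or left < 0 or right > len(contig_seq):
        return False
    if strand == "+":
        codons = (contig_seq[p:p + 3] for p in range(left, right, 3))
    else:
        codons = (reverse_complement(contig_seq[p - 3:p])
                  for p in range(right, left, -3))
    return all(c not in code.stop_codons for c in codons)


def classify_mapping_against_model(mapping: GenomicMapping,
                                   model: GeneModel,
                                   contig_seq: Optional[str] = None,
                                   code: GeneticCode = CILIATE_CODE) -> list:
    """Error categories a contiguous peptide mapping implies for one model.

    Start/stop evidence is a peptide extending beyond the annotated boundary
    in frame: either physically crossing it, or — when the genome is given —
    lying wholly beyond it within the same contiguous stop-free reading
    (tryptic cleavage sites need not straddle the boundary itself).  A
    genuine genomic stop codon at the annotated terminus blocks non-crossing
    stop evidence, since translation would truly terminate there.
    """
    if mapping.contig_id != model.contig_id or mapping.strand != model.strand:
        return []
    if not mapping.contiguous:
        return []
    phases = reading_exon_phases(model)
    key = mapping.frame_key
    ms, me = mapping.start, mapping.end
    cats = []

    (first_iv, first_key) = phases[0]
    (last_iv, last_key) = phases[-1]
    off = model.cds_frame_offset
    if model.strand == "+":
        start_boundary = first_iv[0] + off
        stop_boundary = last_iv[1]
    else:
        start_boundary = first_iv[1] - off
        stop_boundary = last_iv[0]

    if key == first_key:
        if ms < start_boundary < me:
            cats.append(ERR_START)
        elif contig_seq is not None:
            # wholly upstream of the annotated start, reading uninterrupted
            if model.strand == "+" and me <= start_boundary and \
                    _stop_free_reading(contig_seq, "+", code, me, start_boundary):
                cats.append(ERR_START)
            elif model.strand == "-" and ms >= start_boundary and \
                    _stop_free_reading(contig_seq, "-", code, start_boundary, ms):
                cats.append(ERR_START)
    if key == last_key:
        if ms < stop_boundary < me:
            cats.append(ERR_STOP)
        elif contig_seq is not None:
            if model.strand == "+":
                terminal_codon = contig_seq[stop_boundary - 3:stop_boundary]
                beyond = ms >= stop_boundary and \
                    _stop_free_reading(contig_seq, "+", code, stop_boundary, ms)
            else:
                terminal_codon = reverse_complement(
                    contig_seq[stop_boundary:stop_boundary + 3])
                beyond = me <= stop_boundary and \
                    _stop_free_reading(contig_seq, "-", code, me, stop_boundary)
            if beyond and terminal_codon not in code.stop_codons:
                cats.append(ERR_STOP)

    for ((iv_a, key_a), (iv_b, key_b)) in zip(phases, phases[1:]):
        if model.strand == "+":
            intron = (iv_a[1], iv_b[0])
            donor, acceptor = intron[0], intron[1]
        else:
            intron = (iv_b[1], iv_a[0])
            donor, acceptor = intron[1], intron[0]
        if intron[1] <= intron[0]:
            continue
        crosses_donor = ms < donor < me and key == key_a
        crosses_acceptor = ms < acceptor < me and key == key_b
        if crosses_donor or crosses_acceptor:
            cats.append(ERR_INTRON_BOUNDARY)
        inside = intron[0] <= ms and me <= intron[1]
        if inside and key in (key_a, key_b):
            cats.append(ERR_INTRON_CODING)
    return cats


def detect_gene_model_errors(evidence: Sequence, gene_models: Sequence,
                             contigs: Optional[Dict[str, str]] = None,
                             code: GeneticCode = CILIATE_CODE) -> list:
    """Audit annotated models against GSSP mappings.

    One record per (gene, category), with all supporting peptides attached.
    """
    records: Dict[tuple, GeneModelError] = {}
    models_by_contig: Dict[str, list] = {}
    for model in gene_models:
        models_by_contig.setdefault(model.contig_id, []).append(model)
    for ev in evidence:
        if ev.uniqueness != UNIQUENESS_GSSP:
            continue
        for m in ev.genomic_mappings:
            seq = contigs.get(m.contig_id) if contigs else None
            for model in models_by_contig.get(m.contig_id, ()):
                gs, ge = model.span
                # peptides relevant to a model lie within reach of its span
                if m.end < gs - 10000 or m.start > ge + 10000:
                    continue
                for cat in classify_mapping_against_model(m, model, seq, code):
                    rec = records.get((model.gene_id, cat))
                    if rec is None:
                        rec = records[(model.gene_id, cat)] = GeneModelError(
                            gene_id=model.gene_id, category=cat,
                            evidence_peptides=set(),
                            description=f"{cat} supported by peptide evidence")
                    rec.evidence_peptides.add(ev.sequence)
    return [records[k] for k in sorted(records)]


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_novel_calls_gff3(path, calls: Sequence, source: str = "protegap") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in calls:
            s, e = c.orf_interval
            attrs = (f"ID={c.call_id};gssp_count={len(c.supporting_gssps)};"
                     f"start_class={c.start_class};start_codon={c.start_codon}")
            fh.write(f"{c.contig_id}\t{source}\tgene\t{s + 1}\t{e}\t.\t{c.strand}\t.\t{attrs}\n")
            fh.write(f"{c.contig_id}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{c.strand}\t0\t"
                     f"ID=cds-{c.call_id};Parent={c.call_id}\n")


def write_error_audit_tsv(path, errors: Sequence) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcategory\tn_peptides\tevidence_peptides\n")
        for r in errors:
            fh.write(f"{r.gene_id}\t{r.category}\t{len(r.evidence_peptides)}\t"
                     f"{';'.join(sorted(r.evidence_peptides))}\n")
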