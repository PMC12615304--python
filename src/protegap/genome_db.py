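"""Genetic-code-aware translation and proteogenomic search-database construction.

Builds the combined search space for a proteogenomic experiment: six-frame
translation of a genome, three-frame translation of assembled transcripts,
the annotated reference proteome, contaminants, and reversed decoys.

Ciliate nuclear genomes (e.g. *Tetrahymena thermophila*) reassign TAA and TAG
to glutamine, leaving TGA as the sole stop codon; translation therefore runs
through a :class:`GeneticCode` object rather than a fixed table.  Internal
coordinates are 0-based half-open throughout; GFF3 I/O converts to/from the
1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

STOP = "*"
_DNA_ALPHABET = frozenset("ACGTN")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ORIGIN_REFERENCE = "reference"
ORIGIN_SIX_FRAME = "six_frame"
ORIGIN_TRANSCRIPT = "transcript_frame"
ORIGIN_CONTAMINANT = "contaminant"
ORIGIN_DECOY = "decoy"

#: Origins that count as "annotated / non-genomic" when classifying GSSPs.
REFERENCE_LIKE_ORIGINS = frozenset({ORIGIN_REFERENCE, ORIGIN_CONTAMINANT})


class InvalidSequenceError(ValueError):
    """Raised for sequences containing characters outside {A,C,G,T,N}."""


# ---------------------------------------------------------------------------
# Genetic codes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table with explicit start and stop codon sets."""

    table_id: str
    codon_to_aa: dict
    start_codons: frozenset
    stop_codons: frozenset

    def __post_init__(self):
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"genetic code must map all 64 codons, got {len(self.codon_to_aa)}")
        derived_stops = frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP)
        if derived_stops != self.stop_codons:
            raise ValueError("stop_codons inconsistent with codon table")

    def aa(self, codon: str) -> str:
        """Translate one codon; codons containing N yield 'X'."""
        if "N" in codon:
            return "X"
        return self.codon_to_aa[codon]


def _code_from_ncbi(table_id: int, name: str) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = STOP
    return GeneticCode(
        table_id=name,
        codon_to_aa=mapping,
        start_codons=frozenset(table.start_codons),
        stop_codons=frozenset(table.stop_codons),
    )


#: NCBI translation table 1.
STANDARD_CODE = _code_from_ncbi(1, "standard")

#: NCBI translation table 6 (ciliate nuclear): TAA/TAG -> Q, TGA sole stop.
CILIATE_CODE = _code_from_ncbi(6, "ciliate")

GENETIC_CODES = {"1": STANDARD_CODE, "standard": STANDARD_CODE,
                 "6": CILIATE_CODE, "ciliate": CILIATE_CODE}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise InvalidSequenceError(f"contig {self.id}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise InvalidSequenceError(f"contig {self.id}: invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene: ordered CDS exons on a contig.

    ``exons`` are genomic 0-based half-open intervals sorted by genomic start
    regardless of strand; for minus-strand genes the reading order is the
    reverse of the genomic order.  CDS intervals include the stop codon.
    """

    gene_id: str
    contig_id: str
    strand: str
    exons: tuple
    cds_frame_offset: int = 0

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        ex = list(self.exons)
        if not ex:
            raise ValueError(f"{self.gene_id}: no exons")
        for (s, e) in ex:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
        for (_, e1), (s2, _) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping or unsorted exons")
        if (self.cds_length - self.cds_frame_offset) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not a codon multiple after frame offset")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])

    def reading_exons(self) -> list:
        """Exons in 5'->3' reading order."""
        return list(self.exons) if self.strand == "+" else list(reversed(self.exons))

    def spliced_cds(self, contig_seq: str) -> str:
        """Spliced CDS in reading orientation (reverse-complemented on '-')."""
        parts = [contig_seq[s:e] for s, e in self.exons]
        cds = "".join(parts)
        if self.strand == "-":
            cds = reverse_complement(cds)
        return cds[self.cds_frame_offset:]

    def protein(self, contig_seq: str, code: GeneticCode) -> str:
        """Translated protein, stop codon stripped if present at the end."""
        aa = translate(self.spliced_cds(contig_seq), code, 1)
        return aa[:-1] if aa.endswith(STOP) else aa


@dataclass(frozen=True)
class GenomicProvenance:
    contig_id: str
    strand: str
    frame: int           # +1/+2/+3 forward, -1/-2/-3 reverse complement
    start: int           # genomic, 0-based half-open
    end: int


@dataclass(frozen=True)
class TranscriptProvenance:
    transcript_id: str
    frame: int           # 1/2/3


@dataclass(frozen=True)
class ProteinEntry:
    entry_id: str
    sequence: str
    origin: str
    provenance: object = None
    source_entry_id: Optional[str] = None  # for decoys: the target they mirror


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str, code: GeneticCode, frame: int = 1) -> str:
    """Translate ``dna`` in one forward frame (1, 2 or 3).

    One letter per complete codon; stops are rendered as '*', N-containing
    codons as 'X'; a trailing partial codon is dropped.
    """
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame}")
    bad = set(dna) - _DNA_ALPHABET
    if bad:
        raise InvalidSequenceError(f"invalid DNA characters {sorted(bad)}")
    offset = frame - 1
    if len(dna) < offset + 3:
        raise InvalidSequenceError(f"sequence too short for frame {frame}")
    n_codons = (len(dna) - offset) // 3
    return "".join(code.aa(dna[offset + 3 * i: offset + 3 * i + 3]) for i in range(n_codons))


def _stop_free_stretches(aa: str) -> Iterable:
    """Yield (start_aa, end_aa) of maximal stop-free runs (0-based half-open)."""
    start = 0
    for i, ch in enumerate(aa):
        if ch == STOP:
            if i > start:
                yield (start, i)
            start = i + 1
    if len(aa) > start:
        yield (start, len(aa))


def six_frame_entries(contig: Contig, code: GeneticCode = CILIATE_CODE,
                      min_len: int = 20) -> list:
    """Maximal stop-free translation stretches in all six frames.

    Entries shorter than ``min_len`` residues are discarded.  Genomic
    provenance intervals are always given on forward-strand coordinates; for
    minus-strand frames the entry sequence equals the translation of the
    reverse complement of the recorded interval.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    entries = []
    L = len(contig.sequence)
    rc = reverse_complement(contig.sequence)
    for strand, seq in (("+", contig.sequence), ("-", rc)):
        for offset in range(3):
            if len(seq) < offset + 3:
                continue
            aa = translate(seq, code, offset + 1)
            frame = (offset + 1) if strand == "+" else -(offset + 1)
            for a, b in _stop_free_stretches(aa):
                if b - a < min_len:
                    continue
                if strand == "+":
                    g_start, g_end = offset + 3 * a, offset + 3 * b
                else:
                    g_start, g_end = L - offset - 3 * b, L - offset - 3 * a
                entry_id = f"{contig.id}|{strand}{offset + 1}|{g_start}-{g_end}"
                entries.append(ProteinEntry(
                    entry_id=entry_id,
                    sequence=aa[a:b],
                    origin=ORIGIN_SIX_FRAME,
                    provenance=GenomicProvenance(contig.id, strand, frame, g_start, g_end),
                ))
    return entries


def transcript_entries(transcripts: Sequence, code: GeneticCode = CILIATE_CODE,
                       min_len: int = 20) -> list:
    """Three-frame (sense) translation of assembled transcripts."""
    seen = set()
    entries = []
    for tid, seq in transcripts:
        if tid in seen:
            raise ValueError(f"duplicate transcript id {tid}")
        seen.add(tid)
        for offset in range(3):
            if len(seq) < offset + 3:
                continue
            aa = translate(seq, code, offset + 1)
            for a, b in _stop_free_stretches(aa):
                if b - a < min_len:
                    continue
                entries.append(ProteinEntry(
                    entry_id=f"{tid}|f{offset + 1}|{a}-{b}",
                    sequence=aa[a:b],
                    origin=ORIGIN_TRANSCRIPT,
                    provenance=TranscriptProvenance(tid, offset + 1),
                ))
    return entries


# ---------------------------------------------------------------------------
# Database assembly
# ---------------------------------------------------------------------------

@dataclass
class SearchDatabase:
    entries: list
    by_id: dict = field(init=False)
    origin_counts: dict = field(init=False)

    def __post_init__(self):
        self.by_id = {}
        counts: dict = {}
        for e in self.entries:
            if e.entry_id in self.by_id:
                raise ValueError(f"duplicate entry id {e.entry_id}")
            self.by_id[e.entry_id] = e
            counts[e.origin] = counts.get(e.origin, 0) + 1
        self.origin_counts = counts

    def __len__(self):
        return len(self.entries)


def reverse_decoy(entry: ProteinEntry) -> ProteinEntry:
    """Full-sequence reversal decoy for one target entry."""
    return ProteinEntry(
        entry_id=f"DECOY_{entry.entry_id}",
        sequence=entry.sequence[::-1],
        origin=ORIGIN_DECOY,
        source_entry_id=entry.entry_id,
    )


def build_database(reference: Sequence = (), genomic: Sequence = (),
                   transcript: Sequence = (), contaminants: Sequence = (),
                   with_decoys: bool = True) -> SearchDatabase:
    """Concatenate all sources and (optionally) append one reversed decoy per target."""
    targets = list(reference) + list(genomic) + list(transcript) + list(contaminants)
    entries = list(targets)
    if with_decoys:
        entries.extend(reverse_decoy(e) for e in targets)
    return SearchDatabase(entries)


def synthetic_contaminants() -> list:
    """Synthetic stand-in contaminant entries (trypsin/keratin surrogates).

    The sequences are fixed, arbitrary synthetic strings — placeholders for the
    real common-contaminant sequences appended in practice, which are not
    bundled here.  Labelled synthetic by id prefix.
    """
    seqs = {
        "SYN_CONTAM_TRYPSIN": "IVGGYTCGANTVPYQVSLNSGYHFCGGSLINSQWVVSAAHCYK"
                              "SGIQVRLGEDNINVVEGNEQFISASK",
        "SYN_CONTAM_KERATIN1": "SLNNQFASFIDKVRFLEQQNQVLQTKWELLQQVDTSTRTHNLEPYFESFINNLRRR"
                               "VDQLKSDQSRLDSELKNMQDMVEDYRNK",
        "SYN_CONTAM_KERATIN2": "GGGFGGGSGFGGGSGFGGGSGFSGGGFGGGGFGGGRFGGFGGPGGVGGLGGPGGFGPGGYPGGIHEVSVNQSLLQPLNVK",
    }
    return [ProteinEntry(k, v, ORIGIN_CONTAMINANT) for k, v in sorted(seqs.items())]


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> list:
    """Read a FASTA file as [(id, uppercase sequence), ...]."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_contigs(path) -> list:
    return [Contig(name, seq) for name, seq in read_fasta(path)]


def read_reference_proteins(path) -> list:
    return [ProteinEntry(name, seq, ORIGIN_REFERENCE) for name, seq in read_fasta(path)]


def write_fasta(path, records: Sequence) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_database_fasta(path, db: SearchDatabase) -> None:
    """Write the search database with structured origin|provenance headers."""
    records = []
    for e in db.entries:
        p = e.provenance
        if isinstance(p, GenomicProvenance):
            header = f"{e.entry_id} {e.origin}|{p.contig_id}|{p.strand}|{p.frame}|{p.start}|{p.end}"
        elif isinstance(p, TranscriptProvenance):
            header = f"{e.entry_id} {e.origin}|{p.transcript_id}|.|{p.frame}|.|."
        else:
            header = f"{e.entry_id} {e.origin}|.|.|.|.|."
        records.append((header, e.sequence))
    write_fasta(path, records)


def write_gene_models_gff3(path, models: Sequence, source: str = "protegap") -> None:
    """Write gene models as GFF3 (gene + CDS features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            fh.write(f"{m.contig_id}\t{source}\tgene\t{s + 1}\t{e}\t.\t{m.strand}\t.\tID={m.gene_id}\n")
            phase = m.cds_frame_offset
            for (xs, xe) in (m.exons if m.strand == "+" else reversed(m.exons)):
                fh.write(f"{m.contig_id}\t{source}\tCDS\t{xs + 1}\t{xe}\t.\t{m.strand}\t{phase}\t"
                         f"ID=cds-{m.gene_id};Parent={m.gene_id}\n")
                phase = (3 - ((xe - xs) - phase) % 3) % 3
            fh.write("###\n")


def read_gene_models_gff3(path) -> list:
    """Parse gene models (gene + CDS with Parent attributes) from a GFF3 file."""
    import gffutils
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models = []
    for gene in db.features_of_type("gene"):
        cds = sorted(db.children(gene, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            continue
        exons = tuple((f.start - 1, f.end) for f in cds)
        reading_first = cds[0] if gene.strand == "+" else cds[-1]
        try:
            offset = int(reading_first.frame)
        except (TypeError, ValueError):
            offset = 0
        models.append(GeneModel(gene_id=gene.id, contig_id=gene.seqid,
                                strand=gene.strand, exons=exons,
                                cds_frame_offset=offset))
    return models
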