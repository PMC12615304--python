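"""Synthetic proteogenomic study generator with a complete ground-truth ledger.

Emulates the study design this pipeline targets: an AT-rich ciliate-like
genome read with the ciliate nuclear code (TAA/TAG = Q, TGA the sole stop),
annotated genes with 0-2 introns, hidden genes absent from the annotation,
annotation errors injected per category (the genome always retains the true
CDS; only the GFF3 record is corrupted), tryptic peptides observed as noisy
b/y fragment spectra with optional planted PTM shifts across ten life-cycle
states, and negative-binomial RNA-seq counts whose true levels are
constructed to hit a configured mRNA-protein correlation on the log scale.

Every observable traces to a ledger record, so each pipeline stage can be
scored against known truth.  A fixed seed makes every output byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .digestion_mass import DEFAULT_MASSES, Peptide, digest, mz, peptide_mass
from .genome_db import (CILIATE_CODE, Contig, GeneModel, GeneticCode,
                        reverse_complement, six_frame_entries, translate,
                        write_fasta, write_gene_models_gff3)
from .novel_genes import ERR_INTRON_BOUNDARY, ERR_INTRON_CODING, ERR_START, ERR_STOP
from .ptm_annotator import ModificationCatalog, load_catalog
from .search_engine import Spectrum, theoretical_ions, write_mgf

#: Life-cycle states: growth, starvation (3/15 h), conjugation (2/12/18 h),
#: and sexual progeny 3A1 at ~27/~80 divisions under growth/starvation.
STATE_NAMES = ("G", "S3", "S15", "C2", "C12", "C18",
               "3A1-27G", "3A1-27S", "3A1-80G", "3A1-80S")

_DEFAULT_ERROR_GENES = {ERR_START: 3, ERR_STOP: 3,
                        ERR_INTRON_BOUNDARY: 3, ERR_INTRON_CODING: 2}
_DEFAULT_PTM_RATES = {"Phospho": 0.04, "Acetyl": 0.03, "Trimethyl": 0.02,
                      "GlyGly": 0.02, "Oxidation": 0.04}


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_contigs: int = 3
    n_annotated_genes: int = 50          # error genes are drawn from these
    n_hidden_genes: int = 5
    n_error_genes: Dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_ERROR_GENES))
    at_fraction: float = 0.75
    hidden_gc_boost: float = 0.10        # novel CDS modestly GC-richer
    intron_rate: float = 0.5
    annotated_codons: tuple = (80, 220)
    hidden_codons: tuple = (45, 110)
    peptide_sampling_depth: int = 200    # spectra per state
    n_noise_spectra: int = 1000
    ptm_rates: Dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_PTM_RATES))
    noise_peaks: int = 10
    mass_error_ppm: float = 5.0
    n_states: int = 10
    mrna_protein_correlation: float = 0.5
    rnaseq_depth: float = 2e6            # fragments per state
    nb_dispersion: float = 0.1
    abundance_sd_shared: float = 1.2     # log2 sd of the per-gene baseline
    abundance_sd_state: float = 1.0      # log2 sd of per-state deviations

    def __post_init__(self):
        if not 0 < self.at_fraction < 1:
            raise ValueError("at_fraction must be in (0,1)")
        if not 0 <= self.mrna_protein_correlation <= 1:
            raise ValueError("mrna_protein_correlation must be in [0,1]")
        if sum(self.n_error_genes.values()) > self.n_annotated_genes:
            raise ValueError("more error genes requested than annotated genes")
        if self.n_states != len(self.states):
            raise ValueError("n_states inconsistent with the state list")

    @property
    def states(self) -> tuple:
        return STATE_NAMES[:self.n_states]


@dataclass
class TrueGene:
    gene_id: str
    contig_id: str
    strand: str
    cds_interval: tuple              # genomic, stop codon included
    true_exons: tuple                # genomic intervals of the TRUE structure
    protein: str
    is_hidden: bool
    error_category: Optional[str] = None
    start_codon: str = "ATG"


@dataclass
class InjectedError:
    gene_id: str
    category: str
    description: str


@dataclass
class SpectrumTruth:
    spectrum_id: str
    peptide: Optional[str]           # None for noise-only spectra
    gene_id: Optional[str]
    state: Optional[str]
    modification: Optional[str]
    site: Optional[int]
    charge: int


@dataclass
class TruthLedger:
    genes: Dict[str, TrueGene] = field(default_factory=dict)
    errors: List[InjectedError] = field(default_factory=list)
    protein_level: Optional[pd.DataFrame] = None    # linear scale, genes x states
    mrna_level: Optional[pd.DataFrame] = None
    spectral_counts: Optional[pd.DataFrame] = None  # realized sampling counts
    spectra: List[SpectrumTruth] = field(default_factory=list)

    @property
    def hidden_genes(self) -> list:
        return [g for g in self.genes.values() if g.is_hidden]


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    contigs: Dict[str, str]
    annotated_models: List[GeneModel]
    transcripts: List[tuple]                 # (transcript_id, spliced true CDS)
    truth: TruthLedger
    spectra: List[Spectrum] = field(default_factory=list)
    rna_counts: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------

def _random_dna(rng, n, at_fraction):
    p_at = at_fraction / 2
    p_gc = (1 - at_fraction) / 2
    return "".join(rng.choice(list("ATGC"), size=n, p=[p_at, p_at, p_gc, p_gc]))


def _random_codons(rng, n, at_fraction, code: GeneticCode):
    """n codons with no in-frame stop under ``code``."""
    out = []
    while len(out) < n:
        codon = _random_dna(rng, 3, at_fraction)
        if codon in code.stop_codons:
            continue
        out.append(codon)
    return out


def _gene_fragment(rng, cfg: SyntheticConfig, code: GeneticCode, hidden: bool,
                   error_category: Optional[str]):
    """Build one gene in reading orientation.

    Returns (fragment, true_cds (r-interval incl stop), true_exons (r),
    annotated_exons (r) or None, protein, description).
    """
    at = cfg.at_fraction - (cfg.hidden_gc_boost if hidden else 0.0)
    lo, hi = cfg.hidden_codons if hidden else cfg.annotated_codons
    n_codons = int(rng.integers(lo, hi + 1))
    codons = _random_codons(rng, n_codons, at, code)
    desc = ""

    if error_category == ERR_START:
        codons[10] = "ATG"  # internal Met the corrupted annotation starts at
    cds = "ATG" + "".join(codons) + "TGA"
    cds_len = len(cds)
    protein = translate(cds, code, 1)[:-1]

    if hidden:
        # an in-frame stop immediately upstream makes the ORF boundaries of
        # the hidden gene identifiable from peptide evidence alone
        fragment = "TGA" + cds
        true_cds = (3, 3 + cds_len)
        true_exons = (true_cds,)
        return fragment, true_cds, true_exons, None, protein, desc

    fragment = cds
    true_cds = (0, cds_len)
    true_exons = [true_cds]
    annotated_exons = [true_cds]

    if error_category == ERR_START:
        annotated_exons = [(33, cds_len)]  # 11 codons late (ATG at codon 11)
        desc = "annotated start 33 nt downstream of the true start"
    elif error_category == ERR_STOP:
        annotated_exons = [(0, cds_len - 27)]  # truncates 8 codons + stop
        desc = "annotated stop 27 nt upstream of the true stop"
    elif error_category in (ERR_INTRON_BOUNDARY, ERR_INTRON_CODING):
        ilen = 30 if error_category == ERR_INTRON_BOUNDARY else 120
        # codon-boundary insertion point, frame preserved (ilen % 3 == 0);
        # both flanking annotated exons keep >= 45 nt so peptides can span them
        p = 3 * int(rng.integers(15, (cds_len - ilen - 45) // 3 + 1))
        annotated_exons = [(0, p), (p + ilen, cds_len)]
        desc = f"annotated {ilen} nt intron at {p} inside a contiguous true CDS"
    elif error_category is None and rng.random() < cfg.intron_rate:
        # genuine introns: GT..AG inserted into the genome, annotation correct
        n_introns = int(rng.integers(1, 3))
        points = sorted(rng.choice(np.arange(6, cds_len - 6), size=n_introns,
                                   replace=False).tolist())
        parts = []
        exons = []
        prev = 0
        shift = 0
        for point in points:
            parts.append(fragment[prev:point])
            exons.append((prev + shift, point + shift))
            intron = "GT" + _random_dna(rng, int(rng.integers(41, 77)), cfg.at_fraction) + "AG"
            parts.append(intron)
            shift += len(intron)
            prev = point
        parts.append(fragment[prev:])
        exons.append((prev + shift, cds_len + shift))
        fragment = "".join(parts)
        true_cds = (0, len(fragment))
        true_exons = exons
        annotated_exons = list(exons)
        desc = f"{n_introns} genuine intron(s)"

    return fragment, true_cds, tuple(true_exons), tuple(annotated_exons), protein, desc


def _flip_interval(iv, length):
    return (length - iv[1], length - iv[0])


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(config: SyntheticConfig,
                    rng: Optional[np.random.Generator] = None,
                    code: GeneticCode = CILIATE_CODE) -> SyntheticStudy:
    """Contigs, annotation (with injected errors), hidden genes, abundances."""
    if rng is None:
        rng = np.random.default_rng(config.seed)

    error_plan: List[Optional[str]] = []
    for cat in (ERR_START, ERR_STOP, ERR_INTRON_BOUNDARY, ERR_INTRON_CODING):
        error_plan.extend([cat] * config.n_error_genes.get(cat, 0))
    error_plan.extend([None] * (config.n_annotated_genes - len(error_plan)))
    rng.shuffle(error_plan)

    jobs = [("GENE", i, error_plan[i]) for i in range(config.n_annotated_genes)]
    jobs += [("HIDDEN", i, None) for i in range(config.n_hidden_genes)]
    order = rng.permutation(len(jobs))

    contig_parts: List[list] = [[] for _ in range(config.n_contigs)]
    contig_pos = [0] * config.n_contigs
    truth = TruthLedger()
    models: List[GeneModel] = []
    transcripts: List[tuple] = []

    for slot, job_idx in enumerate(order):
        kind, idx, err = jobs[job_idx]
        hidden = kind == "HIDDEN"
        gene_id = f"{'HG' if hidden else 'TTHERM'}{idx + 1:05d}"
        c = slot % config.n_contigs
        contig_id = f"chr{c + 1}"
        pad = _random_dna(rng, int(rng.integers(150, 401)), config.at_fraction)
        contig_parts[c].append(pad)
        contig_pos[c] += len(pad)

        frag, true_cds_r, true_exons_r, ann_exons_r, protein, desc = _gene_fragment(
            rng, config, code, hidden, err)
        strand = "+" if rng.random() < 0.5 else "-"
        flen = len(frag)
        placed = frag if strand == "+" else reverse_complement(frag)
        base = contig_pos[c]
        contig_parts[c].append(placed)
        contig_pos[c] += flen

        def to_genomic(iv):
            if strand == "+":
                return (base + iv[0], base + iv[1])
            f = _flip_interval(iv, flen)
            return (base + f[0], base + f[1])

        true_exons_g = tuple(sorted(to_genomic(iv) for iv in true_exons_r))
        truth.genes[gene_id] = TrueGene(
            gene_id=gene_id, contig_id=contig_id, strand=strand,
            cds_interval=to_genomic(true_cds_r), true_exons=true_exons_g,
            protein=protein, is_hidden=hidden, error_category=err)
        transcripts.append((f"{gene_id}.t1", _spliced_true_cds(frag, true_exons_r)))
        if not hidden:
            ann_exons_g = tuple(sorted(to_genomic(iv) for iv in ann_exons_r))
            models.append(GeneModel(gene_id=gene_id, contig_id=contig_id,
                                    strand=strand, exons=ann_exons_g))
            if err is not None:
                truth.errors.append(InjectedError(gene_id, err, desc))

    for c in range(config.n_contigs):
        tail = _random_dna(rng, int(rng.integers(150, 401)), config.at_fraction)
        contig_parts[c].append(tail)
    contigs = {f"chr{c + 1}": "".join(contig_parts[c]) for c in range(config.n_contigs)}

    _draw_abundances(config, rng, truth)
    models.sort(key=lambda m: (m.contig_id, m.span[0]))
    transcripts.sort()
    return SyntheticStudy(config=config, contigs=contigs, annotated_models=models,
                          transcripts=transcripts, truth=truth)


def _spliced_true_cds(fragment: str, true_exons_r: Sequence) -> str:
    return "".join(fragment[s:e] for s, e in true_exons_r)


def _draw_abundances(config: SyntheticConfig, rng, truth: TruthLedger) -> None:
    """Log-normal protein/mRNA levels hitting the target log-scale correlation.

    With a shared per-gene baseline (variance v0) plus per-state deviations
    (variance v1) whose cross-layer correlation is c, the per-state
    gene-to-gene correlation is (v0 + c*v1) / (v0 + v1); c is solved from the
    configured target.
    """
    genes = sorted(truth.genes)
    states = list(config.states)
    v0 = config.abundance_sd_shared ** 2
    v1 = config.abundance_sd_state ** 2
    rho = config.mrna_protein_correlation
    c = (rho * (v0 + v1) - v0) / v1
    c = float(np.clip(c, -1.0, 1.0))
    n, k = len(genes), len(states)
    mu = rng.normal(4.0, np.sqrt(v0), size=n)
    cov = np.array([[v1, c * v1], [c * v1, v1]])
    dev = rng.multivariate_normal([0.0, 0.0], cov, size=(n, k))
    log_m = mu[:, None] + dev[:, :, 0]
    log_p = mu[:, None] + dev[:, :, 1]
    truth.mrna_level = pd.DataFrame(np.exp2(log_m), index=genes, columns=states)
    truth.protein_level = pd.DataFrame(np.exp2(log_p), index=genes, columns=states)


# ---------------------------------------------------------------------------
# Spectrum simulation
# ---------------------------------------------------------------------------

def detectable_peptide_set(study: SyntheticStudy,
                           code: GeneticCode = CILIATE_CODE,
                           min_entry_len: int = 20) -> set:
    """Peptide sequences findable in the six-frame + reference search space."""
    seqs = set()
    for cid, seq in sorted(study.contigs.items()):
        for entry in six_frame_entries(Contig(cid, seq), code, min_entry_len):
            for pep in digest(entry.sequence):
                if pep.matchable:
                    seqs.add(pep.sequence)
    for model in study.annotated_models:
        prot = model.protein(study.contigs[model.contig_id], code)
        for pep in digest(prot):
            if pep.matchable:
                seqs.add(pep.sequence)
    return seqs


def _sample_peptides_per_gene(study: SyntheticStudy, detectable: set) -> Dict[str, list]:
    """(peptide, weight) lists per gene; fewer missed cleavages weigh more."""
    weights = {0: 1.0, 1: 0.3, 2: 0.1}
    out: Dict[str, list] = {}
    for gene_id, gene in sorted(study.truth.genes.items()):
        peps = {}
        for pep in digest(gene.protein):
            if pep.matchable and pep.sequence in detectable:
                w = weights[pep.missed_cleavages]
                peps[pep.sequence] = max(peps.get(pep.sequence, 0.0), w)
        out[gene_id] = sorted(peps.items())
    return out


def simulate_spectra(study: SyntheticStudy,
                     rng: Optional[np.random.Generator] = None,
                     catalog: Optional[ModificationCatalog] = None,
                     code: GeneticCode = CILIATE_CODE) -> List[Spectrum]:
    """Per-state DDA-like spectra of abundance-sampled tryptic peptides.

    Each spectrum carries the peptide's b/y ladder with randomized
    intensities, multiplicative N(0, mass_error_ppm) m/z errors, an optional
    planted PTM shift at a ledger-recorded site, and uniform noise peaks.
    Noise-only spectra model unmatchable acquisitions.
    """
    cfg = study.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if catalog is None:
        catalog = load_catalog()
    detectable = detectable_peptide_set(study, code)
    per_gene = _sample_peptides_per_gene(study, detectable)
    genes = sorted(g for g in per_gene if per_gene[g])
    counts = pd.DataFrame(0, index=sorted(study.truth.genes), columns=list(cfg.states))

    ptm_items = sorted(cfg.ptm_rates.items())
    total_rate = sum(r for _n, r in ptm_items)
    if total_rate > 1:
        raise ValueError("ptm_rates sum above 1")

    spectra: List[Spectrum] = []
    charges = np.array([2, 3, 4, 5, 6])
    charge_p = np.array([0.45, 0.33, 0.15, 0.05, 0.02])

    for state in cfg.states:
        levels = np.array([study.truth.protein_level.loc[g, state] for g in genes])
        p = levels / levels.sum()
        picks = rng.choice(len(genes), size=cfg.peptide_sampling_depth, p=p)
        for i, gi in enumerate(picks):
            gene_id = genes[gi]
            plist = per_gene[gene_id]
            w = np.array([wt for _s, wt in plist])
            seq = plist[rng.choice(len(plist), p=w / w.sum())][0]
            counts.loc[gene_id, state] += 1

            mod_name = None
            site = None
            u = rng.random()
            acc = 0.0
            for name, rate in ptm_items:
                acc += rate
                if u < acc:
                    mod = catalog.by_name[name]
                    pos = [j for j, aa in enumerate(seq) if aa in mod.residues]
                    if pos:
                        mod_name = name
                        site = int(rng.choice(pos))
                    break
            mods = ((site, mod_name, catalog.by_name[mod_name].mass),) if mod_name else ()
            pep = Peptide(sequence=seq, modifications=mods)

            sid = f"{state}_{i:05d}"
            spectra.append(_make_spectrum(rng, cfg, sid, pep))
            study.truth.spectra.append(SpectrumTruth(
                spectrum_id=sid, peptide=seq, gene_id=gene_id, state=state,
                modification=mod_name, site=site, charge=spectra[-1].charge))

    for i in range(cfg.n_noise_spectra):
        sid = f"NOISE_{i:05d}"
        charge = int(rng.choice([2, 3]))
        neutral = float(rng.uniform(800.0, 2600.0))
        n_peaks = 40
        peaks = rng.uniform(100.0, 1600.0, size=n_peaks)
        inten = rng.lognormal(3.0, 0.7, size=n_peaks)
        spectra.append(Spectrum(sid, mz(neutral, charge), charge, peaks, inten))
        study.truth.spectra.append(SpectrumTruth(sid, None, None, None, None, None, charge))

    study.truth.spectral_counts = counts
    study.spectra = spectra
    return spectra


def _make_spectrum(rng, cfg: SyntheticConfig, sid: str, pep: Peptide) -> Spectrum:
    constants = DEFAULT_MASSES
    b, y = theoretical_ions(pep, constants)
    ions = np.concatenate([b, y])
    inten = rng.lognormal(4.0, 0.6, size=len(ions))
    err = rng.normal(0.0, cfg.mass_error_ppm * 1e-6, size=len(ions))
    ions = ions * (1.0 + err)
    if cfg.noise_peaks > 0:
        noise_mz = rng.uniform(100.0, max(1600.0, ions.max() + 50.0), size=cfg.noise_peaks)
        noise_in = rng.lognormal(2.5, 0.6, size=cfg.noise_peaks)
        ions = np.concatenate([ions, noise_mz])
        inten = np.concatenate([inten, noise_in])
    charge = int(rng.choice([2, 3, 4, 5, 6], p=[0.45, 0.33, 0.15, 0.05, 0.02]))
    pmass = peptide_mass(pep, constants)
    pmz = mz(pmass, charge, constants) * (1.0 + rng.normal(0.0, cfg.mass_error_ppm * 1e-6))
    return Spectrum(sid, pmz, charge, ions, inten)


# ---------------------------------------------------------------------------
# RNA-seq simulation
# ---------------------------------------------------------------------------

def simulate_rnaseq(study: SyntheticStudy,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Negative-binomial counts around length-scaled true mRNA levels."""
    cfg = study.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    genes = sorted(study.truth.genes)
    lengths_kb = np.array([
        sum(e - s for s, e in study.truth.genes[g].true_exons) / 1000.0 for g in genes])
    counts = pd.DataFrame(0, index=genes, columns=list(cfg.states))
    for state in cfg.states:
        level = study.truth.mrna_level.loc[genes, state].to_numpy()
        raw = level * lengths_kb
        if cfg.rnaseq_depth <= 0 or raw.sum() == 0:
            continue
        mean = raw / raw.sum() * cfg.rnaseq_depth
        if cfg.nb_dispersion > 0:
            r = 1.0 / cfg.nb_dispersion
            pnb = r / (r + mean)
            counts[state] = rng.negative_binomial(r, pnb)
        else:
            counts[state] = rng.poisson(mean)
    study.rna_counts = counts
    return counts


# ---------------------------------------------------------------------------
# Convenience driver and file output
# ---------------------------------------------------------------------------

def simulate(config: SyntheticConfig) -> SyntheticStudy:
    """Full deterministic simulation: genome, spectra, RNA-seq counts."""
    rng = np.random.default_rng(config.seed)
    study = generate_genome(config, rng)
    simulate_spectra(study, rng)
    simulate_rnaseq(study, rng)
    return study


def write_outputs(study: SyntheticStudy, outdir) -> None:
    """Write genome FASTA, GFF3, transcript FASTA, MGF, counts and ledger TSVs."""
    import os
    os.makedirs(outdir, exist_ok=True)
    join = lambda name: os.path.join(str(outdir), name)
    write_fasta(join("genome.fasta"), sorted(study.contigs.items()))
    write_gene_models_gff3(join("annotation.gff3"), study.annotated_models)
    write_fasta(join("transcripts.fasta"), study.transcripts)
    write_fasta(join("reference_proteins.fasta"),
                [(m.gene_id, m.protein(study.contigs[m.contig_id], CILIATE_CODE))
                 for m in study.annotated_models])
    if study.spectra:
        write_mgf(join("spectra.mgf"), study.spectra)
    if study.rna_counts is not None:
        study.rna_counts.to_csv(join("rna_counts.tsv"), sep="\t")
    with open(join("truth_genes.tsv"), "w") as fh:
        fh.write("gene_id\tcontig\tstrand\tcds_start\tcds_end\thidden\terror\tprotein\n")
        for g in sorted(study.truth.genes.values(), key=lambda x: x.gene_id):
            fh.write(f"{g.gene_id}\t{g.contig_id}\t{g.strand}\t{g.cds_interval[0]}\t"
                     f"{g.cds_interval[1]}\t{int(g.is_hidden)}\t{g.error_category or ''}\t"
                     f"{g.protein}\n")
    with open(join("truth_spectra.tsv"), "w") as fh:
        fh.write("spectrum_id\tpeptide\tgene_id\tstate\tmodification\tsite\tcharge\n")
        for s in study.truth.spectra:
            fh.write(f"{s.spectrum_id}\t{s.peptide or ''}\t{s.gene_id or ''}\t"
                     f"{s.state or ''}\t{s.modification or ''}\t"
                     f"{'' if s.site is None else s.site}\t{s.charge}\n")
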