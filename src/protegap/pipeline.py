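"""End-to-end proteogenomic pipeline orchestration.

Glues the stages together in the order the analysis runs: database
construction -> open search -> peptide/protein FDR -> peptide evidence and
grouping -> genome mapping -> novel-gene calling and gene-model audit ->
PTM annotation -> NSAF/FPKM quantification and cross-omics correlation.
Each stage remains independently usable; this module only wires defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .digestion_mass import DEFAULT_MASSES, MassConstants, build_peptide_index
from .genome_db import (CILIATE_CODE, Contig, GeneModel, GeneticCode, ProteinEntry,
                        ORIGIN_REFERENCE, SearchDatabase, build_database,
                        six_frame_entries, synthetic_contaminants, transcript_entries)
from .mapping_grouping import (PeptideEvidence, ProteinGroup, UNIQUENESS_GSSP,
                               assign_peptides, group_proteins,
                               map_peptide_to_genome, prefer_reference_anchors)
from .novel_genes import (GeneModelError, NovelGeneCall, call_novel_gene,
                          cluster_gssps, detect_gene_model_errors, gene_frame_keys)
from .ptm_annotator import ModificationCatalog, assign_ptms, load_catalog, summarize_ptms
from .quant_integration import (AbundanceMatrix, correlate_omics, fpkm_matrix,
                                nsaf_matrix)
from .search_engine import (PSM, FragmentIndex, annotate_q_values, open_search,
                            protein_fdr)
from .synthetic_data import SyntheticConfig, SyntheticStudy, simulate


@dataclass
class PipelineConfig:
    fdr_threshold: float = 0.01
    precursor_window: tuple = (-500.0, 500.0)
    frag_tol_ppm: float = 20.0
    precursor_tol_ppm: float = 20.0
    max_missed: int = 2
    min_peptide_len: int = 6
    max_peptide_len: int = 60
    db_min_entry_len: int = 20
    include_transcripts: bool = False
    max_gssp_gap: int = 300
    min_unique_gssps: int = 2
    constants: MassConstants = field(default_factory=lambda: DEFAULT_MASSES)


@dataclass
class PipelineResult:
    database: SearchDatabase
    ranked_psms: List[PSM]
    accepted_psms: List[PSM]
    evidence: List[PeptideEvidence]
    groups: List[ProteinGroup]
    accepted_groups: List[ProteinGroup]
    novel_calls: List[NovelGeneCall]
    rerouted_calls: List[NovelGeneCall]
    gene_model_errors: List[GeneModelError]
    ptm_assignments: list
    ptm_summary: pd.DataFrame
    nsaf: Optional[AbundanceMatrix] = None
    fpkm: Optional[AbundanceMatrix] = None
    correlations: Optional[Dict[str, float]] = None

    @property
    def gssps(self) -> list:
        return [ev for ev in self.evidence if ev.uniqueness == UNIQUENESS_GSSP]


def build_study_database(study: SyntheticStudy, pconf: PipelineConfig,
                         code: GeneticCode = CILIATE_CODE) -> SearchDatabase:
    reference = [ProteinEntry(m.gene_id, m.protein(study.contigs[m.contig_id], code),
                              ORIGIN_REFERENCE)
                 for m in study.annotated_models]
    genomic = []
    for cid, seq in sorted(study.contigs.items()):
        genomic.extend(six_frame_entries(Contig(cid, seq), code, pconf.db_min_entry_len))
    transcripts = (transcript_entries(study.transcripts, code, pconf.db_min_entry_len)
                   if pconf.include_transcripts else [])
    return build_database(reference=reference, genomic=genomic,
                          transcript=transcripts,
                          contaminants=synthetic_contaminants(), with_decoys=True)


def run_pipeline(study: SyntheticStudy, pconf: Optional[PipelineConfig] = None,
                 catalog: Optional[ModificationCatalog] = None,
                 code: GeneticCode = CILIATE_CODE) -> PipelineResult:
    pconf = pconf or PipelineConfig()
    catalog = catalog or load_catalog()
    models = study.annotated_models
    models_by_id = {m.gene_id: m for m in models}

    database = build_study_database(study, pconf, code)
    index = build_peptide_index(database, max_missed=pconf.max_missed,
                                min_len=pconf.min_peptide_len,
                                max_len=pconf.max_peptide_len,
                                constants=pconf.constants)
    psms = open_search(study.spectra, index,
                       precursor_window=pconf.precursor_window,
                       frag_tol_ppm=pconf.frag_tol_ppm,
                       precursor_tol_ppm=pconf.precursor_tol_ppm,
                       constants=pconf.constants)
    ranked = annotate_q_values(psms)
    accepted = [p for p in ranked if p.q_value <= pconf.fdr_threshold and not p.is_decoy]
    accepted_decoys = [p for p in ranked if p.q_value <= pconf.fdr_threshold and p.is_decoy]

    evidence = assign_peptides(accepted, database)
    groups = group_proteins(evidence, database)
    prefer_reference_anchors(groups, evidence, database)
    decoy_groups: list = []
    if accepted_decoys:
        decoy_evidence = assign_peptides(accepted_decoys, database, decoy_side=True)
        decoy_groups = group_proteins(decoy_evidence, database, is_decoy=True)
    accepted_groups = protein_fdr(groups + decoy_groups, pconf.fdr_threshold)

    map_peptide_to_genome(evidence, database, models_by_id)
    novel_loci, _audit_loci = cluster_gssps(evidence, models, pconf.max_gssp_gap)
    novel_calls, rerouted = [], []
    for n, locus in enumerate(novel_loci):
        call = call_novel_gene(locus, study.contigs, code,
                               min_unique_gssps=pconf.min_unique_gssps,
                               call_id=f"NOVEL{n + 1:04d}")
        if call is None:
            continue
        # an inferred ORF that runs into an annotated gene in the same frame
        # is annotation-error evidence, not a novel gene
        if _orf_overlaps_annotated(call, models):
            rerouted.append(call)
        else:
            novel_calls.append(call)
    errors = detect_gene_model_errors(evidence, models, study.contigs, code)

    spectra_by_id = {s.spectrum_id: s for s in study.spectra}
    anchor_of_entry = {eid: g.anchor_entry for g in groups for eid in g.member_entry_ids}
    assignments = assign_ptms(accepted, spectra_by_id, catalog,
                              tol_ppm=pconf.precursor_tol_ppm,
                              frag_tol_ppm=pconf.frag_tol_ppm,
                              constants=pconf.constants,
                              anchor_of_entry=anchor_of_entry)
    summary = summarize_ptms(assignments)

    nsaf_m = fpkm_m = correlations = None
    spectrum_state = {t.spectrum_id: t.state for t in study.truth.spectra}
    states = list(study.config.states)
    if states and accepted:
        nsaf_m = quantify_groups(accepted, evidence, groups, database, states,
                                 spectrum_state)
        if study.rna_counts is not None:
            lengths = {g: sum(e - s for s, e in study.truth.genes[g].true_exons)
                       for g in study.truth.genes}
            fpkm_m = fpkm_matrix(study.rna_counts, lengths)
            correlations = correlate_omics(fpkm_m, nsaf_m)

    return PipelineResult(
        database=database, ranked_psms=ranked, accepted_psms=accepted,
        evidence=evidence, groups=groups, accepted_groups=accepted_groups,
        novel_calls=novel_calls, rerouted_calls=rerouted,
        gene_model_errors=errors, ptm_assignments=assignments,
        ptm_summary=summary, nsaf=nsaf_m, fpkm=fpkm_m, correlations=correlations)


def _orf_overlaps_annotated(call: NovelGeneCall, models: Sequence) -> bool:
    s, e = call.orf_interval
    for m in models:
        gs, ge = m.span
        if (m.contig_id == call.contig_id and m.strand == call.strand
                and gs < e and s < ge and call.frame_key in gene_frame_keys(m)):
            return True
    return False


def quantify_groups(accepted: Sequence, evidence: Sequence, groups: Sequence,
                    database: SearchDatabase, states: Sequence,
                    spectrum_state: Dict[str, Optional[str]]) -> AbundanceMatrix:
    """Per-state NSAF over protein groups (anchor length as the group length).

    Shared peptides count toward their home group only, so the column totals
    equal the number of state-assigned accepted PSMs.
    """
    home: Dict[str, str] = {}
    for g in sorted(groups, key=lambda g: g.group_id):
        for pep in g.peptides:
            home.setdefault(pep, g.anchor_entry)
    anchors = sorted({g.anchor_entry for g in groups})
    counts = pd.DataFrame(0, index=anchors, columns=list(states))
    for psm in accepted:
        state = spectrum_state.get(psm.spectrum_id)
        if state is None or psm.peptide not in home:
            continue
        counts.loc[home[psm.peptide], state] += 1
    lengths = {a: len(database.by_id[a].sequence) for a in anchors}
    return nsaf_matrix(counts, lengths)


# ---------------------------------------------------------------------------
# FDR calibration study
# ---------------------------------------------------------------------------

def realized_false_proportion(study: SyntheticStudy, result: PipelineResult,
                              il_equivalent: bool = True) -> tuple:
    """(n_false, n_accepted): accepted PSMs whose peptide is not the ledger's
    generating peptide for that spectrum (noise-only spectra count as false).

    Isoleucine and leucine are isobaric, so fragmentation spectra cannot in
    principle distinguish sequences that differ only at I/L positions; by
    default such matches count as correct (``il_equivalent``), the standard
    convention when scoring identifications against a known ground truth.
    """
    def norm(seq):
        if seq is None:
            return None
        return seq.replace("I", "L") if il_equivalent else seq
    truth = {t.spectrum_id: norm(t.peptide) for t in study.truth.spectra}
    n_false = sum(1 for p in result.accepted_psms
                  if truth.get(p.spectrum_id) != norm(p.peptide))
    return n_false, len(result.accepted_psms)


def fdr_calibration(base_config: Optional[SyntheticConfig] = None,
                    seeds: Sequence = tuple(range(1, 11)),
                    pconf: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Realized vs estimated FDR across independently seeded simulations."""
    base_config = base_config or SyntheticConfig()
    rows = []
    for seed in seeds:
        cfg = replace(base_config, seed=int(seed))
        study = simulate(cfg)
        result = run_pipeline(study, pconf)
        n_false, n_acc = realized_false_proportion(study, result)
        rows.append({"seed": int(seed), "n_accepted": n_acc, "n_false": n_false,
                     "realized_fdr": n_false / n_acc if n_acc else 0.0})
    return pd.DataFrame(rows)
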