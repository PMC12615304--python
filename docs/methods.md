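# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Translation and database construction

Translation runs through an explicit codon table. The default is the
ciliate nuclear code (NCBI table 6): TAA and TAG encode glutamine and TGA is
the only stop, which is why six-frame translation of a *Tetrahymena*-like
genome is wrong under the standard code — stop-free stretches would be
fragmented at every in-frame TAA/TAG. Both tables are taken from Biopython's
`CodonTable` and wrapped with explicit start/stop sets. Codons containing N
translate to X; X never matches a spectrum (conservative handling of
ambiguity). Coordinates are 0-based half-open internally; GFF3 I/O converts
to 1-based inclusive at the boundary.

Six-frame entries are **maximal inter-stop stretches**, not start-to-stop
ORFs. The reason is the object being searched for: a GSSP may lie upstream
of any start codon (that is precisely what makes start-codon errors and
noncanonical initiation discoverable), so start inference is deferred to the
novel-gene caller. Stretches shorter than 20 residues are dropped — below
that length tryptic peptides rarely yield confident identifications and the
index roughly doubles. Decoys are full-sequence reversals: deterministic,
reproducible, and composition-preserving. A peptide sequence reachable from
both a target and a decoy entry counts as target (the standard resolution of
reversal collisions). The contaminant entries are synthetic stand-ins for
the usual trypsin/keratin additions (fixed arbitrary sequences, labelled
`SYN_CONTAM_*`); they exercise the contaminant-handling logic without
bundling third-party sequence data.

## Digestion and masses

Fully tryptic cleavage C-terminal to K/R except before proline, up to 2
missed cleavages, peptide length 6–60. The 60-residue cap bounds the index
at the long end of detectable tryptic peptides and is configurable. Residue
masses are standard monoisotopic values (pyteomics); water 18.0105647 Da,
proton 1.0072765 Da. Carbamidomethylation of cysteine (+57.021464 Da) is
applied as a fixed modification by default, reflecting routine iodoacetamide
alkylation; `UNMODIFIED_MASSES` switches it off. Protein N-terminal
methionine is not specially removed and no semi-tryptic peptides are
generated, matching a fully tryptic search.

## Open search

Candidates for a spectrum are peptides whose unmodified mass lies within
[−500, +500] Da of the observed neutral mass — wide enough to cover every
entry in the modification catalog (largest: ADP-ribosyl, +541 Da, reachable
only in the negative direction as a neutral loss would be; in practice the
window covers all catalog masses with margin). Candidate preselection uses a
fragment-ion index over the unshifted b/y ladders: a modified spectrum still
shares the untouched half of its ladder with the unshifted ions, so counting
shared ions per peptide and keeping the top 50 candidates (by count) never
discards the generating peptide in practice while keeping the search linear
in spectrum count.

Scoring: the delta is attributed to one residue position; placing it at
position t shifts b-ions containing t and y-ions containing t. The matched
ion count is evaluated for every placement in O(peptide length) via prefix
sums, the best placement kept (ties → lowest position). The reported score
is (matched peaks) + (matched intensity fraction). A delta within the
precursor tolerance (20 ppm of the peptide mass) is scored as unmodified.

Tie-breaking between candidates is total and deterministic: score, then the
fraction of the candidate's own theoretical ions that found a peak
(parsimony — an explanation that accounts for more of its predicted spectrum
wins), then smaller |delta|, then lexicographic sequence. The parsimony key
resolves a structural ambiguity class in open searches: a peptide with a
C-terminal modification ties, peak for peak, with its one-missed-cleavage
superstring at a compensating delta (e.g. +GG at the terminal K vs an
appended K at delta −14.06 Da), and only the completeness of the predicted
ladder distinguishes them.

The scorer is intentionally simple and documented rather than a
reimplementation of a production engine: its job on this pipeline's data is
to rank the generating peptide first and to give decoys the same score
distribution as false targets, which is what the calibration test measures.

## FDR control

Estimated FDR at a score cutoff is #decoys/#targets above the cutoff;
q-values are the running minimum from the bottom of the ranked list;
accepted = q ≤ 1%, decoys removed after estimation. The +1 correction is off
by default (transparency at toy scale; available via `plus_one=True`). The
same estimator applies at protein-group level with groups scored by their
best peptide. Consequence of no +1: the estimator is very slightly
anti-conservative; across ten simulated studies the realized
false-identification proportion averages just above the nominal 1% but
within binomial sampling slack, which is exactly what the acceptance test
asserts. When scoring realized errors against the ground truth, sequences
differing only at I/L positions count as correct: leucine and isoleucine are
isobaric, b/y fragmentation cannot distinguish them even in principle, and
decoy-based estimation cannot model them as errors.

## Evidence, grouping, mapping

Peptide-to-entry matching is exact substring with tryptic termini (enforced
by construction: matches come from the digest index). I and L are distinct
for matching. A peptide is a GSSP iff none of its matches is a reference or
contaminant entry. Grouping is greedy parsimony: entries processed by
descending peptide count then id; identical sets merge, subsets are
subsumed; shared-peptide spectral counts go to the peptide's first
(anchor) group only, so counts are conserved — the sum of group spectral
counts equals the number of accepted PSMs. Groups containing an annotated
accession are re-anchored on it so per-gene quantification is direct.
Six-frame matches map to the genome by provenance arithmetic (3 nt per
residue, strand-aware); reference matches are projected through the gene
model's exons and may span junctions. Every mapping re-translates to its
peptide exactly; the test suite checks this for every mapping the default
simulation produces.

## Novel genes and the gene-model audit

GSSP loci = contiguous GSSP mappings on one contig/strand/frame merged
within 300 nt (no value is established for this gap in the source analyses;
300 nt spans typical inter-peptide gaps at modest coverage and is
configurable). Loci in frame with an annotated gene are routed to the audit.
A call needs ≥ 2 unique GSSPs. ORF inference prefers ATG over a more
upstream alternative start (GTG/CTG/TTG), reproducing the observed
predominance of ATG among novel genes while still surfacing alternative and
noncanonical cases; when no candidate start exists between the upstream stop
and the evidence, the call is evidence-bounded: the codon at the most
upstream evidence-consistent position is reported and flagged noncanonical
rather than guessing an initiation rule. Calls whose inferred ORF runs into
an annotated gene in frame are rerouted to the audit (they are annotation
evidence, not novel genes). Only single-exon ORFs are called. ORF intervals
include the stop codon; GC content is computed over the ORF with N excluded.

Audit categories, evaluated per contiguous GSSP mapping against each
same-strand model:

- **start_error / stop_error** — the peptide extends beyond the annotated
  start/stop in frame: it crosses the boundary, or lies wholly beyond it
  within 300 nt with no intervening in-frame genomic stop. For stop errors
  the non-crossing form additionally requires that the annotated terminal
  codon is not a genomic stop (if it were, translation would genuinely end
  there). The wholly-beyond form matters because tryptic cleavage sites need
  not straddle the boundary.
- **intron_boundary_error** — the peptide is translated contiguously across
  an annotated exon–intron boundary, in frame with the flanking exon.
- **intron_coding** — the peptide lies wholly inside an annotated intron, in
  frame with either flanking exon's contiguous reading.

One record per (gene, category) with all supporting peptides. In-frame
comparisons use per-exon codon phases, so genes with genuine introns and
frame offsets are handled; spliced (reference-projected) mappings are never
audited, which is what keeps correctly annotated intron-containing genes
free of false records.

## PTM annotation

The catalog ships 30 modifications with Unimod monoisotopic masses, residue
specificities and position rules, as a TSV (`protegap/data/modifications.tsv`)
so it can be swapped per study. Delta matching minimizes |delta − mass|
within 20 ppm of the peptide mass — the precursor scale, consistent with the
search tolerance. Exact-distance ties are reported as ambiguous with both
names. A match is *resolved* only if the runner-up within tolerance is at
least 0.02 Da further away (20 ppm at 1000 Da): acetyl/trimethyl (0.0364 Da
apart) resolve on peptides up to ~1800 Da, phospho/sulfo (0.0095 Da apart)
never resolve at this tolerance, and such assignments are reported but not
confident. Localization rescoring places the shift at every
specificity-compatible position; the winner must lead by ≥ 1 matched ion to
be confident, ties go to the lowest position unconfident. One modification
per PSM (the single-delta open search cannot represent more). Summaries
deduplicate sites by (protein anchor, coordinate, type); an ambiguous PSM
contributes to each tied type.

## Quantification and integration

NSAF per protein group uses the anchor length; columns sum to 1 by
construction and all-zero states are flagged, not divided. FPKM uses the
column sum as library size. Z-scores use the sample (n−1) standard
deviation, matching common spreadsheet/clustering-tool behavior; constant
rows become zeros and are flagged. State specificity is strict: z > 2 in
exactly one state and z < 0 in the remaining nine. Cross-omics correlations
are computed on log2(x + offset) by default — offset 1 for FPKM, half the
smallest positive value for NSAF (whose values are ≪ 1) — because abundance
distributions are heavy-tailed; `transform="none"` is available. Entities
enter a state's correlation only if quantified in both layers; fewer than 3
shared entities reports missing.

## The synthetic study

Defaults define the simulated study conditions: 3 contigs, 50 annotated
genes (80–220 codons) of which 3/3/3/2 carry injected
start/stop/intron-boundary/intron-coding errors, 5 hidden genes (45–110
codons, mirroring the shorter lengths reported for novel genes), AT fraction
0.75 for the genome and 0.65 for hidden CDS (novel coding sequences are
modestly GC-richer, giving the GC comparison signal), intron probability 0.5
with 1–2 GT..AG introns of 45–80 nt, ten life-cycle states named
G/S3/S15/C2/C12/C18/3A1-27G/3A1-27S/3A1-80G/3A1-80S, 200 sampled spectra per
state plus 1000 noise-only spectra, 10 noise peaks and 5 ppm mass error per
spectrum, PTM plant rates 4%/3%/2%/2%/4% for
phospho/acetyl/trimethyl/GG/oxidation, negative-binomial RNA counts
(dispersion 0.1, 2×10⁶ fragments per state), and a target mRNA–protein
log-scale correlation of 0.5 — the middle of the moderate range such
comparisons typically report.

Construction details that make ground truth exact: in-frame stops never
occur inside a CDS under the ciliate code; an in-frame TGA is placed
immediately upstream of each hidden gene's ATG, so the true ORF boundaries
are identifiable from peptide evidence alone and recovery can be scored as
interval equality; injected errors corrupt only the GFF3 record while the
genome keeps the true CDS; fake introns have lengths divisible by 3 at codon
boundaries so the corrupted annotation still translates. Spectra sample
peptides proportional to per-state protein abundance, restricted to peptides
present in the search space (protein N-terminal peptides of mid-stretch
genes lack a tryptic N-terminus in the six-frame entry and are not
observable by construction — real searches have the same blind spot).
Abundances combine a shared per-gene baseline (log2 SD 1.2) with per-state
deviations (SD 1.0) whose cross-layer correlation is solved so that the
per-state gene-to-gene correlation hits the configured target.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: chromatographic behavior and co-elution, isotope
envelopes and co-isolation chimeras, charge-dependent fragmentation
efficiency, fragment ions above charge 1, semi-tryptic and in-source decay
peptides, sequence polymorphisms, multi-exon novel genes, and annotation
errors subtler than the four injected classes. FDR calibration measured here
says the decoy model matches this generator's false-match process, not every
false-match process real spectra produce.

## Problem sizes

Defaults were chosen so a full ten-seed calibration study (≈30,000 spectra
against ≈40,000 indexed peptides) completes in minutes on one CPU, and the
default single simulation in well under a minute — large enough for stable
proportions (≈2,000 accepted PSMs per seed), small enough to iterate.

## Known limitations

- The open search attributes the whole delta to one site; co-occurring
  modifications are misassigned or rejected.
- Realized FDR tracks the estimator only as well as decoys model false
  matches; isobaric substitutions (I/L, Q↔GA, N↔GG) are invisible to it.
- The audit's non-crossing boundary evidence requires a clear in-frame
  reading; a genuine downstream gene in the same frame within 300 nt could
  in principle masquerade as a stop error (not constructible in the
  generator, untested on real genomes).
- Novel-gene calling assumes single-exon ORFs; a hidden gene with an intron
  would be called as its largest exonic fragment.
- Transcript-frame matches carry no genomic provenance and never contribute
  to mapping-based stages (they still affect GSSP status and grouping).
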