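"""Label-free quantification and proteome-transcriptome integration.

Protein abundance uses the normalized spectral abundance factor,
NSAF_k = (SpC_k / L_k) / sum_j (SpC_j / L_j), where SpC is the spectral
count and L the protein length in residues; every NSAF column sums to one.
Transcript abundance uses FPKM = count * 1e9 / (exon length in bp * total
mapped fragments).  Cross-state profiles are row Z-scored (sample standard
deviation), state-specific high expression follows the z > 2 in one state
and z < 0 in all others rule, and the two omics layers are compared per
state by Pearson correlation, by default on log2-transformed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

KIND_SPECTRAL = "spectral_count"
KIND_NSAF = "NSAF"
KIND_READ_COUNT = "read_count"
KIND_FPKM = "FPKM"
KIND_ZSCORE = "zscore"


@dataclass
class AbundanceMatrix:
    """Entities x life-cycle states, with the quantification kind attached."""

    values: pd.DataFrame
    kind: str
    flagged_columns: tuple = ()      # all-zero states (no PSMs / no reads)
    flagged_rows: tuple = ()         # constant rows zeroed by Z-scoring

    @property
    def entity_ids(self) -> list:
        return list(self.values.index)

    @property
    def state_ids(self) -> list:
        return list(self.values.columns)


def nsaf(spectral_counts: Sequence, lengths: Sequence) -> np.ndarray:
    """Normalized spectral abundance factors for one state."""
    spc = np.asarray(spectral_counts, dtype=float)
    length = np.asarray(lengths, dtype=float)
    if np.any(length <= 0):
        raise ValueError("protein lengths must be positive")
    if np.any(spc < 0):
        raise ValueError("spectral counts must be non-negative")
    saf = spc / length
    total = saf.sum()
    if total == 0:
        raise ZeroDivisionError("no spectral counts in this state")
    return saf / total


def nsaf_matrix(counts: pd.DataFrame, lengths: Dict[str, int]) -> AbundanceMatrix:
    """Column-wise NSAF of an entity x state spectral-count table.

    States without any PSM are left all-zero and flagged rather than divided.
    """
    length = np.array([lengths[e] for e in counts.index], dtype=float)
    out = pd.DataFrame(0.0, index=counts.index, columns=counts.columns)
    flagged = []
    for state in counts.columns:
        col = counts[state].to_numpy(dtype=float)
        if col.sum() == 0:
            flagged.append(state)
            continue
        out[state] = nsaf(col, length)
    return AbundanceMatrix(out, KIND_NSAF, flagged_columns=tuple(flagged))


def fpkm(read_counts: Sequence, exon_lengths_bp: Sequence,
         total_mapped: float) -> np.ndarray:
    counts = np.asarray(read_counts, dtype=float)
    length = np.asarray(exon_lengths_bp, dtype=float)
    if np.any(length <= 0):
        raise ValueError("exon lengths must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped fragments must be positive")
    return counts * 1e9 / (length * total_mapped)


def fpkm_matrix(counts: pd.DataFrame, exon_lengths: Dict[str, int]) -> AbundanceMatrix:
    """Column-wise FPKM; per-state library size = column sum."""
    length = np.array([exon_lengths[e] for e in counts.index], dtype=float)
    out = pd.DataFrame(0.0, index=counts.index, columns=counts.columns)
    flagged = []
    for state in counts.columns:
        col = counts[state].to_numpy(dtype=float)
        total = col.sum()
        if total == 0:
            flagged.append(state)
            continue
        out[state] = fpkm(col, length, total)
    return AbundanceMatrix(out, KIND_FPKM, flagged_columns=tuple(flagged))


def zscore_rows(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Per-row (x - mean) / sd with sample sd (n-1); constant rows -> zeros."""
    df = matrix.values
    if df.shape[1] < 2:
        raise ValueError("Z-scoring needs at least two states")
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    constant = sd == 0
    safe_sd = sd.where(~constant, 1.0)
    z = df.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    return AbundanceMatrix(z, KIND_ZSCORE,
                           flagged_columns=matrix.flagged_columns,
                           flagged_rows=tuple(df.index[constant]))


@dataclass(frozen=True)
class StateSpecificityCall:
    entity_id: str
    specific_state: Optional[str]
    hi_threshold: float = 2.0
    lo_threshold: float = 0.0


def state_specific(z_matrix: AbundanceMatrix, hi: float = 2.0,
                   lo: float = 0.0) -> list:
    """Entities with z > hi in exactly one state and z < lo in all others."""
    calls = []
    for entity, row in z_matrix.values.iterrows():
        above = row[row > hi]
        below_ok = (row < lo).sum() == len(row) - 1
        if len(above) == 1 and below_ok:
            calls.append(StateSpecificityCall(entity, above.index[0], hi, lo))
        else:
            calls.append(StateSpecificityCall(entity, None, hi, lo))
    return calls


def pearson(x: Sequence, y: Sequence) -> Optional[float]:
    """Product-moment correlation; None for constant input (undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("pearson needs two equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y)[0])


def _log2_offset(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    # FPKM: conventional +1 offset; NSAF values are tiny, so use half the
    # smallest positive value to avoid swamping the signal
    if kind == KIND_NSAF:
        positive = df.to_numpy()
        positive = positive[positive > 0]
        offset = positive.min() / 2 if positive.size else 1.0
    else:
        offset = 1.0
    return np.log2(df + offset)


def correlate_omics(fpkm_m: AbundanceMatrix, nsaf_m: AbundanceMatrix,
                    state_pairing: Optional[Dict[str, str]] = None,
                    transform: str = "log2_offset",
                    min_shared: int = 3) -> Dict[str, Optional[float]]:
    """Per-state Pearson r between transcript and protein abundance.

    ``state_pairing`` maps proteome states to transcriptome states (identity
    by default).  Entities quantified in both layers (intersection of ids)
    enter the correlation; states with fewer than ``min_shared`` shared
    entities report None.
    """
    if state_pairing is None:
        shared_states = [s for s in nsaf_m.state_ids if s in set(fpkm_m.state_ids)]
        state_pairing = {s: s for s in shared_states}
    shared = fpkm_m.values.index.intersection(nsaf_m.values.index)
    f = fpkm_m.values.loc[shared]
    n = nsaf_m.values.loc[shared]
    if transform == "log2_offset":
        f = _log2_offset(f, fpkm_m.kind)
        n = _log2_offset(n, nsaf_m.kind)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    out = {}
    for prot_state, rna_state in state_pairing.items():
        if len(shared) < min_shared:
            out[prot_state] = None
            continue
        out[prot_state] = pearson(f[rna_state], n[prot_state])
    return out


def read_matrix_tsv(path, kind: str) -> AbundanceMatrix:
    return AbundanceMatrix(pd.read_csv(path, sep="\t", index_col=0), kind)


def write_matrix_tsv(path, matrix: AbundanceMatrix) -> None:
    matrix.values.to_csv(path, sep="\t")
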