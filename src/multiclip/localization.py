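"""mRNA localization from membrane/cytosol fractionation RNA-seq.

Counts are normalized by median-of-ratios size factors, membrane-to-cytosol
enrichment M is the log2 ratio of normalized means, and genes are called
membrane (M >= 1.5), cytosolic (M <= 0.5) or undefined in between, for all
genes with whole-cell TPM >= 10. Targeting-signal classes (signal peptide,
TM helix, tail-anchored, mtDNA, nuclear-encoded mitochondrial) are derived
from protein-level annotations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import (
    LocalizationClass,
    SignalKind,
    TargetingClass,
    TranscriptModel,
)


def size_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one per sample column).

    The reference is the per-gene geometric mean across samples, computed
    over genes with all-positive counts; each sample's factor is the median
    of its count/reference ratios.
    """
    if count_matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    counts = count_matrix.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with all-positive counts")
    kept = counts[positive]
    ref = np.exp(np.log(kept).mean(axis=1))
    factors = np.median(kept / ref[:, None], axis=0)
    return pd.Series(factors, index=count_matrix.columns, name="size_factor")


def normalized_counts(count_matrix: pd.DataFrame) -> pd.DataFrame:
    return count_matrix / size_factors(count_matrix)


def membrane_enrichment(
    count_matrix: pd.DataFrame,
    membrane_cols: list[str],
    cytosol_cols: list[str],
    pseudocount: float = 1.0,
    per_replicate: bool = False,
) -> pd.Series:
    """Per-gene log2 membrane-to-cytosol enrichment M.

    Counts are size-factor normalized over the whole matrix; M is the log2
    of the ratio of means (default) or the mean of per-replicate log2
    ratios, with ``pseudocount`` normalized counts added to both sides.
    """
    missing = [c for c in membrane_cols + cytosol_cols if c not in count_matrix]
    if missing:
        raise ValueError(f"columns missing from count matrix: {missing}")
    norm = normalized_counts(count_matrix)
    if per_replicate:
        if len(membrane_cols) != len(cytosol_cols):
            raise ValueError("per-replicate mode needs paired columns")
        ratios = [
            np.log2((norm[m] + pseudocount) / (norm[c] + pseudocount))
            for m, c in zip(membrane_cols, cytosol_cols)
        ]
        m = pd.concat(ratios, axis=1).mean(axis=1)
    else:
        m = np.log2(
            (norm[membrane_cols].mean(axis=1) + pseudocount)
            / (norm[cytosol_cols].mean(axis=1) + pseudocount)
        )
    m.name = "log2_membrane_enrichment"
    return m


def classify_localization(
    m: pd.Series,
    tpm: pd.Series,
    hi: float = 1.5,
    lo: float = 0.5,
    min_tpm: float = 10.0,
) -> pd.Series:
    """Localization class per gene from enrichment M and whole-cell TPM.

    Boundaries are inclusive: membrane iff M >= hi, cytosolic iff M <= lo;
    genes under the TPM floor are excluded regardless of M.
    """
    m, tpm = m.align(tpm, join="left")
    out = pd.Series(LocalizationClass.UNDEFINED.value, index=m.index, name="localization_class")
    out[m >= hi] = LocalizationClass.MEMBRANE.value
    out[m <= lo] = LocalizationClass.CYTOSOLIC.value
    out[tpm < min_tpm] = LocalizationClass.EXCLUDED.value
    return out


def classify_targeting(
    transcript: TranscriptModel,
    mito_genes: set[str] | None = None,
    tail_anchor_max_dist: int = 50,
) -> TargetingClass:
    """Targeting-signal class of one gene.

    Precedence: mtDNA-encoded ("MT-" gene prefix) > tail-anchored (TM but
    no signal peptide, first TM helix starting within ``tail_anchor_max_dist``
    aa of the C-terminus) > SP+TM > SP only > TM only > nuclear-encoded
    mitochondrial (from the provided list) > membrane-localized without a
    known signal > no signal.
    """
    mito_genes = mito_genes or set()
    sp = [s for s in transcript.signals if s.kind is SignalKind.SIGNAL_PEPTIDE]
    tm = sorted(
        (s for s in transcript.signals if s.kind is SignalKind.TM_HELIX),
        key=lambda s: s.aa_start,
    )
    plen = transcript.protein_length
    for s in transcript.signals:
        if s.aa_end > transcript.n_codons:
            raise ValueError(
                f"{transcript.transcript_id}: signal beyond protein length"
            )
    if transcript.is_mt or transcript.gene_id.startswith("MT-"):
        return TargetingClass.MTDNA
    if tm and not sp and plen - tm[0].aa_start <= tail_anchor_max_dist:
        return TargetingClass.TAIL_ANCHORED
    if sp and tm:
        return TargetingClass.SP_AND_TM
    if sp:
        return TargetingClass.SP_ONLY
    if tm:
        return TargetingClass.TM_ONLY
    if transcript.gene_id in mito_genes:
        return TargetingClass.MITO_NUCLEAR
    if transcript.localization_class is LocalizationClass.MEMBRANE:
        return TargetingClass.MEMBRANE_NO_TS
    return TargetingClass.NO_TS


def compute_tpm(counts: pd.Series, lengths: pd.Series) -> pd.Series:
    """Transcripts-per-million from counts and effective lengths.

    TPM_g = (counts_g / len_g) / sum(counts / len) * 1e6; sums to 1e6.
    """
    counts, lengths = counts.align(lengths, join="left")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts / lengths
    tpm = rate / rate.sum() * 1e6
    tpm.name = "tpm"
    return tpm
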