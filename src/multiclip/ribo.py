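"""P-site assignment, metagene profiles, codon occupancy, and TE contrast.

Ribosome footprints arrive as 5'-end positions in transcript coordinates;
a fixed 13-nt offset locates the P-site. Metagenes are scale-then-average:
each transcript's coverage is normalized to its own reference mean (trimmed
CDS mean for start/stop profiles, codons 20-40 for targeting-signal
profiles) before positional averaging, so highly expressed transcripts do
not dominate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .localization import size_factors
from .models import SignalKind, TranscriptModel, spell_rna

logger = logging.getLogger("multiclip")

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: the 61 sense codons, alphabetical, RNA spelling — fixed output order
SENSE_CODONS = sorted(
    spell_rna(a + b + c)
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


@dataclass
class FootprintProfile:
    """Per-nucleotide P-site coverage of one transcript in one sample."""

    transcript_id: str
    condition: str
    replicate: int
    psite_counts: np.ndarray
    len5utr: int = 0
    lencds: int = 0

    def codon_counts(self) -> np.ndarray:
        """P-site counts summed per CDS codon."""
        cds = self.psite_counts[self.len5utr : self.len5utr + self.lencds]
        return cds.reshape(-1, 3).sum(axis=1)


def apply_psite_offset(
    reads: pd.DataFrame,
    transcriptome: dict[str, TranscriptModel],
    offset: int = 13,
) -> tuple[list[FootprintProfile], int]:
    """Shift footprint 5' ends by the P-site offset and build profiles.

    Reads whose shifted position falls outside the transcript are dropped
    and counted; retained + dropped equals the input read total.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    profiles: dict[tuple[str, str, int], FootprintProfile] = {}
    dropped = 0
    for row in reads.itertuples(index=False):
        model = transcriptome[str(row.transcript_id)]
        pos = int(row.pos5p)
        if not 0 <= pos < model.length:
            raise ValueError(
                f"5' end {pos} outside transcript {model.transcript_id}"
            )
        count = int(row.count)
        psite = pos + offset
        if psite >= model.length:
            dropped += count
            continue
        key = (model.transcript_id, str(row.condition), int(row.replicate))
        prof = profiles.get(key)
        if prof is None:
            prof = FootprintProfile(
                transcript_id=model.transcript_id,
                condition=str(row.condition),
                replicate=int(row.replicate),
                psite_counts=np.zeros(model.length, dtype=np.int64),
                len5utr=model.len5utr,
                lencds=model.lencds,
            )
            profiles[key] = prof
        prof.psite_counts[psite] += count
    return list(profiles.values()), dropped


def rolling_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean with edge shrinkage (window truncated)."""
    return (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def _sum_by_transcript(profiles: list[FootprintProfile]) -> dict[str, FootprintProfile]:
    out: dict[str, FootprintProfile] = {}
    for p in profiles:
        acc = out.get(p.transcript_id)
        if acc is None:
            out[p.transcript_id] = FootprintProfile(
                p.transcript_id, "pooled", 0, p.psite_counts.copy(), p.len5utr, p.lencds
            )
        else:
            acc.psite_counts += p.psite_counts
    return out


def metagene_start_stop(
    profiles: list[FootprintProfile],
    min_codon_cov: float = 5.0,
    trim_codons: int = 2,
    roll: int = 10,
    span_start: tuple[int, int] = (-30, 120),
    span_stop: tuple[int, int] = (-120, 30),
) -> tuple[np.ndarray, np.ndarray]:
    """Mean scaled per-nt P-site profile around start and stop codons.

    Replicates are pooled per transcript. Transcripts with total codon
    coverage below ``min_codon_cov`` are excluded; the first and last
    ``trim_codons`` codons are left out of the scaling mean (initiation and
    termination peaks would mask the rest). Each transcript's coverage is
    divided by its trimmed-CDS per-nt mean, positionally averaged, then
    smoothed with a centered ``roll``-nt rolling mean.
    """
    pooled = _sum_by_transcript(profiles)
    start_len = span_start[1] - span_start[0]
    stop_len = span_stop[1] - span_stop[0]
    start_sum = np.zeros(start_len)
    start_n = np.zeros(start_len)
    stop_sum = np.zeros(stop_len)
    stop_n = np.zeros(stop_len)
    for prof in pooled.values():
        n_codons = prof.lencds // 3
        if n_codons <= 2 * trim_codons:
            raise ValueError(
                f"{prof.transcript_id}: CDS of {n_codons} codons shorter than "
                f"2 x trim ({trim_codons})"
            )
        codon_cov = prof.codon_counts()
        if codon_cov.sum() < min_codon_cov:
            continue
        trimmed = prof.psite_counts[
            prof.len5utr + 3 * trim_codons : prof.len5utr + prof.lencds - 3 * trim_codons
        ]
        mean = trimmed.mean()
        if mean <= 0:
            continue
        scaled = prof.psite_counts / mean
        cds_start = prof.len5utr
        cds_end = prof.len5utr + prof.lencds
        for i in range(start_len):
            pos = cds_start + span_start[0] + i
            if 0 <= pos < len(scaled):
                start_sum[i] += scaled[pos]
                start_n[i] += 1
        for i in range(stop_len):
            pos = cds_end + span_stop[0] + i
            if 0 <= pos < len(scaled):
                stop_sum[i] += scaled[pos]
                stop_n[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        start_prof = np.where(start_n > 0, start_sum / np.maximum(start_n, 1), np.nan)
        stop_prof = np.where(stop_n > 0, stop_sum / np.maximum(stop_n, 1), np.nan)
    return rolling_mean(start_prof, roll), rolling_mean(stop_prof, roll)


def metagene_targeting_signal(
    profiles: list[FootprintProfile],
    transcriptome: dict[str, TranscriptModel],
    tpm: dict[str, float] | None = None,
    norm_codons: tuple[int, int] = (20, 40),
    roll: int = 5,
    span: int = 500,
    min_tpm: float = 10.0,
    min_transcripts: int = 5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Scaled codon-level metagene for targeting-signal-bearing mRNAs.

    Includes transcripts with at least one signal peptide or TM helix (and
    TPM >= ``min_tpm`` when TPM is supplied). Codon coverage is normalized
    to the mean over codons ``norm_codons`` (1-based inclusive) of the same
    transcript; transcripts with zero coverage there are excluded and
    logged. Codons supported by fewer than ``min_transcripts`` transcripts
    are NaN — the far tail of the span is otherwise dominated by the few
    longest CDSs. Returns a long table (group, codon 1..span, mean scaled
    coverage after a ``roll``-codon rolling mean, n transcripts) plus the
    median signal-end codon per group, for annotating the pause position.
    """
    pooled = _sum_by_transcript(profiles)
    lo, hi = norm_codons
    groups: dict[str, list[np.ndarray]] = {}
    sig_ends: dict[str, list[int]] = {}
    n_excluded = 0
    for prof in pooled.values():
        model = transcriptome[prof.transcript_id]
        if not model.signals:
            continue
        if tpm is not None and tpm.get(model.gene_id, 0.0) < min_tpm:
            continue
        first = min(model.signals, key=lambda s: s.aa_start)
        group = "SP" if first.kind is SignalKind.SIGNAL_PEPTIDE else "TM"
        codon_cov = prof.codon_counts().astype(float)
        ref = codon_cov[lo - 1 : hi]
        if len(ref) == 0 or ref.mean() <= 0:
            n_excluded += 1
            continue
        groups.setdefault(group, []).append(codon_cov / ref.mean())
        sig_ends.setdefault(group, []).append(first.aa_end)
    if n_excluded:
        logger.info(
            "metagene_targeting_signal: %d transcripts excluded "
            "(zero coverage in normalization window)",
            n_excluded,
        )
    rows = []
    medians: dict[str, float] = {}
    for group, vecs in groups.items():
        acc = np.zeros(span)
        n = np.zeros(span)
        for v in vecs:
            upto = min(span, len(v))
            acc[:upto] += v[:upto]
            n[:upto] += 1
        mean = np.where(n >= max(min_transcripts, 1), acc / np.maximum(n, 1), np.nan)
        smooth = rolling_mean(mean, roll)
        medians[group] = float(np.median(sig_ends[group]))
        for codon in range(span):
            rows.append(
                {
                    "group": group,
                    "codon": codon + 1,
                    "mean_scaled": float(smooth[codon]),
                    "n_transcripts": int(n[codon]),
                }
            )
    return (
        pd.DataFrame(rows, columns=["group", "codon", "mean_scaled", "n_transcripts"]),
        medians,
    )


def locate_pause(
    profile: np.ndarray, baseline: float | None = None, search_from: int = 5
) -> int:
    """Onset codon (1-based) of an elongation pause in a scaled metagene.

    The pause onset is the first codon where the profile reaches halfway
    between ``baseline`` (default: the profile median, since most codons
    sit at baseline) and the profile maximum; half-rise is robust to the
    plateau shape of a multi-codon pause, unlike the argmax.
    """
    prof = np.asarray(profile, dtype=float)
    finite = np.isfinite(prof)
    if baseline is None:
        baseline = float(np.nanmedian(prof[search_from:]))
    peak = np.nanmax(prof[search_from:]) if finite[search_from:].any() else baseline
    thresh = baseline + 0.5 * (peak - baseline)
    for i in range(search_from, len(prof)):
        if finite[i] and prof[i] >= thresh:
            return i + 1
    return int(np.nanargmax(prof)) + 1


def codon_occupancy_shift(
    profiles_wt: list[FootprintProfile],
    profiles_ko: list[FootprintProfile],
    transcriptome: dict[str, TranscriptModel],
    site: str = "P",
) -> pd.DataFrame:
    """Footprint-weighted codon frequency shift between conditions.

    Per replicate, the frequency of each sense codon is the fraction of
    P-site (or E-site: one codon 5' of the P-site) footprints whose codon
    has that identity; stop codons are excluded and frequencies renormalized
    to 1. ``delta`` is mean(KO) - mean(WT) per codon (sums to 0 exactly)
    and ``delta_sd`` the SD over replicate pairs.
    """
    if site not in {"P", "E"}:
        raise ValueError("site must be 'P' or 'E'")
    shift = 0 if site == "P" else -1

    def _freqs(profiles: list[FootprintProfile]) -> dict[int, pd.Series]:
        by_rep: dict[int, dict[str, float]] = {}
        for prof in profiles:
            model = transcriptome[prof.transcript_id]
            counts = prof.codon_counts()
            acc = by_rep.setdefault(prof.replicate, {})
            for i, c in enumerate(counts):
                if c == 0:
                    continue
                j = i + shift
                if j < 0 or j >= model.n_codons:
                    continue
                codon = spell_rna(model.codon(j))
                if codon.replace("U", "T") in STOP_CODONS:
                    continue
                acc[codon] = acc.get(codon, 0.0) + float(c)
        out = {}
        for rep, acc in by_rep.items():
            s = pd.Series(acc).reindex(SENSE_CODONS).fillna(0.0)
            total = s.sum()
            if total <= 0:
                raise ValueError(f"replicate {rep}: no sense-codon footprints")
            out[rep] = s / total
        return out

    fwt = _freqs(profiles_wt)
    fko = _freqs(profiles_ko)
    if sorted(fwt) != sorted(fko):
        raise ValueError("replicate sets differ between conditions")
    reps = sorted(fwt)
    deltas = pd.DataFrame({r: fko[r] - fwt[r] for r in reps})
    out = pd.DataFrame(
        {
            "codon": SENSE_CODONS,
            "freq_wt": pd.DataFrame(fwt).mean(axis=1).to_numpy(),
            "freq_ko": pd.DataFrame(fko).mean(axis=1).to_numpy(),
            "delta": deltas.mean(axis=1).to_numpy(),
            "delta_sd": deltas.std(axis=1, ddof=1 if len(reps) > 1 else 0).to_numpy(),
        }
    )
    return out


def translation_efficiency(
    rpf_counts: pd.DataFrame,
    rna_counts: pd.DataFrame,
    conditions: dict[str, str],
    ko: str = "KO",
    wt: str = "WT",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2 translation-efficiency change KO vs WT per gene.

    RPF and RNA matrices are size-factor normalized separately; the result
    is log2(((RPF_KO + pc)/(RNA_KO + pc)) / ((RPF_WT + pc)/(RNA_WT + pc)))
    on condition means of normalized counts. Antisymmetric under swapping
    the two conditions.
    """
    if not rpf_counts.index.equals(rna_counts.index):
        missing = rpf_counts.index.symmetric_difference(rna_counts.index)
        raise ValueError(f"genes missing from one matrix: {list(missing)[:5]}")
    rpf = rpf_counts / size_factors(rpf_counts)
    rna = rna_counts / size_factors(rna_counts)

    def _cond_mean(norm: pd.DataFrame, cond: str) -> pd.Series:
        cols = [c for c in norm.columns if conditions.get(c) == cond]
        if not cols:
            raise ValueError(f"no columns for condition {cond!r}")
        return norm[cols].mean(axis=1)

    te = np.log2(
        ((_cond_mean(rpf, ko) + pseudocount) / (_cond_mean(rna, ko) + pseudocount))
        / ((_cond_mean(rpf, wt) + pseudocount) / (_cond_mean(rna, wt) + pseudocount))
    )
    return pd.DataFrame({"gene_id": te.index, "log2_te_change": te.to_numpy()})
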