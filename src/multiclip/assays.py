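"""tRNA crosslink enrichment, BioID filtering, pSILAC hygiene, RIP-qPCR.

tRNA enrichment divides library-normalized T-C transition counts by
library-normalized abundance reads per tRNA, after masking modified-uridine
positions (dihydrouridine causes reverse-transcription misincorporation
that mimics crosslink signal). BioID enrichment requires per-replicate
Dox/noDox LFQ ratios with the study's asymmetric replicate pairing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("multiclip")

#: Dox replicate -> noDox replicate pairing (three Dox batches but only two
#: untreated batches; Dox batch 1 is divided by untreated batch 2).
BIOID_PAIRING = {1: 2, 2: 2, 3: 3}


def trna_enrichment(
    trna_pileups: pd.DataFrame,
    abundance_reads: pd.DataFrame,
    masks: dict[str, set[int]],
    clip_library_total: float | None = None,
    rna_library_total: float | None = None,
) -> pd.DataFrame:
    """Crosslink enrichment per tRNA with modification masking.

    ``trna_pileups`` has columns trna_id/position/coverage/tc;
    ``abundance_reads`` has trna_id/reads from total-RNA sequencing.
    Masked positions are excluded *before* summation. Enrichment is
    (tc * 1e6 / clip_total) / (reads * 1e6 / rna_total), descending rank,
    ties broken by id.
    """
    known = set(abundance_reads["trna_id"].astype(str))
    unknown = set(trna_pileups["trna_id"].astype(str)) - known
    if unknown:
        raise ValueError(f"tRNAs in pileups absent from reference: {sorted(unknown)}")
    if clip_library_total is None:
        clip_library_total = float(trna_pileups["tc"].sum())
    if rna_library_total is None:
        rna_library_total = float(abundance_reads["reads"].sum())
    masked = trna_pileups.copy()
    masked["masked"] = [
        int(p) in masks.get(str(t), set())
        for t, p in zip(masked["trna_id"], masked["position"])
    ]
    kept = masked[~masked["masked"]]
    tc_sum = kept.groupby("trna_id")["tc"].sum()
    rows = []
    for row in abundance_reads.itertuples(index=False):
        tid = str(row.trna_id)
        tc_norm = float(tc_sum.get(tid, 0.0)) * 1e6 / clip_library_total
        abundance_norm = float(row.reads) * 1e6 / rna_library_total
        rows.append(
            {
                "trna_id": tid,
                "tc_norm": tc_norm,
                "abundance_norm": abundance_norm,
                "enrichment": tc_norm / abundance_norm if abundance_norm > 0 else np.nan,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["enrichment", "trna_id"], ascending=[False, True], kind="stable"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def trna_specificity(trna_pileups: pd.DataFrame) -> pd.DataFrame:
    """Per-position transition specificity (tc / coverage) per tRNA."""
    out = trna_pileups.copy()
    out["specificity"] = np.where(
        out["coverage"] > 0, out["tc"] / out["coverage"], np.nan
    )
    return out


def bioid_filter(
    quant: pd.DataFrame,
    min_enrich: float = 3.0,
    min_log2_lfq: float = 27.0,
    min_peptides: int = 3,
    pairing: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Enriched-protein calls from a BioID LFQ table.

    Expects columns ``protein_group``, ``razor_unique_peptides``,
    ``lfq_dox_1..3`` and ``lfq_nodox_2..3``. A protein is enriched when in
    every one of the three replicate pairs either LFQ(Dox)/LFQ(noDox) >=
    ``min_enrich`` with log2 LFQ(Dox) >= ``min_log2_lfq``, or LFQ(noDox)
    is zero and log2 LFQ(Dox) >= ``min_log2_lfq``; plus at least
    ``min_peptides`` razor unique peptides. Ranking is by mean Dox LFQ.
    ``display_enrichment`` is the mean log2 enrichment, replaced for
    zero-denominator proteins by the table maximum plus 2.
    """
    pairing = pairing or BIOID_PAIRING
    needed = {"protein_group", "razor_unique_peptides"} | {
        f"lfq_dox_{d}" for d in pairing
    } | {f"lfq_nodox_{n}" for n in pairing.values()}
    missing = needed - set(quant.columns)
    if missing:
        raise ValueError(f"missing replicate columns: {sorted(missing)}")
    quant = quant.copy()
    rep_pass = []
    rep_log2_enrich = []
    any_zero_den = np.zeros(len(quant), dtype=bool)
    for dox, nodox in pairing.items():
        num = quant[f"lfq_dox_{dox}"].to_numpy(dtype=float)
        den = quant[f"lfq_nodox_{nodox}"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den > 0, num / den, np.nan)
            log2_num = np.where(num > 0, np.log2(np.maximum(num, 1e-300)), -np.inf)
        zero_den = den == 0
        any_zero_den |= zero_den
        passes = np.where(
            zero_den,
            log2_num >= min_log2_lfq,
            (ratio >= min_enrich) & (log2_num >= min_log2_lfq),
        )
        rep_pass.append(passes)
        rep_log2_enrich.append(np.where(zero_den, np.nan, np.log2(np.maximum(ratio, 1e-300))))
    quant["enriched"] = (
        np.all(rep_pass, axis=0)
        & (quant["razor_unique_peptides"].to_numpy() >= min_peptides)
    )
    quant["mean_lfq_dox"] = quant[[f"lfq_dox_{d}" for d in pairing]].mean(axis=1)
    stacked = np.vstack(rep_log2_enrich)
    all_nan = np.isnan(stacked).all(axis=0)
    mean_log2 = np.full(stacked.shape[1], np.nan)
    mean_log2[~all_nan] = np.nanmean(stacked[:, ~all_nan], axis=0)
    finite = np.isfinite(mean_log2) & ~any_zero_den
    ceiling = np.nanmax(mean_log2[finite]) + 2.0 if finite.any() else 2.0
    quant["display_enrichment"] = np.where(any_zero_den, ceiling, mean_log2)
    out = quant[quant["enriched"]].sort_values(
        ["mean_lfq_dox", "protein_group"], ascending=[False, True], kind="stable"
    )
    out = out.reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def psilac_aggregate(
    pairs: pd.DataFrame, invert_reverse: bool = True
) -> pd.DataFrame:
    """Per-protein mean log2 KO/WT ratio from pulsed-SILAC pairs.

    ``pairs`` columns: protein, log2_ratio_hm (heavy/medium as measured),
    orientation ('forward': heavy = KO; 'reverse': labels switched),
    requant_num, requant_den (booleans). Pairs quantified from two
    requantified intensities are dropped; reverse ratios are negated onto
    the KO/WT scale; proteins need at least one value in both orientations.
    """
    valid = {"forward", "reverse"}
    bad = set(pairs["orientation"].astype(str)) - valid
    if bad:
        raise ValueError(f"unknown orientation labels: {sorted(bad)}")
    kept = pairs[~(pairs["requant_num"].astype(bool) & pairs["requant_den"].astype(bool))].copy()
    sign = np.where(
        (kept["orientation"] == "reverse") & invert_reverse, -1.0, 1.0
    )
    kept["log2_ko_wt"] = kept["log2_ratio_hm"].to_numpy(dtype=float) * sign
    have_both = (
        kept.groupby("protein")["orientation"].nunique().loc[lambda s: s == 2].index
    )
    kept = kept[kept["protein"].isin(have_both)]
    out = (
        kept.groupby("protein")["log2_ko_wt"]
        .mean()
        .rename("mean_log2_ko_wt")
        .reset_index()
    )
    return out


def rip_fold_enrichment(
    ct_flag: float, ct_igg: float, control_minus_bait: bool = True
) -> float:
    """qPCR fold enrichment of bait IP over IgG control.

    With Ct semantics (lower Ct = more template), enrichment over control is
    2**(Ct_IgG - Ct_bait) >= 1 for bait-bound RNAs; the flag flips to the
    literal bait-minus-control exponent.
    """
    if not (np.isfinite(ct_flag) and np.isfinite(ct_igg)):
        raise ValueError("Ct values must be finite")
    exponent = ct_igg - ct_flag if control_minus_bait else ct_flag - ct_igg
    return float(2.0**exponent)
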