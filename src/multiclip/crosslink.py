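"""Reproducible crosslink sites, clusters, and per-gene summaries.

PAR-CLIP marks protein-RNA crosslinks as T-C transitions in aligned reads.
This module consumes per-position pileup tables (coverage + T-C counts)
and per-replicate cluster tables, applies the reproducibility and
specificity filters, normalizes for library size, and aggregates per gene
and into meta-transcript profiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .models import Region, TranscriptModel

logger = logging.getLogger("multiclip")


def filter_reproducible_clusters(
    clusters_rep1: pd.DataFrame,
    clusters_rep2: pd.DataFrame,
    min_overlap: float = 0.5,
    max_peak_dist: int = 10,
    min_mean_tc: float = 3.0,
    reciprocal: bool = True,
    kept_coords: str = "rep1",
) -> pd.DataFrame:
    """Keep clusters supported by both biological replicates.

    A replicate-1 cluster is kept when some replicate-2 cluster on the same
    transcript (i) overlaps it by at least ``min_overlap`` of the cluster
    length (reciprocally by default: of *both* lengths), (ii) has its
    maximum-T-C position no more than ``max_peak_dist`` nt away, and
    (iii) the pair's mean T-C sum is at least ``min_mean_tc``. The kept
    cluster carries replicate-1 coordinates (or the union, per
    ``kept_coords``) and ``mean_tc`` of the best-supporting pair
    (highest mean T-C, ties to the earlier replicate-2 cluster).
    """
    for df in (clusters_rep1, clusters_rep2):
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("malformed cluster interval (start >= end)")
    if kept_coords not in {"rep1", "union"}:
        raise ValueError(f"kept_coords must be 'rep1' or 'union', got {kept_coords!r}")
    out_rows = []
    rep2_by_tx = {
        str(t): g.sort_values("start", kind="stable")
        for t, g in clusters_rep2.groupby("transcript_id", sort=False)
    }
    for row in clusters_rep1.itertuples(index=False):
        cand = rep2_by_tx.get(str(row.transcript_id))
        if cand is None:
            continue
        best = None
        for other in cand.itertuples(index=False):
            if other.start >= row.end:
                break
            ov = min(row.end, other.end) - max(row.start, other.start)
            if ov <= 0:
                continue
            len1 = row.end - row.start
            len2 = other.end - other.start
            if reciprocal:
                ok = ov >= min_overlap * len1 and ov >= min_overlap * len2
            else:
                ok = ov >= min_overlap * len1 or ov >= min_overlap * len2
            if not ok:
                continue
            if abs(int(row.max_tc_pos) - int(other.max_tc_pos)) > max_peak_dist:
                continue
            mean_tc = (float(row.tc_sum) + float(other.tc_sum)) / 2.0
            if mean_tc < min_mean_tc:
                continue
            if best is None or mean_tc > best[0]:
                best = (mean_tc, other)
        if best is not None:
            mean_tc, other = best
            start, end = int(row.start), int(row.end)
            if kept_coords == "union":
                start, end = min(start, int(other.start)), max(end, int(other.end))
            out_rows.append(
                {
                    "transcript_id": str(row.transcript_id),
                    "start": start,
                    "end": end,
                    "tc_sum": float(row.tc_sum),
                    "max_tc_pos": int(row.max_tc_pos),
                    "mean_tc": mean_tc,
                }
            )
    return pd.DataFrame(
        out_rows,
        columns=["transcript_id", "start", "end", "tc_sum", "max_tc_pos", "mean_tc"],
    )


def filter_sites(
    pileups_rep1: pd.DataFrame,
    pileups_rep2: pd.DataFrame,
    transcriptome: dict[str, TranscriptModel],
    max_specificity: float = 0.95,
) -> pd.DataFrame:
    """Reproducible T-C positions present in both replicates.

    Positions must have a T-C count > 0 in both replicates and a transition
    specificity (T-C count / coverage) below ``max_specificity`` in both —
    near-1 specificity flags a genomic variant, not a crosslink. Returns
    one row per kept position with per-replicate counts, coverages,
    specificities and the region label.
    """
    for df in (pileups_rep1, pileups_rep2):
        bad = (df["coverage"] <= 0) & (df["tc"] > 0)
        if bad.any():
            raise ValueError("pileup with tc > 0 but coverage 0")
    merged = pileups_rep1.merge(
        pileups_rep2,
        on=["transcript_id", "position"],
        suffixes=("_rep1", "_rep2"),
        how="inner",
    )
    merged = merged[(merged["tc_rep1"] > 0) & (merged["tc_rep2"] > 0)].copy()
    merged["specificity_rep1"] = merged["tc_rep1"] / merged["coverage_rep1"]
    merged["specificity_rep2"] = merged["tc_rep2"] / merged["coverage_rep2"]
    merged = merged[
        (merged["specificity_rep1"] < max_specificity)
        & (merged["specificity_rep2"] < max_specificity)
    ].copy()
    merged["region"] = [
        transcriptome[str(t)].region_of(int(p)).value
        for t, p in zip(merged["transcript_id"], merged["position"])
    ]
    merged["tc"] = (merged["tc_rep1"] + merged["tc_rep2"]) / 2.0
    return merged.reset_index(drop=True)


def normalize_tc_per_million(
    sites: pd.DataFrame, library_totals: dict[str, float] | None = None
) -> pd.DataFrame:
    """Attach library-size-normalized T-C (per million) per replicate.

    ``library_totals`` maps replicate name ("rep1", "rep2") to the library
    total; by default the total T-C events of each replicate in ``sites``.
    Adds ``tcpm_rep1``, ``tcpm_rep2`` and their mean ``tcpm``.
    """
    sites = sites.copy()
    reps = [c.removeprefix("tc_") for c in sites.columns if c.startswith("tc_rep")]
    if library_totals is None:
        library_totals = {r: float(sites[f"tc_{r}"].sum()) for r in reps}
    for r in reps:
        total = library_totals[r]
        if total <= 0:
            raise ValueError(f"library total for {r} must be positive")
        sites[f"tcpm_{r}"] = sites[f"tc_{r}"] * 1e6 / total
    sites["tcpm"] = sites[[f"tcpm_{r}" for r in reps]].mean(axis=1)
    return sites


def assign_crosslink_group(
    stat: pd.Series, low: float = 0.3, high: float = 1.39
) -> pd.Series:
    """Three-way grouping of a gene-level crosslink statistic."""
    return pd.cut(
        stat,
        bins=[-np.inf, low, high, np.inf],
        labels=["low", "mid", "high"],
    ).astype(str)


def summarize_gene_crosslinks(
    sites: pd.DataFrame,
    transcriptome: dict[str, TranscriptModel],
    tpm: dict[str, float],
    group_thresholds: tuple[float, float] = (0.3, 1.39),
    ratio_pseudocount: float = 0.5,
    group_pseudocount: float = 0.5,
    tc_col: str = "tc",
) -> pd.DataFrame:
    """Per-gene crosslink totals, enrichment, and CDS/3'UTR ratio.

    ``tc_total`` splits exactly into the three region sums. The enrichment
    E = tc_total / TPM corrects for expression-level bias; the grouping
    statistic is log2(E + pseudocount) cut at ``group_thresholds``. The
    length-normalized CDS vs 3'UTR ratio R is reported as log2 with a
    pseudocount on both region sums; genes without a 3'UTR get NaN.
    """
    region_cols = {Region.UTR5: "tc_5utr", Region.CDS: "tc_cds", Region.UTR3: "tc_3utr"}
    by_gene: dict[str, dict[str, float]] = {}
    for row in sites.itertuples(index=False):
        model = transcriptome[str(row.transcript_id)]
        region = model.region_of(int(row.position))
        acc = by_gene.setdefault(
            model.gene_id, {"tc_5utr": 0.0, "tc_cds": 0.0, "tc_3utr": 0.0}
        )
        acc[region_cols[region]] += float(getattr(row, tc_col))
    rows = []
    for model in transcriptome.values():
        acc = by_gene.get(model.gene_id)
        if acc is None:
            continue
        tc_total = acc["tc_5utr"] + acc["tc_cds"] + acc["tc_3utr"]
        gene_tpm = tpm.get(model.gene_id, 0.0)
        enrichment = tc_total / gene_tpm if gene_tpm > 0 else np.nan
        if model.len3utr > 0 and model.lencds > 0:
            ratio = np.log2(
                ((acc["tc_cds"] + ratio_pseudocount) / model.lencds)
                / ((acc["tc_3utr"] + ratio_pseudocount) / model.len3utr)
            )
        else:
            ratio = np.nan
        rows.append(
            {
                "gene_id": model.gene_id,
                "transcript_id": model.transcript_id,
                "localization_class": model.localization_class.value,
                "tc_total": tc_total,
                "tc_5utr": acc["tc_5utr"],
                "tc_cds": acc["tc_cds"],
                "tc_3utr": acc["tc_3utr"],
                "tpm_wholecell": gene_tpm,
                "enrichment": enrichment,
                "log2_cds_utr3_ratio": ratio,
            }
        )
    summary = pd.DataFrame(rows)
    if len(summary):
        stat = np.log2(summary["enrichment"].fillna(0.0) + group_pseudocount)
        summary["group_stat"] = stat
        summary["crosslink_group"] = assign_crosslink_group(stat, *group_thresholds)
    return summary


def meta_transcript_profile(
    sites: pd.DataFrame,
    transcriptome: dict[str, TranscriptModel],
    min_tcpm: float = 5.0,
    bins_per_region: dict[Region, int] | None = None,
    per_nucleotide: bool = False,
) -> pd.DataFrame:
    """Mean scaled T-C profile over 5'UTR, CDS and 3'UTR.

    Transcripts whose total T-C per million is below ``min_tcpm`` in either
    replicate are excluded. Within each included transcript, per-site T-C
    per million values are scaled to the transcript maximum (so the maximum
    is exactly 1); sites are mapped to fixed relative bins per region
    (default 100/300/200) and each transcript contributes its per-bin
    maximum, zero where it has no site. The profile is the mean over
    transcripts per bin. ``per_nucleotide`` uses one bin per nucleotide of
    relative position instead (grid = max region length).
    """
    if bins_per_region is None:
        bins_per_region = {Region.UTR5: 100, Region.CDS: 300, Region.UTR3: 200}
    needed = {"tcpm_rep1", "tcpm_rep2", "tcpm"}
    if not needed <= set(sites.columns):
        raise ValueError("sites must carry tcpm columns; run normalize_tc_per_million")

    profiles: dict[Region, list[np.ndarray]] = {r: [] for r in Region}
    n_included = 0
    for tid, group in sites.groupby("transcript_id", sort=False):
        if group["tcpm_rep1"].sum() < min_tcpm or group["tcpm_rep2"].sum() < min_tcpm:
            continue
        model = transcriptome[str(tid)]
        scale = group["tcpm"].max()
        if scale <= 0:
            continue
        n_included += 1
        scaled = group["tcpm"] / scale
        for region in Region:
            start, end = model.region_bounds(region)
            length = end - start
            if length == 0:
                continue
            nbins = length if per_nucleotide else bins_per_region[region]
            vec = np.zeros(nbins)
            sel = group[(group["position"] >= start) & (group["position"] < end)]
            for pos, val in zip(sel["position"], scaled[sel.index]):
                rel = (int(pos) - start) / length
                b = min(int(rel * nbins), nbins - 1)
                vec[b] = max(vec[b], float(val))
            profiles[region].append(vec)
    rows = []
    for region in Region:
        vecs = profiles[region]
        if not vecs:
            continue
        if per_nucleotide:
            width = max(len(v) for v in vecs)
            # relative-position grid: resample by bin index over common width
            acc = np.zeros(width)
            for v in vecs:
                idx = (np.arange(len(v)) * width / len(v)).astype(int)
                tmp = np.zeros(width)
                np.maximum.at(tmp, idx, v)
                acc += tmp
            mean = acc / len(vecs)
        else:
            mean = np.mean(np.stack(vecs), axis=0)
        for b, val in enumerate(mean):
            rows.append({"region": region.value, "bin": b, "mean_scaled_tc": float(val)})
    logger.info("meta-transcript profile over %d transcripts", n_included)
    return pd.DataFrame(rows, columns=["region", "bin", "mean_scaled_tc"])
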