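"""Independent brute-force reference implementations.

These are deliberately naive (all-pairs loops, explicit window scans,
row-by-row filters) and share no code with the package internals; tests
compare the package's outputs against them on random instances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_reproducible_clusters(rep1, rep2, min_overlap=0.5, max_peak_dist=10, min_mean_tc=3.0):
    """All-pairs cluster reproducibility filter; returns kept rep1 rows."""
    kept = []
    for _, a in rep1.iterrows():
        best = None
        for _, b in rep2.iterrows():
            if a["transcript_id"] != b["transcript_id"]:
                continue
            ov = min(a["end"], b["end"]) - max(a["start"], b["start"])
            if ov <= 0:
                continue
            if ov < min_overlap * (a["end"] - a["start"]):
                continue
            if ov < min_overlap * (b["end"] - b["start"]):
                continue
            if abs(int(a["max_tc_pos"]) - int(b["max_tc_pos"])) > max_peak_dist:
                continue
            mean_tc = (a["tc_sum"] + b["tc_sum"]) / 2
            if mean_tc < min_mean_tc:
                continue
            if best is None or mean_tc > best:
                best = mean_tc
        if best is not None:
            kept.append(
                (a["transcript_id"], int(a["start"]), int(a["end"]), float(best))
            )
    return kept


def brute_crosslinked_kmer_counts(sites, sequences, k):
    """Enumerate every k-window overlapping each crosslink position."""
    counts = {}
    for _, row in sites.iterrows():
        seq = sequences[row["transcript_id"]]
        p = int(row["position"])
        for s in range(len(seq) - k + 1):
            if s <= p <= s + k - 1:
                kmer = seq[s : s + k]
                counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def brute_multivalency_score(seq, pos, group, half_window=40, exclusion=4):
    """Scan every start position of the sequence explicitly."""
    w = len(next(iter(group)))
    score = 0
    for s in range(len(seq) - w + 1):
        if seq[s : s + w] not in group:
            continue
        if s < pos - half_window or s > pos + half_window:
            continue
        if pos - exclusion < s < pos + exclusion:
            continue
        score += 1
    return score


def brute_window_tc(positions, tcs, pos, half_window=40, exclusion=4):
    total = 0.0
    for q, tc in zip(positions, tcs):
        d = q - pos
        if -half_window <= d <= half_window and abs(d) >= exclusion:
            total += tc
    return total


def brute_sliding_window_mean(seq, group, window=30, min_count=3):
    """Per-window occurrence counts with explicit scans; mean of kept."""
    w = len(next(iter(group)))
    kept = []
    for start in range(len(seq) - window + 1):
        n = 0
        for s in range(start, start + window):
            if seq[s : s + w] in group:
                n += 1
        if n >= min_count:
            kept.append(n)
    return float(np.mean(kept)) if kept else 0.0


def brute_bioid_filter(quant, min_enrich=3.0, min_log2_lfq=27.0, min_peptides=3):
    """Row-by-row BioID filter with the Dox->noDox pairing 1->2, 2->2, 3->3."""
    enriched = []
    for _, row in quant.iterrows():
        if row["razor_unique_peptides"] < min_peptides:
            continue
        ok = True
        for dox, nodox in ((1, 2), (2, 2), (3, 3)):
            num, den = row[f"lfq_dox_{dox}"], row[f"lfq_nodox_{nodox}"]
            if num <= 0:
                ok = False
                break
            if den == 0:
                if np.log2(num) < min_log2_lfq:
                    ok = False
                    break
            elif num / den < min_enrich or np.log2(num) < min_log2_lfq:
                ok = False
                break
        if ok:
            enriched.append(row["protein_group"])
    return set(enriched)


def brute_meta_profile(site_rows, models, min_tcpm, bins):
    """Scale-to-max then per-bin-max then mean, fully explicit.

    ``site_rows``: DataFrame with transcript_id, position, tcpm_rep1,
    tcpm_rep2, tcpm. ``bins``: dict region name -> bin count.
    Returns dict region -> mean vector.
    """
    per_region_vecs = {r: [] for r in bins}
    for tid in site_rows["transcript_id"].unique():
        grp = site_rows[site_rows["transcript_id"] == tid]
        if grp["tcpm_rep1"].sum() < min_tcpm or grp["tcpm_rep2"].sum() < min_tcpm:
            continue
        model = models[tid]
        mx = grp["tcpm"].max()
        if mx <= 0:
            continue
        bounds = {
            "utr5": (0, model.len5utr),
            "cds": (model.len5utr, model.len5utr + model.lencds),
            "utr3": (model.len5utr + model.lencds, model.length),
        }
        for region, nb in bins.items():
            start, end = bounds[region]
            if end == start:
                continue
            vec = np.zeros(nb)
            for _, row in grp.iterrows():
                p = int(row["position"])
                if start <= p < end:
                    b = min(int((p - start) / (end - start) * nb), nb - 1)
                    vec[b] = max(vec[b], row["tcpm"] / mx)
            per_region_vecs[region].append(vec)
    return {
        r: (np.mean(v, axis=0) if v else None) for r, v in per_region_vecs.items()
    }


def brute_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios from the textbook formula."""
    keep = [g for g in range(counts.shape[0]) if (counts[g] > 0).all()]
    ref = [np.prod(counts[g].astype(float)) ** (1 / counts.shape[1]) for g in keep]
    factors = []
    for s in range(counts.shape[1]):
        ratios = [counts[g, s] / r for g, r in zip(keep, ref)]
        factors.append(np.median(ratios))
    return np.array(factors)


def brute_start_metagene(profiles_by_tx, span, trim_codons=2, min_cov=5.0):
    """Scale-then-average around the CDS start, explicit loops.

    ``profiles_by_tx``: dict tid -> (counts array, len5utr, lencds).
    Returns the un-smoothed positional mean (NaN where no transcript).
    """
    lo, hi = span
    sums = np.zeros(hi - lo)
    ns = np.zeros(hi - lo)
    for counts, len5, lencds in profiles_by_tx.values():
        codons = [
            counts[len5 + 3 * i : len5 + 3 * i + 3].sum() for i in range(lencds // 3)
        ]
        if sum(codons) < min_cov:
            continue
        trimmed = counts[len5 + 3 * trim_codons : len5 + lencds - 3 * trim_codons]
        mean = trimmed.mean()
        if mean <= 0:
            continue
        for i in range(hi - lo):
            pos = len5 + lo + i
            if 0 <= pos < len(counts):
                sums[i] += counts[pos] / mean
                ns[i] += 1
    out = np.full(hi - lo, np.nan)
    out[ns > 0] = sums[ns > 0] / ns[ns > 0]
    return out
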