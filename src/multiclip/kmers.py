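"""Crosslinked k-mer counting, class-wise k-mer z-scores, multivalency.

The central quantity is the multivalency score of a crosslink site: the
number of occurrences of a small group of high-affinity four-mers within
+/-40 nt of the site, excluding the innermost +/-4 nt (which would be
dominated by the crosslinked four-mer itself). Multivalent windows are the
sequence signature of an RNA-binding protein contacting RNA through many
tandem domains simultaneously.

K-mers are handled in the run alphabet (default DNA) internally and spelled
in RNA in every output table.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .models import Region, TranscriptModel, normalize_alphabet, spell_rna

logger = logging.getLogger("multiclip")

K_MIN, K_MAX = 4, 12


def _check_k(k: int) -> None:
    if not K_MIN <= k <= K_MAX:
        raise ValueError(f"k must be in [{K_MIN}, {K_MAX}], got {k}")


def site_kmers(sequence: str, position: int, k: int, mode: str = "overlap") -> list[str]:
    """k-mers of ``sequence`` attributed to a crosslink at ``position``.

    ``overlap`` counts every k-window covering the crosslinked nucleotide
    (up to k windows, truncated at transcript ends); ``anchored`` counts
    only the window starting at the position.
    """
    n = len(sequence)
    if mode == "anchored":
        starts = [position] if position + k <= n else []
    elif mode == "overlap":
        starts = range(max(0, position - k + 1), min(position, n - k) + 1)
    else:
        raise ValueError(f"unknown k-mer counting mode {mode!r}")
    return [sequence[s : s + k] for s in starts]


def count_crosslinked_kmers(
    sites: pd.DataFrame,
    transcriptome: dict[str, TranscriptModel],
    k: int = 4,
    mode: str = "overlap",
) -> pd.DataFrame:
    """Count and rank k-mers at crosslink positions.

    Returns one row per observed k-mer with columns ``kmer`` (RNA
    spelling), ``count``, ``frequency`` (sums to 1) and ``rank`` (1 =
    most frequent; ties broken lexicographically).
    """
    _check_k(k)
    counts: dict[str, int] = {}
    for tid, group in sites.groupby("transcript_id", sort=False):
        seq = transcriptome[str(tid)].sequence
        for pos in group["position"].to_numpy():
            for kmer in site_kmers(seq, int(pos), k, mode):
                counts[kmer] = counts.get(kmer, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["kmer", "count", "frequency", "rank"])
    df = pd.DataFrame(
        {"kmer": [spell_rna(s) for s in counts], "count": list(counts.values())}
    )
    total = df["count"].sum()
    df["frequency"] = df["count"] / total
    df = df.sort_values(["count", "kmer"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def count_crosslinked_kmers_grouped(
    sites: pd.DataFrame,
    transcriptome: dict[str, TranscriptModel],
    k: int = 4,
    mode: str = "overlap",
) -> pd.DataFrame:
    """Per-(localization class, region) crosslinked k-mer tables.

    ``sites`` must carry a ``region`` column; the class is taken from the
    transcript model. Frequencies are normalized within each group.
    """
    frames = []
    sites = sites.copy()
    sites["_class"] = [
        transcriptome[t].localization_class.value for t in sites["transcript_id"]
    ]
    for (cls, region), grp in sites.groupby(["_class", "region"], sort=False):
        tab = count_crosslinked_kmers(grp, transcriptome, k, mode)
        tab.insert(0, "localization_class", cls)
        tab.insert(1, "region", region)
        frames.append(tab)
    if not frames:
        return pd.DataFrame(
            columns=["localization_class", "region", "kmer", "count", "frequency", "rank"]
        )
    return pd.concat(frames, ignore_index=True)


def kmer_crosslink_signal(
    sites: pd.DataFrame,
    transcriptome: dict[str, TranscriptModel],
    tpm: dict[str, float],
    k: int = 4,
    regions: tuple[Region, ...] = (Region.CDS, Region.UTR3),
    mode: str = "overlap",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression- and length-normalized per-gene crosslinked k-mer signal.

    For each gene and region, the T-C counts of sites are attributed to the
    k-mers overlapping them, summed, and divided by the region length and
    the gene's whole-cell TPM. Returns the long per-gene table and a
    ranking of k-mers by median log2 normalized signal across genes.
    """
    _check_k(k)
    rows: list[dict] = []
    for tid, group in sites.groupby("transcript_id", sort=False):
        model = transcriptome[str(tid)]
        gene_tpm = tpm.get(model.gene_id, 0.0)
        if gene_tpm <= 0:
            logger.warning("gene %s skipped: TPM is 0", model.gene_id)
            continue
        for region in regions:
            start, end = model.region_bounds(region)
            length = end - start
            if length == 0:
                continue
            in_region = group[
                (group["position"] >= start) & (group["position"] < end)
            ]
            sums: dict[str, float] = {}
            for pos, tc in zip(in_region["position"], in_region["tc"]):
                # a site's T-C counts once per distinct overlapping k-mer
                for kmer in set(site_kmers(model.sequence, int(pos), k, mode)):
                    sums[kmer] = sums.get(kmer, 0.0) + float(tc)
            for kmer, total in sums.items():
                rows.append(
                    {
                        "gene_id": model.gene_id,
                        "region": region.value,
                        "kmer": spell_rna(kmer),
                        "signal": total / length / gene_tpm,
                    }
                )
    table = pd.DataFrame(rows, columns=["gene_id", "region", "kmer", "signal"])
    if len(table):
        ranking = (
            table.assign(log2_signal=np.log2(table["signal"]))
            .groupby("kmer")["log2_signal"]
            .median()
            .rename("median_log2_signal")
            .reset_index()
            .sort_values(
                ["median_log2_signal", "kmer"], ascending=[False, True], kind="stable"
            )
            .reset_index(drop=True)
        )
        ranking["rank"] = np.arange(1, len(ranking) + 1)
    else:
        ranking = pd.DataFrame(columns=["kmer", "median_log2_signal", "rank"])
    return table, ranking


def _window_frequencies(seqs: list[str], k: int) -> tuple[dict[str, float], int]:
    counts: dict[str, int] = {}
    total = 0
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
            total += 1
    if total == 0:
        raise ValueError(f"no k-windows of length {k} in sequence set")
    return {s: c / total for s, c in counts.items()}, total


def kmer_class_zscores(
    seqs_a: list[str],
    seqs_b: list[str],
    k: int,
    top_bound_set: list[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Z-scores of k-mer frequency differences between two sequence sets.

    Frequencies come from all k-windows of each set; ``delta_f`` is
    f(A) - f(B) and z standardizes delta_f over the k-mers observed in
    either set. When ``top_bound_set`` is given (e.g. the 40 most
    crosslinked k-mers) the z-score distributions of that group vs all
    other k-mers are compared with a two-sided rank-sum test; the p-value
    is returned alongside the table (NaN without a top set).
    """
    _check_k(k)
    if not seqs_a or not seqs_b:
        raise ValueError("both sequence sets must be non-empty")
    fa, _ = _window_frequencies(seqs_a, k)
    fb, _ = _window_frequencies(seqs_b, k)
    kmers = sorted(set(fa) | set(fb))
    delta = np.array([fa.get(s, 0.0) - fb.get(s, 0.0) for s in kmers])
    sd = delta.std(ddof=0)
    z = (delta - delta.mean()) / sd if sd > 0 else np.zeros_like(delta)
    df = pd.DataFrame(
        {
            "kmer": [spell_rna(s) for s in kmers],
            "f_a": [fa.get(s, 0.0) for s in kmers],
            "f_b": [fb.get(s, 0.0) for s in kmers],
            "delta_f": delta,
            "z": z,
        }
    )
    pvalue = float("nan")
    if top_bound_set is not None:
        top = {spell_rna(normalize_alphabet(s)) for s in top_bound_set}
        df["in_top"] = df["kmer"].isin(top)
        if df["in_top"].any() and (~df["in_top"]).any():
            pvalue = float(
                stats.ranksums(df.loc[df["in_top"], "z"], df.loc[~df["in_top"], "z"]).pvalue
            )
    return df, pvalue


def occurrence_positions(sequence: str, group: list[str]) -> np.ndarray:
    """Sorted start positions of any group member in ``sequence``.

    Overlapping occurrences each count; no greedy masking.
    """
    members = {normalize_alphabet(m) for m in group}
    lengths = {len(m) for m in members}
    if len(lengths) != 1:
        raise ValueError("all group members must have equal length")
    (w,) = lengths
    return np.array(
        [i for i in range(len(sequence) - w + 1) if sequence[i : i + w] in members],
        dtype=np.int64,
    )


def multivalency_scores(
    sites: pd.DataFrame,
    transcriptome: dict[str, TranscriptModel],
    fourmer_group: list[str],
    half_window: int = 40,
    exclusion: int = 4,
    n_bins: int = 5,
    tc_col: str = "tcpm",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multivalency score, bin, window T-C and positional profile per site.

    For each anchor site, group-member occurrences whose start ``s``
    satisfies ``exclusion <= |s - pos| <= half_window`` are counted (the
    open innermost zone is excluded; offsets exactly +/-`exclusion` count).
    Anchors are quantile-binned into ``n_bins`` near-equal groups by score
    (bin 1 = lowest). ``window_tc`` sums the normalized T-C of other sites
    under the same window/exclusion geometry. The second return value holds
    per-bin positional T-C percentage profiles over the 2*half_window+1
    offsets (each row sums to 100 when any signal is present; the exclusion
    zone is zero by construction).
    """
    if not fourmer_group:
        raise ValueError("fourmer_group must be non-empty")
    records: list[dict] = []
    # per-anchor contribution vectors for positional profiles, filled later
    offsets_len = 2 * half_window + 1
    contribs: list[np.ndarray] = []
    for tid, group in sites.groupby("transcript_id", sort=False):
        model = transcriptome[str(tid)]
        occ = occurrence_positions(model.sequence, fourmer_group)
        positions = group["position"].to_numpy(dtype=np.int64)
        tc = group[tc_col].to_numpy(dtype=float)
        order = np.argsort(positions, kind="stable")
        positions_sorted = positions[order]
        tc_sorted = tc[order]
        for pos, site_tc in zip(positions, tc):
            lo, hi = pos - half_window, pos + half_window
            n_all = np.searchsorted(occ, hi, side="right") - np.searchsorted(
                occ, lo, side="left"
            )
            n_excl = np.searchsorted(occ, pos + exclusion, side="left") - np.searchsorted(
                occ, pos - exclusion, side="right"
            )
            score = int(n_all - n_excl)
            i0 = np.searchsorted(positions_sorted, lo, side="left")
            i1 = np.searchsorted(positions_sorted, hi, side="right")
            vec = np.zeros(offsets_len)
            wtc = 0.0
            for q, qtc in zip(positions_sorted[i0:i1], tc_sorted[i0:i1]):
                off = int(q - pos)
                if abs(off) < exclusion:
                    continue
                wtc += qtc
                vec[off + half_window] += qtc
            records.append(
                {
                    "transcript_id": str(tid),
                    "position": int(pos),
                    "score": score,
                    "window_tc": wtc,
                    "tc": float(site_tc),
                    "truncated": bool(pos - half_window < 0 or pos + half_window >= model.length),
                }
            )
            contribs.append(vec)
    rec = pd.DataFrame(
        records,
        columns=["transcript_id", "position", "score", "window_tc", "tc", "truncated"],
    )
    if not len(rec):
        return rec.assign(bin=pd.Series(dtype=int)), pd.DataFrame()
    # stable quantile binning: (score, transcript_id, position)
    order = rec.sort_values(
        ["score", "transcript_id", "position"], kind="stable"
    ).index.to_numpy()
    bins = np.empty(len(rec), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins), start=1):
        bins[chunk] = b
    rec["bin"] = bins
    mat = np.stack(contribs)
    prof_rows = []
    for b in range(1, n_bins + 1):
        total = mat[bins == b].sum(axis=0)
        s = total.sum()
        prof_rows.append(100.0 * total / s if s > 0 else total)
    profiles = pd.DataFrame(
        prof_rows,
        index=pd.Index(range(1, n_bins + 1), name="bin"),
        columns=[str(o) for o in range(-half_window, half_window + 1)],
    )
    return rec, profiles


def sliding_window_potential(
    transcriptome: dict[str, TranscriptModel],
    fourmer_group: list[str],
    window: int = 30,
    min_count: int = 3,
    regions: tuple[Region, ...] = (Region.CDS, Region.UTR3),
) -> pd.DataFrame:
    """Mean multivalency potential of region sequences.

    Slides a ``window``-nt window one nt at a time over each region
    sequence, counts group-member occurrences whose start lies inside the
    window, discards windows with fewer than ``min_count`` occurrences, and
    reports the per-transcript mean over kept windows (0 if none kept).
    """
    rows = []
    for model in transcriptome.values():
        for region in regions:
            seq = model.region_sequence(region)
            if len(seq) < window:
                continue
            occ = occurrence_positions(seq, fourmer_group)
            ind = np.zeros(len(seq), dtype=np.int64)
            ind[occ] = 1
            counts = np.convolve(ind, np.ones(window, dtype=np.int64), mode="valid")
            kept = counts[counts >= min_count]
            rows.append(
                {
                    "transcript_id": model.transcript_id,
                    "gene_id": model.gene_id,
                    "localization_class": model.localization_class.value,
                    "region": region.value,
                    "mean_score": float(kept.mean()) if len(kept) else 0.0,
                    "n_kept": int(len(kept)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "gene_id",
            "localization_class",
            "region",
            "mean_score",
            "n_kept",
        ],
    )


def compare_distributions(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of two score distributions."""
    res = stats.ranksums(np.asarray(a, dtype=float), np.asarray(b, dtype=float), alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def all_kmers(k: int) -> list[str]:
    """All 4**k DNA k-mers in lexicographic order."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]
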