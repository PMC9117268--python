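"""Synthetic transcriptome and raw tables with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: CU-rich motif hotspots in the CDS of membrane-class transcripts
(multivalent binding), a bimodal membrane-to-cytosol enrichment, an
elongation pause downstream of targeting signals in the wild type, a mild
codon-specific dwell increase in the knockout, crosslink excess on a subset
of tRNAs with modification-position noise, and a planted true-positive
proximity-labeling set. Every simulated table is fully determined by the
seed; one global seed expands into per-stage streams in a fixed order
(transcriptome, PAR-CLIP, fractions, footprints, tRNA, proteomics).

Noise models are the standard count models for each assay: Negative
Binomial for RNA-seq counts, Binomial conversion given Poisson coverage for
PAR-CLIP, Poisson for footprints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import parse_motifs
from .kmers import occurrence_positions
from .models import (
    LocalizationClass,
    SignalKind,
    TargetingSignal,
    TranscriptModel,
    normalize_alphabet,
)

DEFAULT_MOTIFS = ["TTCT", "CTTC", "TCTT", "CTCT"]
DEFAULT_KO_DWELL_CODONS = ["CTT", "CTC", "TTC", "TTT"]

_STAGES = ("transcriptome", "parclip", "fractions", "footprints", "trna", "proteomics")


def stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    """Expand one global seed into per-stage seed sequences (fixed order)."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return dict(zip(_STAGES, children))


@dataclass
class SimTruth:
    """Planted ground truth, sufficient to regenerate every table."""

    seed: int
    genes: pd.DataFrame  # per-gene labels, enrichment, expression, pause
    motif_positions: dict[str, np.ndarray] = field(default_factory=dict)
    hotspots: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    motifs: list[str] = field(default_factory=lambda: list(DEFAULT_MOTIFS))
    pause_len_codons: int = 10
    pause_mult: dict[str, float] = field(
        default_factory=lambda: {"WT": 2.0, "KO": 1.2}
    )
    ko_dwell_codons: list[str] = field(
        default_factory=lambda: list(DEFAULT_KO_DWELL_CODONS)
    )
    ko_dwell_mult: float = 1.3
    trna_excess: dict[str, float] = field(default_factory=dict)
    trna_masks: dict[str, set[int]] = field(default_factory=dict)
    bioid_true_positives: set[str] = field(default_factory=set)

    def tpm(self) -> dict[str, float]:
        return dict(zip(self.genes["gene_id"], self.genes["tpm"]))

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(directory / "truth_genes.tsv", sep="\t", index=False)
        rows = [
            {"transcript_id": t, "position": int(p)}
            for t, arr in self.motif_positions.items()
            for p in arr
        ]
        pd.DataFrame(rows, columns=["transcript_id", "position"]).to_csv(
            directory / "truth_motif_positions.tsv", sep="\t", index=False
        )
        scalars = {
            "seed": self.seed,
            "motifs": self.motifs,
            "pause_len_codons": self.pause_len_codons,
            "pause_mult": self.pause_mult,
            "ko_dwell_codons": self.ko_dwell_codons,
            "ko_dwell_mult": self.ko_dwell_mult,
            "trna_excess": self.trna_excess,
            "bioid_true_positives": sorted(self.bioid_true_positives),
        }
        (directory / "truth_params.json").write_text(
            json.dumps(scalars, indent=2, sort_keys=True)
        )


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n)


def simulate_transcriptome(
    n_genes: int = 300,
    class_fractions: dict[str, float] | None = None,
    region_length_dists: dict[str, tuple[int, int]] | None = None,
    motif_params: dict | None = None,
    seed: int = 0,
) -> tuple[dict[str, TranscriptModel], SimTruth]:
    """Generate transcripts with planted motifs, signals and enrichment.

    Membrane-class transcripts carry CDS hotspots of 2-4 motifs within a
    40-nt window plus a planted signal peptide (fixed end codon, default
    aa 25) or TM helix; cytosolic transcripts carry sparser single motifs
    split between CDS and 3'UTR. Background sequence is uniform random.
    Planted log2 membrane enrichment is +2.5 / -1.0 / 0 for membrane /
    cytosolic / undefined genes plus N(0, sd) gene-level scatter.
    """
    class_fractions = class_fractions or {
        "membrane": 0.35,
        "cytosolic": 0.50,
        "undefined": 0.15,
    }
    if abs(sum(class_fractions.values()) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    dists = region_length_dists or {
        "utr5": (60, 200),
        "codons": (150, 400),
        "utr3": (150, 600),
    }
    mp = {
        "motifs": DEFAULT_MOTIFS,
        "hotspot_motifs_min": 2,
        "hotspot_motifs_max": 4,
        "hotspots_per_membrane_cds_kb": 4.0,
        "cytosolic_motifs_per_kb": 1.0,
        "hotspot_window": 40,
        "sp_end_aa": 25,
        "sp_fraction": 0.6,
        "enrich_membrane": 2.5,
        "enrich_cytosolic": -1.0,
        "enrich_sd": 0.3,
    }
    if motif_params:
        unknown = set(motif_params) - set(mp)
        if unknown:
            raise ValueError(f"unknown motif_params keys: {sorted(unknown)}")
        mp.update(motif_params)
    motifs = [normalize_alphabet(m) for m in mp["motifs"]]
    if motifs and len({len(m) for m in motifs}) != 1:
        raise ValueError("motifs must share one length")
    mlen = len(motifs[0]) if motifs else 4
    wlen = mp["hotspot_window"]

    rng = np.random.default_rng(stage_seeds(seed)["transcriptome"])
    # deterministic class counts, shuffled assignment
    labels = []
    for cls, frac in class_fractions.items():
        labels += [cls] * int(round(frac * n_genes))
    while len(labels) < n_genes:
        labels.append("cytosolic")
    labels = list(rng.permutation(np.array(labels[:n_genes])))

    transcriptome: dict[str, TranscriptModel] = {}
    gene_rows = []
    motif_positions: dict[str, np.ndarray] = {}
    hotspots: dict[str, list[tuple[int, int]]] = {}
    expr = rng.lognormal(mean=3.0, sigma=1.0, size=n_genes)
    tpm = expr / expr.sum() * 1e6

    for i, cls in enumerate(labels):
        gid = f"GENE{i:05d}"
        tid = f"TX{i:05d}"
        len5 = int(rng.integers(*dists["utr5"]))
        n_codons = int(rng.integers(*dists["codons"]))
        lencds = 3 * n_codons
        len3 = int(rng.integers(*dists["utr3"]))
        seq = _random_seq(rng, len5 + lencds + len3)
        planted: list[int] = []
        spots: list[tuple[int, int]] = []
        signals: list[TargetingSignal] = []
        pause_codon = np.nan
        if cls == "membrane":
            if lencds < wlen:
                raise ValueError("CDS too short for a hotspot window")
            rate = mp["hotspots_per_membrane_cds_kb"]
            n_spots = max(1, int(round(rate * lencds / 1000))) if rate > 0 else 0
            for _ in range(n_spots):
                w0 = len5 + int(rng.integers(0, lencds - wlen + 1))
                k = int(rng.integers(mp["hotspot_motifs_min"], mp["hotspot_motifs_max"] + 1))
                offs = rng.choice(np.arange(0, wlen - mlen + 1, mlen), size=min(k, (wlen // mlen)), replace=False)
                for off in sorted(offs):
                    m = motifs[int(rng.integers(len(motifs)))]
                    pos = w0 + int(off)
                    seq[pos : pos + mlen] = np.frombuffer(m.encode(), dtype="S1")
                    planted.append(pos)
                spots.append((w0, w0 + wlen))
            if rng.random() < mp["sp_fraction"]:
                sig = TargetingSignal(SignalKind.SIGNAL_PEPTIDE, 1, mp["sp_end_aa"])
            else:
                start = int(rng.integers(25, 61))
                sig = TargetingSignal(SignalKind.TM_HELIX, start, start + 6)
            signals.append(sig)
            pause_codon = sig.aa_end
        else:
            per_kb = mp["cytosolic_motifs_per_kb"] * (1.0 if cls == "cytosolic" else 0.5)
            for start, length in (
                (len5, lencds),
                (len5 + lencds, len3),
            ):
                n_m = int(round(per_kb * length / 1000))
                for _ in range(n_m):
                    pos = start + int(rng.integers(0, length - mlen + 1))
                    m = motifs[int(rng.integers(len(motifs)))]
                    seq[pos : pos + mlen] = np.frombuffer(m.encode(), dtype="S1")
                    planted.append(pos)
        enrich_mean = {
            "membrane": mp["enrich_membrane"],
            "cytosolic": mp["enrich_cytosolic"],
            "undefined": 0.0,
        }[cls]
        enrich = enrich_mean + rng.normal(0.0, mp["enrich_sd"])
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            sequence=b"".join(seq).decode(),
            len5utr=len5,
            lencds=lencds,
            len3utr=len3,
            localization_class=LocalizationClass(cls),
            signals=signals,
            tpm=float(tpm[i]),
        )
        transcriptome[tid] = model
        motif_positions[tid] = np.array(sorted(planted), dtype=np.int64)
        hotspots[tid] = spots
        gene_rows.append(
            {
                "gene_id": gid,
                "transcript_id": tid,
                "localization_class": cls,
                "log2_enrichment": float(enrich),
                "tpm": float(tpm[i]),
                "pause_codon": pause_codon,
                "signal_kind": signals[0].kind.value if signals else "",
            }
        )
    truth = SimTruth(
        seed=seed,
        genes=pd.DataFrame(gene_rows),
        motif_positions=motif_positions,
        hotspots=hotspots,
        motifs=motifs,
    )
    return transcriptome, truth


def local_motif_counts(
    model: TranscriptModel, motifs: list[str], half_window: int = 20
) -> np.ndarray:
    """Motif occurrences starting within +/-``half_window`` nt per position."""
    occ = occurrence_positions(model.sequence, motifs)
    pos = np.arange(model.length)
    return (
        np.searchsorted(occ, pos + half_window, side="right")
        - np.searchsorted(occ, pos - half_window, side="left")
    ).astype(np.int64)


def crosslink_propensity(
    model: TranscriptModel,
    motifs: list[str],
    half_window: int = 20,
    saturation: int = 4,
) -> np.ndarray:
    """Per-position crosslink propensity in [0, 1].

    Proportional to the local motif multivalency of the (planted) sequence
    (occurrences within +/-``half_window`` nt, saturating at
    ``saturation``), non-zero only at U/T positions.
    """
    counts = local_motif_counts(model, motifs, half_window)
    prop = np.minimum(counts / saturation, 1.0)
    is_t = np.frombuffer(model.sequence.encode(), dtype="S1") == b"T"
    return np.where(is_t, prop, 0.0)


def simulate_parclip(
    transcriptome: dict[str, TranscriptModel],
    truth: SimTruth,
    depth: float = 50.0,
    conv_rate: float = 0.3,
    err_rate: float = 0.001,
    n_replicates: int = 2,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], list[pd.DataFrame]]:
    """Per-replicate pileup and cluster tables with planted crosslinks.

    Coverage at each convertible (T) position is Poisson with mean
    proportional to transcript TPM times ``depth``; the T-C count is
    Binomial(coverage, conv_rate * propensity + err_rate). Clusters are
    the maximal runs of positions within the propensity support, with
    replicate-jittered boundaries; replicates are independent draws.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= conv_rate <= 1:
        raise ValueError("conv_rate must be in [0, 1]")
    rng = np.random.default_rng(stage_seeds(seed)["parclip"])
    mean_tpm = float(np.mean([t.tpm or 0.0 for t in transcriptome.values()])) or 1.0
    pileups: list[list[dict]] = [[] for _ in range(n_replicates)]
    clusters: list[list[dict]] = [[] for _ in range(n_replicates)]
    for model in transcriptome.values():
        prop = crosslink_propensity(model, truth.motifs)
        is_t = np.frombuffer(model.sequence.encode(), dtype="S1") == b"T"
        t_idx = np.flatnonzero(is_t)
        if len(t_idx) == 0:
            continue
        cov_mean = depth * (model.tpm or 0.0) / mean_tpm
        p_conv = np.clip(conv_rate * prop[t_idx] + err_rate, 0.0, 1.0)
        # cluster support: runs where the local multivalency is non-zero
        runs = _runs(local_motif_counts(model, truth.motifs) > 0)
        for rep in range(n_replicates):
            cov = rng.poisson(cov_mean, size=len(t_idx))
            tc = rng.binomial(cov, p_conv)
            keep = cov > 0
            for pos, c, t in zip(t_idx[keep], cov[keep], tc[keep]):
                pileups[rep].append(
                    {
                        "transcript_id": model.transcript_id,
                        "position": int(pos),
                        "coverage": int(c),
                        "tc": int(t),
                    }
                )
            tc_full = np.zeros(model.length, dtype=np.int64)
            tc_full[t_idx] = tc
            for r0, r1 in runs:
                j0 = max(0, r0 + int(rng.integers(-3, 4)))
                j1 = min(model.length, r1 + int(rng.integers(-3, 4)))
                if j1 <= j0:
                    continue
                seg = tc_full[j0:j1]
                total = int(seg.sum())
                if total == 0:
                    continue
                clusters[rep].append(
                    {
                        "transcript_id": model.transcript_id,
                        "start": int(j0),
                        "end": int(j1),
                        "tc_sum": total,
                        "max_tc_pos": int(j0 + np.argmax(seg)),
                    }
                )
    pileup_cols = ["transcript_id", "position", "coverage", "tc"]
    cluster_cols = ["transcript_id", "start", "end", "tc_sum", "max_tc_pos"]
    return (
        [pd.DataFrame(p, columns=pileup_cols) for p in pileups],
        [pd.DataFrame(c, columns=cluster_cols) for c in clusters],
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean array."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def simulate_fraction_counts(
    transcriptome: dict[str, TranscriptModel],
    truth: SimTruth,
    lib_sizes: dict[str, int] | None = None,
    dispersion: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Whole-cell / cytosol x2 / membrane x2 count matrix (genes x samples).

    Each gene's expression is split between membrane and cytosol by its
    planted log2 enrichment; counts are Negative Binomial (Gamma-Poisson)
    with the given dispersion, Poisson when dispersion is 0.
    """
    lib_sizes = lib_sizes or {
        "wholecell": 2_000_000,
        "cytosol_1": 2_000_000,
        "cytosol_2": 2_000_000,
        "membrane_1": 2_000_000,
        "membrane_2": 2_000_000,
    }
    if any(v <= 0 for v in lib_sizes.values()):
        raise ValueError("library sizes must be positive")
    rng = np.random.default_rng(stage_seeds(seed)["fractions"])
    genes = truth.genes
    x = genes["tpm"].to_numpy(dtype=float)
    e = genes["log2_enrichment"].to_numpy(dtype=float)
    mem_share = 2.0**e / (1.0 + 2.0**e)
    w_cyt = x * (1 - mem_share)
    w_mem = x * mem_share
    # fraction weights keep their relative mass (common denominator, scaled
    # so the two fractions together match one whole-cell library): absolute
    # per-fraction renormalization would shift every gene's enrichment by
    # the unidentifiable compartment mass ratio
    denom = (w_cyt.sum() + w_mem.sum()) / 2.0
    weights = {
        "wholecell": (x, x.sum()),
        "cytosol_1": (w_cyt, denom),
        "cytosol_2": (w_cyt, denom),
        "membrane_1": (w_mem, denom),
        "membrane_2": (w_mem, denom),
    }
    out = {}
    for sample, lib in lib_sizes.items():
        w, d = weights[sample]
        mean = lib * w / d
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
        else:
            lam = mean
        out[sample] = rng.poisson(lam)
    counts = pd.DataFrame(out, index=pd.Index(genes["gene_id"], name="gene_id"))
    return counts


def simulate_footprints(
    transcriptome: dict[str, TranscriptModel],
    truth: SimTruth,
    depth: float = 50.0,
    n_replicates: int = 2,
    conditions: tuple[str, ...] = ("WT", "KO"),
    offset: int = 13,
    seed: int = 0,
) -> pd.DataFrame:
    """Footprint 5'-end tables per condition x replicate.

    Per-codon counts are Poisson with mean proportional to TPM x depth,
    modulated by dwell multipliers: the WT pauses (default 2.0x over 10
    codons) starting at the targeting-signal end codon, the KO retains a
    reduced pause (1.2x) and gains a dwell increase (1.3x) on the CU/UU
    codon set. 5' ends are emitted at P-site - offset nt.
    """
    rng = np.random.default_rng(stage_seeds(seed)["footprints"])
    mean_tpm = float(np.mean([t.tpm or 0.0 for t in transcriptome.values()])) or 1.0
    ko_set = {normalize_alphabet(c) for c in truth.ko_dwell_codons}
    pause_by_tx = dict(zip(truth.genes["transcript_id"], truth.genes["pause_codon"]))
    rows = []
    for model in transcriptome.values():
        n_codons = model.n_codons
        base = depth * (model.tpm or 0.0) / mean_tpm / 10.0
        codon_seqs = [model.codon(i) for i in range(n_codons)]
        pause = pause_by_tx.get(model.transcript_id, np.nan)
        for condition in conditions:
            mult = np.ones(n_codons)
            if not np.isnan(pause):
                p0 = int(pause) - 1  # pause starts at the signal-end codon
                p1 = p0 + truth.pause_len_codons
                if p1 > n_codons:
                    raise ValueError(
                        f"{model.transcript_id}: pause window extends past CDS"
                    )
                mult[p0:p1] *= truth.pause_mult.get(condition, 1.0)
            if condition == "KO":
                for i, c in enumerate(codon_seqs):
                    if c in ko_set:
                        mult[i] *= truth.ko_dwell_mult
            for rep in range(1, n_replicates + 1):
                counts = rng.poisson(base * mult)
                for i in np.flatnonzero(counts):
                    pos5p = model.cds_start + 3 * int(i) - offset
                    if pos5p < 0:
                        continue
                    rows.append(
                        {
                            "transcript_id": model.transcript_id,
                            "pos5p": pos5p,
                            "count": int(counts[i]),
                            "condition": condition,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["transcript_id", "pos5p", "count", "condition", "replicate"]
    )


def simulate_trna_and_proteomics(
    truth: SimTruth,
    n_trnas: int = 20,
    trna_len: int = 76,
    trna_depth: float = 200.0,
    base_tc_rate: float = 0.02,
    mod_tc_rate: float = 0.15,
    excess: float = 3.0,
    n_excess: int = 3,
    n_proteins: int = 200,
    n_true: int = 20,
    true_ratio: float = 8.0,
    n_silac: int = 100,
    requant_frac: float = 0.1,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """tRNA pileups + abundance reads, BioID LFQ table, SILAC pair table.

    A subset of tRNAs gets a crosslink excess factor (default 3x) at
    non-masked U positions; masked (dihydrouridine-like) positions get a
    condition-independent high T-C noise rate. One extra tRNA
    ("tRNA-ModOnly") carries signal only at masked positions. BioID true
    positives get a Dox/noDox ratio of ``true_ratio``; a fraction of SILAC
    pairs is flagged requantified on either side.
    """
    if excess < 0:
        raise ValueError("excess factor must be non-negative")
    seeds = stage_seeds(seed)
    rng_t = np.random.default_rng(seeds["trna"])
    rng_p = np.random.default_rng(seeds["proteomics"])

    # ---- tRNA ----
    trna_ids = [f"tRNA-{i:02d}" for i in range(n_trnas)] + ["tRNA-ModOnly"]
    excess_ids = trna_ids[:n_excess]
    pile_rows = []
    abund_rows = []
    truth.trna_excess = {}
    truth.trna_masks = {}
    for tid in trna_ids:
        seq = _random_seq(rng_t, trna_len)
        mask_pos = {16, 17, 20}
        for p in mask_pos:
            seq[p] = b"T"
        t_positions = np.flatnonzero(seq == b"T")
        abundance = float(rng_t.lognormal(0.0, 0.7))
        factor = excess if tid in excess_ids else (0.0 if tid == "tRNA-ModOnly" else 1.0)
        # per-position rate scaled by U content so per-tRNA crosslinkability
        # depends only on the planted excess factor, not sequence composition
        u_scale = (trna_len / 4.0) / max(len(t_positions), 1)
        unmasked_rate = base_tc_rate * u_scale * (factor if factor > 0 else 1.0)
        truth.trna_excess[tid] = factor if tid != "tRNA-ModOnly" else 1.0
        truth.trna_masks[tid] = mask_pos
        for p in t_positions:
            cov = int(rng_t.poisson(abundance * trna_depth))
            if cov == 0:
                continue
            rate = mod_tc_rate if int(p) in mask_pos else (
                unmasked_rate if tid != "tRNA-ModOnly" else base_tc_rate * u_scale
            )
            tc = int(rng_t.binomial(cov, min(rate, 1.0)))
            pile_rows.append(
                {"trna_id": tid, "position": int(p), "coverage": cov, "tc": tc}
            )
        abund_rows.append(
            {"trna_id": tid, "reads": int(rng_t.poisson(abundance * trna_depth * 5))}
        )
    trna_pileups = pd.DataFrame(
        pile_rows, columns=["trna_id", "position", "coverage", "tc"]
    )
    trna_abundance = pd.DataFrame(abund_rows, columns=["trna_id", "reads"])
    masks = pd.DataFrame(
        [
            {"trna_id": t, "position": p}
            for t in trna_ids
            for p in sorted(truth.trna_masks[t])
        ]
    )

    # ---- BioID ----
    protein_ids = [f"PROT{i:04d}" for i in range(n_proteins)]
    true_set = set(protein_ids[:n_true])
    truth.bioid_true_positives = true_set
    lfq_rows = []
    for pid in protein_ids:
        is_true = pid in true_set
        # true positives clear the Dox LFQ floor (2^27) with a wide margin:
        # nodox ~ 2^25.5 and ratio 8 put Dox near 2^28.5
        log2_nodox = rng_p.normal(25.5, 0.3) if is_true else rng_p.normal(26.0, 1.2)
        ratio = true_ratio if is_true else float(rng_p.lognormal(0.0, 0.25))
        row = {
            "protein_group": pid,
            "razor_unique_peptides": int(rng_p.integers(3, 21))
            if is_true
            else int(rng_p.integers(1, 21)),
        }
        for n in (2, 3):
            row[f"lfq_nodox_{n}"] = 2.0 ** (log2_nodox + rng_p.normal(0.0, 0.15))
        for d in (1, 2, 3):
            row[f"lfq_dox_{d}"] = 2.0 ** (
                log2_nodox + np.log2(ratio) + rng_p.normal(0.0, 0.15)
            )
        lfq_rows.append(row)
    lfq = pd.DataFrame(lfq_rows)

    # ---- pSILAC ----
    silac_rows = []
    for i in range(n_silac):
        prot = f"SPROT{i:04d}"
        true_log2 = rng_p.normal(0.0, 0.5)
        forward_only = rng_p.random() < 0.1
        for orientation in ("forward", "reverse"):
            if orientation == "reverse" and forward_only:
                continue
            for _rep in range(2):
                measured = true_log2 + rng_p.normal(0.0, 0.2)
                if orientation == "reverse":
                    measured = -true_log2 + rng_p.normal(0.0, 0.2)
                silac_rows.append(
                    {
                        "protein": prot,
                        "log2_ratio_hm": measured,
                        "orientation": orientation,
                        "requant_num": bool(rng_p.random() < requant_frac),
                        "requant_den": bool(rng_p.random() < requant_frac),
                    }
                )
    silac = pd.DataFrame(silac_rows)
    return {
        "trna_pileups": trna_pileups,
        "trna_abundance": trna_abundance,
        "trna_masks": masks,
        "bioid_lfq": lfq,
        "silac_pairs": silac,
    }
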