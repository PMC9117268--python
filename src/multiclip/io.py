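"""Readers and writers for the pipeline's exchange formats.

Everything on disk is plain text: FASTA for sequences, BED6 (transcript
space, strand fixed ``+``) for sites and clusters, and headered TSV for
pileups, count matrices and summaries. Internal coordinates are 0-based
half-open throughout, matching BED.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    LocalizationClass,
    SignalKind,
    TargetingSignal,
    TranscriptModel,
    normalize_alphabet,
)

logger = logging.getLogger("multiclip")

#: columns of a pileup table (per replicate): per-position read coverage and
#: T-C transition counts in transcript coordinates.
PILEUP_COLUMNS = ["transcript_id", "position", "coverage", "tc"]

#: columns of a cluster table (per replicate).
CLUSTER_COLUMNS = ["transcript_id", "start", "end", "tc_sum", "max_tc_pos"]


def read_transcriptome(
    fasta_path: str | Path,
    regions_path: str | Path,
    signals_path: str | Path | None = None,
    alphabet: str = "T",
) -> dict[str, TranscriptModel]:
    """Load transcript sequences plus a region table into models.

    The region table is a TSV with columns ``transcript_id``, ``gene_id``,
    ``len5utr``, ``lencds``, ``len3utr`` and optionally ``tpm``,
    ``localization_class``. When a gene has several isoforms, the
    highest-TPM one is kept (the representative-isoform rule); without a
    TPM column duplicate genes are an error.
    """
    seqs = {
        rec.id: normalize_alphabet(str(rec.seq), alphabet)
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    regions = pd.read_csv(regions_path, sep="\t")
    signals_by_tx: dict[str, list[TargetingSignal]] = {}
    if signals_path is not None:
        signals_by_tx = read_signals(signals_path)

    by_gene: dict[str, TranscriptModel] = {}
    for row in regions.itertuples(index=False):
        tid = str(row.transcript_id)
        if tid not in seqs:
            raise ValueError(f"transcript {tid} in region table but not FASTA")
        tpm = float(row.tpm) if "tpm" in regions.columns else None
        loc = (
            LocalizationClass(row.localization_class)
            if "localization_class" in regions.columns
            else LocalizationClass.UNDEFINED
        )
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=str(row.gene_id),
            sequence=seqs[tid],
            len5utr=int(row.len5utr),
            lencds=int(row.lencds),
            len3utr=int(row.len3utr),
            localization_class=loc,
            signals=signals_by_tx.get(tid, []),
            is_mt=str(row.gene_id).startswith("MT-"),
            tpm=tpm,
        )
        prev = by_gene.get(model.gene_id)
        if prev is None:
            by_gene[model.gene_id] = model
        else:
            # one isoform per gene: keep the most highly expressed
            if prev.tpm is None or model.tpm is None:
                raise ValueError(
                    f"gene {model.gene_id} has multiple isoforms and no TPM "
                    "column to pick the representative one"
                )
            if model.tpm > prev.tpm:
                by_gene[model.gene_id] = model
    models = {m.transcript_id: m for m in by_gene.values()}
    logger.info("loaded %d transcripts (%d genes)", len(models), len(by_gene))
    return models


def write_transcriptome(
    transcriptome: dict[str, TranscriptModel],
    fasta_path: str | Path,
    regions_path: str | Path,
    signals_path: str | Path | None = None,
) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        for t in transcriptome.values()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "len5utr": t.len5utr,
            "lencds": t.lencds,
            "len3utr": t.len3utr,
            "tpm": t.tpm if t.tpm is not None else float("nan"),
            "localization_class": t.localization_class.value,
        }
        for t in transcriptome.values()
    ]
    pd.DataFrame(rows).to_csv(regions_path, sep="\t", index=False)
    if signals_path is not None:
        write_signals(
            {t.transcript_id: t.signals for t in transcriptome.values() if t.signals},
            signals_path,
        )


def read_signals(path: str | Path) -> dict[str, list[TargetingSignal]]:
    """Read targeting-signal annotations (1-based inclusive protein coords)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[TargetingSignal]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.transcript_id), []).append(
            TargetingSignal(
                kind=SignalKind(row.kind),
                aa_start=int(row.aa_start),
                aa_end=int(row.aa_end),
            )
        )
    return out


def write_signals(
    signals: dict[str, list[TargetingSignal]], path: str | Path
) -> None:
    rows = [
        {
            "transcript_id": tid,
            "kind": s.kind.value,
            "aa_start": s.aa_start,
            "aa_end": s.aa_end,
        }
        for tid, sigs in signals.items()
        for s in sigs
    ]
    pd.DataFrame(rows, columns=["transcript_id", "kind", "aa_start", "aa_end"]).to_csv(
        path, sep="\t", index=False
    )


def write_sites_bed(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a site table as BED6 in transcript space.

    ``sites`` needs columns ``transcript_id``, ``position``, ``tc``;
    score carries the T-C count, strand is always ``+``.
    """
    if len(sites) and (sites["position"] < 0).any():
        raise ValueError("negative site position")
    bed = pd.DataFrame(
        {
            "chrom": sites["transcript_id"],
            "start": sites["position"].astype(int),
            "end": sites["position"].astype(int) + 1,
            "name": "site",
            "score": sites["tc"].astype(int),
            "strand": "+",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_sites_bed(path: str | Path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        bed = pd.read_csv(path, sep="\t", header=None, names=names)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["transcript_id", "position", "tc"])
    return pd.DataFrame(
        {
            "transcript_id": bed["chrom"].astype(str),
            "position": bed["start"].astype(int),
            "tc": bed["score"].astype(int),
        }
    )


def write_clusters_bed(clusters: pd.DataFrame, path: str | Path) -> None:
    """Clusters as BED6 plus a ``max_tc_pos`` column (BED6+1)."""
    bed = pd.DataFrame(
        {
            "chrom": clusters["transcript_id"],
            "start": clusters["start"].astype(int),
            "end": clusters["end"].astype(int),
            "name": "cluster",
            "score": clusters["tc_sum"],
            "strand": "+",
            "max_tc_pos": clusters["max_tc_pos"].astype(int),
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_clusters_bed(path: str | Path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand", "max_tc_pos"]
    try:
        bed = pd.read_csv(path, sep="\t", header=None, names=names)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=CLUSTER_COLUMNS)
    return pd.DataFrame(
        {
            "transcript_id": bed["chrom"].astype(str),
            "start": bed["start"].astype(int),
            "end": bed["end"].astype(int),
            "tc_sum": bed["score"],
            "max_tc_pos": bed["max_tc_pos"].astype(int),
        }
    )


def read_table(path: str | Path) -> pd.DataFrame:
    """Headered TSV (pileups, count matrices, footprints, proteomics)."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
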