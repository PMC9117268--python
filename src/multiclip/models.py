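"""Domain types shared by all pipeline stages.

All coordinates are transcript-space, 0-based half-open, on the sense
strand. Protein coordinates (targeting signals) are 1-based inclusive, the
convention of SignalP/TMHMM-style annotation tables; the conversion to
transcript nucleotides lives on :class:`TargetingSignal`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class LocalizationClass(str, Enum):
    """mRNA localization call from membrane/cytosol fractionation."""

    MEMBRANE = "membrane"
    CYTOSOLIC = "cytosolic"
    UNDEFINED = "undefined"
    EXCLUDED = "excluded"


class Region(str, Enum):
    UTR5 = "utr5"
    CDS = "cds"
    UTR3 = "utr3"


class SignalKind(str, Enum):
    SIGNAL_PEPTIDE = "signal_peptide"
    TM_HELIX = "tm_helix"


class TargetingClass(str, Enum):
    """Gene classes by encoded co-translational targeting signal."""

    NO_TS = "no_TS"
    MITO_NUCLEAR = "mito_nuclear"
    TAIL_ANCHORED = "tail_anchored"
    MTDNA = "mtDNA"
    MEMBRANE_NO_TS = "membrane_no_TS"
    SP_ONLY = "SP_only"
    TM_ONLY = "TM_only"
    SP_AND_TM = "SP_and_TM"


@dataclass(frozen=True)
class TargetingSignal:
    """A signal peptide or transmembrane helix in protein coordinates.

    ``aa_start``/``aa_end`` are 1-based inclusive amino-acid positions.
    Transcript-space nucleotide coordinates are derived, 0-based half-open.
    """

    kind: SignalKind
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if self.aa_start < 1 or self.aa_end < self.aa_start:
            raise ValueError(
                f"invalid protein coordinates [{self.aa_start}, {self.aa_end}]"
            )

    def nt_span(self, len5utr: int) -> tuple[int, int]:
        """Transcript nucleotide span (0-based half-open) of the signal."""
        return len5utr + 3 * (self.aa_start - 1), len5utr + 3 * self.aa_end


@dataclass
class TranscriptModel:
    """One representative isoform of a gene with region annotation.

    The sequence alphabet is normalized at load time (default DNA, i.e. U
    replaced by T); reports spell k-mers in RNA.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    len5utr: int
    lencds: int
    len3utr: int
    localization_class: LocalizationClass = LocalizationClass.UNDEFINED
    signals: list[TargetingSignal] = field(default_factory=list)
    is_mt: bool = False
    tpm: float | None = None

    def __post_init__(self) -> None:
        if min(self.len5utr, self.lencds, self.len3utr) < 0:
            raise ValueError(f"{self.transcript_id}: negative region length")
        if self.len5utr + self.lencds + self.len3utr != len(self.sequence):
            raise ValueError(
                f"{self.transcript_id}: region lengths "
                f"({self.len5utr}, {self.lencds}, {self.len3utr}) do not sum "
                f"to sequence length {len(self.sequence)}"
            )
        if self.lencds and self.lencds % 3:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.lencds} not a "
                "multiple of 3"
            )
        for sig in self.signals:
            if sig.aa_end > self.lencds // 3:
                raise ValueError(
                    f"{self.transcript_id}: signal ends at aa {sig.aa_end} "
                    f"beyond CDS ({self.lencds // 3} codons)"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_start(self) -> int:
        return self.len5utr

    @property
    def cds_end(self) -> int:
        return self.len5utr + self.lencds

    @property
    def n_codons(self) -> int:
        return self.lencds // 3

    @property
    def protein_length(self) -> int:
        """Amino acids encoded, excluding the stop codon."""
        return max(self.n_codons - 1, 0)

    def region_of(self, position: int) -> Region:
        """Region containing a 0-based transcript position."""
        if not 0 <= position < self.length:
            raise ValueError(
                f"{self.transcript_id}: position {position} outside "
                f"[0, {self.length})"
            )
        if position < self.len5utr:
            return Region.UTR5
        if position < self.cds_end:
            return Region.CDS
        return Region.UTR3

    def region_bounds(self, region: Region) -> tuple[int, int]:
        if region is Region.UTR5:
            return 0, self.len5utr
        if region is Region.CDS:
            return self.cds_start, self.cds_end
        return self.cds_end, self.length

    def region_sequence(self, region: Region) -> str:
        start, end = self.region_bounds(region)
        return self.sequence[start:end]

    def codon_index(self, position: int) -> int:
        """0-based codon index of a CDS nucleotide position."""
        if not self.cds_start <= position < self.cds_end:
            raise ValueError(
                f"{self.transcript_id}: position {position} not in CDS"
            )
        return (position - self.cds_start) // 3

    def codon(self, index: int) -> str:
        """Codon sequence at 0-based codon index."""
        start = self.cds_start + 3 * index
        return self.sequence[start : start + 3]


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive (for reports)."""
    return start0 + 1, end0


def from_one_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open."""
    return start1 - 1, end1


def normalize_alphabet(seq: str, alphabet: str = "T") -> str:
    """Normalize an RNA/DNA sequence to a single alphabet (T or U)."""
    seq = seq.upper()
    if alphabet == "T":
        return seq.replace("U", "T")
    if alphabet == "U":
        return seq.replace("T", "U")
    raise ValueError(f"alphabet must be 'T' or 'U', got {alphabet!r}")


def spell_rna(kmer: str) -> str:
    """Spell a k-mer in the RNA alphabet for human-facing tables."""
    return kmer.upper().replace("T", "U")
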