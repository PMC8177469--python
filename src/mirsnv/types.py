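"""Shared domain types for the 3'-UTR SNV / miRNA binding-site pipeline.

Coordinate conventions: genomic and transcript coordinates are 1-based
inclusive throughout (GFF3/VCF convention).  Genomic sequences use the DNA
alphabet (T); windows, queries and miRNAs are RNA (U).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation or filter parameters."""


class ReferenceMismatchError(ValueError):
    """Raised when a variant's REF allele disagrees with the reference sequence."""


class NoMappingError(ValueError):
    """Raised when a genomic position does not map into a transcript."""


@dataclass(frozen=True)
class VariantCall:
    """One called SNV/indel from one caller in one sample."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    dp: int | None = None
    mq: float | None = None
    sample: str = ""
    caller: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.dp is not None and self.dp < 0:
            raise ValueError("DP must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class SampleCallSet:
    """All calls from one caller for one sample, keyed by (chrom, pos, ref, alt)."""

    sample: str
    caller: str
    calls: dict[tuple[str, int, str, str], VariantCall] = field(default_factory=dict)

    def add(self, call: VariantCall) -> None:
        self.calls[call.key] = call

    def __len__(self) -> int:
        return len(self.calls)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self.calls

    def keys(self):
        return self.calls.keys()


@dataclass
class RecurrentVariant:
    """A variant passing the cohort recurrence rule, with its carrier samples."""

    chrom: str
    pos: int
    ref: str
    alt: str
    carriers: frozenset[str]

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


@dataclass
class TranscriptModel:
    """A single-transcript gene model: exon/CDS layout plus the spliced sequence.

    ``exons`` are 1-based inclusive genomic intervals sorted by start and
    non-overlapping.  ``cds`` is the genomic span of the coding region; the
    spliced CDS length must be divisible by 3.  ``sequence`` is the spliced
    transcript in 5'->3' orientation (DNA alphabet).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds: tuple[int, int]
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            if end < start:
                raise ValueError("exon end before start")
            prev_end = end

    @property
    def exonic_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class ConsequenceCall:
    """Classification of one variant against one transcript."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    category: str  # missense | three_prime_utr | five_prime_utr | intronic | other
    detail: str = ""


CATEGORIES = ("missense", "three_prime_utr", "five_prime_utr", "intronic", "other")


@dataclass(frozen=True)
class UtrWindowPair:
    """71-nt reference/variant RNA windows with the SNV at 1-based index 36."""

    gene_id: str
    variant_key: tuple[str, int, str, str]
    ref_window: str
    alt_window: str
    snv_index: int  # always 36
    tx_span: tuple[int, int]  # transcript positions covered, 1-based inclusive

    def __post_init__(self) -> None:
        if len(self.ref_window) != len(self.alt_window):
            raise ValueError("window length mismatch")
        diffs = [i for i, (a, b) in enumerate(zip(self.ref_window, self.alt_window)) if a != b]
        if diffs != [self.snv_index - 1]:
            raise ValueError(
                f"windows must differ exactly at index {self.snv_index}, differ at {diffs}"
            )


@dataclass(frozen=True)
class QueryPair:
    """11-nt reference/variant query with the SNV at 1-based index 6."""

    ref_query: str
    alt_query: str
    snv_index: int = 6


@dataclass(frozen=True)
class WindowSkip:
    """A variant excluded from window extraction (insufficient flank)."""

    gene_id: str
    variant_key: tuple[str, int, str, str]
    reason: str


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA, 5'->3' RNA, with its seed span (1-based, default 2..8)."""

    mirna_id: str
    sequence: str
    seed_start: int = 2
    seed_end: int = 8

    def __post_init__(self) -> None:
        if not set(self.sequence) <= set("ACGU"):
            raise ValueError(f"miRNA {self.mirna_id} not over ACGU")
        if not (1 <= self.seed_start < self.seed_end <= len(self.sequence)):
            raise ValueError("seed span out of bounds")

    @property
    def seed(self) -> str:
        return self.sequence[self.seed_start - 1 : self.seed_end]


@dataclass(frozen=True)
class TargetSite:
    """A predicted miRNA site on a window, with its duplex energy."""

    mirna_id: str
    start: int  # 1-based inclusive window coordinates
    end: int
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer
    duplex_energy: float = 0.0
    paired_count: int = 0
    agreement: str = "seed_only"  # seed_only | energy_only | both


@dataclass(frozen=True)
class GainLossRecord:
    """Per (gene, variant) sets of miRNAs whose sites were gained/lost."""

    gene_id: str
    variant_key: tuple[str, int, str, str]
    gained: frozenset[str]
    lost: frozenset[str]

    def __post_init__(self) -> None:
        if self.gained & self.lost:
            raise ValueError("gained and lost miRNA sets must be disjoint")


@dataclass(frozen=True)
class FoldResult:
    """One MFE secondary structure: dot-bracket, energy, and its pair set."""

    sequence: str
    dotbracket: str
    energy: float
    pairs: frozenset[tuple[int, int]]  # 0-based (i, j), i < j


@dataclass(frozen=True)
class StructureDelta:
    """Reference-vs-variant folding comparison for one window pair."""

    variant_key: tuple[str, int, str, str]
    gene_id: str
    ref_energy: float
    alt_energy: float
    bp_distance: int

    @property
    def delta_energy(self) -> float:
        return self.alt_energy - self.ref_energy
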