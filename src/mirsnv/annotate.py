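"""Variant consequence classification against single-transcript gene models.

Each variant is placed into one of five categories — missense, 3'-UTR,
5'-UTR, intronic, other — using strand-aware transcript coordinates.
Synonymous coding changes, near-gene (±5 kb) and intergenic positions all
collapse into ``other`` with the subtype preserved in the detail field.
"""

from __future__ import annotations

import pandas as pd
from Bio.Seq import Seq

from .types import (
    CATEGORIES,
    ConsequenceCall,
    ReferenceMismatchError,
    TranscriptModel,
    VariantCall,
)
from .windows import genomic_to_transcript, transcript_alleles

NEAR_GENE_BP = 5000

#: severity used when a variant hits several transcripts (most severe wins)
SEVERITY = {
    "missense": 4,
    "three_prime_utr": 3,
    "five_prime_utr": 3,
    "intronic": 2,
    "other": 1,
}


def _cds_transcript_span(t: TranscriptModel) -> tuple[int, int]:
    """CDS span in transcript coordinates (1-based inclusive, 5'->3')."""
    a = genomic_to_transcript(t.cds[0], t)
    b = genomic_to_transcript(t.cds[1], t)
    return (min(a, b), max(a, b))


def classify_variant(v: VariantCall, t: TranscriptModel) -> ConsequenceCall:
    """Classify one variant against one transcript model."""
    if v.chrom != t.chrom:
        raise ValueError(f"variant chrom {v.chrom} != transcript chrom {t.chrom}")
    span_lo, span_hi = t.span

    def call(category: str, detail: str = "") -> ConsequenceCall:
        return ConsequenceCall(
            chrom=v.chrom,
            pos=v.pos,
            ref=v.ref,
            alt=v.alt,
            gene_id=t.gene_id,
            category=category,
            detail=detail,
        )

    if v.pos < span_lo or v.pos > span_hi:
        if span_lo - NEAR_GENE_BP <= v.pos <= span_hi + NEAR_GENE_BP:
            upstream_genomic = v.pos < span_lo
            if (t.strand == "+") == upstream_genomic:
                return call("other", "upstream")
            return call("other", "downstream")
        return call("other", "intergenic")

    in_exon = any(start <= v.pos <= end for start, end in t.exons)
    if not in_exon:
        return call("intronic")

    offset = genomic_to_transcript(v.pos, t)
    ref_tx, alt_tx = transcript_alleles(v, t)
    if len(v.ref) == 1 and len(v.alt) == 1:
        tx_base = t.sequence[offset - 1]
        if tx_base != ref_tx:
            raise ReferenceMismatchError(
                f"{t.transcript_id} pos {v.pos} (offset {offset}): "
                f"reference is {tx_base}, variant ref is {ref_tx}"
            )
    cds_lo, cds_hi = _cds_transcript_span(t)
    if offset < cds_lo:
        return call("five_prime_utr")
    if offset > cds_hi:
        return call("three_prime_utr")
    if len(v.ref) != 1 or len(v.alt) != 1:
        return call("other", "coding_indel")

    cds_off = offset - cds_lo  # 0-based within CDS
    codon_start = cds_lo + (cds_off // 3) * 3
    codon = t.sequence[codon_start - 1 : codon_start + 2]
    frame = cds_off % 3
    alt_codon = codon[:frame] + alt_tx + codon[frame + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return call("other", "synonymous")
    detail = f"{ref_aa}->{alt_aa}"
    if alt_aa == "*":
        detail += " (stop_gained)"
    elif ref_aa == "*":
        detail += " (stop_lost)"
    return call("missense", detail)


def classify_against_models(
    v: VariantCall, models: list[TranscriptModel]
) -> ConsequenceCall:
    """Most severe consequence of a variant across candidate transcripts."""
    candidates = [t for t in models if t.chrom == v.chrom]
    if not candidates:
        return ConsequenceCall(
            chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
            gene_id="", category="other", detail="intergenic",
        )
    calls = [classify_variant(v, t) for t in candidates]
    return max(calls, key=lambda c: SEVERITY[c.category])


def tabulate_consequences(calls: list[ConsequenceCall]) -> pd.DataFrame:
    """Five-category count table (rows fixed and ordered; counts sum to input size)."""
    counts = pd.Series([c.category for c in calls]).value_counts()
    data = {cat: int(counts.get(cat, 0)) for cat in CATEGORIES}
    return pd.DataFrame({"category": list(data), "n": list(data.values())})


def per_gene_consequences(calls: list[ConsequenceCall]) -> pd.DataFrame:
    """Per-gene breakdown of consequence categories."""
    if not calls:
        return pd.DataFrame(columns=["gene_id", *CATEGORIES])
    df = pd.DataFrame([{"gene_id": c.gene_id, "category": c.category} for c in calls])
    wide = (
        df.pivot_table(index="gene_id", columns="category", aggfunc="size", fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
        .reset_index()
    )
    wide.columns.name = None
    return wide
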