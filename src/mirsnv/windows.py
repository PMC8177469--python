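"""Transcript-coordinate lifting and fixed-window extraction around 3'-UTR SNVs.

Each SNV that survives filtering is mapped from genomic to transcript
coordinates, then two fixed sequence contexts are cut from the spliced
transcript (RNA alphabet): a 71-nt structure window with the variant base
at position 36, and an 11-nt query with the variant base at position 6.
Variants too close to a transcript end for the full flank are skipped and
logged rather than padded.
"""

from __future__ import annotations

from .types import (
    NoMappingError,
    QueryPair,
    ReferenceMismatchError,
    TranscriptModel,
    UtrWindowPair,
    VariantCall,
    WindowSkip,
)

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

STRUCTURE_FLANK = 35  # 71-nt window, SNV at 1-based index 36
QUERY_FLANK = 5  # 11-nt query, SNV at 1-based index 6


def comp_dna(base: str) -> str:
    return base.translate(_DNA_COMPLEMENT)


def genomic_to_transcript(pos: int, t: TranscriptModel) -> int:
    """1-based transcript offset of a genomic position.

    Counts exonic bases from the transcript 5' end; on the minus strand
    counting runs from the rightmost exon leftward.  Raises NoMappingError
    for intronic or out-of-span positions.
    """
    upstream = 0
    for start, end in t.exons:
        if start <= pos <= end:
            within = pos - start + 1
            if t.strand == "+":
                return upstream + within
            # minus strand: exonic bases 3' (genomically right) of pos, then flip
            downstream_exonic = sum(
                e - max(s, pos) + 1 for s, e in t.exons if e >= pos
            )
            return downstream_exonic
        upstream += end - start + 1
    raise NoMappingError(
        f"genomic position {t.chrom}:{pos} is intronic or outside transcript {t.transcript_id}"
    )


def transcript_to_genomic(offset: int, t: TranscriptModel) -> int:
    """Inverse of genomic_to_transcript (1-based both ways)."""
    if offset < 1 or offset > t.exonic_length:
        raise NoMappingError(f"offset {offset} outside transcript {t.transcript_id}")
    exons = t.exons if t.strand == "+" else list(reversed(t.exons))
    remaining = offset
    for start, end in exons:
        length = end - start + 1
        if remaining <= length:
            return start + remaining - 1 if t.strand == "+" else end - remaining + 1
        remaining -= length
    raise AssertionError("unreachable")


def transcript_alleles(v: VariantCall, t: TranscriptModel) -> tuple[str, str]:
    """Variant alleles in transcript (coding-strand) orientation, DNA alphabet."""
    if t.strand == "+":
        return v.ref, v.alt
    return comp_dna(v.ref), comp_dna(v.alt)


def extract_window(
    t: TranscriptModel,
    offset: int,
    ref: str,
    alt: str,
    variant_key: tuple[str, int, str, str],
    flank: int = STRUCTURE_FLANK,
) -> UtrWindowPair | WindowSkip:
    """Cut the (2*flank+1)-nt reference/variant RNA windows around a transcript offset.

    ``ref``/``alt`` are single-base alleles already in transcript orientation
    (DNA).  Returns a WindowSkip record when the flank does not fit inside
    the transcript; raises ReferenceMismatchError when the transcript base
    at ``offset`` disagrees with ``ref``.
    """
    n = len(t.sequence)
    if offset - flank < 1 or offset + flank > n:
        return WindowSkip(
            gene_id=t.gene_id,
            variant_key=variant_key,
            reason=f"offset {offset} leaves <{flank} nt flank in transcript of length {n}",
        )
    tx_base = t.sequence[offset - 1]
    if tx_base != ref:
        raise ReferenceMismatchError(
            f"{t.transcript_id} offset {offset}: transcript has {tx_base}, variant ref is {ref}"
        )
    raw = t.sequence[offset - flank - 1 : offset + flank]
    ref_window = raw.replace("T", "U")
    alt_rna = alt.replace("T", "U")
    alt_window = ref_window[:flank] + alt_rna + ref_window[flank + 1 :]
    return UtrWindowPair(
        gene_id=t.gene_id,
        variant_key=variant_key,
        ref_window=ref_window,
        alt_window=alt_window,
        snv_index=flank + 1,
        tx_span=(offset - flank, offset + flank),
    )


def extract_query(
    t: TranscriptModel,
    offset: int,
    ref: str,
    alt: str,
    variant_key: tuple[str, int, str, str],
) -> QueryPair | WindowSkip:
    """11-nt reference/variant query with the SNV at 1-based index 6."""
    result = extract_window(t, offset, ref, alt, variant_key, flank=QUERY_FLANK)
    if isinstance(result, WindowSkip):
        return result
    return QueryPair(ref_query=result.ref_window, alt_query=result.alt_window, snv_index=6)


def apply_cooccurring(
    wp: UtrWindowPair, others: list[tuple[int, str]]
) -> UtrWindowPair:
    """Phase co-occurring SNVs into BOTH windows of a pair.

    ``others`` lists (transcript offset, alt base in transcript orientation,
    DNA or RNA) of additional variants; positions outside the window span or
    colliding with the pair's own SNV are ignored.  Because each phased base
    is written into reference and variant windows alike, the pair still
    differs only at its own SNV index.
    """
    from dataclasses import replace

    lo, hi = wp.tx_span
    own = lo + wp.snv_index - 1
    ref, alt = list(wp.ref_window), list(wp.alt_window)
    for off, base in others:
        if off < lo or off > hi or off == own:
            continue
        b = base.replace("T", "U")
        ref[off - lo] = b
        alt[off - lo] = b
    return replace(wp, ref_window="".join(ref), alt_window="".join(alt))


def window_pair_for_variant(
    v: VariantCall, t: TranscriptModel, flank: int = STRUCTURE_FLANK
) -> UtrWindowPair | WindowSkip:
    """Convenience: lift a genomic SNV into a window pair on its transcript."""
    offset = genomic_to_transcript(v.pos, t)
    ref, alt = transcript_alleles(v, t)
    return extract_window(t, offset, ref, alt, v.key, flank=flank)
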