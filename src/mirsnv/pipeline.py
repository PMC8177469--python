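"""End-to-end orchestration: filtered cohort variants -> consequence calls ->
3'-UTR windows -> miRNA gain/loss -> structure comparison -> reports."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

from . import consensus as cns
from .annotate import classify_against_models
from .fold import compare_pair
from .report import GainLossTable, aggregate_gainloss, write_reports
from .targets import consensus_sites, diff_sites
from .types import (
    ConsequenceCall,
    GainLossRecord,
    MatureMiRNA,
    RecurrentVariant,
    StructureDelta,
    TranscriptModel,
    UtrWindowPair,
    VariantCall,
    WindowSkip,
)
from .windows import (
    apply_cooccurring,
    extract_window,
    genomic_to_transcript,
    transcript_alleles,
)


@dataclass
class PipelineParams:
    dp_min: int = 100
    mq_min: float = 30.0
    k_min: int = 10
    control_mode: str = "strict"  # strict | ignore
    mode: str = "dual_caller"  # dual_caller | strict_all
    energy_threshold: float = -8.0
    fold_structures: bool = True
    # apply co-occurring recurrent SNVs of the same transcript jointly to
    # both windows of each pair (adjacent multi-SNV loci); off by default
    phase_adjacent: bool = False


@dataclass
class PipelineResult:
    recurrent: list[RecurrentVariant] = field(default_factory=list)
    consequences: list[ConsequenceCall] = field(default_factory=list)
    windows: list[UtrWindowPair] = field(default_factory=list)
    skips: list[WindowSkip] = field(default_factory=list)
    gainloss: list[GainLossRecord] = field(default_factory=list)
    deltas: list[StructureDelta] = field(default_factory=list)
    table: GainLossTable = field(default_factory=GainLossTable)


def analyse_variants(
    recurrent: list[RecurrentVariant],
    models: list[TranscriptModel],
    mirnas: list[MatureMiRNA],
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Annotate, window, target-scan and fold a list of recurrent variants."""
    params = params or PipelineParams()
    by_chrom = {m.chrom: m for m in models}
    result = PipelineResult(recurrent=recurrent)
    utr_variants: list[tuple[VariantCall, TranscriptModel, int, str, str]] = []
    for rv in recurrent:
        v = VariantCall(chrom=rv.chrom, pos=rv.pos, ref=rv.ref, alt=rv.alt)
        model = by_chrom.get(rv.chrom)
        if model is None:
            continue
        call = classify_against_models(v, [model])
        result.consequences.append(call)
        if call.category != "three_prime_utr" or not v.is_snv:
            continue
        offset = genomic_to_transcript(v.pos, model)
        ref_tx, alt_tx = transcript_alleles(v, model)
        utr_variants.append((v, model, offset, ref_tx, alt_tx))
    # co-occurring 3'-UTR SNVs per transcript, for optional joint phasing
    cooccurring: dict[str, list[tuple[int, str]]] = {}
    for v, model, offset, _, alt_tx in utr_variants:
        cooccurring.setdefault(model.chrom, []).append((offset, alt_tx))
    for v, model, offset, ref_tx, alt_tx in utr_variants:
        wp = extract_window(model, offset, ref_tx, alt_tx, v.key)
        if isinstance(wp, WindowSkip):
            result.skips.append(wp)
            continue
        if params.phase_adjacent:
            others = [o for o in cooccurring[model.chrom] if o[0] != offset]
            wp = apply_cooccurring(wp, others)
        result.windows.append(wp)
        ref_sites = consensus_sites(
            wp.ref_window, wp.snv_index, mirnas, params.energy_threshold
        )
        alt_sites = consensus_sites(
            wp.alt_window, wp.snv_index, mirnas, params.energy_threshold
        )
        result.gainloss.append(diff_sites(wp.gene_id, v.key, ref_sites, alt_sites))
        if params.fold_structures:
            result.deltas.append(compare_pair(wp))
    result.table = aggregate_gainloss(result.gainloss)
    return result


def run_pipeline(
    patients_dir: str | os.PathLike,
    controls_dir: str | os.PathLike,
    models: list[TranscriptModel],
    mirnas: list[MatureMiRNA],
    params: PipelineParams | None = None,
    out_dir: str | os.PathLike | None = None,
) -> PipelineResult:
    """Full run from per-sample dual-caller VCF directories to reports."""
    params = params or PipelineParams()
    recurrent = cns.consensus_cohort(
        patients_dir,
        controls_dir,
        dp_min=params.dp_min,
        mq_min=params.mq_min,
        k_min=params.k_min,
        control_mode=params.control_mode,
        mode=params.mode,
    )
    result = analyse_variants(recurrent, models, mirnas, params)
    if out_dir is not None:
        write_reports(
            result.table,
            Path(out_dir),
            consequences=result.consequences,
            skips=result.skips,
            deltas=result.deltas,
            run_params={
                "dp_min": params.dp_min,
                "mq_min": params.mq_min,
                "k_min": params.k_min,
                "control_mode": params.control_mode,
                "mode": params.mode,
                "energy_threshold": params.energy_threshold,
            },
        )
    return result
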