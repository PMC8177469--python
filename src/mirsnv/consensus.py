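"""Dual-caller VCF ingestion, QC filtering, caller intersection and cohort
recurrence rules.

The filtering scheme mirrors a dual-mapper RNA-seq variant-calling design:
per-sample call sets from two independent mappers are QC-filtered
(DP >= 100, MQ > 30 by default), intersected so only variants seen by both
callers survive, then screened across the cohort — kept only when carried
by at least ``k_min`` patients (default 10) and, in strict mode, by no
control sample.
"""

from __future__ import annotations

import os
from collections import defaultdict
from pathlib import Path

import pysam

from .types import ConfigurationError, RecurrentVariant, SampleCallSet, VariantCall

CALLER_SUFFIXES = {"caller_A": ".bowtie.vcf", "caller_B": ".bwa.vcf"}


def read_callset(path: str | os.PathLike, sample: str = "", caller: str = "") -> SampleCallSet:
    """Read one VCF into a SampleCallSet; multiallelic records are split per ALT.

    DP and MQ are taken from INFO; records missing either are kept with the
    field set to None (they are dropped later by qc_filter).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not sample:
        sample = path.name.split(".")[0]
    cs = SampleCallSet(sample=sample, caller=caller)
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            dp = rec.info.get("DP")
            mq = rec.info.get("MQ")
            for alt in rec.alts or ():
                if alt in (".", rec.ref):
                    continue
                cs.add(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        dp=int(dp) if dp is not None else None,
                        mq=float(mq) if mq is not None else None,
                        sample=sample,
                        caller=caller,
                    )
                )
    return cs


def read_sample_pair(directory: str | os.PathLike, sample: str) -> dict[str, SampleCallSet]:
    """Read the two per-caller VCFs (<sample>.bowtie.vcf / <sample>.bwa.vcf)."""
    directory = Path(directory)
    return {
        caller: read_callset(directory / f"{sample}{suffix}", sample=sample, caller=caller)
        for caller, suffix in CALLER_SUFFIXES.items()
    }


def qc_filter(callset: SampleCallSet, dp_min: int = 100, mq_min: float = 30.0) -> SampleCallSet:
    """Retain calls with DP >= dp_min and MQ > mq_min; missing DP/MQ dropped.

    DP is inclusive (a depth floor); MQ is strict.
    """
    out = SampleCallSet(sample=callset.sample, caller=callset.caller)
    for call in callset.calls.values():
        if call.dp is None or call.mq is None:
            continue
        if call.dp >= dp_min and call.mq > mq_min:
            out.add(call)
    return out


def intersect_callers(a: SampleCallSet, b: SampleCallSet) -> SampleCallSet:
    """Variants called by both callers; DP/MQ become the minimum across callers."""
    if a.sample != b.sample:
        raise ValueError(f"sample mismatch: {a.sample!r} vs {b.sample!r}")
    out = SampleCallSet(sample=a.sample, caller="consensus")
    for key in a.keys() & b.keys():
        ca, cb = a.calls[key], b.calls[key]
        dp = None if ca.dp is None or cb.dp is None else min(ca.dp, cb.dp)
        mq = None if ca.mq is None or cb.mq is None else min(ca.mq, cb.mq)
        out.add(
            VariantCall(
                chrom=ca.chrom, pos=ca.pos, ref=ca.ref, alt=ca.alt,
                dp=dp, mq=mq, sample=a.sample, caller="consensus",
            )
        )
    return out


def recurrence_filter(
    patient_sets: list[SampleCallSet],
    control_sets: list[SampleCallSet],
    k_min: int = 10,
    control_mode: str = "strict",
) -> list[RecurrentVariant]:
    """Cohort recurrence rule: keep variants carried by >= k_min patients.

    In ``strict`` control mode any variant seen in a control sample is
    excluded outright; in ``ignore`` mode controls are not consulted.
    """
    if control_mode not in {"strict", "ignore"}:
        raise ValueError(f"unknown control_mode {control_mode!r}")
    if k_min > len(patient_sets):
        raise ConfigurationError(
            f"k_min={k_min} exceeds the {len(patient_sets)} patient samples"
        )
    carriers: dict[tuple[str, int, str, str], set[str]] = defaultdict(set)
    for cs in patient_sets:
        for key in cs.keys():
            carriers[key].add(cs.sample)
    control_keys: set[tuple[str, int, str, str]] = set()
    if control_mode == "strict":
        for cs in control_sets:
            control_keys |= set(cs.keys())
    out = [
        RecurrentVariant(chrom=k[0], pos=k[1], ref=k[2], alt=k[3], carriers=frozenset(samples))
        for k, samples in carriers.items()
        if len(samples) >= k_min and k not in control_keys
    ]
    out.sort(key=lambda rv: rv.key)
    return out


def consensus_cohort(
    patients_dir: str | os.PathLike,
    controls_dir: str | os.PathLike,
    dp_min: int = 100,
    mq_min: float = 30.0,
    k_min: int = 10,
    control_mode: str = "strict",
    mode: str = "dual_caller",
    snv_only: bool = True,
) -> list[RecurrentVariant]:
    """Run the per-sample QC/consensus stages over VCF directories, then the
    cohort recurrence rule.

    ``mode='dual_caller'`` (default) intersects the two callers per sample and
    applies the >= k_min recurrence rule.  ``mode='strict_all'`` uses the
    second mapper's calls alone and requires presence in every patient.
    """
    if mode not in {"dual_caller", "strict_all"}:
        raise ValueError(f"unknown mode {mode!r}")

    def consensus_sets(directory: Path) -> list[SampleCallSet]:
        samples = sorted(
            {p.name.rsplit(".", 2)[0] for p in directory.glob("*.vcf")}
        )
        sets = []
        for sample in samples:
            pair = read_sample_pair(directory, sample)
            filtered = {c: qc_filter(cs, dp_min, mq_min) for c, cs in pair.items()}
            if mode == "dual_caller":
                merged = intersect_callers(filtered["caller_A"], filtered["caller_B"])
            else:
                merged = filtered["caller_B"]
            if snv_only:
                kept = SampleCallSet(sample=merged.sample, caller=merged.caller)
                for call in merged.calls.values():
                    if call.is_snv:
                        kept.add(call)
                merged = kept
            sets.append(merged)
        return sets

    patient_sets = consensus_sets(Path(patients_dir))
    control_sets = consensus_sets(Path(controls_dir))
    effective_k = len(patient_sets) if mode == "strict_all" else k_min
    return recurrence_filter(patient_sets, control_sets, effective_k, control_mode)
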