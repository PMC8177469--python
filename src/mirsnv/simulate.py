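"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure the downstream analysis assumes: a
cohort of patient and control samples (default 35 + 3), each with two
per-mapper VCF call sets; single-transcript gene models with non-empty
5'-UTR, CDS and 3'-UTR; a mature miRNA library with pairwise-distinct
seeds; and planted recurrent 3'-UTR SNVs that create (gain) or destroy
(loss) canonical 8mer seed-match sites for specific miRNAs.

Decoy variants are planted one class per filter — sub-recurrence, sub-DP,
sub-MQ, single-caller and control-shared — so that every filtering rule
has a test surface.  Genomic files use the DNA alphabet (T); RNA-level
material (miRNAs, windows) uses U.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pysam

from .targets import revcomp_rna, seed_sites
from .types import ConfigurationError, MatureMiRNA, TranscriptModel
from .windows import comp_dna, transcript_to_genomic

UTR5_MIN, UTR5_MAX = 60, 120
CDS_MIN, CDS_MAX = 90, 300  # multiples of 3
UTR3_MIN = 240
INTRON_MIN, INTRON_MAX = 60, 150
PAD = 50

DECOY_CLASSES = ("sub_recurrence", "sub_dp", "sub_mq", "single_caller", "control_shared")
CALLERS = ("caller_A", "caller_B")
CALLER_FILE_SUFFIX = {"caller_A": "bowtie", "caller_B": "bwa"}

# QC thresholds of the analysis the generator emulates; failing decoys are
# drawn strictly below these.
ANALYSIS_DP_MIN = 100
ANALYSIS_MQ_MIN = 30.0


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort."""

    n_patients: int = 35
    n_controls: int = 3
    n_genes: int = 96
    transcript_len_range: tuple[int, int] = (700, 1100)
    gc_content: float = 0.5
    n_mirnas: int = 60
    n_planted_gain: int = 30
    n_planted_loss: int = 30
    recurrence_range: tuple[int, int] = (10, 35)
    caller_overlap: float = 0.8
    dp_range: tuple[int, int] = (120, 400)
    mq_range: tuple[int, int] = (40, 60)
    rng_seed: int = 0
    decoy_fraction: float = 0.1  # per decoy class, relative to planted count
    n_background_per_sample: int = 10

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for name in ("gc_content", "caller_overlap", "decoy_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {val}")
        lo, hi = self.recurrence_range
        if not (1 <= lo <= hi <= self.n_patients):
            raise ConfigurationError(
                f"recurrence_range {self.recurrence_range} must lie within [1, n_patients]"
            )
        if self.transcript_len_range[0] < UTR5_MIN + CDS_MIN + UTR3_MIN:
            raise ConfigurationError(
                "transcript_len_range too small to hold CDS + both UTRs "
                f"(need >= {UTR5_MIN + CDS_MIN + UTR3_MIN})"
            )

    @property
    def patient_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_patients)]

    @property
    def control_ids(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_controls)]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted gain/loss variant."""

    gene_id: str
    tx_pos: int  # 1-based transcript position of the SNV
    ref: str  # transcript-orientation DNA alleles
    alt: str
    effect: str  # gain | loss | neutral
    mirna_id: str
    n_samples_carrying: int
    chrom: str = ""
    genomic_pos: int = 0
    genomic_ref: str = ""
    genomic_alt: str = ""


@dataclass(frozen=True)
class DecoyRecord:
    """A planted variant that must be rejected by exactly one filter."""

    gene_id: str
    decoy_class: str
    chrom: str
    genomic_pos: int
    genomic_ref: str
    genomic_alt: str
    n_patients_carrying: int
    n_controls_carrying: int


@dataclass(frozen=True)
class SimCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    dp: int
    mq: float


@dataclass
class Reference:
    """Gene models plus the genomic contigs they live on (one contig per gene)."""

    models: list[TranscriptModel]
    genome: dict[str, str]

    def model_by_chrom(self, chrom: str) -> TranscriptModel:
        for m in self.models:
            if m.chrom == chrom:
                return m
        raise KeyError(chrom)


@dataclass
class SimResult:
    config: SimConfig
    reference: Reference
    mirnas: list[MatureMiRNA]
    truth: list[TruthRecord]
    decoys: list[DecoyRecord]
    # sample -> caller -> list of calls
    calls: dict[str, dict[str, list[SimCall]]] = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n else ""


def gen_reference(config: SimConfig) -> Reference:
    """Generate one single-transcript gene per contig, deterministic in rng_seed."""
    rng = np.random.default_rng(config.rng_seed)
    models: list[TranscriptModel] = []
    genome: dict[str, str] = {}
    lo, hi = config.transcript_len_range
    for i in range(config.n_genes):
        tx_len = int(rng.integers(lo, hi + 1))
        utr5_cap = min(UTR5_MAX, tx_len - CDS_MIN - UTR3_MIN)
        utr5 = int(rng.integers(UTR5_MIN, utr5_cap + 1))
        cds_cap = min(CDS_MAX, tx_len - utr5 - UTR3_MIN) // 3 * 3
        cds_len = int(rng.integers(CDS_MIN // 3, cds_cap // 3 + 1)) * 3
        tx_seq = _random_dna(rng, tx_len, config.gc_content)

        n_exons = int(rng.integers(1, 4))
        # split the transcript into n_exons contiguous parts, each >= 50 nt
        while n_exons > 1 and tx_len < 50 * n_exons:
            n_exons -= 1
        cuts = sorted(rng.choice(np.arange(50, tx_len - 49), size=n_exons - 1, replace=False)) if n_exons > 1 else []
        bounds = [0, *map(int, cuts), tx_len]
        parts = [tx_seq[bounds[k] : bounds[k + 1]] for k in range(n_exons)]
        strand = "+" if rng.random() < 0.5 else "-"
        introns = [_random_dna(rng, int(rng.integers(INTRON_MIN, INTRON_MAX + 1)), config.gc_content) for _ in range(n_exons - 1)]
        pad5 = _random_dna(rng, PAD, config.gc_content)
        pad3 = _random_dna(rng, PAD, config.gc_content)

        if strand == "+":
            genomic_parts = parts
        else:
            genomic_parts = [str(revcomp_dna(p)) for p in reversed(parts)]
        pieces = [pad5]
        exon_ivals: list[tuple[int, int]] = []
        cursor = PAD + 1
        for k, part in enumerate(genomic_parts):
            exon_ivals.append((cursor, cursor + len(part) - 1))
            pieces.append(part)
            cursor += len(part)
            if k < len(introns):
                pieces.append(introns[k])
                cursor += len(introns[k])
        pieces.append(pad3)
        chrom = f"ctg{i:04d}"
        gene = f"GENE{i:04d}"
        model = TranscriptModel(
            gene_id=gene,
            transcript_id=f"TX{i:04d}",
            chrom=chrom,
            strand=strand,
            exons=exon_ivals,
            cds=(0, 0),  # placeholder until mapped below
            sequence=tx_seq,
        )
        cds_tx = (utr5 + 1, utr5 + cds_len)
        g1 = transcript_to_genomic(cds_tx[0], model)
        g2 = transcript_to_genomic(cds_tx[1], model)
        model.cds = (min(g1, g2), max(g1, g2))
        models.append(model)
        genome[chrom] = "".join(pieces)
    return Reference(models=models, genome=genome)


def revcomp_dna(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def gen_mirna_library(config: SimConfig) -> list[MatureMiRNA]:
    """Random mature miRNAs (19-24 nt) with pairwise-distinct seeds (2..8)."""
    if config.n_mirnas < 1:
        raise ConfigurationError("n_mirnas must be >= 1")
    rng = np.random.default_rng(config.rng_seed + 1)
    mirnas: list[MatureMiRNA] = []
    seen_seeds: set[str] = set()
    attempts = 0
    while len(mirnas) < config.n_mirnas:
        attempts += 1
        if attempts > 10000 * config.n_mirnas:
            raise RuntimeError("could not sample miRNAs with distinct seeds")
        length = int(rng.integers(19, 25))
        seq = "".join(rng.choice(list("ACGU"), size=length))
        seed = seq[1:8]
        if seed in seen_seeds:
            continue
        seen_seeds.add(seed)
        mirnas.append(MatureMiRNA(mirna_id=f"syn-miR-{len(mirnas) + 1:03d}", sequence=seq))
    return mirnas


def _cds_tx_span(model: TranscriptModel) -> tuple[int, int]:
    from .windows import genomic_to_transcript

    a = genomic_to_transcript(model.cds[0], model)
    b = genomic_to_transcript(model.cds[1], model)
    return (min(a, b), max(a, b))


def _set_tx_base(ref: Reference, model: TranscriptModel, tx_pos: int, base_dna: str) -> None:
    """Write one transcript-orientation base through to transcript and genome."""
    model.sequence = model.sequence[: tx_pos - 1] + base_dna + model.sequence[tx_pos:]
    gpos = transcript_to_genomic(tx_pos, model)
    gbase = base_dna if model.strand == "+" else comp_dna(base_dna)
    contig = ref.genome[model.chrom]
    ref.genome[model.chrom] = contig[: gpos - 1] + gbase + contig[gpos:]


def _window(seq: str, center: int, flank: int = 35) -> str:
    return seq[center - flank - 1 : center + flank].replace("T", "U")


def _site_overlapping(window: str, mirna: MatureMiRNA, index: int) -> list:
    return [s for s in seed_sites(window, mirna) if s.start <= index <= s.end]


def _plant_site_variant(
    ref: Reference,
    model: TranscriptModel,
    mirna: MatureMiRNA,
    effect: str,
    rng: np.random.Generator,
    max_attempts: int = 80,
) -> tuple[int, str, str]:
    """Plant one gain/loss SNV in the 3'-UTR; returns (tx_pos, ref, alt) in
    transcript orientation (DNA).

    The 8mer site (reverse complement of miRNA seed 2-8 followed by A) is
    written into the transcript; the SNV breaks one core position so that
    exactly one of the two windows carries the site.  Placement is validated
    with the seed scanner and retried on collision.
    """
    utr3_start = _cds_tx_span(model)[1] + 1
    tx_len = len(model.sequence)
    site_rna = revcomp_rna(mirna.seed) + "A"  # [m8-comp][core 2-7][A], 8 nt
    site_dna = site_rna.replace("U", "T")
    snv_lo = max(utr3_start + 8, 36 + 1)
    snv_hi = tx_len - 35 - 8
    if snv_hi < snv_lo:
        raise ConfigurationError(f"3'-UTR of {model.gene_id} too short to plant a window")
    original_tx = model.sequence
    original_contig = ref.genome[model.chrom]
    for _ in range(max_attempts):
        snv_off = int(rng.integers(snv_lo, snv_hi + 1))
        d = int(rng.integers(1, 7))  # break a core (seed 2-7 complement) position
        site_start = snv_off - d
        site_base = site_dna[d]
        other = [b for b in "ACGT" if b != site_base]
        broken_base = other[int(rng.integers(0, 3))]
        # write the full site, then break it at the SNV position on one side
        for k, b in enumerate(site_dna):
            _set_tx_base(ref, model, site_start + k, b)
        if effect == "gain":
            tx_ref, tx_alt = broken_base, site_base
        else:
            tx_ref, tx_alt = site_base, broken_base
        _set_tx_base(ref, model, snv_off, tx_ref)

        ref_win = _window(model.sequence, snv_off)
        alt_win = ref_win[:35] + tx_alt.replace("T", "U") + ref_win[36:]
        with_site = alt_win if effect == "gain" else ref_win
        without_site = ref_win if effect == "gain" else alt_win
        ok = (
            any(s.site_type == "8mer" for s in _site_overlapping(with_site, mirna, 36))
            and not _site_overlapping(without_site, mirna, 36)
        )
        if ok:
            return snv_off, tx_ref, tx_alt
        model.sequence = original_tx
        ref.genome[model.chrom] = original_contig
    raise RuntimeError(
        f"could not place a {effect} site for {mirna.mirna_id} in {model.gene_id} "
        f"after {max_attempts} attempts (seed-match collisions)"
    )


def _utr3_positions(model: TranscriptModel) -> tuple[int, int]:
    """Window-eligible 3'-UTR transcript span."""
    utr3_start = _cds_tx_span(model)[1] + 1
    return max(utr3_start, 36), len(model.sequence) - 35


def plant_variants(
    reference: Reference, mirna_lib: list[MatureMiRNA], config: SimConfig
) -> tuple[list[TruthRecord], list[DecoyRecord], dict[str, dict[str, list[SimCall]]]]:
    """Plant recurrent gain/loss SNVs, decoys and background noise.

    Mutates ``reference`` in place (planted sites become part of the
    reference sequence).  Returns truth records, decoy records and the
    per-sample per-caller call lists.
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    n_decoys_per_class = max(1, round(config.decoy_fraction * (config.n_planted_gain + config.n_planted_loss)))
    n_needed = config.n_planted_gain + config.n_planted_loss + n_decoys_per_class * len(DECOY_CLASSES)
    if config.n_genes < n_needed:
        raise ConfigurationError(
            f"n_genes={config.n_genes} < {n_needed} planted variants (one gene per variant)"
        )
    calls: dict[str, dict[str, list[SimCall]]] = {
        s: {c: [] for c in CALLERS} for s in (*config.patient_ids, *config.control_ids)
    }
    gene_order = list(rng.permutation(len(reference.models)))
    gene_iter = iter(gene_order)

    def emit(sample: str, caller: str, call: SimCall) -> None:
        calls[sample][caller].append(call)

    def genomic_alleles(model: TranscriptModel, tx_ref: str, tx_alt: str) -> tuple[str, str]:
        if model.strand == "+":
            return tx_ref, tx_alt
        return comp_dna(tx_ref), comp_dna(tx_alt)

    def sample_dp_mq(fail_dp: bool = False, fail_mq: bool = False) -> tuple[int, float]:
        if fail_dp:
            dp = int(rng.integers(10, ANALYSIS_DP_MIN))  # strictly below the DP floor
        else:
            dp = int(rng.integers(config.dp_range[0], config.dp_range[1] + 1))
        if fail_mq:
            mq = float(rng.integers(5, int(ANALYSIS_MQ_MIN) + 1))  # <= 30 fails strict MQ
        else:
            mq = float(rng.integers(config.mq_range[0], config.mq_range[1] + 1))
        return dp, mq

    truth: list[TruthRecord] = []
    effects = ["gain"] * config.n_planted_gain + ["loss"] * config.n_planted_loss
    for effect in effects:
        model = reference.models[next(gene_iter)]
        mirna = mirna_lib[int(rng.integers(0, len(mirna_lib)))]
        tx_pos, tx_ref, tx_alt = _plant_site_variant(reference, model, mirna, effect, rng)
        gpos = transcript_to_genomic(tx_pos, model)
        gref, galt = genomic_alleles(model, tx_ref, tx_alt)
        n_carry = int(rng.integers(config.recurrence_range[0], config.recurrence_range[1] + 1))
        carriers = rng.choice(config.patient_ids, size=n_carry, replace=False)
        for sample in sorted(carriers):
            for caller in CALLERS:
                dp, mq = sample_dp_mq()
                emit(sample, caller, SimCall(model.chrom, gpos, gref, galt, dp, mq))
        truth.append(
            TruthRecord(
                gene_id=model.gene_id, tx_pos=tx_pos, ref=tx_ref, alt=tx_alt,
                effect=effect, mirna_id=mirna.mirna_id, n_samples_carrying=n_carry,
                chrom=model.chrom, genomic_pos=gpos, genomic_ref=gref, genomic_alt=galt,
            )
        )

    decoys: list[DecoyRecord] = []
    for decoy_class in DECOY_CLASSES:
        for _ in range(n_decoys_per_class):
            model = reference.models[next(gene_iter)]
            lo, hi = _utr3_positions(model)
            tx_pos = int(rng.integers(lo, hi + 1))
            tx_ref = model.sequence[tx_pos - 1]
            tx_alt = [b for b in "ACGT" if b != tx_ref][int(rng.integers(0, 3))]
            gpos = transcript_to_genomic(tx_pos, model)
            gref, galt = genomic_alleles(model, tx_ref, tx_alt)
            k_min = config.recurrence_range[0]
            n_pat = max(1, k_min - 1) if decoy_class == "sub_recurrence" else int(
                rng.integers(k_min, config.n_patients + 1)
            )
            patients = sorted(rng.choice(config.patient_ids, size=n_pat, replace=False))
            n_ctl = 0
            for sample in patients:
                callers = ("caller_A",) if decoy_class == "single_caller" else CALLERS
                for caller in callers:
                    dp, mq = sample_dp_mq(
                        fail_dp=decoy_class == "sub_dp",
                        fail_mq=decoy_class == "sub_mq",
                    )
                    emit(sample, caller, SimCall(model.chrom, gpos, gref, galt, dp, mq))
            if decoy_class == "control_shared" and config.n_controls > 0:
                n_ctl = int(rng.integers(1, config.n_controls + 1))
                for sample in sorted(rng.choice(config.control_ids, size=n_ctl, replace=False)):
                    for caller in CALLERS:
                        dp, mq = sample_dp_mq()
                        emit(sample, caller, SimCall(model.chrom, gpos, gref, galt, dp, mq))
            decoys.append(
                DecoyRecord(
                    gene_id=model.gene_id, decoy_class=decoy_class, chrom=model.chrom,
                    genomic_pos=gpos, genomic_ref=gref, genomic_alt=galt,
                    n_patients_carrying=n_pat, n_controls_carrying=n_ctl,
                )
            )

    # low-recurrence background noise exercising the caller_overlap fraction
    planted_keys = {(t.chrom, t.genomic_pos) for t in truth} | {
        (d.chrom, d.genomic_pos) for d in decoys
    }
    if reference.models:
        for sample in (*config.patient_ids, *config.control_ids):
            for _ in range(config.n_background_per_sample):
                model = reference.models[int(rng.integers(0, len(reference.models)))]
                lo, hi = _utr3_positions(model)
                tx_pos = int(rng.integers(lo, hi + 1))
                gpos = transcript_to_genomic(tx_pos, model)
                if (model.chrom, gpos) in planted_keys:
                    continue
                tx_ref = model.sequence[tx_pos - 1]
                tx_alt = [b for b in "ACGT" if b != tx_ref][int(rng.integers(0, 3))]
                gref, galt = genomic_alleles(model, tx_ref, tx_alt)
                dp, mq = sample_dp_mq()
                shared = rng.random() < config.caller_overlap
                callers = CALLERS if shared else (CALLERS[int(rng.integers(0, 2))],)
                for caller in callers:
                    emit(sample, caller, SimCall(model.chrom, gpos, gref, galt, dp, mq))
    return truth, decoys, calls


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: reference, miRNA library, planted cohort calls."""
    reference = gen_reference(config)
    mirnas = gen_mirna_library(config)
    truth, decoys, calls = plant_variants(reference, mirnas, config)
    return SimResult(
        config=config, reference=reference, mirnas=mirnas,
        truth=truth, decoys=decoys, calls=calls,
    )


# ---------------------------------------------------------------------------
# serialization


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(models: list[TranscriptModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span
            fh.write(
                f"{m.chrom}\tmirsnv\tgene\t{span[0]}\t{span[1]}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\tmirsnv\tmRNA\t{span[0]}\t{span[1]}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for k, (start, end) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\tmirsnv\texon\t{start}\t{end}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.exon{k};Parent={m.transcript_id}\n"
                )
            fh.write(
                f"{m.chrom}\tmirsnv\tCDS\t{m.cds[0]}\t{m.cds[1]}\t.\t{m.strand}\t0\t"
                f"ID={m.transcript_id}.cds;Parent={m.transcript_id}\n"
            )


def _vcf_header(genome: dict[str, str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">')
    header.add_line('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">')
    for chrom, seq in genome.items():
        header.contigs.add(chrom, length=len(seq))
    return header


def write_vcfs(result: SimResult, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the two per-caller VCFs per sample under patients/ and controls/."""
    out_dir = Path(out_dir)
    dirs = {"patients": out_dir / "patients", "controls": out_dir / "controls"}
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)
    header = _vcf_header(result.reference.genome)
    for sample, per_caller in result.calls.items():
        group = "patients" if sample.startswith("P") else "controls"
        for caller, sim_calls in per_caller.items():
            path = dirs[group] / f"{sample}.{CALLER_FILE_SUFFIX[caller]}.vcf"
            with pysam.VariantFile(str(path), "w", header=header) as vcf:
                for c in sorted(sim_calls, key=lambda c: (c.chrom, c.pos, c.alt)):
                    rec = vcf.new_record(
                        contig=c.chrom, start=c.pos - 1, stop=c.pos,
                        alleles=(c.ref, c.alt),
                    )
                    rec.info["DP"] = c.dp
                    rec.info["MQ"] = c.mq
                    vcf.write(rec)
    return dirs


def write_simulation(result: SimResult, out_dir: str | os.PathLike) -> None:
    """Write genome/transcript FASTA, GFF3, miRNA FASTA, truth tables and VCFs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.reference.genome, out_dir / "genome.fa")
    write_fasta(
        {m.transcript_id: m.sequence for m in result.reference.models},
        out_dir / "transcripts.fa",
    )
    write_gff3(result.reference.models, out_dir / "models.gff3")
    write_fasta({m.mirna_id: m.sequence for m in result.mirnas}, out_dir / "mirnas.fa")
    with open(out_dir / "truth.tsv", "w") as fh:
        cols = [
            "gene_id", "chrom", "genomic_pos", "genomic_ref", "genomic_alt",
            "tx_pos", "ref", "alt", "effect", "mirna_id", "n_samples_carrying",
        ]
        fh.write("\t".join(cols) + "\n")
        for t in result.truth:
            fh.write("\t".join(str(getattr(t, c)) for c in cols) + "\n")
    with open(out_dir / "decoys.tsv", "w") as fh:
        cols = [
            "gene_id", "decoy_class", "chrom", "genomic_pos", "genomic_ref",
            "genomic_alt", "n_patients_carrying", "n_controls_carrying",
        ]
        fh.write("\t".join(cols) + "\n")
        for d in result.decoys:
            fh.write("\t".join(str(getattr(d, c)) for c in cols) + "\n")
    with open(out_dir / "config.json", "w") as fh:
        json.dump(asdict(result.config), fh, indent=2, default=list)
        fh.write("\n")
    write_vcfs(result, out_dir / "vcf")
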