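"""Readers for the standard on-disk inputs: FASTA, GFF3 gene models, miRNA FASTA."""

from __future__ import annotations

import os

import gffutils
from Bio import SeqIO

from .types import MatureMiRNA, TranscriptModel


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    with open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def read_mirna_fasta(path: str | os.PathLike, seed_start: int = 2, seed_end: int = 8) -> list[MatureMiRNA]:
    with open(path) as fh:
        return [
            MatureMiRNA(
                mirna_id=rec.id,
                sequence=str(rec.seq).upper().replace("T", "U"),
                seed_start=seed_start,
                seed_end=seed_end,
            )
            for rec in SeqIO.parse(fh, "fasta")
        ]


def _splice(genome: dict[str, str], chrom: str, exons: list[tuple[int, int]], strand: str) -> str:
    from .simulate import revcomp_dna

    parts = [genome[chrom][start - 1 : end] for start, end in exons]
    spliced = "".join(parts)
    return spliced if strand == "+" else revcomp_dna(spliced)


def read_gene_models(gff_path: str | os.PathLike, genome_fasta: str | os.PathLike) -> list[TranscriptModel]:
    """Build TranscriptModels from a GFF3 (gene/mRNA/exon/CDS) and genome FASTA.

    One transcript per gene is assumed; exon coordinates are 1-based
    inclusive.  The spliced sequence is oriented 5'->3' on the coding strand.
    """
    genome = read_fasta(genome_fasta)
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds_feats = list(db.children(mrna, featuretype="CDS"))
        if not exons or not cds_feats:
            raise ValueError(f"transcript {mrna.id} lacks exon or CDS features")
        cds = (min(f.start for f in cds_feats), max(f.end for f in cds_feats))
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=[(int(s), int(e)) for s, e in exons],
                cds=cds,
                sequence=_splice(genome, mrna.seqid, exons, mrna.strand),
            )
        )
    models.sort(key=lambda m: m.gene_id)
    return models
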