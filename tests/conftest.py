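"""Shared fixtures: crafted transcript models and a small synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from mirsnv.simulate import SimConfig, simulate
from mirsnv.types import MatureMiRNA, TranscriptModel


@pytest.fixture(scope="session")
def let7a() -> MatureMiRNA:
    return MatureMiRNA("let-7a", "UGAGGUAGUAGGUUGUAUAGUU")


def _random_dna(seed: int, n: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def single_exon_model() -> TranscriptModel:
    """Plus-strand single exon 1..300 with CDS 101..250."""
    return TranscriptModel(
        gene_id="GENE_SE",
        transcript_id="TX_SE",
        chrom="ctg_se",
        strand="+",
        exons=[(1, 300)],
        cds=(101, 250),
        sequence=_random_dna(11, 300),
    )


@pytest.fixture(scope="session")
def two_exon_model() -> TranscriptModel:
    """Plus-strand exons 1..100 and 201..300 (intron 101..200), CDS 31..262."""
    return TranscriptModel(
        gene_id="GENE_2E",
        transcript_id="TX_2E",
        chrom="ctg_2e",
        strand="+",
        exons=[(1, 100), (201, 300)],
        cds=(31, 262),  # spliced CDS length 132
        sequence=_random_dna(12, 200),
    )


@pytest.fixture(scope="session")
def minus_exon_model() -> TranscriptModel:
    """Minus-strand single exon 1..100, CDS 21..80 (spliced length 60)."""
    return TranscriptModel(
        gene_id="GENE_ME",
        transcript_id="TX_ME",
        chrom="ctg_me",
        strand="-",
        exons=[(1, 100)],
        cds=(21, 80),
        sequence=_random_dna(13, 100),
    )


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down cohort for fast unit tests (recurrence floor 5 of 12)."""
    return SimConfig(
        n_patients=12,
        n_controls=2,
        n_genes=30,
        n_mirnas=20,
        n_planted_gain=6,
        n_planted_loss=6,
        recurrence_range=(5, 12),
        rng_seed=42,
        n_background_per_sample=5,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate(small_config)
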