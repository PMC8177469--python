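"""Synthetic cohort generator: contracts, determinism, planted ground truth."""

import numpy as np
import pytest

from mirsnv.annotate import classify_variant
from mirsnv.simulate import (
    DECOY_CLASSES,
    SimConfig,
    gen_mirna_library,
    gen_reference,
    simulate,
)
from mirsnv.targets import seed_sites
from mirsnv.types import ConfigurationError, VariantCall
from mirsnv.windows import genomic_to_transcript


class TestSimConfig:
    def test_defaults_match_cohort_design(self):
        cfg = SimConfig()
        assert (cfg.n_patients, cfg.n_controls) == (35, 3)
        assert cfg.recurrence_range[0] == 10

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_patients": 0},
            {"gc_content": 1.5},
            {"recurrence_range": (10, 40)},  # exceeds n_patients
            {"transcript_len_range": (100, 200)},  # cannot hold UTRs + CDS
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimConfig(**kwargs)


class TestGenReference:
    def test_deterministic_given_seed(self):
        cfg = dict(n_genes=6, rng_seed=1)
        a, b = gen_reference(SimConfig(**cfg)), gen_reference(SimConfig(**cfg))
        assert a.genome == b.genome
        assert [(m.exons, m.cds, m.strand, m.sequence) for m in a.models] == [
            (m.exons, m.cds, m.strand, m.sequence) for m in b.models
        ]

    def test_empty_gene_set(self):
        ref = gen_reference(SimConfig(n_genes=0))
        assert ref.models == [] and ref.genome == {}

    def test_gc_one_yields_only_gc_bases(self):
        ref = gen_reference(SimConfig(n_genes=3, gc_content=1.0, rng_seed=2))
        for m in ref.models:
            assert set(m.sequence) <= {"G", "C"}

    def test_utrs_and_cds_all_non_empty(self):
        ref = gen_reference(SimConfig(n_genes=8, rng_seed=3))
        for m in ref.models:
            cds_tx = sorted(genomic_to_transcript(g, m) for g in m.cds)
            assert cds_tx[0] > 1  # 5'-UTR non-empty
            assert cds_tx[1] < len(m.sequence)  # 3'-UTR non-empty
            assert (cds_tx[1] - cds_tx[0] + 1) % 3 == 0

    def test_spliced_exons_reconstruct_transcript(self):
        from mirsnv.io import _splice

        ref = gen_reference(SimConfig(n_genes=8, rng_seed=4))
        for m in ref.models:
            assert _splice(ref.genome, m.chrom, m.exons, m.strand) == m.sequence


class TestMirnaLibrary:
    def test_contract(self):
        lib = gen_mirna_library(SimConfig(n_mirnas=5, rng_seed=7))
        assert len(lib) == 5
        assert len({m.mirna_id for m in lib}) == 5
        for m in lib:
            assert 19 <= len(m.sequence) <= 24
            assert set(m.sequence) <= set("ACGU")

    def test_deterministic(self):
        a = gen_mirna_library(SimConfig(n_mirnas=1, rng_seed=7))[0]
        b = gen_mirna_library(SimConfig(n_mirnas=1, rng_seed=7))[0]
        assert a.sequence == b.sequence

    def test_seeds_pairwise_distinct(self):
        lib = gen_mirna_library(SimConfig(n_mirnas=60, rng_seed=8))
        seeds = [m.sequence[1:8] for m in lib]
        assert len(set(seeds)) == len(seeds)


class TestPlantedTruth:
    def test_scanner_oracle_on_planted_windows(self, small_sim):
        """For every planted variant the seed scanner finds the target miRNA
        on exactly the window that is supposed to carry the site."""
        by_id = {m.mirna_id: m for m in small_sim.mirnas}
        models = {m.gene_id: m for m in small_sim.reference.models}
        for t in small_sim.truth:
            model = models[t.gene_id]
            seq = model.sequence
            ref_win = seq[t.tx_pos - 36 : t.tx_pos + 35].replace("T", "U")
            alt_win = ref_win[:35] + t.alt.replace("T", "U") + ref_win[36:]
            assert ref_win[35] == t.ref.replace("T", "U")
            mirna = by_id[t.mirna_id]
            with_site, without_site = (
                (alt_win, ref_win) if t.effect == "gain" else (ref_win, alt_win)
            )
            hit = [s for s in seed_sites(with_site, mirna) if s.start <= 36 <= s.end]
            assert any(s.site_type == "8mer" for s in hit)
            assert not [s for s in seed_sites(without_site, mirna) if s.start <= 36 <= s.end]

    def test_planted_positions_are_three_prime_utr(self, small_sim):
        models = {m.chrom: m for m in small_sim.reference.models}
        for t in small_sim.truth:
            v = VariantCall(chrom=t.chrom, pos=t.genomic_pos, ref=t.genomic_ref, alt=t.genomic_alt)
            assert classify_variant(v, models[t.chrom]).category == "three_prime_utr"

    def test_carriers_and_callers_by_construction(self, small_sim):
        cfg = small_sim.config
        for t in small_sim.truth:
            key = (t.chrom, t.genomic_pos, t.genomic_ref, t.genomic_alt)
            carriers = {
                s
                for s, per_caller in small_sim.calls.items()
                if all(
                    any((c.chrom, c.pos, c.ref, c.alt) == key for c in calls)
                    for calls in per_caller.values()
                )
            }
            assert len(carriers & set(cfg.patient_ids)) == t.n_samples_carrying
            assert not carriers & set(cfg.control_ids)
            lo, hi = cfg.recurrence_range
            assert lo <= t.n_samples_carrying <= hi

    def test_decoy_classes_have_their_designed_defect(self, small_sim):
        cfg = small_sim.config
        assert {d.decoy_class for d in small_sim.decoys} == set(DECOY_CLASSES)
        for d in small_sim.decoys:
            key = (d.chrom, d.genomic_pos, d.genomic_ref, d.genomic_alt)
            per_sample = {
                s: {
                    caller: [c for c in calls if (c.chrom, c.pos, c.ref, c.alt) == key]
                    for caller, calls in per_caller.items()
                }
                for s, per_caller in small_sim.calls.items()
            }
            patient_hits = {
                s for s in cfg.patient_ids if any(per_sample[s][c] for c in per_sample[s])
            }
            if d.decoy_class == "sub_recurrence":
                assert len(patient_hits) < cfg.recurrence_range[0]
            elif d.decoy_class == "sub_dp":
                assert all(
                    c.dp < 100
                    for s in patient_hits
                    for calls in per_sample[s].values()
                    for c in calls
                )
            elif d.decoy_class == "sub_mq":
                assert all(
                    c.mq <= 30.0
                    for s in patient_hits
                    for calls in per_sample[s].values()
                    for c in calls
                )
            elif d.decoy_class == "single_caller":
                assert all(not per_sample[s]["caller_B"] for s in patient_hits)
            elif d.decoy_class == "control_shared":
                assert any(per_sample[s]["caller_A"] for s in cfg.control_ids)

    def test_simulation_deterministic_in_memory(self, small_config):
        a, b = simulate(small_config), simulate(small_config)
        assert a.truth == b.truth
        assert a.decoys == b.decoys
        assert a.calls == b.calls
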