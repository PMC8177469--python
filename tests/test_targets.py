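"""Seed scanner, duplex energy DP and dual-predictor consensus."""

import numpy as np
import pytest

from mirsnv.targets import (
    DuplexParams,
    consensus_sites,
    diff_sites,
    duplex_brute_force,
    duplex_energy,
    revcomp_rna,
    seed_sites,
)
from mirsnv.types import MatureMiRNA, TargetSite


class TestSeedSites:
    def test_let7_canonical_8mer(self, let7a):
        # reverse complement of let-7a positions 2-8 is CUACCUC; +A gives the 8mer
        sites = seed_sites("AAAA" + "CUACCUCA" + "AAAA", let7a)
        assert [s.site_type for s in sites] == ["8mer"]
        assert (sites[0].start, sites[0].end) == (5, 12)

    @pytest.mark.parametrize(
        "window, expected_type",
        [
            ("AAAACUACCUCGAAA", "7mer-m8"),  # m8 match but G instead of the A1
            ("AAAAUACCUCAAAAA", "7mer-A1"),  # A1 but no m8 complement
            ("AAAAUACCUCGAAAA", "6mer"),  # bare core
        ],
    )
    def test_site_type_hierarchy(self, let7a, window, expected_type):
        sites = seed_sites(window, let7a)
        assert [s.site_type for s in sites] == [expected_type]

    def test_no_match_gives_empty_list(self, let7a):
        assert seed_sites("GGGGGGGGGGGGGGGG", let7a) == []

    def test_gu_not_allowed_in_seed(self, let7a):
        # replace one core C by U (would pair G:U with the miRNA): no site
        assert seed_sites("AAAACUAUCUCAAAAA", let7a) == []

    def test_masking_snv_base_only_affects_overlapping_sites(self, let7a):
        window = "AAAACUACCUCAAAAAAAAACUACCUCAAAAA"
        masked = window[:8] + "N" + window[9:]  # inside the first site
        orig = {(s.start, s.end, s.site_type) for s in seed_sites(window, let7a)}
        kept = {(s.start, s.end, s.site_type) for s in seed_sites(masked, let7a)}
        assert kept < orig
        assert all(not (s[0] <= 9 <= s[1]) for s in kept)


class TestDuplexEnergy:
    def test_perfect_gc_helix(self):
        # 4 GC pairs + 3 stacking bonuses
        energy, paired, pairing = duplex_energy("GGGG", "CCCC")
        assert energy == pytest.approx(-15.0)
        assert paired == 4
        assert pairing == "t1:m4,t2:m3,t3:m2,t4:m1"

    def test_no_complementarity_scores_zero(self):
        energy, paired, pairing = duplex_energy("AAAA", "GGGG")
        assert energy == 0.0 and paired == 0 and pairing == ""

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            duplex_energy("", "ACGU")

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(150):
            t = "".join(rng.choice(list("ACGU"), size=int(rng.integers(1, 9))))
            m = "".join(rng.choice(list("ACGU"), size=int(rng.integers(1, 9))))
            assert duplex_energy(t, m)[0] == pytest.approx(duplex_brute_force(t, m))

    def test_bulge_penalty_applied(self):
        # GG-A-GG vs CCCC: one unpaired target residue inside the duplex
        energy, paired, _ = duplex_energy("GGAGG", "CCCC")
        # 4 GC pairs, 2 stacks, one 1-nt bulge: -12 - 2 + 2 + 0.5 = -11.5
        assert energy == pytest.approx(-11.5)
        assert paired == 4


class TestConsensusSites:
    def test_planted_site_reported_with_both_predictors(self, let7a):
        window = ("A" * 31 + "CUACCUCA" + "A" * 32)  # site spans 32..39, contains 36
        sites = consensus_sites(window, 36, [let7a])
        assert len(sites) == 1
        site = sites[0]
        assert site.mirna_id == "let-7a" and site.site_type == "8mer"
        assert site.agreement == "both"
        assert site.duplex_energy <= -8.0
        assert site.paired_count >= 7

    def test_site_not_overlapping_snv_is_ignored(self, let7a):
        window = "CUACCUCA" + "A" * 63  # site at 1..8, SNV index 36
        assert consensus_sites(window, 36, [let7a]) == []

    def test_energy_threshold_gates_seed_matches(self, let7a):
        window = ("A" * 31 + "CUACCUCA" + "A" * 32)
        assert consensus_sites(window, 36, [let7a], energy_threshold=-50.0) == []

    def test_threshold_monotonicity(self, small_sim):
        """Tightening the energy threshold never adds consensus miRNAs."""
        rng = np.random.default_rng(3)
        lib = small_sim.mirnas
        for _ in range(10):
            window = "".join(rng.choice(list("ACGU"), size=71))
            prev: set[str] | None = None
            for thr in (-6.0, -10.0, -14.0, -18.0):
                ids = {s.mirna_id for s in consensus_sites(window, 36, lib, thr)}
                if prev is not None:
                    assert ids <= prev
                prev = ids

    def test_snv_index_validated(self, let7a):
        with pytest.raises(ValueError):
            consensus_sites("ACGU", 9, [let7a])


class TestDiffSites:
    @staticmethod
    def _site(mirna_id: str) -> TargetSite:
        return TargetSite(mirna_id=mirna_id, start=30, end=37, site_type="8mer")

    def test_gain_and_loss_directions(self):
        key = ("c", 1, "A", "G")
        rec = diff_sites("g", key, [], [self._site("let-7a")])
        assert rec.gained == {"let-7a"} and rec.lost == set()
        rec = diff_sites("g", key, [self._site("miR-X")], [])
        assert rec.lost == {"miR-X"} and rec.gained == set()

    def test_shared_sites_are_neither_gained_nor_lost(self):
        rec = diff_sites(
            "g", ("c", 1, "A", "G"),
            [self._site("m1"), self._site("m2")],
            [self._site("m2"), self._site("m3")],
        )
        assert rec.gained == {"m3"} and rec.lost == {"m1"}

    def test_antisymmetry_under_ref_alt_exchange(self):
        rng = np.random.default_rng(17)
        ids = [f"m{i}" for i in range(8)]
        for _ in range(25):
            ref = [self._site(i) for i in rng.choice(ids, size=4, replace=False)]
            alt = [self._site(i) for i in rng.choice(ids, size=4, replace=False)]
            fwd = diff_sites("g", ("c", 1, "A", "G"), ref, alt)
            rev = diff_sites("g", ("c", 1, "A", "G"), alt, ref)
            assert fwd.gained == rev.lost and fwd.lost == rev.gained
            assert not (fwd.gained & fwd.lost)


def test_duplex_params_gu_weaker_than_wc():
    p = DuplexParams()
    assert p.pair_energy("G", "U") == -1.0
    assert p.pair_energy("U", "G") == -1.0
    assert p.pair_energy("A", "C") is None


def test_revcomp_rna():
    assert revcomp_rna("GAGGUAG") == "CUACCUC"
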