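"""VCF ingestion, QC thresholds, caller intersection, cohort recurrence."""

import pytest

from mirsnv.consensus import intersect_callers, qc_filter, read_callset, recurrence_filter
from mirsnv.types import ConfigurationError, SampleCallSet, VariantCall

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">\n'
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n'
    "##contig=<ID=tx1,length=10000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(tmp_path, name, body_lines):
    path = tmp_path / name
    path.write_text(VCF_HEADER + "".join(line + "\n" for line in body_lines))
    return path


def make_set(sample, caller, *keys, dp=200, mq=50.0):
    cs = SampleCallSet(sample=sample, caller=caller)
    for chrom, pos, ref, alt in keys:
        cs.add(VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, dp=dp, mq=mq,
                           sample=sample, caller=caller))
    return cs


class TestReadCallset:
    def test_direct_field_mapping(self, tmp_path):
        path = write_vcf(tmp_path, "s1.bowtie.vcf", ["tx1\t120\t.\tG\tA\t50\t.\tDP=150;MQ=40"])
        cs = read_callset(path, sample="s1", caller="caller_A")
        assert len(cs) == 1
        call = cs.calls[("tx1", 120, "G", "A")]
        assert (call.dp, call.mq) == (150, 40.0)
        assert call.sample == "s1" and call.caller == "caller_A"

    def test_multiallelic_record_split_per_alt(self, tmp_path):
        path = write_vcf(tmp_path, "s1.bwa.vcf", ["tx1\t120\t.\tG\tA,C\t50\t.\tDP=150;MQ=40"])
        cs = read_callset(path)
        assert set(cs.keys()) == {("tx1", 120, "G", "A"), ("tx1", 120, "G", "C")}

    def test_empty_body_gives_empty_set(self, tmp_path):
        cs = read_callset(write_vcf(tmp_path, "s1.bowtie.vcf", []))
        assert len(cs) == 0

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_callset(tmp_path / "nope.vcf")

    def test_missing_info_fields_kept_with_none(self, tmp_path):
        path = write_vcf(tmp_path, "s1.bowtie.vcf", ["tx1\t120\t.\tG\tA\t50\t.\tDP=150"])
        cs = read_callset(path)
        call = cs.calls[("tx1", 120, "G", "A")]
        assert call.dp == 150 and call.mq is None


class TestQcFilter:
    @pytest.mark.parametrize(
        "dp, mq, kept",
        [
            (100, 40.0, True),  # DP floor is inclusive
            (99, 60.0, False),
            (500, 30.0, False),  # MQ is strict
            (100, 30.01, True),
            (None, 40.0, False),
            (150, None, False),
        ],
    )
    def test_boundaries(self, dp, mq, kept):
        cs = SampleCallSet(sample="s", caller="caller_A")
        cs.add(VariantCall(chrom="tx1", pos=10, ref="G", alt="A", dp=dp, mq=mq, sample="s"))
        out = qc_filter(cs, dp_min=100, mq_min=30.0)
        assert (len(out) == 1) is kept

    def test_output_is_subset(self):
        cs = make_set("s", "caller_A", ("tx1", 1, "A", "G"), ("tx1", 2, "C", "T"))
        assert set(qc_filter(cs).keys()) <= set(cs.keys())


class TestIntersectCallers:
    def test_shared_key_kept_alt_mismatch_dropped(self):
        a = make_set("s", "caller_A", ("tx1", 10, "G", "A"), ("tx1", 20, "G", "A"))
        b = make_set("s", "caller_B", ("tx1", 10, "G", "A"), ("tx1", 20, "G", "C"))
        merged = intersect_callers(a, b)
        assert set(merged.keys()) == {("tx1", 10, "G", "A")}

    def test_empty_side_gives_empty_intersection(self):
        a = make_set("s", "caller_A")
        b = make_set("s", "caller_B", ("tx1", 10, "G", "A"))
        assert len(intersect_callers(a, b)) == 0

    def test_commutative_and_idempotent(self):
        a = make_set("s", "caller_A", ("tx1", 10, "G", "A"), ("tx1", 30, "C", "T"))
        b = make_set("s", "caller_B", ("tx1", 10, "G", "A"))
        ab, ba = intersect_callers(a, b), intersect_callers(b, a)
        assert set(ab.keys()) == set(ba.keys()) <= set(a.keys())
        again = intersect_callers(ab, ab)
        assert set(again.keys()) == set(ab.keys())

    def test_dp_mq_take_minimum(self):
        a = make_set("s", "caller_A", ("tx1", 10, "G", "A"), dp=300, mq=60.0)
        b = make_set("s", "caller_B", ("tx1", 10, "G", "A"), dp=120, mq=45.0)
        call = intersect_callers(a, b).calls[("tx1", 10, "G", "A")]
        assert (call.dp, call.mq) == (120, 45.0)

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValueError):
            intersect_callers(make_set("s1", "caller_A"), make_set("s2", "caller_B"))


class TestRecurrenceFilter:
    @staticmethod
    def _cohort(n_with, n_without=0, key=("tx1", 10, "G", "A")):
        sets = [make_set(f"P{i}", "consensus", key) for i in range(n_with)]
        sets += [make_set(f"P{n_with + i}", "consensus") for i in range(n_without)]
        return sets

    def test_recurrence_threshold(self):
        kept = recurrence_filter(self._cohort(10, 25), [], k_min=10)
        assert len(kept) == 1 and kept[0].n_carriers == 10
        assert recurrence_filter(self._cohort(9, 26), [], k_min=10) == []

    def test_control_carrier_excluded_in_strict_mode(self):
        patients = self._cohort(35)
        controls = [make_set("C1", "consensus", ("tx1", 10, "G", "A"))]
        assert recurrence_filter(patients, controls, k_min=10, control_mode="strict") == []
        kept = recurrence_filter(patients, controls, k_min=10, control_mode="ignore")
        assert len(kept) == 1

    def test_k_min_one_ignore_controls_is_union_of_patient_keys(self):
        sets = [
            make_set("P0", "consensus", ("tx1", 1, "A", "G")),
            make_set("P1", "consensus", ("tx1", 2, "C", "T"), ("tx1", 1, "A", "G")),
            make_set("P2", "consensus"),
        ]
        kept = recurrence_filter(sets, [], k_min=1, control_mode="ignore")
        assert {rv.key for rv in kept} == {("tx1", 1, "A", "G"), ("tx1", 2, "C", "T")}

    def test_k_min_above_cohort_size_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            recurrence_filter(self._cohort(5), [], k_min=10)
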