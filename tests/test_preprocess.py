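import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ILLUMINA_3P
from oracles import oracle_trim_cut

from dimerqc.fastq_io import ReadRecord
from dimerqc.preprocess import (
    PlatformProfile,
    ReadClass,
    adapter_content_curve,
    classify_read,
    get_preset,
    overrepresented_sequences,
    process_sample,
    quality_trim_end,
)
from dimerqc.simulate import SimConfig, matching_profile, simulate_library


def read(bases, qual=40, read_id="r"):
    return ReadRecord(read_id, bases, tuple([qual] * len(bases)))


@pytest.fixture(scope="module")
def illumina():
    """Illumina profile without the 5'-primer pass (simulated constructs
    carry no residual primer)."""
    return matching_profile(SimConfig(platform="illumina"))


class TestQualityTrim:
    def test_high_quality_untrimmed(self):
        r = read("ACGTACGT", qual=40)
        assert quality_trim_end(r, 20) == r

    def test_uniformly_bad_read_trimmed_to_empty(self):
        assert len(quality_trim_end(read("ACGTACGT", qual=2), 20)) == 0

    def test_stated_example_matches_cut_point_oracle(self):
        quals = (40, 40, 10, 40, 5, 5)
        r = ReadRecord("r", "ACGTAC", quals)
        trimmed = quality_trim_end(r, 20)
        assert len(trimmed) == oracle_trim_cut(quals, 20)

    def test_random_quality_vectors_match_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 40))
            quals = tuple(int(q) for q in rng.integers(2, 41, size=n))
            r = ReadRecord("r", "A" * n, quals)
            assert len(quality_trim_end(r, 20)) == oracle_trim_cut(quals, 20)

    @given(
        quals=st.lists(st.integers(0, 41), min_size=1, max_size=60),
        threshold=st.integers(0, 41),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_trim_cut_property(self, quals, threshold):
        """Any quality vector, any threshold: the cut equals the brute-force
        partial-sum argmin, and trimming is idempotent."""
        quals = tuple(quals)
        r = ReadRecord("r", "A" * len(quals), quals)
        trimmed = quality_trim_end(r, threshold)
        assert len(trimmed) == oracle_trim_cut(quals, threshold)
        if len(trimmed):
            assert quality_trim_end(trimmed, threshold) == trimmed


class TestClassifyRead:
    def test_pure_adapter_start_is_dimer(self, illumina):
        r = read(ILLUMINA_3P + "ATCTCGTATGCCGTCTTCTGCTTGAAAAAAAAAAAAAAAAAA")
        cls, _ = classify_read(r, illumina)
        assert cls is ReadClass.DIMER

    def test_insert_plus_adapter_is_clean(self, illumina):
        insert = "ACGTACGTACGTACGTACGTAC"  # 22 nt
        r = read((insert + ILLUMINA_3P + "ATCTCGTATGCCGTCTTCTGCTTG")[:75].ljust(75, "G"))
        cls, trimmed = classify_read(r, illumina)
        assert cls is ReadClass.CLEAN and trimmed.bases == insert

    def test_sub_minimum_insert_is_short(self, illumina):
        r = read("ACGTACGTAC" + ILLUMINA_3P)  # 10-nt insert < 15
        cls, trimmed = classify_read(r, illumina)
        assert cls is ReadClass.SHORT and len(trimmed) == 10

    def test_quality_truncated_read_is_low_quality(self, illumina):
        bases = "ACGTACGTACGTACGTACGTACGTACGTAC"  # no adapter, 30 nt
        quals = tuple([40] * 10 + [3] * 20)  # bad 3' tail
        cls, trimmed = classify_read(ReadRecord("r", bases, quals), illumina)
        assert cls is ReadClass.LOW_QUALITY and len(trimmed) == 10

    def test_raw_short_read_without_adapter_is_short(self, illumina):
        cls, _ = classify_read(read("ACGTACGTAC"), illumina)
        assert cls is ReadClass.SHORT


class TestProcessSample:
    def test_exact_composition(self, illumina):
        """40 dimer + 10 short + 50 clean constructs: percentages are exact
        and loss is 50."""
        dimer = read((ILLUMINA_3P + "ATCTCGTATGCCGTCTTCTGCTTG").ljust(75, "A"))
        short = read("ACGTACGTAC" + ILLUMINA_3P)
        clean = read(("ACGTACGTACGTACGTACGTAC" + ILLUMINA_3P).ljust(75, "C"))
        reads = [dimer] * 40 + [short] * 10 + [clean] * 50
        qc = process_sample(iter(reads), illumina, "s")
        assert (qc.pct_dimer, qc.pct_short, qc.pct_read_loss) == (40.0, 10.0, 50.0)
        assert qc.n_raw == qc.n_dimer + qc.n_short + qc.n_lowq + qc.n_clean

    def test_loss_is_raw_minus_clean(self, illumina):
        dimer = read((ILLUMINA_3P + "ATCTCG").ljust(75, "A"))
        clean = read(("ACGTACGTACGTACGTACGTAC" + ILLUMINA_3P).ljust(75, "C"))
        qc = process_sample(iter([dimer] * 28 + [clean] * 72), illumina, "s")
        assert qc.pct_read_loss == 28.0 and qc.n_clean == 72

    def test_empty_stream_is_flagged(self, illumina):
        qc = process_sample(iter([]), illumina, "s")
        assert qc.is_empty and qc.n_raw == 0 and np.isnan(qc.pct_read_loss)

    @pytest.mark.parametrize("platform", ["illumina", "iontorrent"])
    def test_simulated_fraction_recovery_within_3_binomial_se(self, platform):
        cfg = SimConfig(
            n_reads=10_000,
            dimer_fraction=0.4,
            short_fraction=0.1,
            platform=platform,
            substitution_rate=0.01,
            indel_rate=0.01,
            seed=7,
        )
        reads, truth = simulate_library(cfg)
        qc = process_sample(iter(reads), matching_profile(cfg), "s")
        n = cfg.n_reads
        for key, got in [("dimer", qc.pct_dimer), ("short", qc.pct_short)]:
            want = 100 * truth.fractions[key]
            se = 100 * np.sqrt(truth.fractions[key] * (1 - truth.fractions[key]) / n)
            assert abs(got - want) <= 3 * se

    def test_clean_writer_receives_trimmed_reads(self, illumina):
        clean = read(("ACGTACGTACGTACGTACGTAC" + ILLUMINA_3P).ljust(75, "C"))
        sink = []
        process_sample(iter([clean] * 5), illumina, "s", clean_writer=sink.append)
        assert len(sink) == 5 and all(r.bases == "ACGTACGTACGTACGTACGTAC" for r in sink)


class TestDiagnostics:
    def test_all_dimers_curve_starts_at_100(self, illumina):
        reads = [read((ILLUMINA_3P + "ATCTCG").ljust(75, "A"))] * 20
        curve = adapter_content_curve(reads, illumina.adapter3)
        assert curve[0] == 100.0

    def test_no_adapter_curve_is_zero(self, illumina):
        curve = adapter_content_curve([read("ACGT" * 10)] * 5, illumina.adapter3)
        assert all(v == 0.0 for v in curve)

    def test_mixture_curve_by_construction(self, illumina):
        dimer = read((ILLUMINA_3P + "ATCTCG").ljust(75, "A"))
        ins22 = read(("ACGTACGTACGTACGTACGTAC" + ILLUMINA_3P).ljust(75, "C"))
        curve = adapter_content_curve([dimer] * 30 + [ins22] * 70, illumina.adapter3)
        assert curve[0] == 30.0 and curve[22] == 100.0
        assert all(b >= a for a, b in zip(curve, curve[1:]))
        assert max(curve) <= 100.0

    def test_overrepresented_single_sequence(self):
        out = overrepresented_sequences([read("ACGTACGT")] * 1000)
        assert out == [("ACGTACGT", 1000, 100.0)]

    def test_overrepresented_all_distinct(self, rng):
        reads = [
            read("".join(rng.choice(list("ACGT"), size=30)), read_id=f"r{i}")
            for i in range(1000)
        ]
        assert overrepresented_sequences(reads) == []

    def test_threshold_is_strict(self):
        """A sequence at exactly 0.1% is excluded ('higher than 0.1%')."""
        reads = [read("AAAAAAAA", read_id="dup")] + [
            read("ACGTACGT", read_id=f"r{i}") for i in range(999)
        ]
        out = overrepresented_sequences(reads, threshold_pct=0.1)
        assert all(seq != "AAAAAAAA" for seq, _, _ in out)


def test_profile_validation():
    preset = get_preset("illumina-truseq-smallrna")
    with pytest.raises(ValueError):
        PlatformProfile("bad", preset.adapter3, min_length=2, dimer_max_insert=5)
    with pytest.raises(KeyError):
        get_preset("nope")
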