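import numpy as np
import pytest

from artfastq.coverage import CoverageParameters
from artfastq.engine import (
    CoverageLedger,
    GenerationParameters,
    can_place_pair,
    generate_pairs,
    pass_over_window,
    reverse_complement,
    sample_template_length,
)
from artfastq.quality import QualitySource
from artfastq.reference import ReferenceSequence, open_window

UNIFORM_COVERAGE = CoverageParameters(
    peak_mean=5.0, sd_multiple=0.0, gc_bias_enabled=False
)


def small_params(**kw):
    defaults = dict(read_length=10, template_mean=30.0, template_sd=0.0, buffer_size=200)
    defaults.update(kw)
    return GenerationParameters(**defaults)


def run_engine(ref_seq, params, cov=UNIFORM_COVERAGE, seed=1, **kw):
    ref = ReferenceSequence("r", ref_seq)
    rng = np.random.default_rng(seed)
    q = QualitySource.uniform(40)
    ledgers = []
    pairs = list(
        generate_pairs(ref, params, cov, q, q, rng, ledger_out=ledgers, **kw)
    )
    return pairs, ledgers[0]


class TestTemplateLength:
    def test_degenerate_sd_always_returns_mean(self):
        params = small_params()
        rng = np.random.default_rng(0)
        assert {sample_template_length(params, rng) for _ in range(10)} == {30}

    def test_moments_recovered(self):
        params = GenerationParameters(
            read_length=100, template_mean=400.0, template_sd=25.0, buffer_size=10000
        )
        rng = np.random.default_rng(1)
        draws = np.array([sample_template_length(params, rng) for _ in range(100_000)])
        assert abs(draws.mean() - 400.0) < 0.5
        assert abs(draws.std() - 25.0) < 0.5

    def test_rejection_floor_at_twice_read_length(self):
        params = GenerationParameters(
            read_length=10, template_mean=20.0, template_sd=15.0, buffer_size=200
        )
        rng = np.random.default_rng(2)
        draws = [sample_template_length(params, rng) for _ in range(2000)]
        assert min(draws) >= 20

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="template.mean"):
            GenerationParameters(read_length=100, template_mean=150.0)
        with pytest.raises(ValueError, match="nucleobaseBufferSize"):
            GenerationParameters(buffer_size=100)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq, expected", [("ACGT", "ACGT"), ("AAC", "GTT"), ("ANT", "ANT"), ("", "")]
    )
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_involution(self):
        seq = "ACGTNACCGTTNA"
        assert reverse_complement(reverse_complement(seq)) == seq


class TestCanPlacePair:
    def test_zero_targets_block_everything(self):
        ledger = CoverageLedger(np.zeros(100, dtype=np.int64))
        assert not can_place_pair(ledger, 1, 30, 10)

    def test_fresh_ledger_accepts(self):
        ledger = CoverageLedger(np.ones(100, dtype=np.int64))
        assert can_place_pair(ledger, 1, 30, 10)

    def test_saturated_coordinates_rejected_after_one_placement(self):
        ledger = CoverageLedger(np.ones(100, dtype=np.int64))
        ledger.add_read(1, 10)
        ledger.add_read(21, 30)
        assert not can_place_pair(ledger, 1, 30, 10)
        # a template elsewhere is still fine
        assert can_place_pair(ledger, 31, 30, 10)

    def test_out_of_bounds_rejected(self):
        ledger = CoverageLedger(np.full(50, 5, dtype=np.int64))
        assert not can_place_pair(ledger, 30, 30, 10)
        assert not can_place_pair(ledger, 0, 30, 10)


class TestPassOverWindow:
    def test_saturated_ledger_accepts_nothing(self):
        ref = ReferenceSequence("r", "ACGT" * 50)
        ledger = CoverageLedger(np.zeros(200, dtype=np.int64))
        window = open_window(ref, 200)
        q = QualitySource.uniform(40)
        out = []
        accepted, _, _ = pass_over_window(
            window, ref, ledger, small_params(), q, q, False, False,
            np.random.default_rng(0), np.random.default_rng(0), 1, out,
        )
        assert accepted == 0 and out == []

    def test_each_pass_consumes_one_coverage_layer(self):
        """With targets of 2 everywhere and a reference exactly one template
        long, exactly two passes accept the single possible pair before the
        window saturates."""
        ref = ReferenceSequence("r", "ACGTACGTACGTACGTACGTACGTACGTAC")  # 30 bases
        params = small_params()  # template length fixed at 30
        ledger = CoverageLedger(np.full(30, 2, dtype=np.int64))
        window = open_window(ref, 200)
        q = QualitySource.uniform(40)
        per_pass = []
        pair_id = 1
        pending = None
        for _ in range(4):
            out = []
            accepted, pair_id, pending = pass_over_window(
                window, ref, ledger, params, q, q, False, False,
                np.random.default_rng(0), np.random.default_rng(0), pair_id, out,
                pending_length=pending,
            )
            per_pass.append(accepted)
        assert per_pass == [1, 1, 0, 0]


class TestGeneratePairs:
    def test_ground_truth_consistency_without_errors(self, fasta_factory):
        _, seq = fasta_factory(5000, seed=9)
        pairs, _ = run_engine(
            seq, GenerationParameters(read_length=50, template_mean=150.0,
                                      template_sd=10.0, buffer_size=1000)
        )
        assert pairs
        for p in pairs:
            assert p.mate1_seq == seq[p.mate1_start - 1 : p.mate1_end]
            assert reverse_complement(p.mate2_seq) == seq[p.mate2_start - 1 : p.mate2_end]
            assert p.template_length == p.mate2_end - p.mate1_start + 1
            assert len(p.mate1_seq) == len(p.mate2_seq) == 50

    def test_zero_targets_yield_empty_stream(self):
        cov = CoverageParameters(peak_mean=1e-9, sd_multiple=0.0, gc_bias_enabled=False)
        pairs, _ = run_engine("ACGT" * 500, small_params(), cov=cov)
        assert pairs == []

    def test_coverage_never_exceeds_target(self):
        """Brute-force recount of per-base coverage from the emitted pairs
        stays within the sampled targets everywhere."""
        cov = CoverageParameters(peak_mean=8.0, sd_multiple=0.3, gc_bias_enabled=True)
        pairs, ledger = run_engine("ACGT" * 1000, small_params(buffer_size=400), cov=cov)
        recount = np.zeros(4000, dtype=int)
        for p in pairs:
            recount[p.mate1_start - 1 : p.mate1_end] += 1
            recount[p.mate2_start - 1 : p.mate2_end] += 1
        assert (recount <= ledger.targets).all()
        assert (recount == ledger.achieved).all()

    def test_mean_coverage_approaches_uniform_target(self):
        """Uniform targets with zero spread: interior bases end up close to
        the cap, never above it."""
        cov = CoverageParameters(peak_mean=10.0, sd_multiple=0.0, gc_bias_enabled=False)
        pairs, ledger = run_engine("ACGT" * 2500, small_params(buffer_size=500), cov=cov)
        interior = ledger.achieved[100:-100]
        assert interior.max() <= 10
        assert interior.mean() >= 8.5

    def test_deterministic_given_seed(self):
        seq = "ACGTN" * 600
        params = small_params(buffer_size=300)
        first, _ = run_engine(seq, params, seed=12, errors_enabled=True)
        second, _ = run_engine(seq, params, seed=12, errors_enabled=True)
        assert first == second

    def test_reference_shorter_than_template_yields_no_reads(self):
        pairs, _ = run_engine("ACGTACGTACGTACG", small_params())
        assert pairs == []

    def test_filtered_n_pairs_consume_no_coverage(self):
        seq = "ACGT" * 5 + "N" * 10 + "ACGT" * 120  # N run near the start
        pairs, ledger = run_engine(seq, small_params(), filter_n=True)
        for p in pairs:
            assert "N" not in p.mate1_seq and "N" not in p.mate2_seq
        assert ledger.achieved[20:30].sum() == 0

    def test_pair_ids_are_sequential_and_named_after_record(self):
        pairs, _ = run_engine("ACGT" * 250, small_params())
        assert [p.pair_id for p in pairs] == list(range(1, len(pairs) + 1))
        assert all(p.read_id == f"r_{p.pair_id}" for p in pairs)
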