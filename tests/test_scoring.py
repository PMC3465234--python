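"""The four scoring variants, overlap mechanics, and scanner equivalence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mlconsensus.align import Alignment
from mlconsensus.consensus import consensus_from_alignment
from mlconsensus.scoring import (
    SCOPES,
    ConsensusScanner,
    ScoringConfig,
    enumerate_overlaps,
    make_overlap,
    match,
    match_pair,
    scan,
    scan_reference,
    score_overlap_basic,
    score_overlap_ic,
    score_overlap_icps,
    score_overlap_ps,
)

from conftest import oracle_scan, random_alignment_rows, random_dna


def consensus_of(*rows):
    return consensus_from_alignment(
        Alignment(rows=list(rows), site_ids=[f"r{i}" for i in range(len(rows))])
    )


class TestMatch:
    def test_exact_base_match(self):
        ov = make_overlap("A", consensus_of("A", "A"), 1)
        assert match(ov, 1) == 1

    def test_ambiguity_code_covers_base(self):
        cons = consensus_of("A", "C")  # column -> I (A/C)
        assert cons.sequence == "I"
        assert match(make_overlap("C", cons, 1), 1) == 1
        assert match(make_overlap("A", cons, 1), 1) == 1
        assert match(make_overlap("G", cons, 1), 1) == 0

    def test_gap_never_matches(self):
        cons = consensus_of("A---", "-C--", "--G-", "---T")  # all columns 0.25
        assert cons.sequence == "----"
        ov = make_overlap("ACGT", cons, 1)
        assert score_overlap_basic(ov) == 0

    def test_match_pair_is_two_or_zero(self):
        cons = consensus_of("AC", "AC")
        both = make_overlap("AC", cons, 1)
        assert match_pair(both, 1, 1) == 2
        one = make_overlap("AG", cons, 1)
        assert match_pair(one, 1, 1) == 0
        neither = make_overlap("GG", cons, 1)
        assert match_pair(neither, 1, 1) == 0


class TestOverlapScores:
    def test_basic_full_identity(self):
        cons = consensus_of("ACGTACGTAC")
        ov = make_overlap("ACGTACGTAC", cons, 1)
        assert score_overlap_basic(ov) == 10

    def test_basic_partial(self):
        cons = consensus_of("ACCTAAGCTG")
        ov = make_overlap("ACACCAAGTA", cons, 1)
        assert score_overlap_basic(ov) == 4

    def test_ic_weighting_uses_alignment_columns(self):
        cons = consensus_of("AAA", "AAA")  # three fully conserved columns
        ov = make_overlap("AAA", cons, 1)
        assert score_overlap_ic(ov, cons.column_ic) == pytest.approx(6.0)

    def test_ic_additivity_with_mismatch(self):
        cons = consensus_of("AC", "AT")  # col1 IC=2.0, col2 IC=1.0, symbol M
        assert cons.column_ic == pytest.approx([2.0, 1.0])
        ov = make_overlap("AG", cons, 1)  # match at col1 only
        assert score_overlap_ic(ov, cons.column_ic) == pytest.approx(2.0)

    def test_ps_small_scope_counts_adjacent_pairs(self):
        cons = consensus_of("ACG", "ACG")
        ov = make_overlap("ACG", cons, 1)
        assert score_overlap_ps(ov, 1) == 4  # pairs (1,2), (2,3), worth 2 each

    def test_ps_literal_triple_sum_at_full_scope(self):
        """For |w|=3 all-match the printed triple sum gives 8: s=1
        contributes pairs (1,2),(2,3); s=2 contributes (1,2),(1,3) only,
        because the first index is bounded by |w|-s."""
        cons = consensus_of("ACG", "ACG")
        ov = make_overlap("ACG", cons, 1)
        assert score_overlap_ps(ov, 2) == 8
        assert score_overlap_ps(ov, "full") == 8

    def test_ps_zero_without_matches(self):
        cons = consensus_of("AAA", "AAA")
        ov = make_overlap("CCC", cons, 1)
        for scope in (1, 2, "full"):
            assert score_overlap_ps(ov, scope) == 0

    def test_icps_weights_pairs_by_pair_ic(self):
        cons = consensus_of("AC", "AC")  # fully conserved pair, IC 4 bits
        ov = make_overlap("AC", cons, 1)
        assert score_overlap_icps(ov, 1, cons.pair_ic) == pytest.approx(8.0)

    def test_length_one_sequence_has_no_pairs(self):
        cons = consensus_of("ACG", "ACG")
        for scope in (1, 5, "full"):
            assert scan("A", cons, ScoringConfig(ps_scope=scope)) == 0.0


class TestScan:
    def test_identity_scan_equals_length(self):
        cons = consensus_of("ACGTACGT")
        assert scan("ACGTACGT", cons) == 8.0

    def test_scan_maximises_over_offsets(self):
        cons = consensus_of("AAAA")
        assert scan("TTAAAATT", cons) == 4.0

    @pytest.mark.parametrize("scope", [None, 1, 3, "full"])
    @pytest.mark.parametrize("use_ic", [False, True])
    def test_scanner_equals_literal_per_overlap_maximum(self, use_ic, scope):
        rng = np.random.default_rng(hash((use_ic, str(scope))) % 2**31)
        for _ in range(25):
            rows = random_alignment_rows(rng)
            cons = consensus_from_alignment(
                Alignment(rows=rows, site_ids=[f"r{i}" for i in range(len(rows))])
            )
            t = random_dna(rng, int(rng.integers(1, 13)))
            cfg = ScoringConfig(use_ic=use_ic, ps_scope=scope)
            assert scan(t, cons, cfg) == pytest.approx(
                scan_reference(t, cons, cfg), rel=1e-10, abs=1e-12
            )

    def test_min_overlap_restricts_offsets(self):
        cons = consensus_of("AAAA")
        # full-width overlap only: single-column overhangs excluded
        assert scan("AATT", cons, min_overlap=4) == 2.0

    def test_batched_variants_match_single_scans(self):
        cons = consensus_of("ACGTAC", "ACGTAC", "ACCTAC")
        scanner = ConsensusScanner(cons)
        variants = [(ic, s) for ic in (False, True) for s in (None, 1, 2, "full")]
        batch = scanner.scores("TACGT", variants)
        for (ic, s), value in zip(variants, batch):
            assert value == pytest.approx(
                scan("TACGT", cons, ScoringConfig(use_ic=ic, ps_scope=s))
            )


class TestMonotonicityAndBounds:
    @given(st.integers(0, 2**32 - 1))
    def test_scores_nonnegative_and_basic_bounded(self, seed):
        rng = np.random.default_rng(seed)
        rows = random_alignment_rows(rng)
        cons = consensus_from_alignment(
            Alignment(rows=rows, site_ids=[f"r{i}" for i in range(len(rows))])
        )
        t = random_dna(rng, int(rng.integers(1, 10)))
        basic = scan(t, cons)
        non_gap = sum(c != "-" for c in cons.sequence)
        assert 0.0 <= basic <= min(len(t), non_gap)
        for scope in (1, 3, "full"):
            assert scan(t, cons, ScoringConfig(ps_scope=scope)) >= 0.0

    def test_ps_nondecreasing_in_scope_per_overlap(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            rows = random_alignment_rows(rng)
            cons = consensus_from_alignment(
                Alignment(rows=rows, site_ids=[f"r{i}" for i in range(len(rows))])
            )
            t = random_dna(rng, int(rng.integers(2, 12)))
            for ov in enumerate_overlaps(t, cons):
                prev_ps, prev_icps = 0.0, 0.0
                for k in range(1, len(ov)):
                    ps = score_overlap_ps(ov, k)
                    icps = score_overlap_icps(ov, k, cons.pair_ic)
                    assert ps >= prev_ps and icps >= prev_icps - 1e-12
                    prev_ps, prev_icps = ps, icps


class TestScoringConfig:
    def test_scope_grid_has_twelve_settings(self):
        assert len(SCOPES) == 12

    def test_scope_normalisation(self):
        assert ScoringConfig(ps_scope="none").ps_scope is None
        assert ScoringConfig(ps_scope="3").ps_scope == 3
        assert ScoringConfig(ps_scope="FULL").ps_scope == "full"
        with pytest.raises(ValueError):
            ScoringConfig(ps_scope=0)
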