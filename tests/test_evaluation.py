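"""LOOCV mechanics, slot ROC, Wilcoxon signed ranks, plateau detection."""

import itertools

import numpy as np
import pytest
from scipy.stats import wilcoxon as scipy_wilcoxon

from mlconsensus.evaluation import (
    LooExperiment,
    build_roc,
    detect_plateau,
    loo_experiment,
    roc_curves_cross,
    run_configuration,
    run_sweep,
    wilcoxon_compare,
)
from mlconsensus.scoring import ScoringConfig
from mlconsensus.seqio import SpeciesDataset

from conftest import make_site_set


def exp(tf_id, site_id, fp, n_neg=10, config=ScoringConfig()):
    return LooExperiment(
        tf_id=tf_id,
        site_id=site_id,
        left_out_index=0,
        config=config,
        positive_score=1.0,
        fp=fp,
        n_negatives=n_neg,
    )


def dataset_of(*site_sets) -> SpeciesDataset:
    return SpeciesDataset("test", {s.tf_id: s for s in site_sets})


class TestLooExperiment:
    def test_tie_with_positive_is_not_a_false_positive(self):
        """Strict inequality: negatives scoring equal to the positive do
        not count as false positives."""
        tf = make_site_set("TF1", ["ACGTACGT", "ACGTACGA", "ACGTACGG"])
        # training on sites 2+3 gives consensus ACGTACGJ; the positive and
        # the first negative both score 7 (a tie), the second scores ~1
        negs = [make_site_set("TF2", ["ACGTACGC", "TTTTTTTT"])]
        res = loo_experiment(tf, 0, negs, ScoringConfig())
        assert res.positive_score == 7.0
        assert res.fp == 0 and res.n_negatives == 2

    def test_constructed_fp_counting(self):
        """With scores positive=2, negatives={0, 2, 3}: only the strictly
        greater negative is a false positive."""
        tf = make_site_set("TF1", ["AAAA", "AAAA", "AAAA", "AAAT"])
        negs = [make_site_set("TF2", ["GGGG", "TAAAA", "AAAAC", "CCCC"])]
        res = loo_experiment(tf, 3, negs, ScoringConfig())
        # positive "AAAT" scores 3; negatives: GGGG=0, TAAAA=4, AAAAC=4, CCCC=0
        assert res.positive_score == 3.0
        assert res.fp == 2 and res.n_negatives == 4

    def test_own_sequence_excluded_from_negatives(self):
        tf = make_site_set("TF1", ["AAAA", "AAAA", "AACA"])
        negs = [make_site_set("TF2", ["AAAA", "GGGG"])]  # AAAA is also a TF1 site
        res = loo_experiment(tf, 2, negs, ScoringConfig())
        assert res.n_negatives == 1

    def test_all_negatives_below_positive(self):
        tf = make_site_set("TF1", ["ACGTAC", "ACGTAC", "ACGTAC"])
        negs = [make_site_set("TF2", ["TTT", "GGG"])]
        res = loo_experiment(tf, 0, negs, ScoringConfig())
        assert res.fp == 0 and res.fpr == 0.0

    def test_too_few_training_sites_rejected(self):
        tf = make_site_set("TF1", ["ACGT", "ACGT"])
        with pytest.raises(ValueError):
            loo_experiment(tf, 0, [make_site_set("TF2", ["ACGT"])], ScoringConfig())


class TestRunConfiguration:
    def test_one_experiment_per_tf_site_pair(self):
        ds = dataset_of(
            make_site_set("TF1", ["ACGTA", "ACGTC", "ACGTG"]),
            make_site_set("TF2", ["TTTTA", "TTTTC", "TTTTG"]),
        )
        exps = run_configuration(ds, ScoringConfig())
        assert len(exps) == 6
        assert [e.tf_id for e in exps] == ["TF1"] * 3 + ["TF2"] * 3

    def test_configs_produce_paired_experiment_lists(self):
        ds = dataset_of(
            make_site_set("TF1", ["ACGTA", "ACGTC", "ACGTG"]),
            make_site_set("TF2", ["TTTTA", "TTTTC", "TTTTG"]),
        )
        a = ScoringConfig(ps_scope=1)
        b = ScoringConfig(ps_scope=2)
        res = run_sweep(ds, [a, b])
        keys_a = [(e.tf_id, e.site_id) for e in res[a]]
        keys_b = [(e.tf_id, e.site_id) for e in res[b]]
        assert keys_a == keys_b

    def test_undersized_tf_excluded(self):
        ds = dataset_of(
            make_site_set("TF1", ["ACGTA", "ACGTC", "ACGTG"]),
            make_site_set("TF2", ["TTTTA", "TTTTC"]),
        )
        exps = run_configuration(ds, ScoringConfig())
        assert {e.tf_id for e in exps} == {"TF1"}

    def test_imported_strategy_without_alignment_names_tf(self):
        ds = dataset_of(make_site_set("TF1", ["ACGTA", "ACGTC", "ACGTG"]))
        with pytest.raises(ValueError, match="TF1"):
            run_configuration(ds, ScoringConfig(alignment_strategy="imported"))


class TestRocCurve:
    def test_two_experiment_worked_example(self):
        """FPRs {0.0, 0.3} with 20 slots to 20%: every slot admits exactly
        the zero-FPR experiment, so TPR is 0.5 throughout and the
        sum-of-TPR area is 10."""
        exps = [exp("TF1", "s1", 0, 10), exp("TF1", "s2", 3, 10)]
        roc = build_roc(exps, fpr_max=0.2, n_slots=20)
        assert np.allclose(roc.tpr, 0.5)
        assert roc.auc == pytest.approx(10.0)

    def test_bounds(self):
        perfect = build_roc([exp("TF1", "s1", 0), exp("TF2", "s1", 0)], n_slots=20)
        assert perfect.auc == pytest.approx(20.0)
        hopeless = build_roc([exp("TF1", "s1", 9, 10)], n_slots=20)
        assert hopeless.auc == pytest.approx(0.0)

    def test_tpr_nondecreasing_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            exps = [
                exp(f"TF{t}", f"s{j}", int(rng.integers(0, 11)))
                for t in range(4)
                for j in range(int(rng.integers(1, 5)))
            ]
            roc = build_roc(exps)
            assert (np.diff(roc.tpr) >= -1e-12).all()

    def test_tf_averaging_before_species_averaging(self):
        # TF1 has two sites (0.5 each toward its mean), TF2 one site
        exps = [exp("TF1", "s1", 0), exp("TF1", "s2", 9, 10), exp("TF2", "s1", 0)]
        roc = build_roc(exps, n_slots=10)
        assert roc.tpr[-1] == pytest.approx((0.5 + 1.0) / 2)

    def test_crossing_curves_flagged(self):
        a = build_roc([exp("TF1", "s1", 0), exp("TF1", "s2", 9, 10)], n_slots=10)
        b = build_roc([exp("TF1", "s1", 1, 10), exp("TF1", "s2", 1, 10)], n_slots=10)
        assert roc_curves_cross(a, b)
        assert not roc_curves_cross(a, a)

    def test_empty_experiments_rejected(self):
        with pytest.raises(ValueError):
            build_roc([])


def paired_experiments(fps_a, fps_b):
    a = [exp("TF1", f"s{i}", fp) for i, fp in enumerate(fps_a)]
    b = [exp("TF1", f"s{i}", fp) for i, fp in enumerate(fps_b)]
    return a, b


class TestWilcoxon:
    def test_worked_example_rank_sums_and_z(self):
        """Differences {2, 4, 6, 8, -1}: ranks of |d| are 2,3,4,5,1 so
        W+ = 14, W- = 1 and the normal approximation gives Z ~ 1.753."""
        a, b = paired_experiments([2, 4, 6, 8, 0], [0, 0, 0, 0, 1])
        res = wilcoxon_compare(a, b)
        assert res.w_plus == 14 and res.w_minus == 1
        assert res.z == pytest.approx(1.753, abs=0.001)
        assert res.superior == "b"  # a accumulated the larger FP rank sum

    def test_all_zero_differences(self):
        a, b = paired_experiments([1, 2, 3], [1, 2, 3])
        res = wilcoxon_compare(a, b)
        assert res.n_pairs == 0 and res.superior is None and res.p_bound == "ns"

    def test_one_sided_extreme(self):
        a, b = paired_experiments([5, 6, 7, 8], [0, 1, 2, 3])
        res = wilcoxon_compare(a, b)
        assert res.w_minus == 0
        assert res.w_plus == 4 * 5 / 2

    def test_rank_sum_identity_after_zero_removal(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            fa = rng.integers(0, 5, size=8)
            fb = rng.integers(0, 5, size=8)
            a, b = paired_experiments(fa, fb)
            res = wilcoxon_compare(a, b)
            assert res.w_plus + res.w_minus == res.n_pairs * (res.n_pairs + 1) / 2

    def test_exact_p_agrees_with_sign_enumeration(self):
        """For n <= 10 the reported p equals twice the lower tail of the
        exact distribution over all 2^n sign assignments of the ranks."""
        from scipy.stats import rankdata

        rng = np.random.default_rng(17)
        checked = 0
        while checked < 25:
            n = int(rng.integers(3, 11))
            d = rng.integers(-6, 7, size=n)
            d = d[d != 0]
            if len(d) < 2:
                continue
            a, b = paired_experiments(np.abs(d) * (d > 0), np.abs(d) * (d < 0))
            res = wilcoxon_compare(a, b)
            ranks = rankdata(np.abs(d))
            w_small = min(res.w_plus, res.w_minus)
            count = sum(
                sum(r for r, s in zip(ranks, signs) if s) <= w_small + 1e-9
                for signs in itertools.product([0, 1], repeat=len(d))
            )
            expected = min(1.0, 2.0 * count / 2 ** len(d))
            assert res.p_value == pytest.approx(expected)
            checked += 1

    def test_matches_scipy_exact_without_ties(self):
        a, b = paired_experiments([10, 7, 5, 12, 20, 3], [1, 2, 3, 4, 5, 6])
        res = wilcoxon_compare(a, b)
        ref = scipy_wilcoxon(
            [10, 7, 5, 12, 20, 3], [1, 2, 3, 4, 5, 6], method="exact"
        )
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_unpaired_inputs_rejected(self):
        a = [exp("TF1", "s1", 1)]
        b = [exp("TF2", "s1", 1)]
        with pytest.raises(ValueError, match="paired"):
            wilcoxon_compare(a, b)


def track_from_fp_lists(per_scope_fps):
    """Build a scope -> experiments map from per-scope FP count lists."""
    return {
        scope: [exp("TF1", f"s{i}", fp) for i, fp in enumerate(fps)]
        for scope, fps in per_scope_fps.items()
    }


class TestPlateau:
    @staticmethod
    def _fps(n, value):
        return [value] * n

    def test_better_then_flat_then_worse(self):
        """Verdicts [better, ns, ns, worse] over scopes 1..5 place the
        plateau at scopes {2, 3, 4}."""
        n = 40
        track = track_from_fp_lists(
            {
                1: self._fps(n, 8),
                2: self._fps(n, 2),   # significantly better than scope 1
                3: self._fps(n, 2),   # no change
                4: self._fps(n, 2),   # no change
                5: self._fps(n, 8),   # significantly worse
            }
        )
        report = detect_plateau(track)
        assert report.verdicts == [None, "better", "ns", "ns", "worse"]
        assert report.plateau == [2, 3, 4]

    def test_all_flat_has_no_plateau(self):
        track = track_from_fp_lists({s: self._fps(10, 3) for s in (1, 2, 3, 4)})
        report = detect_plateau(track)
        assert report.plateau == []

    def test_consecutive_betters_use_literal_caption_rule(self):
        """Verdicts [better, better, ns]: the literal rule starts the
        plateau at the first better-followed-by-ns scope (scope 3); the
        alternative rule starts at the first better (scope 2)."""
        n = 40
        track = track_from_fp_lists(
            {
                1: self._fps(n, 12),
                2: self._fps(n, 6),
                3: self._fps(n, 1),
                4: self._fps(n, 1),
            }
        )
        report = detect_plateau(track)
        assert report.verdicts == [None, "better", "better", "ns"]
        assert report.plateau == [3, 4]
        alt = detect_plateau(track, rule="first_better")
        assert alt.plateau[0] == 2

    def test_reports_auc_peak_membership(self):
        n = 40
        track = track_from_fp_lists(
            {
                None: self._fps(n, 8),
                1: self._fps(n, 2),
                2: self._fps(n, 2),
                3: self._fps(n, 9),
            }
        )
        report = detect_plateau(track)
        assert report.max_auc_scope in (1, 2)
        assert report.peak_in_plateau

    def test_scope_ordering_none_numbers_full(self):
        track = track_from_fp_lists(
            {"full": self._fps(6, 1), 2: self._fps(6, 1), None: self._fps(6, 1)}
        )
        report = detect_plateau(track)
        assert report.scopes == [None, 2, "full"]

    def test_needs_three_scopes(self):
        with pytest.raises(ValueError):
            detect_plateau(track_from_fp_lists({1: [1], 2: [1]}))
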