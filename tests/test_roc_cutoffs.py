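import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tailorcut import (CutoffReport, IndexDistributions, auc_pairwise,
                       optimal_cutoff, roc_curve, screen_indices)


def make_dist(h0, h1, higher=False, name="idx"):
    return IndexDistributions(np.asarray(h0, float), np.asarray(h1, float),
                              higher, name)


def brute_force_auc(dist):
    s0, s1 = dist.badness_scores()
    total = 0.0
    for a in s1:
        for b in s0:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(s0) * len(s1))


def brute_force_best_youden(dist):
    """Exhaustive Youden maximization over all candidate cutoffs."""
    s0, s1 = dist.badness_scores()
    sign = -1.0 if dist.higher_is_better else 1.0
    best = -np.inf
    for t in np.unique(np.concatenate([dist.h0_values, dist.h1_values])):
        sens = np.mean(s1 > sign * t)
        spec = np.mean(s0 <= sign * t)
        best = max(best, sens + spec - 1.0)
    return best


class TestAUC:
    def test_fully_separated(self):
        d = make_dist([.01, .02], [.05, .06])
        assert roc_curve(d).auc == 1.0
        assert auc_pairwise(d) == 1.0

    def test_identical_samples_no_better_than_guess(self):
        d = make_dist([1, 2, 3], [1, 2, 3])
        assert roc_curve(d).auc == pytest.approx(0.5)
        assert auc_pairwise(d) == pytest.approx(0.5)

    def test_all_tied(self):
        d = make_dist([2, 2], [2, 2, 2])
        assert auc_pairwise(d) == 0.5
        assert roc_curve(d).auc == pytest.approx(0.5)

    def test_pairwise_concordance_example(self):
        # (2>1, 2>3, 4>1, 4>3) -> 3 of 4 concordant
        d = make_dist([1, 3], [2, 4])
        assert roc_curve(d).auc == pytest.approx(0.75)

    def test_higher_is_better_orientation(self):
        # for CFI-style indices low values are the "positive" side
        d = make_dist([.99, .98], [.90, .91], higher=True)
        assert roc_curve(d).auc == 1.0

    def test_curve_monotone_with_endpoints(self, rng):
        d = make_dist(rng.normal(0, 1, 40), rng.normal(1, 1, 40))
        pts = roc_curve(d).points
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)
        assert pts[0].tolist() == [0.0, 0.0] and pts[-1].tolist() == [1.0, 1.0]

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            make_dist([], [1.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.booleans())
    def test_trapezoid_equals_pairwise_concordance(self, seed, higher):
        rng = np.random.default_rng(seed)
        # coarse grid forces ties
        h0 = rng.integers(0, 8, rng.integers(2, 30)) / 7.0
        h1 = rng.integers(0, 8, rng.integers(2, 30)) / 7.0 + rng.normal(0, .2)
        d = make_dist(np.round(h0, 3), np.round(h1, 3), higher)
        assert roc_curve(d).auc == pytest.approx(brute_force_auc(d), abs=1e-12)
        assert auc_pairwise(d) == pytest.approx(brute_force_auc(d), abs=1e-12)


class TestOptimalCutoff:
    def test_separated_samples_perfect_classification(self):
        rep = optimal_cutoff(make_dist([.01, .02], [.05, .06]))
        assert rep.accuracy == 1.0
        assert rep.type1 == 0.0 and rep.type2 == 0.0
        assert rep.comparator == "<="

    def test_exhaustive_search_example(self):
        d = make_dist([1, 3], [2, 4])
        rep = optimal_cutoff(d)
        assert rep.youden == pytest.approx(0.5)
        assert rep.youden == pytest.approx(brute_force_best_youden(d))
        # Youden ties at cutoffs 1 and 3; higher specificity picks 3
        assert rep.cutoff == 3.0

    def test_swapped_classes_flagged(self):
        rep = optimal_cutoff(make_dist([.05, .06], [.01, .02]))
        assert rep.auc < 0.5
        assert rep.flagged
        assert "not endorsed" in rep.note

    def test_boundary_value_counts_as_pass(self):
        rep = optimal_cutoff(make_dist([1, 2], [3, 4]))
        assert rep.passes(rep.cutoff)
        assert not rep.passes(rep.cutoff + 1e-9)
        higher = optimal_cutoff(make_dist([.98, .99], [.90, .91], higher=True))
        assert higher.comparator == ">="
        assert higher.passes(higher.cutoff)
        assert not higher.passes(higher.cutoff - 1e-9)

    def test_accuracy_consistent_with_confusion_counts(self, rng):
        for _ in range(20):
            d = make_dist(rng.normal(0, 1, 25), rng.normal(.8, 1, 35))
            rep = optimal_cutoff(d)
            tp = np.sum(d.h1_values > rep.cutoff)
            fn = np.sum(d.h1_values <= rep.cutoff)
            tn = np.sum(d.h0_values <= rep.cutoff)
            fp = np.sum(d.h0_values > rep.cutoff)
            assert rep.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))
            assert rep.sensitivity == pytest.approx(tp / (tp + fn))
            assert rep.specificity == pytest.approx(tn / (tn + fp))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_maps_cutoff_and_preserves_auc(self, seed):
        rng = np.random.default_rng(seed)
        h0 = np.round(rng.normal(0, 1, 20), 2)
        h1 = np.round(rng.normal(1, 1, 20), 2)
        d = make_dist(h0, h1)
        d_t = make_dist(np.exp(h0), np.exp(h1))
        r, r_t = optimal_cutoff(d), optimal_cutoff(d_t)
        assert r_t.auc == pytest.approx(r.auc, abs=1e-12)
        assert r_t.cutoff == pytest.approx(np.exp(r.cutoff), rel=1e-12)
        assert r_t.sensitivity == r.sensitivity
        assert r_t.specificity == r.specificity


def _report(name, auc):
    return CutoffReport(index_name=name, auc=auc, cutoff=0.05,
                        comparator="<=", sensitivity=.9, specificity=.9,
                        accuracy=.9)


class TestScreenIndices:
    def test_all_perfect_tie_flagged_as_co_best(self):
        reports = [_report(n, 1.0) for n in ("chisq", "cfi", "rmsea", "srmr")]
        res = screen_indices(reports)
        assert len(res.kept) == 4 and not res.discarded
        assert sorted(res.best_indices) == ["cfi", "chisq", "rmsea", "srmr"]
        assert res.best_index is None  # no unique best

    def test_low_auc_discarded_best_identified(self):
        reports = [_report("chisq", .90), _report("cfi", .75),
                   _report("rmsea", .88), _report("srmr", .94)]
        res = screen_indices(reports, 0.80)
        assert [r.index_name for r in res.discarded] == ["cfi"]
        assert "below threshold" in res.discarded[0].note
        assert res.best_index == "srmr"

    def test_impossible_threshold_warns(self):
        res = screen_indices([_report("srmr", 1.0)], auc_threshold=1.01)
        assert not res.kept
        assert "not be strong enough" in res.warning

    def test_flagged_reports_never_kept(self):
        bad = _report("chisq", .95)
        bad.flagged = True
        res = screen_indices([bad])
        assert not res.kept
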