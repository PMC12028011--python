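import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bpfuse.evaluation import (
    auc,
    bootstrap_ci,
    confusion_counts,
    delong_test,
    evaluate_scores,
    ppv_npv,
    solve_prevalence,
)

from _oracles import auc_pair_counting, permutation_auc_diff_test


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_reference_value(self):
        # frozen from the exhaustive pair-counting oracle
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
        assert auc_pair_counting([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, size=4000)
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 15))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 5, size=n) / 4.0  # force ties
            assert auc(scores, labels) == pytest.approx(
                auc_pair_counting(scores, labels), abs=1e-12
            )

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            return
        scores = rng.normal(size=n)
        base = auc(scores, labels)
        assert auc(np.exp(scores), labels) == pytest.approx(base, abs=1e-12)
        assert auc(3 * scores - 7, labels) == pytest.approx(base, abs=1e-12)


class TestPpvNpv:
    def test_perfect_specificity(self):
        ppv, _ = ppv_npv(0.8, 1.0, 0.3)
        assert ppv == 1.0

    def test_balanced_identity(self):
        for s in (0.6, 0.75, 0.9):
            ppv, npv = ppv_npv(s, s, 0.5)
            assert ppv == pytest.approx(s)
            assert npv == pytest.approx(s)

    def test_published_radiologist_row(self):
        # sens 0.83, spec 0.71, PPV 81.95% -> NPV ~= 72.48%
        prev = solve_prevalence(0.83, 0.71, 0.8195)
        _, npv = ppv_npv(0.83, 0.71, prev)
        assert npv == pytest.approx(0.7248, abs=1e-4)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            ppv_npv(1.2, 0.5, 0.5)

    def test_degenerate_denominator(self):
        with pytest.raises(ValueError, match="denominator"):
            ppv_npv(0.5, 0.0, 0.0)


class TestSolvePrevalence:
    def test_backsubstitution(self):
        for se, sp, ppv in [(0.83, 0.71, 0.8195), (0.87, 0.65, 0.7315)]:
            p = solve_prevalence(se, sp, ppv)
            assert 0 < p < 1
            got, _ = ppv_npv(se, sp, p)
            assert got == pytest.approx(ppv, abs=1e-6)

    def test_known_values(self):
        assert solve_prevalence(0.83, 0.71, 0.8195) == pytest.approx(0.613, abs=1e-3)
        assert solve_prevalence(0.87, 0.65, 0.7315) == pytest.approx(0.523, abs=1e-3)

    def test_symmetric_identity(self):
        # sens = spec = s and ppv = s imply prevalence 1/2
        assert solve_prevalence(0.7, 0.7, 0.7) == pytest.approx(0.5)

    def test_unattainable(self):
        with pytest.raises(ValueError):
            solve_prevalence(0.8, 0.7, 1.0)


class TestBootstrapCi:
    def test_degenerate_collapse(self):
        lo, hi = bootstrap_ci([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        scores = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        a = bootstrap_ci(scores, labels, n_boot=300, seed=42)
        b = bootstrap_ci(scores, labels, n_boot=300, seed=42)
        assert a == b
        c = bootstrap_ci(scores, labels, n_boot=300, seed=43)
        assert a != c

    def test_interval_contains_point_auc(self):
        rng = np.random.default_rng(4)
        hits = 0
        for rep in range(100):
            n = 40
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.normal(size=n) + 0.8 * labels
            point = auc(scores, labels)
            lo, hi = bootstrap_ci(scores, labels, n_boot=200, seed=rep)
            hits += lo - 1e-12 <= point <= hi + 1e-12
        assert hits >= 95  # point estimate essentially always inside


class TestDelong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(5)
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        a, b, p = delong_test(scores, scores, labels)
        assert a == b
        assert p == 1.0

    def test_auc_estimates_consistent(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        sa = rng.normal(size=50) + labels
        sb = rng.normal(size=50) + 0.3 * labels
        auc_a, auc_b, _ = delong_test(sa, sb, labels)
        assert auc_a == pytest.approx(auc(sa, labels), abs=1e-12)
        assert auc_b == pytest.approx(auc(sb, labels), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        sa = rng.normal(size=40) + labels
        sb = rng.normal(size=40)
        _, _, p1 = delong_test(sa, sb, labels)
        _, _, p2 = delong_test(sb, sa, labels)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_unpaired_lengths_error(self):
        with pytest.raises(ValueError, match="paired"):
            delong_test([0.1, 0.2], [0.1, 0.2, 0.3], [0, 1, 1])

    def test_against_permutation_oracle(self):
        rng = np.random.default_rng(8)
        n = 80
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        signal = rng.normal(size=n)
        sa = signal + 0.9 * labels + 0.3 * rng.normal(size=n)
        sb = signal + 0.55 * labels + 0.3 * rng.normal(size=n)
        _, _, p_delong = delong_test(sa, sb, labels)
        p_perm = permutation_auc_diff_test(sa, sb, labels, n_perm=10_000, seed=0)
        # asymptotic vs exact-ish: agreement within Monte-Carlo/approximation slack
        assert p_delong == pytest.approx(p_perm, abs=0.05)


class TestEvalReport:
    def test_predictive_values_match_confusion_matrix(self):
        rng = np.random.default_rng(9)
        for rep in range(20):
            n = 60
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.clip(rng.normal(0.5, 0.25, size=n) + 0.2 * labels, 0, 1)
            report = evaluate_scores(scores, labels, n_boot=50, seed=rep)
            tp, fp, tn, fn = report.tp, report.fp, report.tn, report.fn
            if tp + fp:
                assert report.ppv == pytest.approx(tp / (tp + fp), abs=1e-9)
            if tn + fn:
                assert report.npv == pytest.approx(tn / (tn + fn), abs=1e-9)
            assert tp + fn == labels.sum()
            assert tn + fp == (1 - labels).sum()

    def test_transported_prevalence(self):
        scores = [0.1, 0.6, 0.7, 0.2, 0.9, 0.4]
        labels = [0, 1, 1, 0, 1, 0]
        report = evaluate_scores(scores, labels, prevalence=0.2, n_boot=50, seed=0)
        se, sp = report.sensitivity, report.specificity
        ppv, npv = ppv_npv(se, sp, 0.2)
        assert report.ppv == pytest.approx(ppv)
        assert report.npv == pytest.approx(npv)

    def test_confusion_counts_threshold(self):
        tp, fp, tn, fn = confusion_counts([0.4, 0.5, 0.6, 0.3], [0, 1, 1, 1], 0.5)
        assert (tp, fp, tn, fn) == (2, 0, 1, 1)
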