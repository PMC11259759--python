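"""Splits, metric panels, soft voting and the BVP/BSA quadrant analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyreact.errors import ValidationError
from polyreact.evaluate import (
    EnsembleSpec,
    MetricPanel,
    QuadrantSummary,
    SplitSpec,
    compute_metrics,
    quadrant_analysis,
    soft_vote,
    split_dataset,
    subgroup_metrics,
)


def brute_force_auc(labels, probs):
    """Pairwise-comparison AUC oracle: P(score_pos > score_neg) + ties/2."""
    pos = [p for y, p in zip(labels, probs) if y == 1]
    neg = [p for y, p in zip(labels, probs) if y == 0]
    wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


class TestSplit:
    @pytest.mark.parametrize("n, holdout", [(1664, 333), (2998, 600)])
    def test_combined_holdout_sizes(self, n, holdout):
        tr, va, te = split_dataset(list(range(n)), SplitSpec(seed=0))
        assert len(va) + len(te) == holdout
        assert len(tr) == n - holdout

    def test_ten_points_split_8_1_1(self):
        tr, va, te = split_dataset(list(range(10)), SplitSpec(seed=1))
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    def test_partition_is_exhaustive_and_disjoint(self):
        items = list(range(137))
        tr, va, te = split_dataset(items, SplitSpec(seed=3))
        assert sorted(tr + va + te) == items

    def test_reproducible_under_seed_and_sensitive_to_it(self):
        items = list(range(200))
        a = split_dataset(items, SplitSpec(seed=5))
        b = split_dataset(items, SplitSpec(seed=5))
        c = split_dataset(items, SplitSpec(seed=6))
        assert a == b
        assert a != c
        assert [len(x) for x in a] == [len(x) for x in c]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            split_dataset(list(range(9)), SplitSpec())

    def test_group_by_sequence_keeps_molecules_together(self, assay_points):
        tr, va, te = split_dataset(
            assay_points, SplitSpec(seed=2, group_by_sequence=True)
        )
        parts = [set(p.antibody.id for p in part) for part in (tr, va, te)]
        # an antibody id may appear in at most one part (panel ids are unique
        # per sequence set)
        assert not (parts[0] & parts[1]) and not (parts[0] & parts[2]) \
            and not (parts[1] & parts[2])


class TestMetrics:
    def test_perfect_separation(self):
        panel = compute_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert panel.auc == 1.0 and panel.accuracy == 1.0

    def test_chance_level_example(self):
        panel = compute_metrics([0, 0, 1, 1], [0.1, 0.9, 0.2, 0.8])
        assert panel.auc == pytest.approx(0.5)

    def test_matches_bruteforce_pairwise_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(20, 200))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            p = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert compute_metrics(y, p).auc == pytest.approx(
                brute_force_auc(y, p), abs=1e-12
            )

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 10_000)
        p = rng.random(10_000)
        assert compute_metrics(y, p).auc == pytest.approx(0.5, abs=0.02)

    def test_single_class_yields_no_auc(self):
        panel = compute_metrics([1, 1, 1], [0.2, 0.9, 0.7])
        assert panel.auc is None
        assert panel.precision == 1.0 and panel.n == 3


class TestSubgroups:
    def test_group_sizes_match_generator_counts(self, assay_points, domain_sets):
        probs = np.linspace(0.01, 0.99, len(assay_points))
        panels = subgroup_metrics(assay_points, probs, "specificity")
        n_bi = sum(p.antibody.is_bispecific() for p in assay_points)
        assert panels["bispecific"].n == n_bi
        assert panels["monospecific"].n == len(assay_points) - n_bi
        chains = subgroup_metrics(assay_points, probs, "chains", domain_sets)
        n_hc = sum(domain_sets[p.antibody.id].hc_only() for p in assay_points)
        assert chains["hc_only"].n == n_hc

    def test_subgroup_positives_partition_overall(self, assay_points, domain_sets):
        probs = np.linspace(0.01, 0.99, len(assay_points))
        overall = compute_metrics([p.label for p in assay_points], probs)
        panels = subgroup_metrics(assay_points, probs, "chains", domain_sets)
        assert sum(p.n for p in panels.values()) == overall.n
        assert sum(p.n_positive for p in panels.values()) == overall.n_positive

    def test_absent_group_is_omitted(self, assay_points):
        mono = [p for p in assay_points if not p.antibody.is_bispecific()]
        panels = subgroup_metrics(mono, np.linspace(0, 1, len(mono)), "specificity")
        assert "bispecific" not in panels and "monospecific" in panels


class TestSoftVote:
    def test_weights_favour_best_validation_auc(self):
        spec = EnsembleSpec(names=["antiberty", "prott5", "esm2"],
                            val_aucs=[0.883, 0.891, 0.878])
        assert spec.weights == [0.25, 0.5, 0.25]

    def test_identical_member_probabilities_pass_through(self):
        spec = EnsembleSpec(names=list("abc"), val_aucs=[0.7, 0.8, 0.9])
        p = np.array([0.3, 0.6])
        assert np.allclose(soft_vote([p, p, p], spec), p)

    def test_weighted_sum_example(self):
        spec = EnsembleSpec(names=list("abc"), val_aucs=[0.9, 0.8, 0.7])
        out = soft_vote([np.array([1.0]), np.array([0.0]), np.array([0.0])], spec)
        assert out[0] == pytest.approx(0.5)

    def test_tie_broken_by_registration_order(self):
        spec = EnsembleSpec(names=list("ab"), val_aucs=[0.8, 0.8])
        assert spec.weights == [0.5, 0.5]
        spec3 = EnsembleSpec(names=list("abc"), val_aucs=[0.8, 0.8, 0.7])
        assert spec3.weights == [0.5, 0.25, 0.25]

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_by_member_extremes(self, probs):
        spec = EnsembleSpec(names=list("abc"), val_aucs=[0.7, 0.9, 0.8])
        out = soft_vote([np.array([p]) for p in probs], spec)[0]
        assert min(probs) - 1e-12 <= out <= max(probs) + 1e-12

    def test_member_weight_mismatch_rejected(self):
        spec = EnsembleSpec(names=list("abc"), val_aucs=[0.7, 0.9, 0.8])
        with pytest.raises(ValidationError):
            soft_vote([np.array([0.5])], spec)


class TestQuadrants:
    def test_identical_assays_collapse_to_diagonal(self):
        folds = {f"ab{i}": 1.0 + i * 0.5 for i in range(8)}
        q = quadrant_analysis(folds, dict(folds))
        assert q.pearson_r == pytest.approx(1.0)
        assert q.pct_bvp_only == 0.0 and q.pct_bsa_only == 0.0

    def test_percentages_sum_to_hundred(self, rng):
        ids = [f"ab{i}" for i in range(50)]
        bvp = {i: float(rng.lognormal(0.5, 0.6)) for i in ids}
        bsa = {i: float(rng.lognormal(0.3, 0.6)) for i in ids}
        q = quadrant_analysis(bvp, bsa)
        total = (q.pct_clean_both + q.pct_bvp_only + q.pct_bsa_only
                 + q.pct_polyreactive_both)
        assert total == pytest.approx(100.0)

    def test_shared_charge_mechanism_gives_positive_correlation(
            self, small_panel, small_spec):
        from polyreact.synthetic import simulate_assay

        records, truths = small_panel
        points = simulate_assay(records, truths, small_spec)
        bvp = {p.antibody.id: p.fold_over_control for p in points
               if p.coating == "BVP" and p.concentration_nM == 667.0}
        bsa = {p.antibody.id: p.fold_over_control for p in points
               if p.coating == "BSA" and p.concentration_nM == 667.0}
        q = quadrant_analysis(bvp, bsa)
        assert q.pearson_r > 0.3
        assert q.n == len(records)

    def test_orphan_ids_listed(self):
        with pytest.raises(ValidationError, match="ab9"):
            quadrant_analysis({"ab1": 1.0, "ab9": 2.0}, {"ab1": 1.0})
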