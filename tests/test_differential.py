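from itertools import combinations

import numpy as np
import pytest
from scipy.stats import rankdata

from microtopics import (
    CountTable,
    DiffSettings,
    SampleMetadata,
    bh_adjust,
    genus_level_screen,
    linda_test,
    wilcoxon_rank_sum,
)


def exact_rank_sum_p(x, y):
    """Enumeration oracle: two-sided p = fraction of label arrangements whose
    rank sum (midranks) is at least as far from its null mean as observed."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, nx = len(pooled), len(x)
    mu = nx * (n + 1) / 2.0
    observed = abs(ranks[:nx].sum() - mu)
    count = 0
    total = 0
    for idx in combinations(range(n), nx):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= observed - 1e-9:
            count += 1
    return count / total


def brute_force_bh(p):
    """Step-up definition evaluated literally: q_(i) = min_{j>=i} p_(j) m/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestWilcoxonRankSum:
    def test_full_separation_exact(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0  # ranks 1+2+3
        assert p == pytest.approx(0.1)  # 2 of 20 arrangements as extreme

    def test_identical_groups(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_all_values_identical_gives_p_one(self):
        w, p = wilcoxon_rank_sum([5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == 1.0
        assert w == 2 * (2 + 3 + 1) / 2.0  # null mean of the rank sum

    def test_ties_use_midranks(self):
        w, _ = wilcoxon_rank_sum([1.0, 2.0], [1.0, 2.0])
        assert w == (1.5 + 3.5)  # midranks; equals the null mean

    @pytest.mark.parametrize("n_x,n_y", [(2, 3), (3, 3), (4, 4), (3, 5), (5, 5)])
    def test_exact_path_matches_enumeration_oracle(self, n_x, n_y):
        rng = np.random.default_rng(n_x * 10 + n_y)
        for _ in range(20):
            pooled = rng.permutation(np.arange(1.0, n_x + n_y + 1))
            x, y = pooled[:n_x], pooled[n_x:]
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBhAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 20))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


def _multinomial_cohort(rng, n_per_group, n_features, depth, case_boost=None):
    base = rng.dirichlet(np.full(n_features, 0.5))
    case = base.copy()
    if case_boost:
        j, mult = case_boost
        case[j] *= mult
        case /= case.sum()
    counts = np.vstack(
        [rng.multinomial(depth, case) for _ in range(n_per_group)]
        + [rng.multinomial(depth, base) for _ in range(n_per_group)]
    ).astype(float)
    ids = [f"s{i}" for i in range(2 * n_per_group)]
    table = CountTable(ids, [f"f{j}" for j in range(n_features)], counts)
    meta = SampleMetadata(ids, ["case"] * n_per_group + ["control"] * n_per_group)
    return table, meta


class TestLindaTest:
    def test_identical_features_identical_p(self):
        rng = np.random.default_rng(3)
        col = rng.integers(1, 100, 12).astype(float)
        counts = np.column_stack([col, col, rng.integers(1, 100, 12)])
        ids = [f"s{i}" for i in range(12)]
        table = CountTable(ids, ["a", "b", "c"], counts)
        meta = SampleMetadata(ids, ["case"] * 6 + ["control"] * 6)
        res = linda_test(table, meta)
        assert res[0].p == pytest.approx(res[1].p, rel=1e-12)
        assert res[0].effect == pytest.approx(res[1].effect, rel=1e-12)

    def test_constant_group_rejected(self):
        table, _ = _multinomial_cohort(np.random.default_rng(0), 5, 10, 1000)
        meta = SampleMetadata(table.sample_ids, ["case"] * 10)
        with pytest.raises(ValueError):
            linda_test(table, meta)

    def test_single_feature_rejected(self):
        ids = ["s1", "s2", "s3", "s4"]
        table = CountTable(ids, ["only"], np.array([[5.0], [6.0], [7.0], [8.0]]))
        meta = SampleMetadata(ids, ["case", "case", "control", "control"])
        with pytest.raises(ValueError, match="2 features"):
            linda_test(table, meta)

    def test_planted_effect_detected_others_null(self):
        rng = np.random.default_rng(11)
        detected = 0
        null_medians = []
        for _ in range(25):
            table, meta = _multinomial_cohort(rng, 50, 100, 10_000, case_boost=(0, 4.0))
            res = linda_test(table, meta, case_level="case")
            detected += res[0].p <= 0.05 and res[0].effect > 0
            null_medians.append(np.median([r.effect for r in res[1:]]))
        assert detected >= 23
        assert abs(np.median(null_medians)) < 0.1

    def test_pure_compositional_shift_corrected_to_zero(self):
        # every feature's composition identical between groups but case depths
        # doubled: after the log-depth transform and mode correction, effects
        # must vanish
        rng = np.random.default_rng(5)
        base = rng.dirichlet(np.full(60, 0.5))
        counts = np.vstack(
            [rng.multinomial(20_000, base) for _ in range(25)]
            + [rng.multinomial(10_000, base) for _ in range(25)]
        ).astype(float)
        ids = [f"s{i}" for i in range(50)]
        table = CountTable(ids, [f"f{j}" for j in range(60)], counts)
        meta = SampleMetadata(ids, ["case"] * 25 + ["control"] * 25)
        res = linda_test(table, meta)
        effects = np.array([r.effect for r in res])
        assert abs(np.median(effects)) < 0.05

    def test_significance_requires_both_thresholds(self):
        rng = np.random.default_rng(7)
        table, meta = _multinomial_cohort(rng, 20, 40, 5000, case_boost=(0, 6.0))
        res = linda_test(table, meta, DiffSettings(p_threshold=0.05, q_threshold=0.25))
        for r in res:
            assert r.significant == (r.p <= 0.05 and r.q <= 0.25)


class TestGenusLevelScreen:
    def test_identical_groups_not_significant(self):
        ids = [f"s{i}" for i in range(8)]
        counts = np.tile(np.array([10.0, 20.0, 30.0]), (8, 1))
        table = CountTable(ids, ["a", "b", "c"], counts)
        meta = SampleMetadata(ids, ["case"] * 4 + ["control"] * 4)
        res = genus_level_screen(table, meta)
        assert not any(r.significant for r in res)
        assert all(r.p == 1.0 for r in res)

    def test_large_planted_shift_detected_with_direction(self):
        rng = np.random.default_rng(13)
        table, meta = _multinomial_cohort(rng, 20, 30, 20_000, case_boost=(0, 8.0))
        res = genus_level_screen(table, meta, case_level="case")
        assert res[0].significant and res[0].effect > 0
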