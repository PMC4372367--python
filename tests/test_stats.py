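"""Nonparametric tests against brute-force enumeration oracles."""

from itertools import combinations, product

import numpy as np
import pytest
import scipy.stats

from dscq.errors import DataError
from dscq.quant import VOIMeasurement
from dscq.stats import (
    format_report,
    mann_whitney_u,
    median_iqr,
    results_to_frame,
    run_group_analysis,
    wilcoxon_signed_rank,
)


def mwu_enumeration_oracle(x, y):
    """Two-sided exact Mann-Whitney p by direct pair counting over all
    C(n+m, n) relabelings; independent of any rank formula."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)
        return min(u, n * m - u)

    u_obs = u_of(range(n))
    hits = sum(u_of(idx) <= u_obs + 1e-12 for idx in combinations(range(n + m), n))
    from math import comb

    return u_obs, hits / comb(n + m, n)


def wilcoxon_signflip_oracle(left, right):
    """Exact two-sided signed-rank p over all 2^k sign patterns."""
    d = np.asarray(left, float) - np.asarray(right, float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    s = ranks.sum()
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    hits = 0
    for signs in product([1, -1], repeat=len(d)):
        w = sum(r for r, sg in zip(ranks, signs) if sg > 0)
        if min(w, s - w) <= w_obs + 1e-12:
            hits += 1
    return w_obs, hits / 2 ** len(d)


class TestMannWhitney:
    def test_identical_samples_give_symmetric_u_and_p_one(self):
        x = [1.0, 2.0, 3.0]
        u, p = mann_whitney_u(x, x, mode="exact")
        assert u == pytest.approx(4.5)  # nm/2
        assert p == pytest.approx(1.0)

    def test_complete_separation_small_sample(self):
        # x=[1,2,3] vs y=[4,5,6]: U=0, exact two-sided p = 2/20
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(2 / 20)

    def test_exact_p_matches_enumeration_on_random_data(self, rng):
        for _ in range(50):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.5, 1, 5)
            u, p = mann_whitney_u(x, y, mode="exact")
            u_o, p_o = mwu_enumeration_oracle(x, y)
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o)

    def test_exact_handles_ties(self, rng):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 4.0]
        u, p = mann_whitney_u(x, y, mode="exact")
        u_o, p_o = mwu_enumeration_oracle(x, y)
        assert (u, p) == (pytest.approx(u_o), pytest.approx(p_o))

    def test_asymptotic_agrees_with_scipy(self, rng):
        # independent cross-check of the tie-corrected normal approximation
        for _ in range(20):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.3, 1, 12)
            _, p = mann_whitney_u(x, y, mode="asymptotic")
            p_sp = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert p == pytest.approx(p_sp, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            mann_whitney_u([], [1.0])

    def test_exact_p_is_permutation_valid(self, rng):
        # under the null, P(p <= t) <= t + enumeration granularity
        ps = []
        for _ in range(300):
            pooled = rng.normal(0, 1, 10)
            _, p = mann_whitney_u(pooled[:5], pooled[5:], mode="exact")
            ps.append(p)
        ps = np.array(ps)
        for t in (0.05, 0.1, 0.25, 0.5):
            granularity = 2 / 252  # minimal exact two-sided step at 5 vs 5
            assert (ps <= t).mean() <= t + granularity + 3 * np.sqrt(t * (1 - t) / 300)


class TestWilcoxon:
    def test_uniform_shift_k5(self):
        left = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        w, p, info = wilcoxon_signed_rank(left, left + 2.0, mode="exact")
        assert w == 0.0
        assert p == pytest.approx(2 / 32)
        assert info["k"] == 5

    def test_antisymmetric_differences_give_p_one(self):
        left = np.array([1.0, -1.0, 2.0, -2.0])
        right = np.zeros(4)
        w, p, _ = wilcoxon_signed_rank(left, right, mode="exact")
        assert p == pytest.approx(1.0)

    def test_zero_differences_dropped_and_counted(self):
        left = np.array([1.0, 2.0, 3.0, 4.0])
        right = np.array([1.0, 2.0, 1.0, 1.0])
        _, _, info = wilcoxon_signed_rank(left, right, mode="exact")
        assert info["n_zero"] == 2 and info["k"] == 2

    def test_all_zero_differences_undefined_not_p_one(self):
        left = np.array([1.0, 2.0])
        w, p, info = wilcoxon_signed_rank(left, left)
        assert np.isnan(p) and info["status"] == "undefined"

    def test_exact_p_matches_signflip_enumeration(self, rng):
        for _ in range(50):
            left = rng.normal(0, 1, 6)
            right = rng.normal(0.3, 1, 6)
            w, p, _ = wilcoxon_signed_rank(left, right, mode="exact")
            w_o, p_o = wilcoxon_signflip_oracle(left, right)
            assert w == pytest.approx(w_o)
            assert p == pytest.approx(p_o)

    def test_asymptotic_agrees_with_scipy(self, rng):
        left = rng.normal(0, 1, 30)
        right = left + rng.normal(0.2, 0.5, 30)
        _, p, _ = wilcoxon_signed_rank(left, right, mode="asymptotic")
        p_sp = scipy.stats.wilcoxon(
            left, right, correction=True, method="approx", alternative="two-sided"
        ).pvalue
        assert p == pytest.approx(p_sp, rel=1e-6)


class TestMedianIqr:
    def test_odd_n_exact_positions(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_constant_vector(self):
        assert median_iqr([7.0] * 6) == (7.0, 7.0, 7.0)

    def test_matches_sort_and_interpolate_oracle(self, rng):
        vals = rng.normal(0, 1, 100)
        med, q1, q3 = median_iqr(vals)
        srt = np.sort(vals)

        def interp(p):
            pos = p * (len(srt) - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            return srt[lo] * (1 - frac) + srt[min(lo + 1, len(srt) - 1)] * frac

        assert med == pytest.approx(interp(0.5))
        assert q1 == pytest.approx(interp(0.25))
        assert q3 == pytest.approx(interp(0.75))

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            median_iqr([])


def _measurements(rng, n_pat=5, n_ctl=15, shift=0.0, structures=("hippocampus",)):
    out = []
    for i in range(n_pat + n_ctl):
        group = "patient" if i < n_pat else "control"
        for structure in structures:
            for side in ("right", "left"):
                base = rng.normal(1.0, 0.1)
                if group == "patient":
                    base -= shift
                out.append(
                    VOIMeasurement(
                        f"s{i:02d}", group, structure, side, 10,
                        50 * base, 4 * base, base, base,
                    )
                )
    return out


class TestRunGroupAnalysis:
    def test_extreme_separation_all_significant(self, rng):
        res = run_group_analysis(_measurements(rng, shift=5.0))
        mw = [r for r in res if r.test == "mann_whitney"]
        assert mw and all(r.significant for r in mw)
        assert all(r.p_value == pytest.approx(min(p.p_value for p in mw)) for r in mw)

    def test_hand_listed_values_match_enumeration_oracle(self, rng):
        ms = _measurements(rng, n_pat=4, n_ctl=6, shift=0.15)
        res = run_group_analysis(ms, mode="exact")
        row = next(r for r in res if r.side == "right" and r.metric == "rcbf")
        pat = [m.rcbf for m in ms if m.group == "patient" and m.side == "right"]
        ctl = [m.rcbf for m in ms if m.group == "control" and m.side == "right"]
        u_o, p_o = mwu_enumeration_oracle(np.array(pat), np.array(ctl))
        assert row.statistic == pytest.approx(u_o)
        assert row.p_value == pytest.approx(p_o)

    def test_null_measurement_level_type_one_error(self, rng):
        # patients drawn from the control distribution: rejection ~ alpha
        n_rep, rejections, n_rows = 500, 0, 0
        for _ in range(n_rep):
            res = run_group_analysis(_measurements(rng, shift=0.0))
            mw = [r for r in res if r.test == "mann_whitney"]
            rejections += sum(r.significant for r in mw)
            n_rows += len(mw)
        rate = rejections / n_rows
        assert 0.02 <= rate <= 0.10

    def test_row_ordering_right_before_left(self, rng):
        res = run_group_analysis(
            _measurements(rng, structures=("amygdala", "hippocampus"))
        )
        mw = [r for r in res if r.test == "mann_whitney" and r.metric == "rcbf"]
        assert [(r.structure, r.side) for r in mw] == [
            ("amygdala", "right"), ("amygdala", "left"),
            ("hippocampus", "right"), ("hippocampus", "left"),
        ]

    def test_wilcoxon_rows_present_per_structure_metric(self, rng):
        res = run_group_analysis(_measurements(rng))
        wil = [r for r in res if r.test == "wilcoxon"]
        assert {(r.structure, r.metric) for r in wil} == {
            ("hippocampus", "rcbf"), ("hippocampus", "rcbv")
        }

    def test_missing_group_rejected(self, rng):
        ms = [m for m in _measurements(rng) if m.group == "control"]
        with pytest.raises(DataError):
            run_group_analysis(ms)

    def test_report_and_frame_outputs(self, rng):
        res = run_group_analysis(_measurements(rng, shift=0.5))
        text = format_report(res)
        assert "Mann-Whitney" in text and "hippocampus" in text
        df = results_to_frame(res)
        assert {"structure", "p_value", "significant"} <= set(df.columns)
        assert df.attrs["n_comparisons"] == len(df)
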