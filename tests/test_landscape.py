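"""High-5hmC delineation, correlations, stratum tests and metaplots."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oxyhmc.landscape import (
    HighSet,
    cpg_correlation,
    cpg_summary,
    recurrence,
    select_high,
    stratum_percentiles,
    tss_distance_bins,
    tss_metaplot,
)


class TestCpGSummary:
    def test_constant_row(self):
        m = pd.DataFrame([[0.2, 0.2, 0.2]], index=["cg0"])
        out = cpg_summary(m)
        assert np.isclose(out.loc["cg0", "mean"], 0.2)
        assert np.isclose(out.loc["cg0", "sd"], 0.0, atol=1e-15)

    def test_closed_form_two_samples(self):
        m = pd.DataFrame([[0.0, 1.0]], index=["cg0"])
        out = cpg_summary(m)
        assert np.isclose(out.loc["cg0", "sd"], np.sqrt(0.5))

    def test_against_streaming_oracle(self, rng):
        m = pd.DataFrame(rng.random((1000, 7)))
        out = cpg_summary(m)
        for i in rng.integers(0, 1000, 50):
            # Welford streaming recomputation
            mean, m2, n = 0.0, 0.0, 0
            for v in m.iloc[i]:
                n += 1
                d = v - mean
                mean += d / n
                m2 += d * (v - mean)
            assert abs(out["mean"].iloc[i] - mean) < 1e-12
            assert abs(out["sd"].iloc[i] - np.sqrt(m2 / (n - 1))) < 1e-12


class TestSelectHigh:
    def test_paper_scale_count(self, rng):
        """387,617 probes at the 1% fraction select exactly 3,876."""
        means = pd.Series(rng.random(387_617),
                          index=[f"cg{i:07d}" for i in range(387_617)])
        high = select_high(means, 0.01)
        assert len(high) == 3_876

    def test_top_k_of_distinct(self, rng):
        means = pd.Series(rng.permutation(1000) / 1000.0,
                          index=[f"cg{i:04d}" for i in range(1000)])
        high = select_high(means, 0.01)
        assert len(high) == 10
        assert set(high.probe_ids) == set(means.nlargest(10).index)
        assert high.threshold == min(means.nlargest(10))

    def test_tie_break_lexicographic(self):
        means = pd.Series(0.5, index=[f"cg{i:02d}" for i in range(12)])
        high = select_high(means, 0.5)
        assert high.probe_ids == [f"cg{i:02d}" for i in range(6)]

    def test_zero_selection_errors(self):
        with pytest.raises(ValueError):
            select_high(pd.Series([0.1, 0.2]), 0.01)

    def test_invariant_to_monotone_transform(self, rng):
        means = pd.Series(rng.random(500), index=[f"cg{i}" for i in range(500)])
        a = select_high(means, 0.05)
        b = select_high(np.exp(3 * means), 0.05)
        assert a.probe_ids == b.probe_ids


class TestRecurrence:
    def _high(self, ids, threshold):
        return HighSet(list(ids), threshold, 0.01)

    def test_inclusive_threshold(self):
        m = pd.DataFrame(0.09, index=["cg0"], columns=list("abcd"))
        counts, frac = recurrence(m, self._high(["cg0"], 0.09), 2)
        assert counts["cg0"] == 4 and frac == 1.0

    def test_below_threshold_everywhere(self):
        m = pd.DataFrame(0.01, index=["cg0"], columns=list("abcd"))
        counts, frac = recurrence(m, self._high(["cg0"], 0.09), 2)
        assert counts["cg0"] == 0 and frac == 0.0

    def test_counts_non_increasing_in_min_samples(self, rng):
        m = pd.DataFrame(rng.random((50, 10)), index=[f"cg{i}" for i in range(50)])
        high = self._high(m.index[:20], 0.5)
        fracs = [recurrence(m, high, k)[1] for k in range(1, 11)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_constructed_recurrent_fraction(self):
        """60% of high probes exceed the threshold in >= 15/30 samples."""
        rng = np.random.default_rng(0)
        n_high, n_samples = 200, 30
        idx = [f"cg{i:03d}" for i in range(n_high)]
        m = pd.DataFrame(0.01, index=idx, columns=[f"s{i}" for i in range(n_samples)])
        thr = 0.09
        recurrent = rng.choice(n_high, int(0.6 * n_high), replace=False)
        for i in range(n_high):
            k = 20 if i in set(recurrent) else 5  # 20 >= 15 samples over threshold
            cols = rng.choice(n_samples, k, replace=False)
            m.iloc[i, cols] = thr + 0.05
        high = self._high(idx, thr)
        _, frac = recurrence(m, high, 15)
        assert abs(frac - 0.6) < 0.05


class TestCpGCorrelation:
    def test_perfect_negative(self):
        pi3 = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["cg0"])
        pi2 = 1 - pi3
        assert np.isclose(cpg_correlation(pi3, pi2)["cg0"], -1.0)

    def test_perfect_positive(self):
        pi3 = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["cg0"])
        assert np.isclose(cpg_correlation(pi3, 0.5 * pi3)["cg0"], 1.0)

    def test_zero_variance_missing(self):
        pi3 = pd.DataFrame([[0.1, 0.1, 0.1]], index=["cg0"])
        pi2 = pd.DataFrame([[0.1, 0.2, 0.3]], index=["cg0"])
        assert np.isnan(cpg_correlation(pi3, pi2)["cg0"])

    def test_matches_scipy_rank_oracle(self, rng):
        pi3 = pd.DataFrame(rng.random((200, 8)))
        pi2 = pd.DataFrame(rng.random((200, 8)))
        # inject ties
        pi3.iloc[:50, 0] = pi3.iloc[:50, 1]
        ours = cpg_correlation(pi3, pi2)
        for i in range(200):
            rho, _ = stats.spearmanr(pi3.iloc[i], pi2.iloc[i])
            assert abs(ours.iloc[i] - rho) < 1e-12


class TestStratumPercentiles:
    def _annotation(self, strata):
        return pd.DataFrame(
            {"stratum": strata}, index=[f"cg{i}" for i in range(len(strata))]
        )

    def test_adjusted_alpha_four_strata(self, rng):
        strata = ["island", "shore", "shelf", "ocean"] * 25
        ann = self._annotation(strata)
        vals = pd.Series(rng.random(100), index=ann.index)
        _, _, alpha = stratum_percentiles(vals, ann)
        assert float(f"{alpha:.2g}") == 8.3e-03

    def test_null_flag_rate(self, rng):
        """Identical stratum distributions: pairwise flag rate ~ adjusted alpha."""
        strata = np.repeat(["island", "shore", "shelf", "ocean"], 1000)
        ann = self._annotation(strata)
        flagged = total = 0
        for rep in range(100):
            vals = pd.Series(rng.random(4000), index=ann.index)
            _, tests, _ = stratum_percentiles(vals, ann)
            flagged += tests["significant"].sum()
            total += len(tests)
        rate = flagged / total
        assert rate < 0.05  # adjusted alpha 0.0083, generous MC bound

    def test_shifted_stratum_all_pairs_flagged(self, rng):
        strata = np.repeat(["island", "shore", "shelf", "ocean"], 500)
        ann = self._annotation(strata)
        vals = pd.Series(rng.random(2000) * 0.3, index=ann.index)
        vals[ann["stratum"] == "ocean"] += 0.2
        _, tests, _ = stratum_percentiles(vals, ann)
        ocean_pairs = tests[(tests["stratum_a"] == "ocean") | (tests["stratum_b"] == "ocean")]
        assert ocean_pairs["significant"].all()

    def test_percentile_linear_interpolation(self):
        strata = ["island"] * 4 + ["ocean"] * 4
        ann = self._annotation(strata)
        vals = pd.Series([1.0, 2.0, 3.0, 4.0] * 2, index=ann.index)
        ptable, _, _ = stratum_percentiles(vals, ann, probs=(0.5,))
        assert ptable.loc["island", "p50"] == 2.5


class TestTssMetaplot:
    def _ann(self, dists):
        return pd.DataFrame(
            {"tss_distance": dists}, index=[f"cg{i}" for i in range(len(dists))]
        )

    def test_constant_matrix(self):
        ann = self._ann([-1000, 0, 500, 1999])
        m = pd.DataFrame(0.3, index=ann.index, columns=["a", "b"])
        out = tss_metaplot(m, ann)
        nz = out.dropna(subset=["mean"])
        assert np.allclose(nz["mean"], 0.3)

    def test_half_open_window(self):
        ann = self._ann([-2000, 2000])
        m = pd.DataFrame(0.5, index=ann.index, columns=["a"])
        out = tss_metaplot(m, ann)
        assert out["n_probes"].sum() == 1  # -2000 in, +2000 out
        assert out.iloc[0]["n_probes"] == 1

    def test_dip_recovered_at_tss(self, rng):
        dists = rng.integers(-2000, 2000, 3000)
        ann = self._ann(dists)
        base = 0.6 - 0.2 * np.exp(-(dists / 200.0) ** 2)  # dip of depth 0.2 at 0
        m = pd.DataFrame({"a": base, "b": base}, index=ann.index)
        out = tss_metaplot(m, ann)
        min_bin = out.loc[out["mean"].idxmin()]
        assert abs((min_bin["bin_start"] + min_bin["bin_end"]) / 2) <= 75

    def test_constant_shift(self, rng):
        dists = rng.integers(-2000, 2000, 500)
        ann = self._ann(dists)
        m = pd.DataFrame(rng.random((500, 3)), index=ann.index)
        a = tss_metaplot(m, ann)["mean"]
        b = tss_metaplot(m + 0.1, ann)["mean"]
        assert np.allclose(b.dropna(), a.dropna() + 0.1)


class TestTssDistanceBins:
    def test_all_at_zero(self):
        ann = pd.DataFrame({"tss_distance": [0, 0, 0]}, index=["a", "b", "c"])
        high = HighSet(["a", "b", "c"], 0.1, 0.01)
        out = tss_distance_bins(high, ann, [-1000, 1000])
        assert out["proportion"].sum() == 1.0
        assert out.loc[1, "proportion"] == 1.0  # the [-1000, 1000) bin

    def test_uniform_symmetric(self, rng):
        dists = rng.uniform(-10_000, 10_000, 20_000).astype(int)
        ann = pd.DataFrame({"tss_distance": dists},
                           index=[f"cg{i}" for i in range(20_000)])
        high = HighSet(list(ann.index), 0.1, 0.01)
        out = tss_distance_bins(high, ann, [-5000, 0, 5000])
        p = out["proportion"].to_numpy()
        assert abs(p[0] - p[3]) < 0.02 and abs(p[1] - p[2]) < 0.02

    def test_empty_high_set_errors(self):
        ann = pd.DataFrame({"tss_distance": [0]}, index=["a"])
        with pytest.raises(ValueError):
            tss_distance_bins(HighSet([], 0.0, 0.01), ann, [-1000, 1000])

    def test_breakpoints_must_increase(self):
        ann = pd.DataFrame({"tss_distance": [0]}, index=["a"])
        with pytest.raises(ValueError):
            tss_distance_bins(HighSet(["a"], 0.1, 0.01), ann, [1000, -1000])
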