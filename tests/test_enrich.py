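"""Interval overlap, CMH, Fisher, multi-set ranking and tertile tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oxyhmc.enrich import (
    StratifiedTable,
    build_stratified_table,
    cmh,
    fisher_exact,
    multi_set_enrichment,
    overlap_flags,
    tertile_enrichment,
)
from oxyhmc.io import RegionSet


def fisher_p_enumeration(a, b, c, d):
    """Oracle: two-sided Fisher p by full hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {x: stats.hypergeom.pmf(x, n, c1, r1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestOverlapFlags:
    def _ann(self, positions, chrom="chr1"):
        return pd.DataFrame(
            {"chromosome": chrom, "position": positions},
            index=[f"cg{i}" for i in range(len(positions))],
        )

    def test_start_exclusive_end_inclusive(self):
        ann = self._ann([100, 101, 200, 201])
        flags = overlap_flags(ann, RegionSet("x", [("chr1", 100, 200)]))
        assert list(flags) == [False, True, True, False]

    def test_orphan_chromosome_warns(self):
        ann = self._ann([100])
        with pytest.warns(UserWarning, match="chr9"):
            overlap_flags(ann, RegionSet("x", [("chr9", 1, 10)]))

    def test_matches_brute_force_oracle(self, rng):
        positions = rng.integers(1, 100_000, 10_000)
        chroms = rng.choice(["chr1", "chr2", "chr3"], 10_000)
        ann = pd.DataFrame(
            {"chromosome": chroms, "position": positions},
            index=[f"cg{i}" for i in range(10_000)],
        )
        starts = rng.integers(0, 100_000, 1000)
        lengths = rng.integers(1, 500, 1000)
        ivs = [
            (c, int(s), int(s + ln))
            for c, s, ln in zip(rng.choice(["chr1", "chr2", "chr3"], 1000), starts, lengths)
        ]
        flags = overlap_flags(ann, RegionSet("r", ivs)).to_numpy()
        # quadratic all-pairs scan
        brute = np.zeros(10_000, dtype=bool)
        for i, (c, p) in enumerate(zip(chroms, positions)):
            for ic, s, e in ivs:
                if ic == c and s < p <= e:
                    brute[i] = True
                    break
        assert (flags == brute).all()


class TestCMH:
    def test_null_table(self):
        t = StratifiedTable(*[np.full(4, 10)] * 4)
        res = cmh(t)
        assert np.isclose(res.or_estimate, 1.0)
        assert np.isclose(res.p, 1.0)

    def test_hand_formula_or_four(self):
        """4 identical strata (20,10,10,20): sum ad/n = 4*400/60, sum bc/n = 4*100/60."""
        t = StratifiedTable(
            np.full(4, 20), np.full(4, 10), np.full(4, 10), np.full(4, 20)
        )
        res = cmh(t)
        assert np.isclose(res.or_estimate, 4.0)
        assert res.ci_low < 4.0 < res.ci_high
        assert res.p < 0.05

    def test_single_stratum_reduces_to_sample_or(self):
        t = StratifiedTable(np.array([12]), np.array([5]), np.array([7]), np.array([30]))
        res = cmh(t)
        assert np.isclose(res.or_estimate, (12 * 30) / (5 * 7))

    def test_pooled_copies_equal_single_table(self):
        one = cmh(StratifiedTable(np.array([20]), np.array([11]), np.array([13]), np.array([40])))
        four = cmh(
            StratifiedTable(np.full(4, 20), np.full(4, 11), np.full(4, 13), np.full(4, 40))
        )
        assert abs(np.log(one.or_estimate) - np.log(four.or_estimate)) < 1e-9

    def test_swapping_feature_columns_inverts_or(self):
        a, b, c, d = np.array([20, 5]), np.array([10, 9]), np.array([7, 3]), np.array([40, 22])
        r1 = cmh(StratifiedTable(a, b, c, d))
        r2 = cmh(StratifiedTable(b, a, d, c))
        assert np.isclose(r1.or_estimate * r2.or_estimate, 1.0)

    def test_zero_bc_infinite_or(self):
        res = cmh(StratifiedTable(np.array([5]), np.array([0]), np.array([0]), np.array([5])))
        assert np.isinf(res.or_estimate)
        assert res.zero_cell_adjusted

    def test_statistic_matches_statsmodels(self, rng):
        from statsmodels.stats.contingency_tables import StratifiedTable as SM

        for _ in range(20):
            counts = rng.integers(1, 40, size=(4, 4))
            t = StratifiedTable(counts[:, 0], counts[:, 1], counts[:, 2], counts[:, 3])
            tables = np.stack([np.stack([counts[:, 0], counts[:, 1]]),
                               np.stack([counts[:, 2], counts[:, 3]])])
            sm = SM(tables.astype(float))
            res = cmh(t)
            expect = sm.test_null_odds(correction=False)
            assert np.isclose(res.statistic, expect.statistic)
            assert np.isclose(res.p, expect.pvalue)


class TestFisherExact:
    def test_small_table_enumeration(self):
        res = fisher_exact(2, 0, 0, 2)
        assert np.isclose(res.p, 1 / 3)

    def test_central_table(self):
        assert np.isclose(fisher_exact(5, 5, 5, 5).p, 1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, 4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            res = fisher_exact(a, b, c, d)
            assert abs(res.p - fisher_p_enumeration(a, b, c, d)) < 1e-9

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            fisher_exact(-1, 2, 3, 4)


class TestMultiSet:
    def _setup(self, rng, n=5000):
        ann = pd.DataFrame(
            {
                "chromosome": "chr1",
                "position": np.arange(1, n + 1) * 1000,
                "stratum": rng.choice(["island", "shore", "shelf", "ocean"], n),
            },
            index=[f"cg{i:05d}" for i in range(n)],
        )
        high = pd.Series(rng.random(n) < 0.05, index=ann.index)
        return ann, high

    def _region_for(self, ann, member_mask, name):
        pos = ann["position"].to_numpy()
        return RegionSet(
            name, [("chr1", int(p - 1 - 250), int(p + 250)) for p in pos[member_mask]]
        )

    def test_single_set_q_equals_p(self, rng):
        ann, high = self._setup(rng)
        member = rng.random(len(ann)) < 0.1
        out = multi_set_enrichment(high, [self._region_for(ann, member, "s")], ann)
        assert np.isclose(out.loc[0, "q"], out.loc[0, "p"])

    def test_bh_q_monotone_in_p_rank(self, rng):
        ann, high = self._setup(rng)
        sets = [
            self._region_for(ann, rng.random(len(ann)) < 0.1, f"s{i}") for i in range(20)
        ]
        out = multi_set_enrichment(high, sets, ann)
        by_p = out.sort_values("p")
        assert (np.diff(by_p["q"].to_numpy()) >= -1e-12).all()

    def test_planted_set_ranks_first(self, rng):
        ann, high = self._setup(rng, n=20_000)
        h = high.to_numpy()
        # planted: members enriched among high probes at OR ~ 4
        member = np.where(h, rng.random(len(ann)) < 0.4, rng.random(len(ann)) < 0.12)
        sets = [self._region_for(ann, member, "planted")] + [
            self._region_for(ann, rng.random(len(ann)) < 0.12, f"null{i}")
            for i in range(9)
        ]
        out = multi_set_enrichment(high, sets, ann)
        assert out.loc[0, "set_name"] == "planted"
        assert out.loc[0, "q"] < 0.05

    def test_empty_collection_errors(self, rng):
        ann, high = self._setup(rng, n=100)
        with pytest.raises(ValueError):
            multi_set_enrichment(high, [], ann)


class TestTertileEnrichment:
    def test_null_p_uniform(self, rng):
        """Independent flags: KS test on 200 null p-values passes."""
        ps = []
        for _ in range(200):
            expr = pd.Series(rng.random(300), index=[f"g{i}" for i in range(300)])
            flags = pd.Series(rng.random(300) < 0.3, index=expr.index)
            _, p, _ = tertile_enrichment(flags, expr)
            ps.append(p)
        _, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_extreme_association(self, rng):
        expr = pd.Series(np.arange(300, dtype=float), index=[f"g{i}" for i in range(300)])
        flags = pd.Series(expr >= expr.quantile(2 / 3), index=expr.index)
        chi2, p, _ = tertile_enrichment(flags, expr)
        assert p < 1e-6

    def test_too_few_distinct_values(self):
        expr = pd.Series([1.0, 1.0, 1.0, 2.0], index=list("abcd"))
        flags = pd.Series([True, False, True, False], index=list("abcd"))
        with pytest.raises(ValueError, match="distinct"):
            tertile_enrichment(flags, expr)


def test_stratified_table_from_flags(tiny_annotation):
    ann = tiny_annotation
    high = pd.Series([True] * 3 + [False] * 7, index=ann.index)
    feat = pd.Series([True, False] * 5, index=ann.index)
    t = build_stratified_table(high, feat, ann["stratum"])
    assert t.total() == 10
    pooled = t.pooled()
    assert pooled[0] + pooled[1] == 3
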