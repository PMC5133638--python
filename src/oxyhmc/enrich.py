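"""Genomic-feature enrichment statistics for high-5hmC CpGs.

The background is always the post-filter retained probe set (never the
genome).  Association between "high 5hmC" and "in feature" is tested
with the Cochran-Mantel-Haenszel test stratified by the 4-level
CpG-density stratum (the stratum strongly shapes 5hmC levels, so the
pooled 2x2 is confounded), or with Fisher's exact test on the pooled
table.  Multi-set collections get Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable as _SMStratifiedTable
from statsmodels.stats.multitest import multipletests

from .io import RegionSet

__all__ = [
    "StratifiedTable",
    "EnrichmentResult",
    "overlap_flags",
    "build_stratified_table",
    "cmh",
    "fisher_exact",
    "multi_set_enrichment",
    "tertile_enrichment",
]


@dataclass(frozen=True)
class StratifiedTable:
    """2x2xK counts: per stratum k, (a, b, c, d) =
    (high & in-feature, high & out, not-high & in-feature, not-high & out)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    strata: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arrs = [np.asarray(x) for x in (self.a, self.b, self.c, self.d)]
        if any((x < 0).any() for x in arrs):
            raise ValueError("counts must be non-negative")
        if len({x.shape for x in arrs}) != 1:
            raise ValueError("count arrays must share a shape")

    @property
    def n_strata(self) -> int:
        return np.asarray(self.a).size

    def total(self) -> int:
        return int(np.sum(self.a) + np.sum(self.b) + np.sum(self.c) + np.sum(self.d))

    def pooled(self) -> tuple[int, int, int, int]:
        return (int(np.sum(self.a)), int(np.sum(self.b)), int(np.sum(self.c)), int(np.sum(self.d)))


@dataclass
class EnrichmentResult:
    """Common odds ratio, 95% CI, 1-df chi-square, p (and q in collections)."""

    or_estimate: float
    ci_low: float
    ci_high: float
    statistic: float
    p: float
    q: float | None = None
    estimator: str = "mantel-haenszel"
    zero_cell_adjusted: bool = False
    extras: dict = field(default_factory=dict)


def overlap_flags(annotation: pd.DataFrame, regions: RegionSet) -> pd.Series:
    """Flag probes whose 1-based position p overlaps a region.

    BED half-open (start, end) in 0-based coordinates maps to 1-based
    probe space as start < p <= end.  Implemented with a sorted-endpoint
    count: p is covered iff #(starts < p) > #(ends < p).
    """
    flags = np.zeros(len(annotation), dtype=bool)
    if len(regions) > 0:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in regions.intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        ann_chroms = set(annotation["chromosome"].unique())
        orphan = set(by_chrom) - ann_chroms
        if orphan:
            warnings.warn(
                f"region chromosomes never seen in annotation: {sorted(orphan)[:5]}",
                stacklevel=2,
            )
        pos = annotation["position"].to_numpy()
        chrom_arr = annotation["chromosome"].to_numpy()
        for chrom, ivs in by_chrom.items():
            mask = chrom_arr == chrom
            if not mask.any():
                continue
            starts = np.sort([s for s, _ in ivs])
            ends = np.sort([e for _, e in ivs])
            p = pos[mask]
            covered = np.searchsorted(starts, p, side="left") > np.searchsorted(
                ends, p, side="left"
            )
            flags[mask] = covered
    return pd.Series(flags, index=annotation.index, name=regions.name)


def build_stratified_table(
    high: pd.Series, in_feature: pd.Series, strata: pd.Series
) -> StratifiedTable:
    """Cross high/feature flags within each CpG-density stratum."""
    levels = tuple(sorted(strata.unique()))
    h = high.to_numpy(dtype=bool)
    f = in_feature.to_numpy(dtype=bool)
    s = strata.to_numpy()
    a, b, c, d = [], [], [], []
    for lev in levels:
        m = s == lev
        a.append(int(np.sum(m & h & f)))
        b.append(int(np.sum(m & h & ~f)))
        c.append(int(np.sum(m & ~h & f)))
        d.append(int(np.sum(m & ~h & ~f)))
    return StratifiedTable(np.array(a), np.array(b), np.array(c), np.array(d), strata=levels)


def cmh(table: StratifiedTable) -> EnrichmentResult:
    """Cochran-Mantel-Haenszel common odds ratio and 1-df test.

    OR_MH = sum_k(a_k d_k / n_k) / sum_k(b_k c_k / n_k); CI from the
    Robins-Breslow-Greenland variance; the test statistic is
    [sum_k(a_k - E a_k)]^2 / sum_k Var(a_k) under the hypergeometric
    null with no continuity correction.  When any cell is zero, 0.5 is
    added to every cell for the OR/CI only (flagged in the result).
    """
    a = np.asarray(table.a, dtype=float)
    b = np.asarray(table.b, dtype=float)
    c = np.asarray(table.c, dtype=float)
    d = np.asarray(table.d, dtype=float)
    n = a + b + c + d
    keep = n > 0
    if not keep.any():
        raise ValueError("all strata empty")
    a, b, c, d, n = a[keep], b[keep], c[keep], d[keep], n[keep]

    # 2x2xK layout for statsmodels: tables[:, :, k] = [[a, b], [c, d]]
    def sm_tables(a, b, c, d):
        return np.stack([np.stack([a, b]), np.stack([c, d])])

    num = np.sum(a * d / n)
    den = np.sum(b * c / n)
    zero_adjusted = False
    if den == 0 and num > 0:
        st = _SMStratifiedTable(sm_tables(a + 0.5, b + 0.5, c + 0.5, d + 0.5))
        ci_low, _ = st.oddsratio_pooled_confint(alpha=0.05)
        or_est, ci_high = np.inf, np.inf
        zero_adjusted = True
    else:
        if min(a.min(), b.min(), c.min(), d.min()) == 0:
            zero_adjusted = True
            st = _SMStratifiedTable(sm_tables(a + 0.5, b + 0.5, c + 0.5, d + 0.5))
        else:
            st = _SMStratifiedTable(sm_tables(a, b, c, d))
        or_est = num / den if den > 0 else float(st.oddsratio_pooled)
        ci_low, ci_high = st.oddsratio_pooled_confint(alpha=0.05)

    # test on the raw counts, no continuity correction
    row1 = a + b
    col1 = a + c
    e_a = row1 * col1 / n
    var_a = row1 * (n - row1) * col1 * (n - col1) / (n**2 * np.maximum(n - 1, 1))
    var_sum = np.sum(var_a)
    if var_sum > 0:
        statistic = float(np.sum(a - e_a) ** 2 / var_sum)
        p = float(stats.chi2.sf(statistic, df=1))
    else:
        statistic, p = 0.0, 1.0

    return EnrichmentResult(
        or_estimate=float(or_est),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        statistic=statistic,
        p=p,
        estimator="mantel-haenszel",
        zero_cell_adjusted=zero_adjusted,
    )


def fisher_exact(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Two-sided Fisher exact test on a pooled 2x2 table.

    The odds-ratio estimate is the sample OR (ad/bc, 0.5-adjusted when a
    cell is zero — flagged); the p-value sums hypergeometric
    probabilities no larger than the observed table's.  The CI is the
    Wald interval on the (adjusted) log sample OR.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    zero_adjusted = min(a, b, c, d) == 0
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if zero_adjusted else (a, b, c, d)
    or_est = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = or_est * np.exp(-1.959963984540054 * se)
    ci_high = or_est * np.exp(1.959963984540054 * se)
    return EnrichmentResult(
        or_estimate=float(or_est),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        statistic=float("nan"),
        p=float(res.pvalue),
        estimator="sample-odds-ratio",
        zero_cell_adjusted=zero_adjusted,
    )


def multi_set_enrichment(
    high: pd.Series,
    region_sets: list[RegionSet],
    annotation: pd.DataFrame,
    stratify: bool = True,
) -> pd.DataFrame:
    """One enrichment test per region set with BH q-values.

    CMH stratified by CpG density when ``stratify``; otherwise Fisher on
    the pooled 2x2.  Output is sorted by q then descending OR.
    """
    if not region_sets:
        raise ValueError("need at least one region set")
    rows = []
    for rs in region_sets:
        flags = overlap_flags(annotation, rs)
        if stratify:
            table = build_stratified_table(high, flags, annotation["stratum"])
            res = cmh(table)
        else:
            h = high.to_numpy(dtype=bool)
            f = flags.to_numpy(dtype=bool)
            res = fisher_exact(
                int(np.sum(h & f)), int(np.sum(h & ~f)),
                int(np.sum(~h & f)), int(np.sum(~h & ~f)),
            )
        rows.append(
            {
                "set_name": rs.name,
                "or": res.or_estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "statistic": res.statistic,
                "p": res.p,
                "estimator": res.estimator,
                "zero_cell_adjusted": res.zero_cell_adjusted,
                "n_overlap_high": int(np.sum(high.to_numpy(dtype=bool) & flags.to_numpy())),
                "n_overlap_bg": int(flags.sum()),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values(["q", "or"], ascending=[True, False]).reset_index(drop=True)


def tertile_enrichment(
    gene_has_high: pd.Series, expression: pd.Series
) -> tuple[float, float, pd.DataFrame]:
    """Chi-square test of high-5hmC gene membership across expression tertiles.

    Genes are cut at the 1/3 and 2/3 expression quantiles into
    low/moderate/high tertiles; the 3x2 contingency of tertile x
    contains-high-5hmC is tested with a chi-square.  Returns
    (statistic, p, table); warns when an expected count is below 5.
    """
    common = gene_has_high.index.intersection(expression.index)
    if len(common) < 3:
        raise ValueError("need at least 3 genes with expression")
    expr = expression.loc[common]
    if expr.nunique() < 3:
        raise ValueError("fewer than 3 distinct expression values; tertiles undefined")
    flags = gene_has_high.loc[common].astype(bool)
    q1, q2 = expr.quantile([1 / 3, 2 / 3])
    tertile = pd.Series(
        np.select([expr <= q1, expr <= q2], ["low", "moderate"], default="high"),
        index=common,
    )
    table = pd.crosstab(tertile, flags).reindex(
        index=["low", "moderate", "high"], fill_value=0
    )
    if table.shape[1] < 2:
        raise ValueError("high-5hmC flag is constant across genes")
    chi2, p, _, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if (expected < 5).any():
        warnings.warn("expected counts below 5 in the tertile table", stacklevel=2)
    return float(chi2), float(p), table
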