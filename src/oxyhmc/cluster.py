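"""Model-based clustering of 5hmC profiles.

Samples are clustered on their beta-value profiles over the high-5hmC
CpGs with a recursively partitioned beta mixture: at each node a
two-component mixture of independent per-CpG beta densities is fitted
by EM; the binary split is accepted when it improves the BIC and both
children are large enough, and recursion continues on accepted
children.  Leaves are labelled in order of increasing mean value, so
"leaf 1" is always the low-5hmC cluster.  This is a hard-assignment
simplification of the classical recursively partitioned mixture model;
the two root-level children define the low/high dichotomy used by the
survival analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, gammaln, logsumexp, polygamma

__all__ = [
    "BetaMixtureFit",
    "ClusterSolution",
    "beta_mixture_em",
    "recursive_partition",
    "stability_check",
    "group_tests",
    "median_dichotomy",
    "RecursiveBetaMixture",
]

_VAL_EPS = 1e-6  # clamp of values away from {0, 1} before beta likelihoods


def _clamp(x: np.ndarray) -> np.ndarray:
    return np.clip(x, _VAL_EPS, 1.0 - _VAL_EPS)


def _weighted_beta_mle(
    x: np.ndarray,
    w: np.ndarray,
    a0: np.ndarray | None = None,
    b0: np.ndarray | None = None,
    n_iter: int = 80,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted per-column beta MLE, vectorised over columns.

    x : (n_samples, n_cpgs) values in (0,1); w : (n_samples,) weights.
    Damped Newton on (alpha, beta) from a method-of-moments start with
    objective backtracking (the beta family is an exponential family,
    so the weighted log-likelihood is concave in (alpha, beta)).  When
    warm-start parameters (a0, b0) are supplied the returned solution is
    never worse than them — this keeps an EM outer loop monotone.
    """
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("zero total weight in M-step")
    wn = w / wsum
    s1 = wn @ np.log(x)       # E_w[ln x]
    s2 = wn @ np.log1p(-x)    # E_w[ln(1-x)]

    def objective(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return (a - 1) * s1 + (b - 1) * s2 - (gammaln(a) + gammaln(b) - gammaln(a + b))

    m = wn @ x
    v = wn @ (x - m) ** 2
    v = np.clip(v, 1e-10, m * (1 - m) * 0.999)
    conc = np.clip(m * (1 - m) / v - 1.0, 0.02, 1e6)
    a = np.clip(m * conc, 1e-2, 1e6)
    b = np.clip((1 - m) * conc, 1e-2, 1e6)
    if a0 is not None:
        better = objective(np.clip(a0, 1e-3, 1e7), np.clip(b0, 1e-3, 1e7)) > objective(a, b)
        a = np.where(better, a0, a)
        b = np.where(better, b0, b)

    f = objective(a, b)
    for _ in range(n_iter):
        psi_ab = digamma(a + b)
        g1 = s1 - digamma(a) + psi_ab
        g2 = s2 - digamma(b) + psi_ab
        if max(np.abs(g1).max(initial=0), np.abs(g2).max(initial=0)) < 1e-9:
            break
        tri_ab = polygamma(1, a + b)
        h11 = -polygamma(1, a) + tri_ab
        h22 = -polygamma(1, b) + tri_ab
        det = h11 * h22 - tri_ab**2
        det = np.where(np.abs(det) < 1e-300, -1e-300, det)
        da = -(h22 * g1 - tri_ab * g2) / det
        db = -(h11 * g2 - tri_ab * g1) / det
        # backtracking: halve the step until the objective does not drop
        t = np.ones_like(a)
        for _bt in range(30):
            an = np.clip(a + t * da, 1e-3, 1e7)
            bn = np.clip(b + t * db, 1e-3, 1e7)
            fn = objective(an, bn)
            worse = fn < f
            if not worse.any():
                break
            t = np.where(worse, t * 0.5, t)
        accept = fn >= f
        a = np.where(accept, an, a)
        b = np.where(accept, bn, b)
        f = np.where(accept, fn, f)
    return a, b


def _beta_logpdf_sum(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-sample sum over CpGs of ln Beta(a_j, b_j) densities at x[i, j]."""
    const = gammaln(a + b) - gammaln(a) - gammaln(b)
    return const.sum() + np.log(x) @ (a - 1.0) + np.log1p(-x) @ (b - 1.0)


@dataclass
class BetaMixtureFit:
    """k-component product-beta mixture fitted by EM."""

    assignments: np.ndarray          # hard labels, (n_samples,)
    responsibilities: np.ndarray     # (n_samples, k)
    alpha: np.ndarray                # (k, n_cpgs)
    beta: np.ndarray                 # (k, n_cpgs)
    weights: np.ndarray              # (k,)
    loglik: float
    n_iter: int
    converged: bool


def beta_mixture_em(
    values: np.ndarray | pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-8,
    init_labels: np.ndarray | None = None,
) -> BetaMixtureFit:
    """EM for a mixture of k product-beta components over samples.

    ``values`` is samples x CpGs in (0,1) after epsilon-clamping.  The
    log-likelihood is asserted non-decreasing across iterations; the fit
    is deterministic given ``seed`` (k-means initialisation of hard
    assignments on the logit scale, unless ``init_labels`` supplies an
    explicit starting partition).
    """
    x = _clamp(np.asarray(values, dtype=float))
    n, j = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    if k == 1:
        a, b = _weighted_beta_mle(x, np.ones(n))
        ll = float(_beta_logpdf_sum(x, a, b).sum())
        return BetaMixtureFit(
            assignments=np.zeros(n, dtype=int),
            responsibilities=np.ones((n, 1)),
            alpha=a[None, :], beta=b[None, :],
            weights=np.array([1.0]), loglik=ll, n_iter=0, converged=True,
        )

    if init_labels is None:
        from sklearn.cluster import KMeans

        logit = np.log(x) - np.log1p(-x)
        init_labels = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(logit).labels_
    init_labels = np.asarray(init_labels, dtype=int)
    resp = np.full((n, k), 1e-3)
    resp[np.arange(n), init_labels] = 1.0
    resp /= resp.sum(axis=1, keepdims=True)

    prev_ll = -np.inf
    ll = -np.inf
    alpha = np.empty((k, j))
    beta = np.empty((k, j))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step
        weights = resp.mean(axis=0)
        if weights.min() * n < 1e-6:
            break  # component died; caller treats as failed split
        warm = it > 1
        for comp in range(k):
            alpha[comp], beta[comp] = _weighted_beta_mle(
                x, resp[:, comp],
                a0=alpha[comp] if warm else None,
                b0=beta[comp] if warm else None,
            )
        # E-step
        log_comp = np.stack(
            [_beta_logpdf_sum(x, alpha[comp], beta[comp]) for comp in range(k)], axis=1
        )
        log_joint = log_comp + np.log(weights)[None, :]
        ll_per_sample = logsumexp(log_joint, axis=1)
        ll = float(ll_per_sample.sum())
        assert ll >= prev_ll - 1e-6 * max(1.0, abs(prev_ll)), (
            f"EM log-likelihood decreased: {prev_ll} -> {ll}"
        )
        resp = np.exp(log_joint - ll_per_sample[:, None])
        if ll - prev_ll < tol * max(1.0, abs(ll)):
            converged = True
            break
        prev_ll = ll

    assignments = resp.argmax(axis=1)
    return BetaMixtureFit(
        assignments=assignments, responsibilities=resp,
        alpha=alpha.copy(), beta=beta.copy(),
        weights=resp.mean(axis=0), loglik=ll, n_iter=it, converged=converged,
    )


@dataclass
class ClusterSolution:
    """Recursive binary-split solution over samples.

    ``labels`` maps sample -> leaf id (1..n_leaves, ordered by
    increasing mean value so leaf 1 is the low cluster); ``root_side``
    is the two-way split at the root ("low"/"high", or "all" when the
    root was not split) that drives the survival analysis.
    """

    labels: pd.Series
    root_side: pd.Series
    tree: list[dict] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return int(self.labels.nunique())


def _partition_node(
    x: np.ndarray,
    sample_idx: np.ndarray,
    node: str,
    min_leaf: int,
    seed: int,
    tree: list[dict],
    leaves: list[np.ndarray],
) -> None:
    n, j = x.shape
    one = beta_mixture_em(x, k=1)
    bic_one = -2.0 * one.loglik + 2.0 * j * np.log(n)
    record = {"node": node, "n_samples": n, "bic_gain": np.nan, "split": False}
    if n >= 2 * min_leaf:
        # several deterministic starts; single-sample beta components can
        # dominate the likelihood, so prefer the best fit whose hard split
        # satisfies the leaf-size constraint
        mean_split = (x.mean(axis=1) > np.median(x.mean(axis=1))).astype(int)
        rng = np.random.default_rng(seed)
        starts: list[np.ndarray | None] = [None, mean_split, rng.permutation(np.arange(n) % 2)]
        fits = [beta_mixture_em(x, k=2, seed=seed, init_labels=lab) for lab in starts]
        valid = [f for f in fits if np.bincount(f.assignments, minlength=2).min() >= min_leaf]
        two = max(valid or fits, key=lambda f: f.loglik)
        bic_two = -2.0 * two.loglik + (4.0 * j + 1.0) * np.log(n)
        sizes = np.bincount(two.assignments, minlength=2)
        gain = bic_one - bic_two
        record["bic_gain"] = float(gain)
        if gain > 0 and sizes.min() >= min_leaf:
            record["split"] = True
            tree.append(record)
            # order children by mean so traversal yields increasing-mean leaves
            means = [x[two.assignments == c].mean() for c in (0, 1)]
            order = np.argsort(means)
            for child_tag, comp in zip(("L", "H"), order):
                mask = two.assignments == comp
                _partition_node(
                    x[mask], sample_idx[mask], node + child_tag, min_leaf,
                    seed + 1, tree, leaves,
                )
            return
    tree.append(record)
    leaves.append(sample_idx)


def recursive_partition(
    values: pd.DataFrame, min_leaf: int = 3, seed: int = 0
) -> ClusterSolution:
    """Recursive binary beta-mixture splitting with BIC gating.

    ``values`` is samples x CpGs (typically the high-5hmC columns).  A
    split is accepted iff BIC(two leaves) < BIC(one leaf) and both
    children hold at least ``min_leaf`` samples.  With fewer than
    2*min_leaf samples the solution is a single leaf.
    """
    x = _clamp(values.to_numpy(dtype=float))
    n = x.shape[0]
    sample_ids = values.index
    tree: list[dict] = []
    leaves: list[np.ndarray] = []
    _partition_node(x, np.arange(n), "r", min_leaf, seed, tree, leaves)

    # leaves arrive in traversal order (low child first); order by mean anyway
    leaf_means = [x[idx].mean() for idx in leaves]
    order = np.argsort(leaf_means, kind="stable")
    labels = np.empty(n, dtype=int)
    for rank, li in enumerate(order, start=1):
        labels[leaves[li]] = rank

    root = next(rec for rec in tree if rec["node"] == "r")
    side = np.full(n, "all", dtype=object)
    if root["split"]:
        # DFS visits the root's low child first, so its leaves lead the list
        low_mask = np.zeros(n, dtype=bool)
        n_low_leaves = sum(
            1 for rec in tree if rec["node"].startswith("rL") and not rec["split"]
        )
        for idx in leaves[:n_low_leaves]:
            low_mask[idx] = True
        side = np.where(low_mask, "low", "high")

    return ClusterSolution(
        labels=pd.Series(labels, index=sample_ids, name="leaf"),
        root_side=pd.Series(side, index=sample_ids, name="root_side"),
        tree=tree,
    )


def _pair_agreement(l1: np.ndarray, l2: np.ndarray) -> float:
    """Fraction of sample pairs co-clustered identically in two labelings."""
    n = l1.size
    same1 = l1[:, None] == l1[None, :]
    same2 = l2[:, None] == l2[None, :]
    iu = np.triu_indices(n, k=1)
    return float(np.mean(same1[iu] == same2[iu]))


def stability_check(
    values: pd.DataFrame,
    means: pd.Series,
    sizes: list[int] = [1000, 2000, 3000, 4000],
    min_leaf: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[int, ClusterSolution]]:
    """Cluster on the top-``size`` CpGs by mean, for each size; compare.

    Returns (pair-agreement matrix, ARI matrix, per-size solutions);
    both matrices are indexed by sorted size, so the result does not
    depend on the order of ``sizes``.
    """
    from sklearn.metrics import adjusted_rand_score

    sizes_sorted = sorted(set(int(s) for s in sizes))
    if sizes_sorted[-1] > means.notna().sum():
        raise ValueError(
            f"max size {sizes_sorted[-1]} exceeds CpGs with defined means ({means.notna().sum()})"
        )
    ranked = means.dropna().sort_values(ascending=False, kind="mergesort")
    solutions: dict[int, ClusterSolution] = {}
    for size in sizes_sorted:
        cols = ranked.index[:size]
        solutions[size] = recursive_partition(values[cols], min_leaf=min_leaf, seed=seed)

    agree = pd.DataFrame(1.0, index=sizes_sorted, columns=sizes_sorted)
    ari = pd.DataFrame(1.0, index=sizes_sorted, columns=sizes_sorted)
    for i, s1 in enumerate(sizes_sorted):
        for s2 in sizes_sorted[i + 1:]:
            a = solutions[s1].labels.to_numpy()
            b = solutions[s2].labels.to_numpy()
            agree.loc[s1, s2] = agree.loc[s2, s1] = _pair_agreement(a, b)
            ari.loc[s1, s2] = ari.loc[s2, s1] = adjusted_rand_score(a, b)
    return agree, ari, solutions


def group_tests(labels: pd.Series, variables: pd.DataFrame) -> pd.DataFrame:
    """Per-variable association of cluster membership with covariates.

    Continuous variables get a Kruskal-Wallis test (tie-corrected);
    binary/categorical variables get Fisher's exact test (2 groups x 2
    levels) or a chi-square otherwise.  Constant variables are reported
    with NaN p-values.
    """
    common = labels.index.intersection(variables.index)
    lab = labels.loc[common]
    groups = sorted(lab.unique())
    if len(groups) < 2 or any((lab == g).sum() == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")
    rows = []
    for col in variables.columns:
        v = variables.loc[common, col]
        if v.nunique(dropna=True) <= 1:
            rows.append({"variable": col, "test": "none", "statistic": np.nan, "p": np.nan})
            continue
        if pd.api.types.is_numeric_dtype(v) and v.nunique() > 2:
            samples = [v[lab == g].dropna().to_numpy() for g in groups]
            stat, p = stats.kruskal(*samples)
            rows.append({"variable": col, "test": "kruskal-wallis", "statistic": stat, "p": p})
        else:
            table = pd.crosstab(lab, v)
            if table.shape == (2, 2):
                _, p = stats.fisher_exact(table.to_numpy())
                rows.append({"variable": col, "test": "fisher", "statistic": np.nan, "p": p})
            else:
                stat, p, _, _ = stats.chi2_contingency(table.to_numpy())
                rows.append({"variable": col, "test": "chi-square", "statistic": stat, "p": p})
    return pd.DataFrame(rows)


def median_dichotomy(index: pd.Series) -> pd.Series:
    """Split samples into low/high groups at the median total-5hmC index.

    Values at or below the median go to "low"; above to "high".  With an
    even number of distinct values the groups are balanced; all-equal
    indices yield all-"low" with a warning.
    """
    if len(index) < 2:
        raise ValueError("need at least 2 samples")
    med = float(index.median())
    labels = pd.Series(np.where(index > med, "high", "low"), index=index.index, name="group")
    if (labels == "low").all():
        import warnings

        warnings.warn("all total-5hmC indices equal: every sample assigned 'low'", stacklevel=2)
    return labels


class RecursiveBetaMixture:
    """Model-object facade: recursive beta-mixture clustering of samples.

    Parameters
    ----------
    values : DataFrame
        samples x CpGs beta-values (typically restricted to a HighSet).
    min_leaf : int
        Smallest admissible leaf.
    """

    def __init__(self, values: pd.DataFrame, min_leaf: int = 3) -> None:
        self.values = values
        self.min_leaf = min_leaf

    def fit(self, seed: int = 0) -> ClusterSolution:
        return recursive_partition(self.values, min_leaf=self.min_leaf, seed=seed)
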