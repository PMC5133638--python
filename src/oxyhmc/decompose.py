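"""Maximum-likelihood decomposition of paired BS/oxBS signals.

Tandem treatment of the same DNA with bisulfite (BS) and oxidative
bisulfite (oxBS) followed by hybridisation to a methylation array yields,
per CpG and sample, a quadruple ``(S_BS, R_BS, S_oxBS, R_oxBS)`` of
methylated and total fluorescence intensities.  The BS arm reads 5mC and
5hmC as methylated; the oxBS arm reads only 5mC.  Writing
``(pi1, pi2, pi3)`` for the unmethylated, 5mC and 5hmC proportions at a
CpG (a point on the 2-simplex), the arm-level methylated fractions have
means

    mu_BS  = pi2 + pi3        (BS sees both modifications)
    mu_ox  = pi2              (oxBS sees only 5mC)

We model the observed fractions ``beta_k = S_k / R_k`` as independent
beta variates with those means and precision ``theta_k = c * R_k`` — the
total intensity acts as an effective pseudo-count weight, so brighter
probes constrain the fit more tightly.  The MLE of ``(pi1, pi2, pi3)``
under the simplex constraint (5hmC proportion never negative) is the
estimator; the "naive subtraction" ``pi3 = max(0, beta_BS - beta_oxBS)``
is kept as the classical alternative.

The joint log-likelihood is separable and strictly concave in
``(mu_BS, mu_ox)`` and the constraint region ``0 <= mu_ox <= mu_BS <= 1``
is convex, so the constrained maximum is found exactly: solve each arm's
concave 1-D problem; if the unconstrained maximisers violate
``mu_ox <= mu_BS`` the optimum lies on the boundary ``mu_ox = mu_BS``
(zero 5hmC) and a single 1-D solve of the pooled score finishes the job.
All solves are vectorised bisections on the monotone score function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

__all__ = [
    "CytosineProportions",
    "FitOptions",
    "FitResult",
    "SignalQuad",
    "naive_subtract",
    "fit_one_cpg",
    "fit_many",
    "total_hydroxy_index",
    "PairedBisulfiteModel",
    "PairedBisulfiteResults",
]

# numerical guards
_FRAC_EPS = 1e-6        # clamp on observed fractions before the likelihood
_SIMPLEX_EPS = 1e-12    # clamp distance from simplex faces during solves
_BOUNDARY_TOL = 1e-8    # pi3 at or below this => boundary flag


@dataclass(frozen=True)
class CytosineProportions:
    """A point on the 2-simplex: unmethylated, 5mC and 5hmC proportions."""

    pi1: float
    pi2: float
    pi3: float

    def __post_init__(self) -> None:
        total = self.pi1 + self.pi2 + self.pi3
        if not np.isfinite(total) or abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total!r}")
        if min(self.pi1, self.pi2, self.pi3) < -1e-12:
            raise ValueError("proportions must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.pi1, self.pi2, self.pi3])


@dataclass(frozen=True)
class SignalQuad:
    """Methylated (S) and total (R) intensities for the BS and oxBS arms."""

    s_bs: float
    r_bs: float
    s_oxbs: float
    r_oxbs: float

    def __post_init__(self) -> None:
        for s, r, arm in ((self.s_bs, self.r_bs, "BS"), (self.s_oxbs, self.r_oxbs, "oxBS")):
            if r <= 0:
                raise ValueError(f"total intensity R_{arm} must be positive, got {r}")
            if not 0 <= s <= r:
                raise ValueError(f"methylated intensity S_{arm}={s} outside [0, R_{arm}={r}]")

    @property
    def beta_bs(self) -> float:
        return self.s_bs / self.r_bs

    @property
    def beta_oxbs(self) -> float:
        return self.s_oxbs / self.r_oxbs


@dataclass(frozen=True)
class FitOptions:
    """Options for the per-CpG fit.

    precision_scale : float
        ``c`` in ``theta_k = c * R_k``; scales how strongly the total
        intensity is trusted as a pseudo-count weight.
    tol : float
        Convergence tolerance of the score bisection (on mu).
    n_starts : int
        Retained for interface compatibility; the solver is globally
        convergent (concave separable objective) so starts are not used.
    """

    precision_scale: float = 1.0
    tol: float = 1e-12
    n_starts: int = 3


@dataclass(frozen=True)
class FitResult:
    proportions: CytosineProportions
    loglik: float
    converged: bool
    boundary: bool
    beta_bs: float
    beta_oxbs: float


def naive_subtract(beta_bs: float, beta_oxbs: float) -> CytosineProportions:
    """Classical subtraction estimate: 5hmC is the BS-minus-oxBS difference.

    ``pi2 = beta_oxBS``, ``pi3 = max(0, beta_BS - beta_oxBS)`` and the
    remainder is unmethylated.  Negative differences are clipped to zero.
    """
    for name, b in (("beta_bs", beta_bs), ("beta_oxbs", beta_oxbs)):
        if not (np.isfinite(b) and 0.0 <= b <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {b!r}")
    pi2 = float(beta_oxbs)
    pi3 = float(max(0.0, beta_bs - beta_oxbs))
    pi1 = float(1.0 - pi2 - pi3)
    return CytosineProportions(pi1, pi2, pi3)


def _beta_loglik(beta: np.ndarray, mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Log density of Beta(theta*mu, theta*(1-mu)) at beta (all arrays)."""
    a = theta * mu
    b = theta * (1.0 - mu)
    return (
        gammaln(theta) - gammaln(a) - gammaln(b)
        + (a - 1.0) * np.log(beta)
        + (b - 1.0) * np.log1p(-beta)
    )


def _solve_mu(logit_beta: np.ndarray, theta: np.ndarray, tol: float) -> np.ndarray:
    """Root of the 1-D score  psi(theta*mu) - psi(theta*(1-mu)) = logit(beta).

    The left-hand side is strictly increasing in mu from -inf to +inf, so a
    bisection on [eps, 1-eps] converges to the unique unconstrained
    maximiser of the concave arm log-likelihood.
    """
    lo = np.full_like(logit_beta, _SIMPLEX_EPS)
    hi = np.full_like(logit_beta, 1.0 - _SIMPLEX_EPS)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        g = digamma(theta * mid) - digamma(theta * (1.0 - mid)) - logit_beta
        hi = np.where(g > 0, mid, hi)
        lo = np.where(g > 0, lo, mid)
        if np.all(hi - lo < tol):
            break
    return 0.5 * (lo + hi)


def _solve_common_mu(
    logit_bs: np.ndarray,
    theta_bs: np.ndarray,
    logit_ox: np.ndarray,
    theta_ox: np.ndarray,
    tol: float,
) -> np.ndarray:
    """Maximiser of the pooled concave objective on the face mu_BS = mu_ox."""
    lo = np.full_like(logit_bs, _SIMPLEX_EPS)
    hi = np.full_like(logit_bs, 1.0 - _SIMPLEX_EPS)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        g = theta_bs * (logit_bs - digamma(theta_bs * mid) + digamma(theta_bs * (1.0 - mid)))
        g += theta_ox * (logit_ox - digamma(theta_ox * mid) + digamma(theta_ox * (1.0 - mid)))
        lo = np.where(g > 0, mid, lo)
        hi = np.where(g > 0, hi, mid)
        if np.all(hi - lo < tol):
            break
    return 0.5 * (lo + hi)


def fit_many(
    s_bs: np.ndarray,
    r_bs: np.ndarray,
    s_oxbs: np.ndarray,
    r_oxbs: np.ndarray,
    options: FitOptions | None = None,
) -> dict[str, np.ndarray]:
    """Vectorised constrained MLE over arrays of signal quadruples.

    Invalid entries (non-finite, R <= 0 or S outside [0, R]) are returned
    with NaN proportions and ``converged=False`` rather than raising, so a
    cohort fit degrades gracefully.  Returns a dict of flat arrays:
    pi1, pi2, pi3, loglik, converged, boundary, beta_bs, beta_oxbs.
    """
    opts = options or FitOptions()
    s_bs, r_bs, s_oxbs, r_oxbs = (
        np.asarray(a, dtype=float).ravel() for a in (s_bs, r_bs, s_oxbs, r_oxbs)
    )
    n = s_bs.size
    valid = (
        np.isfinite(s_bs) & np.isfinite(r_bs) & np.isfinite(s_oxbs) & np.isfinite(r_oxbs)
        & (r_bs > 0) & (r_oxbs > 0)
        & (s_bs >= 0) & (s_bs <= r_bs) & (s_oxbs >= 0) & (s_oxbs <= r_oxbs)
    )

    beta_bs = np.full(n, np.nan)
    beta_ox = np.full(n, np.nan)
    np.divide(s_bs, r_bs, out=beta_bs, where=valid)
    np.divide(s_oxbs, r_oxbs, out=beta_ox, where=valid)

    # clamp fractions away from 0/1 to avoid infinite beta densities
    cb_bs = np.clip(beta_bs, _FRAC_EPS, 1.0 - _FRAC_EPS)
    cb_ox = np.clip(beta_ox, _FRAC_EPS, 1.0 - _FRAC_EPS)
    theta_bs = opts.precision_scale * r_bs
    theta_ox = opts.precision_scale * r_oxbs

    pi1 = np.full(n, np.nan)
    pi2 = np.full(n, np.nan)
    pi3 = np.full(n, np.nan)
    loglik = np.full(n, np.nan)
    boundary = np.zeros(n, dtype=bool)

    if valid.any():
        v = valid
        lb_bs = np.log(cb_bs[v]) - np.log1p(-cb_bs[v])
        lb_ox = np.log(cb_ox[v]) - np.log1p(-cb_ox[v])
        mu_bs = _solve_mu(lb_bs, theta_bs[v], opts.tol)
        mu_ox = _solve_mu(lb_ox, theta_ox[v], opts.tol)

        crossed = mu_ox > mu_bs
        if crossed.any():
            common = _solve_common_mu(
                lb_bs[crossed], theta_bs[v][crossed], lb_ox[crossed], theta_ox[v][crossed], opts.tol
            )
            mu_bs[crossed] = common
            mu_ox[crossed] = common

        p3 = np.where(crossed, 0.0, mu_bs - mu_ox)
        p2 = mu_ox
        p1 = 1.0 - mu_bs
        ll = _beta_loglik(cb_bs[v], mu_bs, theta_bs[v]) + _beta_loglik(cb_ox[v], mu_ox, theta_ox[v])

        pi1[v], pi2[v], pi3[v], loglik[v] = p1, p2, p3, ll
        bflag = np.zeros(n, dtype=bool)
        bflag[v] = p3 <= _BOUNDARY_TOL
        boundary = bflag

    return {
        "pi1": pi1,
        "pi2": pi2,
        "pi3": pi3,
        "loglik": loglik,
        "converged": valid.copy(),
        "boundary": boundary,
        "beta_bs": beta_bs,
        "beta_oxbs": beta_ox,
    }


def fit_one_cpg(q: SignalQuad, options: FitOptions | None = None) -> FitResult:
    """Constrained MLE of (pi1, pi2, pi3) for a single signal quadruple."""
    res = fit_many(
        np.array([q.s_bs]), np.array([q.r_bs]), np.array([q.s_oxbs]), np.array([q.r_oxbs]),
        options,
    )
    if not res["converged"][0]:
        raise ValueError("likelihood non-finite for the supplied quadruple")
    props = CytosineProportions(
        float(res["pi1"][0]), float(res["pi2"][0]), float(res["pi3"][0])
    )
    return FitResult(
        proportions=props,
        loglik=float(res["loglik"][0]),
        converged=True,
        boundary=bool(res["boundary"][0]),
        beta_bs=float(res["beta_bs"][0]),
        beta_oxbs=float(res["beta_oxbs"][0]),
    )


def total_hydroxy_index(pi3: pd.DataFrame) -> pd.Series:
    """Per-sample global 5hmC index: mean 5hmC proportion over all CpGs.

    The mean over retained probes of the per-CpG 5hmC beta-values, one
    scalar per sample (column).
    """
    if pi3.shape[0] == 0:
        raise ValueError("no retained CpGs: cannot compute a total 5hmC index")
    if pi3.isna().any().any():
        raise ValueError("pi3 matrix contains missing values; drop incomplete probes first")
    return pi3.mean(axis=0)


class PairedBisulfiteModel:
    """Joint model of paired BS/oxBS methylated-fraction signals.

    Built from four aligned CpG x sample DataFrames (methylated and total
    intensity per arm); ``fit()`` runs the constrained per-entry MLE and
    returns a :class:`PairedBisulfiteResults`.

    Parameters
    ----------
    s_bs, r_bs, s_oxbs, r_oxbs : DataFrame
        Probe-by-sample matrices sharing index (probe ids) and columns
        (sample ids).
    precision_scale : float
        ``c`` in the beta precision ``theta_k = c * R_k``.
    """

    def __init__(
        self,
        s_bs: pd.DataFrame,
        r_bs: pd.DataFrame,
        s_oxbs: pd.DataFrame,
        r_oxbs: pd.DataFrame,
        precision_scale: float = 1.0,
    ) -> None:
        ref = s_bs
        for name, m in (("r_bs", r_bs), ("s_oxbs", s_oxbs), ("r_oxbs", r_oxbs)):
            if not (m.index.equals(ref.index) and m.columns.equals(ref.columns)):
                raise ValueError(f"matrix {name} is not aligned with s_bs")
        self.s_bs, self.r_bs, self.s_oxbs, self.r_oxbs = s_bs, r_bs, s_oxbs, r_oxbs
        self.options = FitOptions(precision_scale=precision_scale)

    @classmethod
    def from_cohort(cls, cohort, precision_scale: float = 1.0,
                    probes: list[str] | None = None) -> "PairedBisulfiteModel":
        """Construct from an io.Cohort, optionally restricted to retained probes."""
        mats = [cohort.s_bs, cohort.r_bs, cohort.s_oxbs, cohort.r_oxbs]
        if probes is not None:
            mats = [m.loc[probes] for m in mats]
        return cls(*mats, precision_scale=precision_scale)

    def fit(self) -> "PairedBisulfiteResults":
        shape = self.s_bs.shape
        res = fit_many(
            self.s_bs.to_numpy(), self.r_bs.to_numpy(),
            self.s_oxbs.to_numpy(), self.r_oxbs.to_numpy(),
            self.options,
        )
        idx, cols = self.s_bs.index, self.s_bs.columns

        def mat(key: str) -> pd.DataFrame:
            return pd.DataFrame(res[key].reshape(shape), index=idx, columns=cols)

        return PairedBisulfiteResults(
            model=self,
            pi1=mat("pi1"), pi2=mat("pi2"), pi3=mat("pi3"),
            loglik=mat("loglik"),
            converged=mat("converged").astype(bool),
            boundary=mat("boundary").astype(bool),
        )

    def naive(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        """Naive-subtraction matrices (pi1, pi2, pi3), clipped at zero 5hmC."""
        b_bs = self.s_bs / self.r_bs
        b_ox = self.s_oxbs / self.r_oxbs
        pi3 = (b_bs - b_ox).clip(lower=0.0)
        pi2 = b_ox
        pi1 = 1.0 - pi2 - pi3
        return pi1, pi2, pi3


@dataclass
class PairedBisulfiteResults:
    """Fitted proportions and diagnostics for a cohort decomposition."""

    model: PairedBisulfiteModel
    pi1: pd.DataFrame
    pi2: pd.DataFrame
    pi3: pd.DataFrame
    loglik: pd.DataFrame
    converged: pd.DataFrame
    boundary: pd.DataFrame
    _diagnostics: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def failure_rate(self) -> pd.Series:
        """Per-probe fraction of samples whose fit failed."""
        return 1.0 - self.converged.mean(axis=1)

    def total_hydroxy_index(self) -> pd.Series:
        return total_hydroxy_index(self.pi3)

    def diagnostics(self) -> pd.DataFrame:
        """Long-format per-entry diagnostics (probe_id, sample_id, loglik, flags)."""
        if self._diagnostics is None:
            frames = {
                "loglik": self.loglik, "converged": self.converged, "boundary": self.boundary,
            }
            long = {
                k: v.stack(future_stack=True).rename(k) for k, v in frames.items()
            }
            out = pd.concat(long.values(), axis=1).reset_index()
            out.columns = ["probe_id", "sample_id", "loglik", "converged", "boundary"]
            self._diagnostics = out
        return self._diagnostics

    def summary(self) -> pd.DataFrame:
        """Per-sample summary: mean proportions, total 5hmC index, boundary rate."""
        return pd.DataFrame(
            {
                "mean_pi1": self.pi1.mean(axis=0),
                "mean_pi2": self.pi2.mean(axis=0),
                "mean_pi3": self.pi3.mean(axis=0),
                "total_5hmC_index": self.pi3.mean(axis=0),
                "boundary_fraction": self.boundary.mean(axis=0),
                "failed_fraction": 1.0 - self.converged.mean(axis=0),
            }
        ).rename_axis("sample_id")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = self.summary()
        head = (
            f"PairedBisulfiteResults: {self.pi3.shape[0]} CpGs x {self.pi3.shape[1]} samples\n"
            f"mean 5hmC index {s['total_5hmC_index'].mean():.4f}; "
            f"boundary fraction {s['boundary_fraction'].mean():.3f}\n"
        )
        return head + s.to_string(float_format=lambda x: f"{x:.4f}")
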