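"""Seeded synthetic cohorts with known truth for every pipeline stage.

The generator emulates the structure of a tandem BS/oxBS glioblastoma
cohort: CpG-density strata (island/shore/shelf/ocean) with
stratum-dependent Dirichlet priors on the (unmethylated, 5mC, 5hmC)
triple, sample-level multiplicative 5hmC scaling that defines a low- and
a high-5hmC cluster, gamma-distributed total intensities with
beta-distributed methylated fractions per treatment arm, region sets
enriched among true-high-5hmC CpGs at a target odds ratio, and
exponential survival with a cluster hazard ratio and uniform censoring.

All randomness derives from a single seed through numpy SeedSequence
spawning, so identical configs reproduce cohorts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RegionSet

__all__ = [
    "StratumPrior",
    "SimConfig",
    "SyntheticCohort",
    "simulate_truth",
    "simulate_signals",
    "simulate_region_set",
    "simulate_clinical",
    "simulate_cohort",
    "write_cohort",
]

STRATA = ("island", "shore", "shelf", "ocean")
GENE_REGIONS = ("promoter", "exon", "intron", "intergenic")

# Gene-region composition per CpG-density stratum: islands sit mostly in
# promoters, oceans mostly in introns/intergenic space.
_GENE_REGION_P = {
    "island": (0.65, 0.15, 0.15, 0.05),
    "shore": (0.40, 0.15, 0.30, 0.15),
    "shelf": (0.10, 0.15, 0.45, 0.30),
    "ocean": (0.05, 0.10, 0.45, 0.40),
}


@dataclass(frozen=True)
class StratumPrior:
    """Dirichlet prior for (pi1, pi2, pi3) within one CpG-density stratum."""

    mean: tuple[float, float, float]
    concentration: float

    def alpha(self) -> np.ndarray:
        return self.concentration * np.asarray(self.mean, dtype=float)


def _default_priors() -> dict[str, StratumPrior]:
    # Glioblastoma-like landscape: global 5hmC about 1%, most CpGs near
    # zero 5hmC; 5mC (and 5hmC) lowest in islands/shores, highest in
    # shelf/ocean; low concentration gives the bimodal, corner-heavy
    # per-stratum beta distributions methylation arrays show.
    return {
        "island": StratumPrior((0.862, 0.130, 0.008), 2.5),
        "shore": StratumPrior((0.637, 0.350, 0.013), 2.5),
        "shelf": StratumPrior((0.429, 0.550, 0.021), 2.5),
        "ocean": StratumPrior((0.345, 0.630, 0.025), 2.5),
    }


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic tandem-array cohort.

    Defaults describe the emulated study conditions: 30 samples split
    into equal low/high 5hmC clusters (scales 0.3 vs 1.0), fluorescence
    totals ~ Gamma(shape 10, mean 2000), arm fractions ~ Beta with
    precision 200, a target feature/high-5hmC odds ratio of 3, a hazard
    ratio of 3 for the low cluster and 20% censoring.
    """

    n_cpgs: int = 10_000
    n_samples: int = 30
    stratum_fractions: dict[str, float] = field(
        default_factory=lambda: {"island": 0.31, "shore": 0.23, "shelf": 0.10, "ocean": 0.36}
    )
    stratum_pi_priors: dict[str, StratumPrior] = field(default_factory=_default_priors)
    hmc_scale_low: float = 0.3
    hmc_scale_high: float = 1.0
    n_low: int = 15
    n_high: int = 15
    depth_mean: float = 2000.0
    depth_shape: float = 10.0
    depth_distribution: str = "gamma"  # or "lognormal"
    noise_precision: float = 200.0
    target_enrichment_or: float = 3.0
    feature_base_rate: float = 0.15
    survival_hr: float = 3.0
    baseline_median_months: float = 14.5
    censor_rate: float = 0.2
    age_mean: float = 65.0
    age_sd: float = 10.0
    age_cluster_shift: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        errors: list[str] = []
        if self.n_cpgs < 1 or self.n_samples < 1:
            errors.append("n_cpgs and n_samples must be >= 1")
        if self.n_low + self.n_high != self.n_samples:
            errors.append(
                f"n_low + n_high = {self.n_low + self.n_high} must equal n_samples = {self.n_samples}"
            )
        frac_sum = sum(self.stratum_fractions.get(s, 0.0) for s in STRATA)
        if abs(frac_sum - 1.0) > 1e-12:
            errors.append(f"stratum_fractions must sum to 1, got {frac_sum!r}")
        for s in STRATA:
            prior = self.stratum_pi_priors.get(s)
            if prior is None:
                errors.append(f"missing prior for stratum '{s}'")
                continue
            if prior.concentration <= 0 or min(prior.mean) <= 0:
                errors.append(f"degenerate Dirichlet concentration for stratum '{s}'")
            if abs(sum(prior.mean) - 1.0) > 1e-9:
                errors.append(f"prior mean for stratum '{s}' must sum to 1")
        if not (0 < self.hmc_scale_low <= 1 and 0 < self.hmc_scale_high <= 1):
            errors.append("hmc scales must lie in (0, 1]")
        if self.depth_mean <= 0 or self.depth_shape <= 0 or self.noise_precision <= 0:
            errors.append("depth_mean, depth_shape and noise_precision must be positive")
        if self.depth_distribution not in ("gamma", "lognormal"):
            errors.append("depth_distribution must be 'gamma' or 'lognormal'")
        if self.survival_hr <= 0:
            errors.append("survival_hr must be positive")
        if not 0 <= self.censor_rate < 1:
            errors.append(f"censor_rate must lie in [0, 1), got {self.censor_rate}")
        if errors:
            raise ValueError("; ".join(errors))

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticCohort:
    """A complete simulated cohort together with its generating truth."""

    truth_pi1: pd.DataFrame
    truth_pi2: pd.DataFrame
    truth_pi3: pd.DataFrame
    s_bs: pd.DataFrame
    r_bs: pd.DataFrame
    s_oxbs: pd.DataFrame
    r_oxbs: pd.DataFrame
    annotation: pd.DataFrame
    regions: list[RegionSet]
    clinical: pd.DataFrame
    true_labels: pd.Series  # per sample: "low" or "high"
    config: SimConfig


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _simulate_annotation(strata: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic probe coordinates consistent with each probe's stratum.

    Probes are laid down in order along chr1..chr22 with inter-probe gaps
    of at least 600 bp (so a +/-250 bp feature window never captures a
    neighbour).  TSS distances are stratum-dependent: islands hug the
    TSS, oceans sit far away.
    """
    n = strata.size
    probe_ids = np.array([f"cg{i:08d}" for i in range(n)])
    n_chrom = min(22, max(1, n // 50 + 1))
    chrom_idx = rng.integers(0, n_chrom, size=n)
    chroms = np.array([f"chr{c + 1}" for c in chrom_idx])
    gaps = 600 + rng.integers(0, 1000, size=n)
    position = np.empty(n, dtype=np.int64)
    for c in range(n_chrom):
        mask = chrom_idx == c
        position[mask] = 1000 + np.cumsum(gaps[mask])

    tss = np.empty(n)
    sign = rng.choice([-1.0, 1.0], size=n)
    draw = rng.random(n)
    for stratum, (lo, hi) in {
        "island": (0.0, 800.0),
        "shore": (500.0, 2500.0),
        "shelf": (2500.0, 6000.0),
        "ocean": (5000.0, 200000.0),
    }.items():
        m = strata == stratum
        tss[m] = sign[m] * (lo + draw[m] * (hi - lo))

    gene_region = np.empty(n, dtype=object)
    for stratum, probs in _GENE_REGION_P.items():
        m = strata == stratum
        gene_region[m] = rng.choice(GENE_REGIONS, size=int(m.sum()), p=probs)

    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chroms,
            "position": position,
            "stratum": strata,
            "gene_region": gene_region,
            "tss_distance": np.round(tss).astype(np.int64),
            "strand": rng.choice(["+", "-"], size=n),
        }
    ).set_index("probe_id")


def simulate_truth(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Draw the generating truth: per-CpG/sample simplex triples.

    Each CpG gets a stratum, a base triple from the stratum's Dirichlet,
    and each sample's 5hmC is multiplied by its cluster scale with the
    triple renormalised (preserving the pi1:pi2 ratio, so global 5hmC
    loss leaves 5mC content essentially unchanged).

    Returns (pi1, pi2, pi3, annotation, true_labels).
    """
    rng_strata, rng_dir, rng_annot, rng_lab = _child_rngs(config.seed, 4)

    fractions = np.array([config.stratum_fractions[s] for s in STRATA])
    strata = rng_strata.choice(STRATA, size=config.n_cpgs, p=fractions / fractions.sum())

    base = np.empty((config.n_cpgs, 3))
    for s in STRATA:
        mask = strata == s
        if mask.any():
            base[mask] = rng_dir.dirichlet(config.stratum_pi_priors[s].alpha(), size=int(mask.sum()))
    # Dirichlet with small alpha can return exact zeros at float precision
    base = np.clip(base, 1e-12, None)
    base /= base.sum(axis=1, keepdims=True)

    annotation = _simulate_annotation(strata, rng_annot)
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    labels = np.array(["low"] * config.n_low + ["high"] * config.n_high)
    labels = labels[rng_lab.permutation(config.n_samples)]
    scales = np.where(labels == "low", config.hmc_scale_low, config.hmc_scale_high)

    p1 = base[:, [0]]
    p2 = base[:, [1]]
    p3 = base[:, [2]]
    z = p1 + p2 + p3 * scales[None, :]
    pi1 = p1 / z
    pi2 = p2 / z
    pi3 = p3 * scales[None, :] / z

    idx = annotation.index
    mk = lambda a: pd.DataFrame(a, index=idx, columns=sample_ids)
    true_labels = pd.Series(labels, index=sample_ids, name="true_label")
    return mk(pi1), mk(pi2), mk(pi3), annotation, true_labels


def simulate_signals(
    pi2: pd.DataFrame, pi3: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit the (S_BS, R_BS, S_oxBS, R_oxBS) quadruple per CpG per sample.

    Totals R_k are gamma (or lognormal) with mean ``depth_mean`` and shape
    ``depth_shape``, independently per arm; the methylated fraction is a
    beta draw with mean pi2+pi3 (BS) or pi2 (oxBS) and precision
    ``noise_precision``; S_k = fraction * R_k, so S_k <= R_k exactly.
    """
    mu_bs = (pi2 + pi3).to_numpy()
    mu_ox = pi2.to_numpy()
    assert np.all((mu_bs > -1e-12) & (mu_bs < 1 + 1e-12)), "arm mean outside [0,1]"
    assert np.all((mu_ox > -1e-12) & (mu_ox < 1 + 1e-12)), "arm mean outside [0,1]"
    shape = mu_bs.shape
    rng_depth, rng_frac = _child_rngs(config.seed ^ 0x5F5E1, 2)

    def draw_depth() -> np.ndarray:
        if config.depth_distribution == "gamma":
            return rng_depth.gamma(config.depth_shape, config.depth_mean / config.depth_shape, shape)
        sigma = 1.0 / np.sqrt(config.depth_shape)
        mu = np.log(config.depth_mean) - 0.5 * sigma**2
        return rng_depth.lognormal(mu, sigma, shape)

    def draw_frac(mu: np.ndarray) -> np.ndarray:
        m = np.clip(mu, 1e-9, 1 - 1e-9)
        return rng_frac.beta(config.noise_precision * m, config.noise_precision * (1 - m))

    r_bs = draw_depth()
    r_ox = draw_depth()
    s_bs = draw_frac(mu_bs) * r_bs
    s_ox = draw_frac(mu_ox) * r_ox

    idx, cols = pi2.index, pi2.columns
    mk = lambda a: pd.DataFrame(a, index=idx, columns=cols)
    return mk(s_bs), mk(r_bs), mk(s_ox), mk(r_ox)


def realized_odds_ratio(flags_feature: np.ndarray, flags_high: np.ndarray) -> float:
    """Sample odds ratio of the feature x high 2x2 table."""
    a = np.sum(flags_high & flags_feature)
    b = np.sum(flags_high & ~flags_feature)
    c = np.sum(~flags_high & flags_feature)
    d = np.sum(~flags_high & ~flags_feature)
    if min(a, b, c, d) == 0:
        raise ValueError(
            f"degenerate 2x2 margin (a={a}, b={b}, c={c}, d={d}): odds ratio undefined"
        )
    return float(a * d) / float(b * c)


def simulate_region_set(
    annotation: pd.DataFrame,
    true_high_flags: np.ndarray | pd.Series,
    config: SimConfig,
    name: str = "feature",
    rng: np.random.Generator | None = None,
    half_width: int = 250,
) -> RegionSet:
    """Build a region set whose overlap with high-5hmC CpGs hits a target OR.

    Member probes are drawn without replacement at rate
    ``feature_base_rate`` among non-high probes and at the rate whose
    odds are ``target_enrichment_or`` times larger among high probes
    (independently of stratum, so the within-stratum odds ratio equals
    the target).  Exact member counts per group keep the realized odds
    ratio tight around the target.  Intervals are fixed
    +/-``half_width`` bp windows around member probe coordinates.
    """
    flags_high = np.asarray(true_high_flags, dtype=bool)
    if flags_high.size != len(annotation):
        raise ValueError("true_high_flags length must match annotation")
    if flags_high.all() or not flags_high.any():
        raise ValueError("degenerate margin: all (or no) CpGs flagged high; odds ratio undefined")
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed ^ 0xBEDBED))

    p0 = config.feature_base_rate
    odds1 = config.target_enrichment_or * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    if not (0 < p1 < 1):
        raise ValueError(
            f"unattainable target OR {config.target_enrichment_or}; "
            f"attainable member rate bound (0, 1) violated (p1={p1})"
        )
    member = np.zeros(flags_high.size, dtype=bool)
    for group_mask, rate in ((flags_high, p1), (~flags_high, p0)):
        idx = np.flatnonzero(group_mask)
        n_member = int(round(rate * idx.size))
        n_member = min(max(n_member, 1), idx.size - 1) if idx.size > 1 else n_member
        member[rng.choice(idx, size=n_member, replace=False)] = True
    pos = annotation["position"].to_numpy()
    chrom = annotation["chromosome"].to_numpy()
    starts = np.maximum(0, pos[member] - 1 - half_width)
    ends = pos[member] + half_width
    intervals = list(zip(chrom[member].tolist(), starts.tolist(), ends.tolist()))
    return RegionSet(name=name, intervals=intervals)


def simulate_clinical(
    true_labels: pd.Series, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Survival, age and sex per sample with a cluster hazard ratio.

    Survival times are exponential with the low cluster's hazard
    multiplied by ``survival_hr``; censoring is uniform on (0, tau] with
    tau solved so the expected censored fraction matches ``censor_rate``.
    The low cluster is drawn ``age_cluster_shift`` years older.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed ^ 0xC11111))
    labels = true_labels.to_numpy()
    n = labels.size
    lam_base = np.log(2.0) / config.baseline_median_months
    lam = np.where(labels == "low", lam_base * config.survival_hr, lam_base)
    times = rng.exponential(1.0 / lam)

    event = np.ones(n, dtype=int)
    if config.censor_rate > 0:
        # P(censored | lam, tau) for C ~ U(0, tau): (1 - exp(-lam*tau)) / (lam*tau)
        def censored_frac(tau: float) -> float:
            x = lam * tau
            return float(np.mean((1.0 - np.exp(-x)) / x))

        lo, hi = 1e-6, 1e7
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if censored_frac(mid) > config.censor_rate:
                lo = mid
            else:
                hi = mid
        tau = np.sqrt(lo * hi)
        censor_times = rng.uniform(0.0, tau, size=n)
        event = (times <= censor_times).astype(int)
        times = np.minimum(times, censor_times)

    age = rng.normal(config.age_mean, config.age_sd, size=n)
    age += np.where(labels == "low", config.age_cluster_shift, 0.0)
    sex = np.where(np.arange(n) % 2 == 0, "male", "female")
    sex = sex[rng.permutation(n)]

    return pd.DataFrame(
        {
            "sample_id": true_labels.index,
            "age_at_diagnosis": np.round(age, 1),
            "sex": sex,
            "survival_months": times,
            "event": event,
            "excluded_flag": False,
        }
    ).set_index("sample_id")


def simulate_cohort(config: SimConfig, n_region_sets: int = 1,
                    high_fraction: float = 0.01) -> SyntheticCohort:
    """Full cohort: truth, signals, annotation, region sets, clinical data.

    ``true_high_flags`` for region construction are the top
    ``high_fraction`` of CpGs by true mean 5hmC across samples.
    """
    pi1, pi2, pi3, annotation, labels = simulate_truth(config)
    s_bs, r_bs, s_ox, r_ox = simulate_signals(pi2, pi3, config)

    means = pi3.mean(axis=1).to_numpy()
    k = max(1, int(np.floor(high_fraction * config.n_cpgs)))
    order = np.argsort(-means, kind="stable")
    flags = np.zeros(config.n_cpgs, dtype=bool)
    flags[order[:k]] = True

    rngs = _child_rngs(config.seed ^ 0xFEA7, n_region_sets)
    regions = [
        simulate_region_set(annotation, flags, config, name=f"region_set_{i}", rng=rngs[i])
        for i in range(n_region_sets)
    ]
    clinical = simulate_clinical(labels, config)
    return SyntheticCohort(
        truth_pi1=pi1, truth_pi2=pi2, truth_pi3=pi3,
        s_bs=s_bs, r_bs=r_bs, s_oxbs=s_ox, r_oxbs=r_ox,
        annotation=annotation, regions=regions, clinical=clinical,
        true_labels=labels, config=config,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a cohort in the pipeline's on-disk layout plus a truth file."""
    from . import io as oio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, m in (
        ("S_BS", cohort.s_bs), ("R_BS", cohort.r_bs),
        ("S_oxBS", cohort.s_oxbs), ("R_oxBS", cohort.r_oxbs),
    ):
        oio.write_matrix(m, out / f"{name}.tsv")
    cohort.annotation.reset_index().to_csv(out / "annotation.tsv", sep="\t", index=False)
    cohort.clinical.reset_index().to_csv(out / "clinical.tsv", sep="\t", index=False)
    (out / "regions").mkdir(exist_ok=True)
    for rs in cohort.regions:
        oio.write_regions(rs, out / "regions" / f"{rs.name}.bed")
    truth = pd.concat(
        {
            "pi1": cohort.truth_pi1.stack(future_stack=True),
            "pi2": cohort.truth_pi2.stack(future_stack=True),
            "pi3": cohort.truth_pi3.stack(future_stack=True),
        },
        axis=1,
    ).reset_index()
    truth.columns = ["probe_id", "sample_id", "pi1", "pi2", "pi3"]
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    cohort.true_labels.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        out / "true_labels.tsv", sep="\t", index=False
    )
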