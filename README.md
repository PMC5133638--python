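# oxyhmc

Quantifying 5-hydroxymethylcytosine (5hmC) genome-wide from tandem
bisulfite (BS) / oxidative-bisulfite (oxBS) methylation arrays — and
asking what it means. `oxyhmc` is for epigenomics analysts working with
paired BS/oxBS array cohorts (tumour or normal tissue) who need to

1. decompose each CpG's paired signals into unmethylated / 5mC / 5hmC
   proportions by constrained maximum likelihood,
2. delineate and annotate the high-5hmC fraction of the genome
   (stratum percentile tables, TSS metaplots, recurrence),
3. test genomic-feature enrichment with CpG-density-stratified
   Cochran–Mantel–Haenszel statistics and multi-set q-value ranking,
4. cluster samples on their 5hmC profiles with a recursively
   partitioned beta mixture, and
5. relate cluster membership to overall survival with a multivariable
   Cox model.

A seeded synthetic-cohort generator with known ground truth makes every
stage testable without any data download.

## The model

Each CpG × sample observation is a quadruple `(S_BS, R_BS, S_oxBS,
R_oxBS)` of methylated and total intensities. With `(π1, π2, π3)` the
unmethylated/5mC/5hmC proportions (`π_j ≥ 0`, `Σ π_j = 1`), the arm
fractions `β_k = S_k/R_k` are modelled as

    β_BS  ~ Beta(θ_BS μ_BS, θ_BS(1−μ_BS)),   μ_BS = π2 + π3,  θ_BS = c·R_BS
    β_oxBS~ Beta(θ_ox μ_ox, θ_ox(1−μ_ox)),   μ_ox = π2,       θ_ox = c·R_oxBS

and the constrained MLE of `(π1, π2, π3)` is solved exactly — the
likelihood is separable and concave in `(μ_BS, μ_ox)` over a convex
constraint region, so two (occasionally three) vectorised 1-D concave
solves replace generic optimisation. 5hmC is never negative; when the
oxBS fraction exceeds the BS fraction the estimate sits on the `π3 = 0`
boundary and is flagged. The classical naive subtraction
`π3 = max(0, β_BS − β_oxBS)` is provided for comparison and is the
high-intensity limit of the MLE. See `docs/methods.md` for the full
account, including the enrichment, clustering and survival models.

## Worked example

```python
from oxyhmc import PairedBisulfiteModel, SimConfig, cox_fit, simulate_cohort
from oxyhmc.landscape import cpg_summary, recurrence, select_high
from oxyhmc.cluster import recursive_partition

cfg = SimConfig(n_cpgs=2000, n_samples=30, n_low=15, n_high=15, seed=7)
cohort = simulate_cohort(cfg)

model = PairedBisulfiteModel(cohort.s_bs, cohort.r_bs, cohort.s_oxbs, cohort.r_oxbs)
results = model.fit()
print(results.summary().head(3).round(4))

summary = cpg_summary(results.pi3)
high = select_high(summary["mean"], fraction=0.01)
counts, rec_frac = recurrence(results.pi3, high)
print(f"high set: {len(high)} CpGs, threshold {high.threshold:.3f}, "
      f"recurrent fraction {rec_frac:.2f}")

solution = recursive_partition(results.pi3.loc[high.probe_ids].T, seed=7)
fit = cox_fit(cohort.clinical, solution.root_side)
print(f"low-cluster HR = {fit.hr:.2f} "
      f"(95% CI {fit.ci_low:.2f}-{fit.ci_high:.2f}), p = {fit.p:.3f}")
```

prints

```
           mean_pi1  mean_pi2  mean_pi3  total_5hmC_index  boundary_fraction  failed_fraction
sample_id
S000         0.5756    0.4069    0.0176            0.0176             0.4845              0.0
S001         0.5754    0.4062    0.0184            0.0184             0.4645              0.0
S002         0.5752    0.4068    0.0180            0.0180             0.4645              0.0
high set: 20 CpGs, threshold 0.253, recurrent fraction 1.00
low-cluster HR = 3.28 (95% CI 1.11-9.76), p = 0.032
```

Reading this: per sample, roughly 40% of cytosines at these CpGs are
5mC and under 2% are 5hmC (the `total_5hmC_index`); about half of all
CpG × sample fits sit on the zero-5hmC boundary, as expected when most
CpGs carry no hydroxymethylation. The top-1% high-5hmC set (20 of
2,000 CpGs here) reaches the ~0.25 threshold in every sample, the
recursive beta-mixture clustering recovers the cohort's two 5hmC
clusters, and membership in the low-5hmC cluster carries a 3.3-fold
hazard of death after adjusting for age and sex — matching the
generating hazard ratio of 3.

## Command line

The same stages are available as subcommands of the `oxyhmc` console
script — `simulate`, `filter`, `estimate`, `landscape`, `enrich`,
`cluster`, `survive`, and `run-all` (which drives the whole pipeline
from a JSON/YAML config and writes a machine-readable run manifest):

```bash
oxyhmc simulate --outdir cohort/ --seed 7 --n-cpgs 2000 --n-samples 30
oxyhmc run-all --config pipeline.json
```

All stage artefacts are plain TSV/BED, so any stage can be inspected or
re-run from its predecessor's files.

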