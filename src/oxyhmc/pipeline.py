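"""End-to-end orchestration: config validation, staged runs, manifest.

Stages run in order filter -> estimate -> landscape -> enrich ->
cluster -> survive, each writing plain TSV artefacts into the output
directory so any stage can be inspected or re-run from its
predecessor's files.  A machine-readable manifest records package and
library versions, the seed, input checksums and per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cluster as clu
from . import enrich as enr
from . import io as oio
from . import landscape as lsc
from . import survival as surv
from .decompose import PairedBisulfiteModel

__all__ = ["PipelineConfig", "validate_config", "run_all"]

log = logging.getLogger("oxyhmc")

_KNOWN_KEYS = {
    "signals_dir", "annotation", "blacklist", "regions_dir", "clinical", "outdir",
    "drop_sex", "fraction", "min_samples", "stratify", "sizes", "adjust",
    "precision_scale", "min_leaf", "seed", "tss_breakpoints",
}


@dataclass
class PipelineConfig:
    signals_dir: str
    annotation: str
    outdir: str
    clinical: str | None = None
    regions_dir: str | None = None
    blacklist: str | None = None
    drop_sex: bool = True
    fraction: float = 0.01
    min_samples: int | None = None
    stratify: bool = True
    sizes: list[int] = field(default_factory=list)
    adjust: list[str] = field(default_factory=lambda: ["age", "sex"])
    precision_scale: float = 1.0
    min_leaf: int = 3
    seed: int = 0
    tss_breakpoints: list[float] = field(
        default_factory=lambda: [-50_000, -5_000, -1_000, 1_000, 5_000, 50_000]
    )


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a JSON/YAML config, reporting all errors at once.

    Unknown keys produce warnings (forward compatibility), not errors.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)  # YAML is a JSON superset
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")

    errors: list[str] = []
    for key in set(raw) - _KNOWN_KEYS:
        log.warning("config: unknown key %r ignored", key)
        raw.pop(key)

    for key in ("signals_dir", "annotation", "outdir"):
        if key not in raw:
            errors.append(f"missing required key '{key}'")
    for key in ("signals_dir", "annotation", "blacklist", "clinical", "regions_dir"):
        val = raw.get(key)
        if val is not None and not Path(val).exists():
            errors.append(f"{key}: path does not exist: {val}")
    frac = raw.get("fraction", 0.01)
    if not (isinstance(frac, (int, float)) and 0 < frac < 1):
        errors.append(f"fraction must lie in (0, 1), got {frac!r}")
    if raw.get("min_leaf", 3) < 1:
        errors.append("min_leaf must be >= 1")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {seed!r}")
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return PipelineConfig(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "oxyhmc",
        "version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "inputs": {},
        "stages": [],
    }
    signals_dir = Path(config.signals_dir)
    for name in ("S_BS", "R_BS", "S_oxBS", "R_oxBS"):
        p = signals_dir / f"{name}.tsv"
        manifest["inputs"][str(p)] = _sha256(p)
    manifest["inputs"][config.annotation] = _sha256(config.annotation)

    stage = "filter"
    try:
        cohort = oio.read_cohort(config.signals_dir, config.annotation, config.clinical)
        blacklist = set()
        if config.blacklist:
            blacklist = {
                line.strip() for line in open(config.blacklist) if line.strip()
            }
        retained, report = oio.filter_probes(cohort.annotation, blacklist, config.drop_sex)
        pd.Series(retained, name="probe_id").to_csv(out / "retained_probes.tsv", sep="\t", index=False)
        (out / "filter_report.json").write_text(json.dumps(report.as_dict(), indent=1))
        manifest["stages"].append({"stage": stage, "probes_retained": report.n_retained})
        log.info("filter: retained %d / %d probes", report.n_retained, report.n_input)

        stage = "estimate"
        model = PairedBisulfiteModel.from_cohort(
            cohort, precision_scale=config.precision_scale, probes=retained
        )
        fit = model.fit()
        for nm, m in (("pi1", fit.pi1), ("pi2", fit.pi2), ("pi3", fit.pi3)):
            oio.write_matrix(m, out / f"{nm}.tsv")
        fit.diagnostics().to_csv(out / "fit_diagnostics.tsv", sep="\t", index=False)
        manifest["stages"].append(
            {"stage": stage, "n_entries": int(fit.pi3.size),
             "failed": int((~fit.converged.to_numpy()).sum())}
        )

        stage = "landscape"
        annotation = cohort.annotation.loc[retained]
        summary = lsc.cpg_summary(fit.pi3)
        high = lsc.select_high(summary["mean"], fraction=config.fraction)
        counts, rec_frac = lsc.recurrence(fit.pi3, high, config.min_samples)
        high_table = summary.loc[high.probe_ids].assign(recurrence_count=counts)
        high_table.to_csv(out / "high_set.tsv", sep="\t")
        meta5hmc = lsc.tss_metaplot(fit.pi3, annotation)
        meta5mc = lsc.tss_metaplot(fit.pi2, annotation)
        meta = meta5hmc.rename(columns={"mean": "mean_5hmC"})
        meta["mean_5mC"] = meta5mc["mean"]
        meta.to_csv(out / "tss_metaplot.tsv", sep="\t", index=False)
        ptable, ktable, alpha_adj = lsc.stratum_percentiles(summary["mean"], annotation)
        ptable.to_csv(out / "stratum_percentiles.tsv", sep="\t")
        ktable.to_csv(out / "stratum_tests.tsv", sep="\t", index=False)
        dist = lsc.tss_distance_bins(high, annotation, config.tss_breakpoints)
        dist.to_csv(out / "tss_distance_bins.tsv", sep="\t", index=False)
        manifest["stages"].append(
            {"stage": stage, "n_high": len(high), "threshold": high.threshold,
             "recurrent_fraction": rec_frac, "adjusted_alpha": alpha_adj}
        )

        stage = "enrich"
        if config.regions_dir:
            beds = sorted(Path(config.regions_dir).glob("*.bed"))
            sets = [oio.read_regions(p) for p in beds]
            high_flags = pd.Series(
                annotation.index.isin(high.probe_ids), index=annotation.index
            )
            table = enr.multi_set_enrichment(high_flags, sets, annotation, config.stratify)
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"].append({"stage": stage, "sets_tested": len(sets)})
        else:
            manifest["stages"].append({"stage": stage, "sets_tested": 0})

        stage = "cluster"
        values = fit.pi3.loc[high.probe_ids].T  # samples x CpGs
        solution = clu.recursive_partition(values, min_leaf=config.min_leaf, seed=config.seed)
        labels_out = pd.DataFrame(
            {"leaf": solution.labels, "root_side": solution.root_side}
        ).rename_axis("sample_id")
        labels_out.to_csv(out / "cluster_labels.tsv", sep="\t")
        pd.DataFrame(solution.tree).to_csv(out / "cluster_tree.tsv", sep="\t", index=False)
        index = fit.total_hydroxy_index()
        index.rename("total_5hmC_index").to_csv(out / "total_5hmc_index.tsv", sep="\t")
        manifest["stages"].append({"stage": stage, "n_leaves": solution.n_leaves})

        stage = "survive"
        if cohort.clinical is not None and solution.n_leaves == 1:
            log.warning("survive: single-leaf clustering, no group contrast to test")
            manifest["stages"].append({"stage": stage, "skipped": "no root split"})
        elif cohort.clinical is not None:
            fitres = surv.cox_fit(
                cohort.clinical, solution.root_side, tuple(config.adjust)
            )
            pd.DataFrame(
                [{"term": "cluster_low", "hr": fitres.hr, "ci_low": fitres.ci_low,
                  "ci_high": fitres.ci_high, "p": fitres.p}]
            ).to_csv(out / "survival.tsv", sep="\t", index=False)
            surv.km_coordinates(cohort.clinical, solution.root_side).to_csv(
                out / "km_coordinates.tsv", sep="\t", index=False
            )
            manifest["stages"].append(
                {"stage": stage, "hr": fitres.hr, "p": fitres.p, "n_events": fitres.n_events}
            )
        else:
            manifest["stages"].append({"stage": stage, "skipped": True})
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
    return manifest
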