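"""Readers/writers for signal matrices, annotations, region sets and
clinical tables, plus the probe exclusion filter.

On-disk formats: tab-delimited matrices (header row of sample ids, first
column probe_id), BED3+ region files (0-based half-open), and a
tab/comma-delimited clinical table.  Missing signal values are encoded
"NA".  Probe positions are 1-based; the BED/probe overlap convention is
owned by :mod:`oxyhmc.enrich` (a probe at 1-based position p overlaps a
BED interval (start, end] mapped as start < p <= end).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RegionSet",
    "Cohort",
    "FilterReport",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "read_clinical",
    "read_cohort",
    "read_regions",
    "write_regions",
    "filter_probes",
]

ANNOTATION_COLUMNS = [
    "probe_id", "chromosome", "position", "stratum", "gene_region", "tss_distance", "strand",
]
STRATA = ("island", "shore", "shelf", "ocean")
GENE_REGIONS = ("promoter", "exon", "intron", "intergenic")
SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass(frozen=True)
class RegionSet:
    """A named list of genomic intervals, 0-based half-open."""

    name: str
    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"{self.name}: interval {chrom}:{start}-{end} has start >= end")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class Cohort:
    """Aligned signal matrices plus annotation and clinical tables."""

    s_bs: pd.DataFrame
    r_bs: pd.DataFrame
    s_oxbs: pd.DataFrame
    r_oxbs: pd.DataFrame
    annotation: pd.DataFrame
    clinical: pd.DataFrame | None = None

    @property
    def probes(self) -> pd.Index:
        return self.s_bs.index

    @property
    def samples(self) -> pd.Index:
        return self.s_bs.columns


@dataclass
class FilterReport:
    """Counts of probe exclusions by reason (first-applied rule wins)."""

    n_input: int
    n_retained: int
    n_sex_chromosome: int
    n_blacklisted: int

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "retained": self.n_retained,
            "sex_chromosome": self.n_sex_chromosome,
            "blacklisted": self.n_blacklisted,
        }


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probe x sample TSV (first column probe_id, "NA" missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    for col in df.columns[df.dtypes == object]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            probe = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric cell at probe {probe!r}, sample {col!r}: "
                f"{df.loc[probe, col]!r}"
            )
        df[col] = coerced
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a probe x sample matrix; round-trips through read_matrix."""
    matrix.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation missing columns {missing}")
    bad_stratum = set(df["stratum"]) - set(STRATA)
    if bad_stratum:
        raise ValueError(f"{path}: unknown strata {sorted(bad_stratum)}")
    bad_region = set(df["gene_region"]) - set(GENE_REGIONS)
    if bad_region:
        raise ValueError(f"{path}: unknown gene regions {sorted(bad_region)}")
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()[:5]
        raise ValueError(f"{path}: duplicate probe ids, e.g. {dups}")
    return df.set_index("probe_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    required = ["sample_id", "age_at_diagnosis", "sex", "survival_months", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {missing}")
    if "excluded_flag" not in df.columns:
        df["excluded_flag"] = False
    if (df["survival_months"] < 0).any():
        raise ValueError(f"{path}: negative survival_months")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event must be 0/1")
    return df.set_index("sample_id")


def read_cohort(
    signals_dir: str | Path,
    annotation_path: str | Path,
    clinical_path: str | Path | None = None,
) -> Cohort:
    """Read and align the four signal matrices with the annotation.

    The four TSVs must share identical row and column label sets; sample
    order is taken from the S_BS header, probe order from the annotation
    table.  Mismatches are hard errors naming the offending labels.
    """
    d = Path(signals_dir)
    mats = {name: read_matrix(d / f"{name}.tsv") for name in ("S_BS", "R_BS", "S_oxBS", "R_oxBS")}
    ref = mats["S_BS"]
    for name, m in mats.items():
        if set(m.index) != set(ref.index):
            diff = sorted(set(m.index) ^ set(ref.index))[:5]
            raise ValueError(f"{name}: probe set differs from S_BS, e.g. {diff}")
        if set(m.columns) != set(ref.columns):
            diff = sorted(set(m.columns) ^ set(ref.columns))[:5]
            raise ValueError(f"{name}: sample set differs from S_BS, e.g. {diff}")

    annotation = read_annotation(annotation_path)
    missing = sorted(set(ref.index) - set(annotation.index))
    if missing:
        raise ValueError(
            f"{len(missing)} probes present in signals but absent from annotation, "
            f"e.g. {missing[:10]}"
        )
    probe_order = [p for p in annotation.index if p in set(ref.index)]
    annotation = annotation.loc[probe_order]
    aligned = {name: m.loc[probe_order, ref.columns] for name, m in mats.items()}

    clinical = None
    if clinical_path is not None:
        clinical = read_clinical(clinical_path)
        missing_samples = sorted(set(ref.columns) - set(clinical.index))
        if missing_samples:
            raise ValueError(f"samples missing from clinical table: {missing_samples}")
        clinical = clinical.loc[list(ref.columns)]

    return Cohort(
        s_bs=aligned["S_BS"], r_bs=aligned["R_BS"],
        s_oxbs=aligned["S_oxBS"], r_oxbs=aligned["R_oxBS"],
        annotation=annotation, clinical=clinical,
    )


def filter_probes(
    annotation: pd.DataFrame,
    blacklist_ids: set[str] | None = None,
    drop_sex: bool = True,
) -> tuple[list[str], FilterReport]:
    """Exclude sex-chromosome and blacklisted probes.

    Mirrors the usual array pre-filter: sex chromosomes first, then any
    caller-supplied blacklist (cross-reactive / SNP-overlapping probe
    lists).  A probe matching both rules is counted once, under the sex
    rule.  Blacklist ids absent from the annotation are ignored.
    """
    blacklist = set(blacklist_ids or ())
    on_sex = annotation["chromosome"].isin(SEX_CHROMOSOMES) if drop_sex else pd.Series(
        False, index=annotation.index
    )
    in_blacklist = annotation.index.isin(blacklist) & ~on_sex
    retained = annotation.index[~on_sex & ~in_blacklist].tolist()
    report = FilterReport(
        n_input=len(annotation),
        n_retained=len(retained),
        n_sex_chromosome=int(on_sex.sum()),
        n_blacklisted=int(in_blacklist.sum()),
    )
    if not retained:
        warnings.warn("probe filter retained zero probes", stacklevel=2)
    return retained, report


def read_regions(path: str | Path, name: str | None = None) -> RegionSet:
    """Read a BED3+ file (0-based half-open) into a RegionSet."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append((chrom, start, end))
    return RegionSet(name=name or Path(path).stem, intervals=intervals)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
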