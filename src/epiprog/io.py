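"""Readers, writers and validated containers for the tabular formats the
pipeline touches.

Coordinate conventions
----------------------
Files use 1-based, fully-inclusive coordinates (the convention of the
methylKit text dialect and of refGene-style annotation tables).  Internally
everything is converted to 0-based positions / half-open intervals on load
and converted back on write, so interval arithmetic is unambiguous.

Strand symbols ``F``/``R`` (methylKit dialect) are accepted and mapped to
``+``/``-``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "CountMatrix",
    "CpGMethylationTable",
    "CohortData",
    "read_annotation",
    "write_annotation",
    "read_counts",
    "write_counts",
    "read_cpg_table",
    "write_cpg_table",
    "read_cohort",
    "write_cohort",
    "read_table",
    "write_table",
]

_STRAND_MAP = {"F": "+", "R": "-", "+": "+", "-": "-"}


class FormatError(ValueError):
    """A file violated the dialect this pipeline expects."""


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """Gene intervals with strand-aware TSS / transcription terminus.

    ``df`` columns: ``gene_id, chrom, strand, start, end, tss, terminus``
    where ``start``/``end`` are 0-based half-open and ``tss``/``terminus``
    are 0-based positions of the first and last transcribed base.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicate gene_id {dup!r} in annotation")
        if not df["strand"].isin(["+", "-"]).all():
            bad = df.loc[~df["strand"].isin(["+", "-"]), "strand"].iloc[0]
            raise FormatError(f"unknown strand symbol {bad!r}")
        if (df["start"] >= df["end"]).any():
            gid = df.loc[df["start"] >= df["end"], "gene_id"].iloc[0]
            raise FormatError(f"txStart > txEnd for gene {gid!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> pd.Series:
        return self.df["gene_id"]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneAnnotation":
        """Build from 0-based half-open ``start``/``end``, deriving TSS."""
        df = df.copy().reset_index(drop=True)
        plus = df["strand"] == "+"
        df["tss"] = np.where(plus, df["start"], df["end"] - 1)
        df["terminus"] = np.where(plus, df["end"] - 1, df["start"])
        return cls(df[["gene_id", "chrom", "strand", "start", "end", "tss", "terminus"]])


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a TSV with columns gene_id, chrom, strand, txStart, txEnd
    (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "strand", "txStart", "txEnd"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["strand"] = df["strand"].map(lambda s: _STRAND_MAP.get(str(s)))
    if df["strand"].isna().any():
        raise FormatError(f"{path}: unknown strand symbol")
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"].astype(str),
            "chrom": df["chrom"].astype(str),
            "strand": df["strand"],
            "start": df["txStart"].astype(int) - 1,  # to 0-based half-open
            "end": df["txEnd"].astype(int),
        }
    )
    return GeneAnnotation.from_frame(out)


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "gene_id": ann.df["gene_id"],
            "chrom": ann.df["chrom"],
            "strand": ann.df["strand"],
            "txStart": ann.df["start"] + 1,  # back to 1-based inclusive
            "txEnd": ann.df["end"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample raw count matrix with a sample -> group map."""

    counts: pd.DataFrame  # genes x samples, integer
    group_map: Mapping[str, str]

    def __post_init__(self) -> None:
        c = self.counts
        if (c.to_numpy() < 0).any():
            raise FormatError("negative count")
        if not np.issubdtype(c.to_numpy().dtype, np.integer):
            raise FormatError("non-integer count matrix")
        missing = [s for s in c.columns if s not in self.group_map]
        if missing:
            raise FormatError(f"samples without a group: {missing}")
        if len(set(self.group_map[s] for s in c.columns)) < 2:
            raise FormatError("need at least 2 groups")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def group_samples(self, group: str) -> list[str]:
        out = [s for s in self.counts.columns if self.group_map[s] == group]
        if not out:
            raise KeyError(f"unknown group label {group!r}")
        return out


def read_counts(path: str | Path, group_map: Mapping[str, str]) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise FormatError(f"{path}: non-integer count")
        df = df.round().astype(int)
    return CountMatrix(df, dict(group_map))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# CpG methylation calls (methylKit text dialect)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CpGMethylationTable:
    """Strand-resolved per-CpG coverage and methylated-read counts.

    ``sites`` has columns ``chrom, pos, strand`` (pos 0-based); ``coverage``
    and ``meth`` are site x sample integer frames sharing ``sites``'s index.
    Sites absent from a sample carry coverage 0 there (union semantics).
    """

    sites: pd.DataFrame
    coverage: pd.DataFrame
    meth: pd.DataFrame
    group_map: Mapping[str, str]

    def __post_init__(self) -> None:
        if (self.meth.to_numpy() > self.coverage.to_numpy()).any():
            raise FormatError("meth_count exceeds coverage")
        if (self.coverage.to_numpy() < 0).any() or (self.meth.to_numpy() < 0).any():
            raise FormatError("negative coverage or meth_count")
        key = self.sites[["chrom", "pos", "strand"]]
        if key.duplicated().any():
            raise FormatError("duplicate (chrom, pos, strand) site")
        missing = [s for s in self.coverage.columns if s not in self.group_map]
        if missing:
            raise FormatError(f"samples without a group: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.coverage.columns)

    def group_samples(self, group: str) -> list[str]:
        out = [s for s in self.coverage.columns if self.group_map[s] == group]
        if not out:
            raise KeyError(f"unknown group label {group!r}")
        return out

    def __len__(self) -> int:
        return len(self.sites)


_CPG_COLS = ["chrBase", "chr", "base", "strand", "coverage", "freqC", "freqT"]


def _read_one_cpg_file(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        has_header = first.split() and first.split()[0] == "chrBase"
        fh.seek(0)
        df = pd.read_csv(
            fh, sep=r"\s+", header=0 if has_header else None,
            names=None if has_header else _CPG_COLS,
        )
    if has_header:
        missing = [c for c in _CPG_COLS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
    offset = 2 if has_header else 1  # file line number of the first data row
    strand = df["strand"].map(lambda s: _STRAND_MAP.get(str(s)))
    if strand.isna().any():
        line = int(strand.index[strand.isna()][0]) + offset
        raise FormatError(f"{path}, line {line}: unknown strand symbol")
    freq_sum = df["freqC"].astype(float) + df["freqT"].astype(float)
    bad = (freq_sum - 100.0).abs() > 0.5
    if bad.any():
        line = int(bad.index[bad.to_numpy()][0]) + offset
        raise FormatError(
            f"{path}, line {line}: freqC + freqT = {freq_sum[bad].iloc[0]:g}, expected 100"
        )
    cov = df["coverage"].astype(int)
    if (cov < 0).any():
        line = int(cov.index[(cov < 0).to_numpy()][0]) + offset
        raise FormatError(f"{path}, line {line}: negative coverage")
    out = pd.DataFrame(
        {
            "chrom": df["chr"].astype(str),
            "pos": df["base"].astype(int) - 1,  # 1-based file -> 0-based
            "strand": strand,
            "coverage": cov,
            # format stores percentages; recover integer methylated counts
            "meth": np.round(cov * df["freqC"].astype(float) / 100.0).astype(int),
        }
    )
    return out


def read_cpg_table(
    paths: Mapping[str, str | Path], group_map: Mapping[str, str]
) -> CpGMethylationTable:
    """Read one methylKit-style file per sample and take the union of sites.

    ``paths`` maps sample id -> file path.  Sites present in only some
    samples are kept with coverage 0 elsewhere.
    """
    per_sample: dict[str, pd.DataFrame] = {}
    for sample, path in paths.items():
        df = _read_one_cpg_file(path)
        per_sample[sample] = df.set_index(["chrom", "pos", "strand"])
    all_sites = None
    for df in per_sample.values():
        idx = df.index
        all_sites = idx if all_sites is None else all_sites.union(idx)
    all_sites = all_sites.sort_values()
    cov = pd.DataFrame(0, index=all_sites, columns=list(paths), dtype=int)
    meth = pd.DataFrame(0, index=all_sites, columns=list(paths), dtype=int)
    for sample, df in per_sample.items():
        cov.loc[df.index, sample] = df["coverage"].to_numpy()
        meth.loc[df.index, sample] = df["meth"].to_numpy()
    sites = pd.DataFrame(all_sites.to_list(), columns=["chrom", "pos", "strand"])
    cov.index = sites.index
    meth.index = sites.index
    return CpGMethylationTable(sites, cov, meth, dict(group_map))


def write_cpg_table(table: CpGMethylationTable, outdir: str | Path) -> dict[str, Path]:
    """Write one methylKit-style file per sample; returns sample -> path.

    Only the sites covered in a sample are written for it, mirroring how
    such files are produced upstream.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    back = {"+": "F", "-": "R"}
    for sample in table.samples:
        cov = table.coverage[sample].to_numpy()
        keep = cov > 0
        s = table.sites[keep]
        c = cov[keep]
        m = table.meth[sample].to_numpy()[keep]
        base = s["pos"].to_numpy() + 1  # back to 1-based
        freq_c = np.where(c > 0, 100.0 * m / np.maximum(c, 1), 0.0)
        df = pd.DataFrame(
            {
                "chrBase": s["chrom"].astype(str) + "." + pd.Series(base, index=s.index).astype(str),
                "chr": s["chrom"],
                "base": base,
                "strand": s["strand"].map(back),
                "coverage": c,
                "freqC": np.round(freq_c, 2),
                "freqT": np.round(100.0 - freq_c, 2),
            }
        )
        path = outdir / f"{sample}.cpg.txt"
        df.to_csv(path, sep="\t", index=False)
        written[sample] = path
    return written


# ---------------------------------------------------------------------------
# Patient cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortData:
    """Survival times, event indicators, covariates and a feature x patient
    matrix (expression or methylation beta) for one cohort."""

    patient_id: pd.Index
    time: pd.Series  # years, > 0
    event: pd.Series  # {0, 1}
    covariates: pd.DataFrame  # patients x named covariates (may be empty)
    matrix: pd.DataFrame  # features x patients

    def __post_init__(self) -> None:
        if (self.time <= 0).any():
            raise FormatError("survival time must be > 0")
        if not self.event.isin([0, 1]).all():
            raise FormatError("event must be 0/1")
        unknown = [p for p in self.matrix.columns if p not in set(self.patient_id)]
        if unknown:
            raise FormatError(f"matrix patients missing from survival table: {unknown[:5]}")

    @property
    def n(self) -> int:
        return len(self.patient_id)


def read_cohort(survival_path: str | Path, matrix_path: str | Path) -> CohortData:
    """Read a cohort: survival TSV (patient_id, time_years, event,
    covariates...) plus a feature x patient matrix TSV."""
    surv = pd.read_csv(survival_path, sep="\t")
    for col in ("patient_id", "time_years", "event"):
        if col not in surv.columns:
            raise FormatError(f"{survival_path}: missing column {col!r}")
    surv = surv.set_index("patient_id")
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    covars = surv.drop(columns=["time_years", "event"])
    return CohortData(
        patient_id=surv.index,
        time=surv["time_years"].astype(float),
        event=surv["event"].astype(int),
        covariates=covars,
        matrix=matrix,
    )


def write_cohort(cohort: CohortData, survival_path: str | Path, matrix_path: str | Path) -> None:
    surv = pd.DataFrame(
        {
            "patient_id": cohort.patient_id,
            "time_years": cohort.time.to_numpy(),
            "event": cohort.event.to_numpy(),
        }
    )
    for col in cohort.covariates.columns:
        surv[col] = cohort.covariates[col].to_numpy()
    surv.to_csv(survival_path, sep="\t", index=False)
    cohort.matrix.to_csv(matrix_path, sep="\t", index_label="feature")


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a documented header, no index."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
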