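"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators mirror the three data layers of a staged-progression
methylome/transcriptome study:

* grouped negative-binomial RNA-seq counts with planted log2 fold changes,
* beta-binomial CpG methylomes with planted promoter / gene-body shifts
  coupled to the expression effects under the four direction rules
  (promoter hypo -> up, promoter hyper -> down, body hyper -> up,
  body hypo -> down),
* survival cohorts whose hazard is proportional to a planted signature
  score, i.e. exactly the proportional-hazards model the scoring stage fits.

One global seed fans out to per-stage child seeds via
:func:`numpy.random.SeedSequence.spawn`, so stages are reproducible and
independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CohortData, CountMatrix, CpGMethylationTable, GeneAnnotation

__all__ = [
    "PlantedTruth",
    "COUPLING_MODES",
    "make_annotation",
    "simulate_counts",
    "simulate_methylome",
    "simulate_cohort",
    "make_planted_truth",
    "make_progression_truth",
    "child_seeds",
]

log = logging.getLogger(__name__)

#: the four direction-consistent coupling modes plus the two controls
COUPLING_MODES = (
    "promoter-hypo-up",
    "promoter-hyper-down",
    "body-hyper-up",
    "body-hypo-down",
    "null",
    "decoy-discordant",
)

# mode -> (region, sign of log2FC, sign of methylation shift)
_MODE_SPEC = {
    "promoter-hypo-up": ("promoter", +1, -1),
    "promoter-hyper-down": ("promoter", -1, +1),
    "body-hyper-up": ("body", +1, +1),
    "body-hypo-down": ("body", -1, -1),
}
# discordant decoys pair a promoter shift with the *same*-sign expression
# change, violating the direction rules by construction
_DECOY_SPEC = ("promoter", +1, +1)


def child_seeds(seed: int, n: int) -> list[int]:
    """Fan one global seed out into ``n`` independent child seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of planted effects, one row per gene.

    ``df`` columns: ``gene_id, mode, log2fc, region, meth_shift`` where
    ``meth_shift`` is in percentage points and ``region`` is one of
    ``promoter / body / none``.  ``affected_groups`` lists the group labels
    in which the effect is present (expression mean multiplied by
    2**log2fc, region methylation shifted); per-gene overrides live in the
    optional ``affected_groups`` column.
    """

    df: pd.DataFrame
    affected_groups: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = ~self.df["mode"].isin(COUPLING_MODES)
        if bad.any():
            raise ValueError(f"unknown coupling mode {self.df.loc[bad, 'mode'].iloc[0]!r}")

    def groups_for(self, gene_id: str) -> tuple[str, ...]:
        if "affected_groups" in self.df.columns:
            row = self.df.set_index("gene_id").loc[gene_id]
            if isinstance(row["affected_groups"], tuple):
                return row["affected_groups"]
        return self.affected_groups

    @property
    def coupled(self) -> pd.DataFrame:
        return self.df[self.df["mode"].isin(_MODE_SPEC)]

    @property
    def decoys(self) -> pd.DataFrame:
        return self.df[self.df["mode"] == "decoy-discordant"]

    @classmethod
    def null(cls, gene_ids: Sequence[str], groups: Sequence[str] = ()) -> "PlantedTruth":
        df = pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "mode": "null",
                "log2fc": 0.0,
                "region": "none",
                "meth_shift": 0.0,
            }
        )
        return cls(df, tuple(groups))


def make_planted_truth(
    gene_ids: Sequence[str],
    affected_groups: Sequence[str],
    n_coupled: int = 200,
    n_decoy: int = 20,
    log2fc: float = 3.0,
    meth_shift: float = 40.0,
    seed: int = 0,
) -> PlantedTruth:
    """Plant ``n_coupled`` direction-consistent genes (the four modes in
    equal proportion, so up/down effects balance) and ``n_decoy``
    discordant decoys among ``gene_ids``; the rest stay null."""
    gene_ids = list(gene_ids)
    if n_coupled + n_decoy > len(gene_ids):
        raise ValueError("more planted genes than genes")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(gene_ids), size=n_coupled + n_decoy, replace=False)
    modes = np.full(len(gene_ids), "null", dtype=object)
    lfc = np.zeros(len(gene_ids))
    region = np.full(len(gene_ids), "none", dtype=object)
    shift = np.zeros(len(gene_ids))
    mode_cycle = list(_MODE_SPEC)
    for k, idx in enumerate(chosen[:n_coupled]):
        m = mode_cycle[k % 4]
        reg, es, ms = _MODE_SPEC[m]
        modes[idx], lfc[idx], region[idx], shift[idx] = m, es * log2fc, reg, ms * meth_shift
    for idx in chosen[n_coupled:]:
        reg, es, ms = _DECOY_SPEC
        modes[idx] = "decoy-discordant"
        lfc[idx], region[idx], shift[idx] = es * log2fc, reg, ms * meth_shift
    df = pd.DataFrame(
        {"gene_id": gene_ids, "mode": modes, "log2fc": lfc, "region": region, "meth_shift": shift}
    )
    return PlantedTruth(df, tuple(affected_groups))


def make_progression_truth(
    gene_ids: Sequence[str],
    lines: Sequence[str] = ("melan-a", "4C", "4C11-", "4C11+"),
    n_per_archetype: int = 12,
    log2fc: float = 3.0,
    meth_shift: float = 40.0,
    seed: int = 0,
) -> PlantedTruth:
    """Plant malignancy / EMT / metastasis archetypes for the four-line
    progression design.

    Archetypes differ only in which lines carry the effect relative to the
    parental line: malignancy genes are altered in all three derived lines,
    EMT genes in the two mesenchymal-like lines, metastasis genes only in
    the metastatic line.
    """
    parental, premalignant, nonmet, met = lines
    arch_groups = {
        "malignancy": (premalignant, nonmet, met),
        "EMT": (premalignant, nonmet),
        "metastasis": (met,),
    }
    gene_ids = list(gene_ids)
    need = 3 * n_per_archetype
    if need > len(gene_ids):
        raise ValueError("more planted genes than genes")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(gene_ids), size=need, replace=False)
    rows = []
    mode_cycle = list(_MODE_SPEC)
    for a, arch in enumerate(arch_groups):
        for k in range(n_per_archetype):
            idx = chosen[a * n_per_archetype + k]
            m = mode_cycle[k % 4]
            reg, es, ms = _MODE_SPEC[m]
            rows.append(
                {
                    "gene_id": gene_ids[idx],
                    "mode": m,
                    "log2fc": es * log2fc,
                    "region": reg,
                    "meth_shift": ms * meth_shift,
                    "archetype": arch,
                    "affected_groups": arch_groups[arch],
                }
            )
    planted = pd.DataFrame(rows)
    null_ids = [g for g in gene_ids if g not in set(planted["gene_id"])]
    nulls = pd.DataFrame(
        {
            "gene_id": null_ids,
            "mode": "null",
            "log2fc": 0.0,
            "region": "none",
            "meth_shift": 0.0,
            "archetype": "none",
            "affected_groups": [() for _ in null_ids],
        }
    )
    df = pd.concat([planted, nulls], ignore_index=True)
    return PlantedTruth(df, ())


# ---------------------------------------------------------------------------
# Annotation + CpG catalogue
# ---------------------------------------------------------------------------

def make_annotation(
    n_genes: int,
    n_chroms: int = 2,
    gene_length_range: tuple[int, int] = (4000, 8000),
    cpg_spacing: int = 150,
    flank: int = 500,
    min_cpg: int = 6,
    intergenic_gap: int = 3000,
    seed: int = 0,
) -> tuple[GeneAnnotation, pd.DataFrame]:
    """Lay non-overlapping genes along ``n_chroms`` chromosomes and drop a
    CpG catalogue of roughly evenly spaced sites across each gene's
    promoter (TSS +/- ``flank``) and body.

    Returns ``(annotation, catalogue)`` where the catalogue has columns
    ``chrom, pos, strand`` (0-based positions, both CpG strands
    represented).  Raises if spacing and length cannot place ``min_cpg``
    sites in each region.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = gene_length_range
    if (2 * flank + 1) // cpg_spacing + 1 < min_cpg:
        raise ValueError("cpg_spacing too coarse for min_cpg promoter sites")
    if (lo - flank) // cpg_spacing < min_cpg:
        raise ValueError("cpg_spacing too coarse for min_cpg body sites at min length")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    strands = rng.choice(["+", "-"], size=n_genes)
    chroms = [f"chr{(i % n_chroms) + 1}" for i in range(n_genes)]
    rows = []
    cursor = {c: intergenic_gap for c in set(chroms)}
    for i in range(n_genes):
        c = chroms[i]
        start = cursor[c]
        end = start + int(lengths[i])
        cursor[c] = end + intergenic_gap
        rows.append(
            {
                "gene_id": f"g{i:05d}",
                "chrom": c,
                "strand": strands[i],
                "start": start,
                "end": end,
            }
        )
    ann = GeneAnnotation.from_frame(pd.DataFrame(rows))

    cat_rows = []
    for _, g in ann.df.iterrows():
        tss = int(g["tss"])
        orient = 1 if g["strand"] == "+" else -1
        length = int(g["end"] - g["start"])
        # promoter: distances -flank..+flank from the TSS
        prom_d = np.arange(-flank, flank + 1, cpg_spacing)
        # body: distances flank+1 .. gene end, in transcription orientation
        body_d = np.arange(flank + 1 + cpg_spacing // 2, length, cpg_spacing)
        jitter = rng.integers(-cpg_spacing // 4, cpg_spacing // 4 + 1, size=len(body_d))
        body_d = np.clip(body_d + jitter, flank + 1, length - 1)
        for d in np.concatenate([prom_d, body_d]):
            cat_rows.append(
                {
                    "chrom": g["chrom"],
                    "pos": tss + orient * int(d),
                    "strand": rng.choice(["+", "-"]),
                }
            )
    cat = (
        pd.DataFrame(cat_rows)
        .drop_duplicates(["chrom", "pos", "strand"])
        .sort_values(["chrom", "pos", "strand"])
        .reset_index(drop=True)
    )
    return ann, cat


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    annotation: GeneAnnotation,
    groups: Sequence[str],
    reps_per_group: int = 3,
    baseline_mean: float = 200.0,
    dispersion: float = 0.1,
    planted: PlantedTruth | None = None,
    seed: int = 0,
) -> CountMatrix:
    """Negative-binomial counts, triplicate design by default.

    Per-gene baseline means are drawn uniform on (0.25, 2.5) x
    ``baseline_mean`` so the matrix spans realistic depth; in each affected
    group a planted gene's mean is multiplied by ``2**log2fc``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    genes = list(annotation.gene_ids)
    n_genes = len(genes)
    base = rng.uniform(0.25, 2.5, n_genes) * baseline_mean
    samples, sample_groups = [], {}
    for g in groups:
        for r in range(reps_per_group):
            name = f"{g}_{r + 1}"
            samples.append(name)
            sample_groups[name] = g
    mu = np.tile(base[:, None], (1, len(samples)))
    if planted is not None:
        tdf = planted.df.set_index("gene_id")
        lfc = tdf.reindex(genes)["log2fc"].fillna(0.0).to_numpy()
        if "affected_groups" in planted.df.columns:
            aff = tdf.reindex(genes)["affected_groups"]
            aff = [set(a) if isinstance(a, (tuple, list, set)) else set() for a in aff]
        else:
            aff = [set(planted.affected_groups)] * n_genes
        for j, s in enumerate(samples):
            grp = sample_groups[s]
            hit = np.array([grp in a for a in aff])
            mu[:, j] = np.where(hit, mu[:, j] * 2.0 ** lfc, mu[:, j])
    counts = _nb_draw(rng, mu, dispersion)
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    return CountMatrix(df, sample_groups)


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def simulate_methylome(
    annotation: GeneAnnotation,
    cpg_catalogue: pd.DataFrame,
    groups: Sequence[str],
    reps_per_group: int = 3,
    coverage_mean: float = 30.0,
    baseline_beta: float = 0.5,
    precision: float = 300.0,
    planted: PlantedTruth | None = None,
    flank: int = 500,
    seed: int = 0,
) -> CpGMethylationTable:
    """Beta-binomial methylomes with planted region-level shifts.

    Per site and sample, coverage ~ 1 + Poisson(coverage_mean - 1) and
    meth_count ~ Binomial(coverage, p) with p ~ Beta(mean, precision); the
    Beta layer models replicate overdispersion.  All CpGs of a planted
    gene-region shift their mean by ``meth_shift`` points in affected
    groups, clipped to [0.02, 0.98] (a warning is logged when clipping
    bites).
    """
    if not 0 < baseline_beta < 1:
        raise ValueError("baseline_beta must be in (0, 1)")
    if precision <= 0:
        raise ValueError("precision must be > 0")
    rng = np.random.default_rng(seed)
    n_sites = len(cpg_catalogue)
    samples, sample_groups = [], {}
    for g in groups:
        for r in range(reps_per_group):
            name = f"{g}_{r + 1}"
            samples.append(name)
            sample_groups[name] = g

    # per-site baseline mean, shared across groups
    mean = np.full(n_sites, baseline_beta)
    shift = np.zeros((n_sites, len(samples)))
    if planted is not None:
        site_region = _catalogue_regions(annotation, cpg_catalogue, flank)
        tdf = planted.df
        planted_rows = tdf[(tdf["region"] != "none") & (tdf["meth_shift"] != 0)]
        if "affected_groups" in tdf.columns:
            aff_col = planted_rows["affected_groups"]
        else:
            aff_col = pd.Series([planted.affected_groups] * len(planted_rows), index=planted_rows.index)
        for (_, row), aff in zip(planted_rows.iterrows(), aff_col):
            mask = (site_region["gene_id"] == row["gene_id"]) & (
                site_region["region"] == row["region"]
            )
            idx = site_region.index[mask]
            if len(idx) == 0:
                continue
            for j, s in enumerate(samples):
                if sample_groups[s] in set(aff):
                    shift[idx, j] += row["meth_shift"] / 100.0
    p_mean = mean[:, None] + shift
    clipped = (p_mean < 0.02) | (p_mean > 0.98)
    if clipped.any():
        log.warning("planted shift clipped at %d site-samples", int(clipped.sum()))
    p_mean = np.clip(p_mean, 0.02, 0.98)
    cov = 1 + rng.poisson(coverage_mean - 1.0, size=(n_sites, len(samples)))
    p = rng.beta(p_mean * precision, (1.0 - p_mean) * precision)
    meth = rng.binomial(cov, p)
    sites = cpg_catalogue[["chrom", "pos", "strand"]].reset_index(drop=True)
    cov_df = pd.DataFrame(cov, columns=samples)
    meth_df = pd.DataFrame(meth, columns=samples)
    return CpGMethylationTable(sites, cov_df, meth_df, sample_groups)


def _catalogue_regions(
    annotation: GeneAnnotation, cpg_catalogue: pd.DataFrame, flank: int
) -> pd.DataFrame:
    """First (gene, region) hit per catalogue site, aligned to its index."""
    from .regions import assign_region

    hits = assign_region(cpg_catalogue, annotation, flank=flank)
    first = hits.groupby("site_index").first()
    out = pd.DataFrame(
        {"gene_id": pd.NA, "region": pd.NA}, index=cpg_catalogue.index, dtype=object
    )
    out.loc[first.index, "gene_id"] = first["gene_id"]
    out.loc[first.index, "region"] = first["region"]
    return out


# ---------------------------------------------------------------------------
# Survival cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_patients: int,
    signature,
    beta_per_sd: float,
    baseline_hazard: float = 0.1,
    censor_rate: float = 0.2,
    n_noise_genes: int = 100,
    seed: int = 0,
) -> CohortData:
    """Exponential survival with hazard proportional to the signature score.

    Gene expression is standard normal per gene; the combined score is
    computed exactly as the scoring stage defines it (z-transform, +1/-1
    weighting), standardized to unit SD across patients, and enters the
    hazard as ``baseline_hazard * exp(beta_per_sd * score)``.  Censoring is
    independent exponential with its rate solved so the expected censored
    fraction equals ``censor_rate``.  The standardized score is stored as
    covariate ``signature_score``.
    """
    from scipy.optimize import brentq

    from .survival import signature_score, zscore

    if n_patients < 10:
        raise ValueError("n_patients must be >= 10")
    genes = sorted({g for g, _ in signature.up_genes} | {g for g, _ in signature.down_genes})
    if not genes:
        raise ValueError("empty signature")
    rng = np.random.default_rng(seed)
    all_genes = genes + [f"noise{i:04d}" for i in range(n_noise_genes)]
    patients = pd.Index([f"P{i:04d}" for i in range(n_patients)], name="patient_id")
    expr = pd.DataFrame(
        rng.standard_normal((len(all_genes), n_patients)), index=all_genes, columns=patients
    )
    z = zscore(expr)
    score = signature_score(z, signature, mode="combined")["combined_score"]
    sd = score.std(ddof=1)
    score_std = ((score - 0.0) / sd).to_numpy() if sd > 0 else score.to_numpy()

    lam = baseline_hazard * np.exp(beta_per_sd * score_std)
    t_event = rng.exponential(1.0 / lam)
    if censor_rate <= 0:
        time, event = t_event, np.ones(n_patients, dtype=int)
    else:
        def expected_censored(c: float) -> float:
            return float(np.mean(c / (c + lam))) - censor_rate

        c = brentq(expected_censored, 1e-9 * baseline_hazard, 1e6 * baseline_hazard)
        t_cens = rng.exponential(1.0 / c, size=n_patients)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-9)
    covars = pd.DataFrame({"signature_score": score_std}, index=patients)
    return CohortData(
        patient_id=patients,
        time=pd.Series(time, index=patients, name="time_years"),
        event=pd.Series(event, index=patients, name="event"),
        covariates=covars,
        matrix=expr,
    )
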