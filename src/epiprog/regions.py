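"""Map CpG sites to promoter / gene-body regions and lift site-level DMCs
to gene-region differential-methylation calls.

Region definitions, in gene-strand orientation with flank f = 500 bp:

* promoter: TSS - f .. TSS + f, inclusive;
* gene body: TSS + f + 1 .. transcription end, inclusive.

The boundary base TSS + f belongs to the promoter only, keeping the two
regions disjoint.  The gene's strand (never the CpG's) orients the
arithmetic, and CpG calls from opposite strands are kept separate
throughout.  A region call is emitted for a gene region containing at
least ``min_cpgs`` differentially methylated CpGs (the default reading;
``count="tested"`` switches to counting tested CpGs instead).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneAnnotation

__all__ = ["assign_region", "call_region_dm"]


def _region_intervals(ann: GeneAnnotation, flank: int) -> pd.DataFrame:
    """Per gene, 0-based half-open [lo, hi) intervals for promoter and body."""
    df = ann.df
    tss = df["tss"].to_numpy()
    term = df["terminus"].to_numpy()
    prom_lo = tss - flank
    prom_hi = tss + flank + 1
    plus = (df["strand"] == "+").to_numpy()
    body_lo = np.where(plus, tss + flank + 1, term)
    body_hi = np.where(plus, term + 1, tss - flank)
    rows = []
    for i in range(len(df)):
        rows.append((df["gene_id"].iloc[i], df["chrom"].iloc[i], "promoter",
                     int(prom_lo[i]), int(prom_hi[i])))
        if body_hi[i] > body_lo[i]:  # genes shorter than the flank have no body
            rows.append((df["gene_id"].iloc[i], df["chrom"].iloc[i], "body",
                         int(body_lo[i]), int(body_hi[i])))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "region", "lo", "hi"])


def assign_region(
    sites: pd.DataFrame, annotation: GeneAnnotation, flank: int = 500
) -> pd.DataFrame:
    """Assign each site to the gene regions that contain it.

    ``sites`` needs columns ``chrom, pos`` (0-based).  Returns one row per
    (site, gene, region) hit with columns ``site_index, chrom, pos,
    strand, gene_id, region``; sites overlapping several genes yield
    several rows, unassigned sites none.
    """
    iv = _region_intervals(annotation, flank)
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in iv.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (lo, hi, (g, r)) for g, r, lo, hi in zip(sub["gene_id"], sub["region"], sub["lo"], sub["hi"])
        )
    rows = []
    has_strand = "strand" in sites.columns
    for idx, chrom, pos in zip(sites.index, sites["chrom"], sites["pos"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in tree.at(int(pos)):
            g, r = hit.data
            rows.append(
                {
                    "site_index": idx,
                    "chrom": chrom,
                    "pos": int(pos),
                    "strand": sites.at[idx, "strand"] if has_strand else ".",
                    "gene_id": g,
                    "region": r,
                }
            )
    out = pd.DataFrame(
        rows, columns=["site_index", "chrom", "pos", "strand", "gene_id", "region"]
    )
    return out.sort_values(["gene_id", "region", "pos"], kind="stable").reset_index(drop=True)


def call_region_dm(
    dmcs: pd.DataFrame,
    annotation: GeneAnnotation,
    min_cpgs: int = 3,
    flank: int = 500,
    count: str = "dmc",
    precomputed_hits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Summarize site-level results into per-gene-region calls.

    ``dmcs`` is the tested-site frame from :func:`epiprog.diffmeth.call_dmcs`
    (all tested sites, with ``is_dmc``).  A (gene, region) is called when it
    holds at least ``min_cpgs`` DMCs (or tested CpGs, with
    ``count="tested"``).  ``meth_diff_summary`` is the arithmetic mean of
    the member DMCs' differences; ``direction`` its sign (hyper/hypo);
    ``discordant`` flags mixed-sign members.

    ``precomputed_hits`` (columns ``chrom, pos, strand, gene_id, region``)
    lets callers testing many comparisons over one CpG catalogue skip the
    interval lookup; it is joined on (chrom, pos, strand).
    """
    if count not in ("dmc", "tested"):
        raise ValueError("count must be 'dmc' or 'tested'")
    cols = ["gene_id", "region", "n_dmc", "n_cpg_tested", "meth_diff_summary",
            "direction", "discordant"]
    if len(dmcs) == 0:
        out = pd.DataFrame(columns=cols)
        out.attrs.update(dmcs.attrs)
        return out
    if precomputed_hits is not None:
        merged = dmcs[["chrom", "pos", "strand", "meth_diff", "is_dmc"]].merge(
            precomputed_hits[["chrom", "pos", "strand", "gene_id", "region"]],
            on=["chrom", "pos", "strand"],
        )
    else:
        hits = assign_region(dmcs, annotation, flank=flank)
        merged = hits.merge(
            dmcs[["meth_diff", "is_dmc"]], left_on="site_index", right_index=True
        )
    if len(merged) == 0:
        out = pd.DataFrame(columns=cols)
        out.attrs.update(dmcs.attrs)
        return out
    merged = merged.assign(
        diff_dmc=np.where(merged["is_dmc"], merged["meth_diff"], 0.0),
        n_pos=(merged["is_dmc"] & (merged["meth_diff"] > 0)).astype(int),
        n_neg=(merged["is_dmc"] & (merged["meth_diff"] < 0)).astype(int),
        is_dmc_i=merged["is_dmc"].astype(int),
    )
    agg = merged.groupby(["gene_id", "region"], sort=True).agg(
        n_dmc=("is_dmc_i", "sum"),
        n_cpg_tested=("is_dmc_i", "size"),
        diff_sum=("diff_dmc", "sum"),
        n_pos=("n_pos", "sum"),
        n_neg=("n_neg", "sum"),
    )
    counted = agg["n_dmc"] if count == "dmc" else agg["n_cpg_tested"]
    agg = agg[(counted >= min_cpgs) & (agg["n_dmc"] > 0)]
    summary = agg["diff_sum"] / agg["n_dmc"]
    out = pd.DataFrame(
        {
            "gene_id": agg.index.get_level_values("gene_id"),
            "region": agg.index.get_level_values("region"),
            "n_dmc": agg["n_dmc"].to_numpy(),
            "n_cpg_tested": agg["n_cpg_tested"].to_numpy(),
            "meth_diff_summary": summary.to_numpy(),
            "direction": np.where(summary.to_numpy() > 0, "hyper", "hypo"),
            "discordant": ((agg["n_pos"] > 0) & (agg["n_neg"] > 0)).to_numpy(),
        }
    )
    out.attrs.update(dmcs.attrs)
    return out
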