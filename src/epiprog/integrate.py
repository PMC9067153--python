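"""Join pairwise differential-expression calls with gene-region
differential-methylation calls under the direction rules.

A gene is "epigenetically regulated" in a comparison when its expression
change pairs with a region methylation change in the canonical sense:
promoter methylation anti-correlates with expression (hypo -> up,
hyper -> down) while gene-body methylation correlates positively
(hyper -> up, hypo -> down).  Genes carrying BOTH a promoter and a body
call whose summarized |Δmeth| exceeds 20 points are set aside as
ambiguous (dual-region exclusion) and reported in a side table.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

__all__ = ["integrate", "exclude_dual", "VALID_MODES"]

#: (region, meth_direction, expr_direction) -> mode
VALID_MODES = {
    ("promoter", "hypo", "up"): "promoter-hypo-up",
    ("promoter", "hyper", "down"): "promoter-hyper-down",
    ("body", "hyper", "up"): "body-hyper-up",
    ("body", "hypo", "down"): "body-hypo-down",
}

_COLS = [
    "gene_id", "group_a", "group_b", "expr_direction", "region",
    "meth_direction", "mode", "log2fc", "meth_diff_summary",
]


def exclude_dual(
    region_calls: pd.DataFrame, threshold: float = 20.0, rule: str = "either"
) -> tuple[set[str], pd.DataFrame]:
    """Genes with both a promoter and a body call in one comparison whose
    methylation change is too large to attribute to either region.

    ``rule="either"`` (default): excluded when max(|Δ promoter|, |Δ body|)
    strictly exceeds ``threshold``.  ``rule="between"``: when the two
    regions' summarized changes differ by more than ``threshold`` points.
    Returns the excluded gene set and a side table of those genes' calls.
    """
    if rule not in ("either", "between"):
        raise ValueError("rule must be 'either' or 'between'")
    empty = (set(), region_calls.iloc[0:0])
    if len(region_calls) == 0:
        return empty
    wide = region_calls.pivot_table(
        index="gene_id", columns="region", values="meth_diff_summary", aggfunc="first"
    )
    if "promoter" not in wide.columns or "body" not in wide.columns:
        return empty
    both = wide.dropna(subset=["promoter", "body"])
    if rule == "either":
        bad = both[both[["promoter", "body"]].abs().max(axis=1) > threshold]
    else:
        bad = both[(both["promoter"] - both["body"]).abs() > threshold]
    excluded = set(bad.index)
    side = region_calls[region_calls["gene_id"].isin(excluded)].reset_index(drop=True)
    return excluded, side


def integrate(
    de,
    region_calls: pd.DataFrame,
    comparison: tuple[str, str],
    dual_threshold: float = 20.0,
    dual_rule: str = "either",
    skip_discordant: bool = True,
) -> pd.DataFrame:
    """Emit the direction-consistent (gene, region) pairings for one
    ordered comparison.

    ``de`` is either the result frame of
    :func:`epiprog.diffexpr.differential_expression` or a mapping
    gene_id -> direction; ``region_calls`` the frame from
    :func:`epiprog.regions.call_region_dm`.  Both must come from the same
    ordered comparison (checked against their ``.attrs`` when present).
    A gene may be emitted once per qualifying (region, direction) pairing;
    discordant regions are skipped by default and dual-region genes are
    removed per :func:`exclude_dual`.  Output is sorted by
    (gene_id, region) for stable diffs.
    """
    for frame, name in ((de, "de"), (region_calls, "region_calls")):
        comp = getattr(frame, "attrs", {}).get("comparison")
        if comp is not None and tuple(comp) != tuple(comparison):
            raise ValueError(
                f"{name} comes from comparison {comp}, expected {tuple(comparison)}"
            )
    if isinstance(de, Mapping):
        de_dir = dict(de)
        de_lfc: dict[str, float] = {}
    else:
        sig = de[de["direction"].isin(["up", "down"])]
        de_dir = dict(zip(sig["gene_id"], sig["direction"]))
        de_lfc = dict(zip(sig["gene_id"], sig["log2fc"]))

    excluded, _ = exclude_dual(region_calls, threshold=dual_threshold, rule=dual_rule)
    rows = []
    for _, call in region_calls.iterrows():
        gene = call["gene_id"]
        if gene in excluded or gene not in de_dir:
            continue
        if skip_discordant and call["discordant"]:
            continue
        key = (call["region"], call["direction"], de_dir[gene])
        mode = VALID_MODES.get(key)
        if mode is None:
            continue
        rows.append(
            {
                "gene_id": gene,
                "group_a": comparison[0],
                "group_b": comparison[1],
                "expr_direction": de_dir[gene],
                "region": call["region"],
                "meth_direction": call["direction"],
                "mode": mode,
                "log2fc": de_lfc.get(gene, float("nan")),
                "meth_diff_summary": call["meth_diff_summary"],
            }
        )
    out = pd.DataFrame(rows, columns=_COLS)
    out = out.sort_values(["gene_id", "region"], kind="stable").reset_index(drop=True)
    out.attrs["comparison"] = tuple(comparison)
    return out
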