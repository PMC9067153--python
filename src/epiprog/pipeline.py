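"""End-to-end orchestration: per-comparison stage chain and the
progression design over all informative pairwise comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .diffexpr import differential_expression
from .diffmeth import call_dmcs
from .integrate import exclude_dual, integrate
from .io import CountMatrix, CpGMethylationTable, GeneAnnotation
from .regions import assign_region, call_region_dm
from .signatures import (
    ProgressionLines,
    Signature,
    emt_signature,
    malignancy_signature,
    metastasis_signature,
)

__all__ = ["PipelineParams", "ComparisonResult", "run_comparison", "run_progression"]


@dataclass(frozen=True)
class PipelineParams:
    """All tunable thresholds of the integration pipeline with the study's
    defaults."""

    lfc_min: float = 2.0
    de_alpha: float = 0.01
    pseudocount: float = 0.5
    de_engine: str = "moderated"
    min_cov: int = 10
    q_max: float = 0.01
    diff_min: float = 25.0
    min_cpgs: int = 3
    flank: int = 500
    dual_threshold: float = 20.0
    dual_rule: str = "either"
    skip_discordant: bool = True


@dataclass(frozen=True)
class ComparisonResult:
    """All stage outputs for one ordered comparison."""

    comparison: tuple[str, str]
    de: pd.DataFrame
    dmcs: pd.DataFrame
    region_calls: pd.DataFrame
    integrated: pd.DataFrame
    excluded_dual: pd.DataFrame


def run_comparison(
    counts: CountMatrix,
    meth: CpGMethylationTable,
    annotation: GeneAnnotation,
    group_a: str,
    group_b: str,
    params: PipelineParams = PipelineParams(),
    precomputed_hits: pd.DataFrame | None = None,
) -> ComparisonResult:
    """Run DE -> DMC -> region calls -> integration for one ordered pair."""
    de = differential_expression(
        counts, group_a, group_b,
        pseudocount=params.pseudocount, lfc_min=params.lfc_min,
        alpha=params.de_alpha, engine=params.de_engine,
    )
    dmcs = call_dmcs(
        meth, group_a, group_b,
        min_cov=params.min_cov, q_max=params.q_max, diff_min=params.diff_min,
    )
    region_calls = call_region_dm(
        dmcs, annotation, min_cpgs=params.min_cpgs, flank=params.flank,
        precomputed_hits=precomputed_hits,
    )
    integrated = integrate(
        de, region_calls, (group_a, group_b),
        dual_threshold=params.dual_threshold, dual_rule=params.dual_rule,
        skip_discordant=params.skip_discordant,
    )
    _, excluded_tbl = exclude_dual(
        region_calls, threshold=params.dual_threshold, rule=params.dual_rule
    )
    return ComparisonResult((group_a, group_b), de, dmcs, region_calls, integrated, excluded_tbl)


def progression_comparisons(lines: ProgressionLines = ProgressionLines()) -> list[tuple[str, str]]:
    """The five ordered comparisons the three signatures consume."""
    p, pre, non, met = lines.parental, lines.premalignant, lines.nonmetastatic, lines.metastatic
    return [(p, pre), (p, non), (p, met), (pre, met), (non, met)]


def run_progression(
    counts: CountMatrix,
    meth: CpGMethylationTable,
    annotation: GeneAnnotation,
    lines: ProgressionLines = ProgressionLines(),
    params: PipelineParams = PipelineParams(),
) -> tuple[dict[tuple[str, str], ComparisonResult], dict[str, Signature]]:
    """Run every signature-informing comparison and derive the three
    progression signatures."""
    hits = assign_region(meth.sites, annotation, flank=params.flank)
    results = {
        comp: run_comparison(counts, meth, annotation, *comp, params=params,
                             precomputed_hits=hits)
        for comp in progression_comparisons(lines)
    }
    integrated = {comp: r.integrated for comp, r in results.items()}
    sigs = {
        "malignancy": malignancy_signature(integrated, lines),
        "EMT": emt_signature(integrated, lines),
        "metastasis": metastasis_signature(integrated, lines),
    }
    return results, sigs
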