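"""Self-validation of the pipeline on synthetic data.

Each routine here recomputes, from scratch, one of the package's core
correctness properties under the study conditions the synthetic
generators encode: exact-test equivalence against enumeration, null
calibration of the full pipeline, planted-effect recovery, signature set
algebra against brute force, scoring exactness, and Cox parameter
recovery.  They are consumed by the test suite and by
``scripts/acceptance.py``; every expected value is computed by an
independent oracle coded in this module, never assumed.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from . import simulate as sim
from .diffmeth import cpg_test
from .pipeline import PipelineParams, run_comparison, run_progression
from .signatures import (
    ProgressionLines,
    Signature,
    emt_signature,
    malignancy_signature,
    metastasis_signature,
)
from .survival import (
    cox_fit,
    dichotomize_median,
    km_logrank,
    signature_score,
    zscore,
)

__all__ = [
    "fisher_vs_enumeration",
    "null_pipeline_calibration",
    "planted_recovery",
    "signature_set_algebra",
    "archetype_placement",
    "scoring_exactness",
    "cox_recovery",
    "logrank_null_uniformity",
]

# conditions shared by the calibration and recovery runs: 2,000 genes whose
# CpG catalogue holds ~20-25k sites, four groups in triplicate, coverage 30
_STUDY_GENES = 2000
_STUDY_GENE_LENGTHS = (1400, 1700)


def _study_annotation(seed: int):
    return sim.make_annotation(
        _STUDY_GENES, gene_length_range=_STUDY_GENE_LENGTHS, seed=seed
    )


# ---------------------------------------------------------------------------
# 1. Fisher branch vs exhaustive enumeration
# ---------------------------------------------------------------------------

def _fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration, with
    the pmf computed directly from log-factorials."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def log_pmf(x: int) -> float:
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1) - math.lgamma(r2 - c1 + x + 1)
            + math.lgamma(c1 + 1) + math.lgamma(n - c1 + 1) - math.lgamma(n + 1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = math.exp(log_pmf(a))
    total = 0.0
    for x in range(lo, hi + 1):
        px = math.exp(log_pmf(x))
        if px <= p_obs * (1 + 1e-7):  # customary tolerance for pmf ties
            total += px
    return min(total, 1.0)


def fisher_vs_enumeration(max_margin: int = 40) -> dict:
    """Compare the 1-vs-1 branch of :func:`cpg_test` with the enumeration
    oracle on every 2x2 table with both row margins in 1..max_margin."""
    max_diff = 0.0
    n_tables = 0
    for n1 in range(1, max_margin + 1):
        for n2 in range(1, max_margin + 1):
            for a in range(n1 + 1):
                for c in range(n2 + 1):
                    p_impl, _ = cpg_test([a], [n1], [c], [n2])
                    p_oracle = _fisher_oracle(a, n1 - a, c, n2 - c)
                    max_diff = max(max_diff, abs(p_impl - p_oracle))
                    n_tables += 1
    return {"max_abs_diff": max_diff, "n_tables": n_tables}


# ---------------------------------------------------------------------------
# 2. Null calibration of the full pipeline
# ---------------------------------------------------------------------------

def null_pipeline_calibration(n_seeds: int = 50, seed: int = 0) -> dict:
    """Fraction of replicate datasets with *no* planted effects on which
    the full progression pipeline emits an empty integrated list."""
    lines = ProgressionLines()
    groups = [lines.parental, lines.premalignant, lines.nonmetastatic, lines.metastatic]
    clean = 0
    total_integrated = 0
    for k in range(n_seeds):
        s_ann, s_cnt, s_meth = sim.child_seeds(seed + k, 3)
        ann, cat = _study_annotation(s_ann)
        counts = sim.simulate_counts(ann, groups, seed=s_cnt)
        meth = sim.simulate_methylome(ann, cat, groups, seed=s_meth)
        results, _ = run_progression(counts, meth, ann, lines=lines)
        n = sum(len(r.integrated) for r in results.values())
        total_integrated += n
        clean += n == 0
    return {
        "clean_fraction": clean / n_seeds,
        "n_seeds": n_seeds,
        "total_integrated_rows": total_integrated,
    }


# ---------------------------------------------------------------------------
# 3. Planted-effect recovery
# ---------------------------------------------------------------------------

def planted_recovery(
    n_seeds: int = 3,
    seed: int = 0,
    n_coupled: int = 200,
    n_decoy: int = 20,
    log2fc: float = 3.0,
    meth_shift: float = 40.0,
) -> dict:
    """End-to-end sensitivity / FDR for direction-consistent planted genes
    in a two-group comparison, and the recovery rate of discordant decoys
    (which the direction rules must reject)."""
    sens, fdr, decoy_rates = [], [], []
    for k in range(n_seeds):
        s_ann, s_truth, s_cnt, s_meth = sim.child_seeds(seed + k, 4)
        ann, cat = _study_annotation(s_ann)
        truth = sim.make_planted_truth(
            list(ann.gene_ids), affected_groups=["case"],
            n_coupled=n_coupled, n_decoy=n_decoy,
            log2fc=log2fc, meth_shift=meth_shift, seed=s_truth,
        )
        counts = sim.simulate_counts(ann, ["control", "case"], planted=truth, seed=s_cnt)
        meth = sim.simulate_methylome(ann, cat, ["control", "case"], planted=truth, seed=s_meth)
        res = run_comparison(counts, meth, ann, "control", "case")
        emitted = set(res.integrated["gene_id"])
        planted = set(truth.coupled["gene_id"])
        decoys = set(truth.decoys["gene_id"])
        sens.append(len(emitted & planted) / len(planted))
        fdr.append(len(emitted - planted) / max(len(emitted), 1))
        decoy_rates.append(len(emitted & decoys) / max(len(decoys), 1))
    return {
        "sensitivity": float(np.mean(sens)),
        "fdr": float(np.mean(fdr)),
        "decoy_recovery_rate": float(np.mean(decoy_rates)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 4. Signature set algebra vs brute force
# ---------------------------------------------------------------------------

def _random_integrated(rng: np.random.Generator, comparisons, n_genes: int = 40):
    genes = [f"g{i}" for i in range(n_genes)]
    mode_map = {
        ("up", "promoter"): "promoter-hypo-up",
        ("down", "promoter"): "promoter-hyper-down",
        ("up", "body"): "body-hyper-up",
        ("down", "body"): "body-hypo-down",
    }
    out = {}
    for comp in comparisons:
        chosen = rng.choice(genes, size=int(rng.integers(5, n_genes)), replace=False)
        direction = rng.choice(["up", "down"], size=len(chosen))
        region = rng.choice(["promoter", "body"], size=len(chosen))
        out[comp] = pd.DataFrame(
            {
                "gene_id": chosen,
                "expr_direction": direction,
                "region": region,
                "mode": [mode_map[(d, r)] for d, r in zip(direction, region)],
            }
        )
    return out


def _brute_signatures(integrated, lines: ProgressionLines):
    """Independent brute-force enumeration of all three signatures."""
    p, pre, non, met = (lines.parental, lines.premalignant,
                        lines.nonmetastatic, lines.metastatic)

    def dirs(comp):
        f = integrated[comp]
        return dict(zip(f["gene_id"], f["expr_direction"]))

    d = {c: dirs(c) for c in integrated}
    out = {}
    mal_up, mal_down = set(), set()
    for g in set(d[(p, pre)]) & set(d[(p, non)]) & set(d[(p, met)]):
        vals = {d[(p, pre)][g], d[(p, non)][g], d[(p, met)][g]}
        if len(vals) == 1:
            (mal_up if vals.pop() == "up" else mal_down).add(g)
    out["malignancy"] = (mal_up, mal_down)
    emt_up, emt_down = set(), set()
    for g in set(d[(p, pre)]) & set(d[(p, non)]) & set(d[(pre, met)]) & set(d[(non, met)]):
        pat = (d[(p, pre)][g], d[(p, non)][g], d[(pre, met)][g], d[(non, met)][g])
        if pat == ("up", "up", "down", "down"):
            emt_up.add(g)
        elif pat == ("down", "down", "up", "up"):
            emt_down.add(g)
    out["EMT"] = (emt_up, emt_down)
    met_up, met_down = set(), set()
    elsewhere = set(integrated[(p, pre)]["gene_id"]) | set(integrated[(p, non)]["gene_id"])
    for g in set(d[(p, met)]) & set(d[(pre, met)]) & set(d[(non, met)]):
        if g in elsewhere:
            continue
        vals = {d[(p, met)][g], d[(pre, met)][g], d[(non, met)][g]}
        if len(vals) == 1:
            (met_up if vals.pop() == "up" else met_down).add(g)
    out["metastasis"] = (met_up, met_down)
    return out


def signature_set_algebra(n_instances: int = 1000, seed: int = 0) -> dict:
    """Fraction of randomized instances on which each signature operation
    equals its brute-force enumeration (both up and down sets)."""
    lines = ProgressionLines()
    p, pre, non, met = (lines.parental, lines.premalignant,
                        lines.nonmetastatic, lines.metastatic)
    comps = [(p, pre), (p, non), (p, met), (pre, met), (non, met)]
    rng = np.random.default_rng(seed)
    agree = 0
    funcs = {
        "malignancy": malignancy_signature,
        "EMT": emt_signature,
        "metastasis": metastasis_signature,
    }
    for _ in range(n_instances):
        integrated = _random_integrated(rng, comps)
        brute = _brute_signatures(integrated, lines)
        ok = True
        for name, func in funcs.items():
            s = func(integrated, lines)
            ok &= (s.up_ids, s.down_ids) == (frozenset(brute[name][0]), frozenset(brute[name][1]))
        agree += ok
    return {"agreement_fraction": agree / n_instances, "n_instances": n_instances}


def archetype_placement(seed: int = 0, n_genes: int = 400, n_per_archetype: int = 15) -> dict:
    """Plant malignancy/EMT/metastasis archetypes, run the full pipeline,
    and check that every recovered planted gene lands in exactly its
    intended signature."""
    lines = ProgressionLines()
    groups = [lines.parental, lines.premalignant, lines.nonmetastatic, lines.metastatic]
    s_ann, s_truth, s_cnt, s_meth = sim.child_seeds(seed, 4)
    ann, cat = sim.make_annotation(n_genes, gene_length_range=_STUDY_GENE_LENGTHS, seed=s_ann)
    truth = sim.make_progression_truth(
        list(ann.gene_ids), n_per_archetype=n_per_archetype, seed=s_truth
    )
    counts = sim.simulate_counts(ann, groups, planted=truth, seed=s_cnt)
    meth = sim.simulate_methylome(ann, cat, groups, planted=truth, seed=s_meth)
    _, sigs = run_progression(counts, meth, ann, lines=lines)
    arch = truth.df.set_index("gene_id")["archetype"]
    misplaced = 0
    recovered = {}
    for name, s in sigs.items():
        ids = s.up_ids | s.down_ids
        planted = set(arch.index[arch == name])
        others = set(arch.index[(arch != name) & (arch != "none")])
        misplaced += len(ids & others)
        recovered[name] = len(ids & planted) / len(planted)
    return {
        "misplaced_genes": misplaced,
        "min_recovery": min(recovered.values()),
        "recovery": recovered,
    }


# ---------------------------------------------------------------------------
# 5. Scoring exactness
# ---------------------------------------------------------------------------

def _logrank_oracle(time, event, g1_mask) -> float:
    """Risk-set enumeration of the two-group log-rank chi-square,
    independent of the vectorized implementation."""
    records = sorted(zip(time, event, g1_mask))
    o_minus_e, var = 0.0, 0.0
    for t in sorted({t for t, e, _ in records if e}):
        risk = [(tt, ee, gg) for tt, ee, gg in records if tt >= t]
        n = len(risk)
        n1 = sum(1 for _, _, gg in risk if gg)
        dd = sum(1 for tt, ee, _ in risk if tt == t and ee)
        d1 = sum(1 for tt, ee, gg in risk if tt == t and ee and gg)
        o_minus_e += d1 - dd * n1 / n
        if n > 1:
            var += dd * (n1 / n) * (1 - n1 / n) * (n - dd) / (n - 1)
    return (o_minus_e**2) / var if var > 0 else 0.0


def scoring_exactness(seed: int = 0, n_cohorts: int = 200) -> dict:
    """Numerical exactness of the scoring stack: z-transformation moments,
    the worked combined-score example, and log-rank agreement with the
    risk-set enumeration oracle on random small cohorts."""
    rng = np.random.default_rng(seed)
    m = pd.DataFrame(rng.normal(3, 7, size=(50, 80)))
    z = zscore(m)
    zmean = float(np.abs(z.mean(axis=1)).max())
    zvar = float(np.abs(z.var(axis=1, ddof=1) - 1).max())

    sig = Signature("worked", frozenset({("u1", ""), ("u2", "")}), frozenset({("d1", "")}))
    zw = pd.DataFrame({"p1": [1.0, 0.5, -0.5]}, index=["u1", "u2", "d1"])
    worked = float(signature_score(zw, sig)["combined_score"].iloc[0])

    max_lr_diff = 0.0
    for _ in range(n_cohorts):
        n = int(rng.integers(6, 13))
        time = rng.integers(1, 8, n).astype(float)
        event = rng.integers(0, 2, n)
        if event.sum() == 0:
            event[rng.integers(n)] = 1
        g = rng.integers(0, 2, n).astype(bool)
        if g.all() or not g.any():
            g[0] = ~g[0]
        res, _ = km_logrank(pd.Series(np.where(g, "a", "b")), time, event)
        max_lr_diff = max(max_lr_diff, abs(res.logrank_chi2 - _logrank_oracle(time, event, g)))
    return {
        "zscore_max_abs_mean": zmean,
        "zscore_max_abs_var_dev": zvar,
        "worked_combined_score": worked,
        "logrank_max_abs_diff": max_lr_diff,
        "n_cohorts": n_cohorts,
    }


# ---------------------------------------------------------------------------
# 6. Cox parameter recovery and null uniformity
# ---------------------------------------------------------------------------

def _toy_signature() -> Signature:
    return Signature(
        "recovery",
        frozenset({(f"u{i:02d}", "") for i in range(10)}),
        frozenset({(f"d{i:02d}", "") for i in range(10)}),
    )


def cox_recovery(
    beta: float = math.log(1.49), n_patients: int = 700, n_seeds: int = 200, seed: int = 0
) -> dict:
    """Mean bias of the Cox estimate and empirical 95% CI coverage when
    fitting the continuous signature score the hazard was generated
    from."""
    sig = _toy_signature()
    betas, cover = [], 0
    for k in range(n_seeds):
        coh = sim.simulate_cohort(n_patients, sig, beta_per_sd=beta, seed=seed + k)
        fit = cox_fit(coh.covariates["signature_score"], coh.time, coh.event)
        betas.append(fit.beta)
        cover += math.log(fit.ci_low) <= beta <= math.log(fit.ci_high)
    return {
        "mean_bias": float(np.mean(betas) - beta),
        "ci_coverage": cover / n_seeds,
        "n_seeds": n_seeds,
    }


def logrank_null_uniformity(n_patients: int = 700, n_seeds: int = 500, seed: int = 0) -> dict:
    """With no planted hazard, median-dichotomized log-rank p-values should
    be approximately uniform; returns the Kolmogorov-Smirnov p against
    Uniform(0, 1)."""
    sig = _toy_signature()
    ps = []
    for k in range(n_seeds):
        coh = sim.simulate_cohort(n_patients, sig, beta_per_sd=0.0, seed=seed + k)
        z = zscore(coh.matrix)
        score = signature_score(z, sig)["combined_score"]
        groups = dichotomize_median(score)
        res, _ = km_logrank(groups, coh.time, coh.event)
        ps.append(res.p_logrank)
    ks = stats.kstest(ps, "uniform")
    return {"ks_p": float(ks.pvalue), "n_seeds": n_seeds}
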