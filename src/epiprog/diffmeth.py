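"""Per-CpG differential methylation testing and DMC calling.

The methylation difference at a site is the difference of
coverage-pooled methylated fractions (group B minus group A), in
percentage points.  With replicates on both sides the p-value comes from
a likelihood-ratio test of a binomial logistic model
(methylated/coverage ~ group) against the intercept-only model; in the
1-vs-1 case it falls back to a two-sided Fisher exact test on the pooled
2x2 table.  A cytosine is a DMC when q <= 0.01 and |diff| >= 25 points
(inclusive, configurable), q-values by Benjamini-Hochberg over all
tested sites.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CpGMethylationTable

__all__ = ["cpg_test", "call_dmcs"]


def _ll_at_mle(m, c):
    """Σ m log p + (c-m) log(1-p) at p = m/c, with the 0log0 = 0 convention."""
    m = np.asarray(m, float)
    c = np.asarray(c, float)
    out = np.zeros_like(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(c > 0, m / c, 0.0)
        t1 = np.where(m > 0, m * np.log(np.where(p > 0, p, 1.0)), 0.0)
        t2 = np.where(c - m > 0, (c - m) * np.log1p(np.where(p < 1, -p, 0.0)), 0.0)
    return t1 + t2


def _lrt_pvalues(
    meth_a: np.ndarray, cov_a: np.ndarray, meth_b: np.ndarray, cov_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized group-vs-intercept binomial logistic LRT over sites.

    Inputs are (sites x replicates) arrays.  Because the only covariate is
    the group factor, the alternative MLE is each group's pooled
    proportion and the null MLE the overall pooled proportion, giving the
    LRT in closed form.
    """
    MA, CA = meth_a.sum(axis=1), cov_a.sum(axis=1)
    MB, CB = meth_b.sum(axis=1), cov_b.sum(axis=1)
    l1 = _ll_at_mle(MA, CA) + _ll_at_mle(MB, CB)
    l0 = _ll_at_mle(MA + MB, CA + CB)
    lrt = np.maximum(2.0 * (l1 - l0), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = 100.0 * (MB / CB - MA / CA)
    return p, diff


def cpg_test(meth_a, cov_a, meth_b, cov_b) -> tuple[float, float]:
    """Test one CpG site between two groups of samples.

    Parameters are per-sample methylated counts and coverages (sequences).
    Returns ``(p_raw, meth_diff)`` with ``meth_diff`` in percentage points
    (B minus A, coverage-pooled).  With >= 2 informative samples on either
    side the binomial-logistic LRT is used; with one sample per group, a
    two-sided Fisher exact test on the 2x2 table.
    """
    ma = np.atleast_1d(np.asarray(meth_a, float))
    ca = np.atleast_1d(np.asarray(cov_a, float))
    mb = np.atleast_1d(np.asarray(meth_b, float))
    cb = np.atleast_1d(np.asarray(cov_b, float))
    if ((ma < 0) | (ma > ca)).any() or ((mb < 0) | (mb > cb)).any():
        raise ValueError("need 0 <= meth <= coverage per sample")
    if ca.sum() == 0 or cb.sum() == 0:
        raise ValueError("zero total coverage in a group")
    if len(ma) == 1 and len(mb) == 1:
        table = np.array(
            [[ma.sum(), ca.sum() - ma.sum()], [mb.sum(), cb.sum() - mb.sum()]], dtype=int
        )
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        diff = 100.0 * (mb.sum() / cb.sum() - ma.sum() / ca.sum())
        return p, float(diff)
    p, diff = _lrt_pvalues(ma[None, :], ca[None, :], mb[None, :], cb[None, :])
    return float(p[0]), float(diff[0])


def call_dmcs(
    table: CpGMethylationTable,
    group_a: str,
    group_b: str,
    min_cov: int = 10,
    q_max: float = 0.01,
    diff_min: float = 25.0,
) -> pd.DataFrame:
    """Call differentially methylated cytosines between two groups.

    Sites with coverage below ``min_cov`` in any sample of either group
    are excluded before testing; q-values are Benjamini-Hochberg over the
    tested sites.  Returns a frame with columns ``chrom, pos, strand,
    meth_diff, p_raw, q_value, is_dmc``; ``.attrs`` records the
    comparison and the number of sites removed by the coverage filter.
    """
    sa = table.group_samples(group_a)
    sb = table.group_samples(group_b)
    cov_a = table.coverage[sa].to_numpy()
    cov_b = table.coverage[sb].to_numpy()
    meth_a = table.meth[sa].to_numpy()
    meth_b = table.meth[sb].to_numpy()
    keep = (cov_a >= min_cov).all(axis=1) & (cov_b >= min_cov).all(axis=1)
    # a group with zero total coverage is untestable regardless of min_cov
    keep &= (cov_a.sum(axis=1) > 0) & (cov_b.sum(axis=1) > 0)
    n_filtered = int((~keep).sum())
    if not keep.any():
        warnings.warn("no sites left after coverage filtering")
        out = pd.DataFrame(
            columns=["chrom", "pos", "strand", "meth_diff", "p_raw", "q_value", "is_dmc"]
        )
        out.attrs["comparison"] = (group_a, group_b)
        out.attrs["n_filtered"] = n_filtered
        return out

    ma, ca = meth_a[keep], cov_a[keep]
    mb, cb = meth_b[keep], cov_b[keep]
    if len(sa) == 1 and len(sb) == 1:
        p = np.empty(keep.sum())
        for i in range(len(p)):
            tab = np.array(
                [[ma[i, 0], ca[i, 0] - ma[i, 0]], [mb[i, 0], cb[i, 0] - mb[i, 0]]], dtype=int
            )
            p[i] = stats.fisher_exact(tab, alternative="two-sided")[1]
        with np.errstate(invalid="ignore"):
            diff = 100.0 * (mb[:, 0] / cb[:, 0] - ma[:, 0] / ca[:, 0])
    else:
        p, diff = _lrt_pvalues(ma, ca, mb, cb)
    q = multipletests(p, method="fdr_bh")[1]
    is_dmc = (q <= q_max) & (np.abs(diff) >= diff_min)
    out = table.sites.loc[keep, ["chrom", "pos", "strand"]].reset_index(drop=True)
    out["meth_diff"] = diff
    out["p_raw"] = p
    out["q_value"] = q
    out["is_dmc"] = is_dmc
    out.attrs["comparison"] = (group_a, group_b)
    out.attrs["n_filtered"] = n_filtered
    return out
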