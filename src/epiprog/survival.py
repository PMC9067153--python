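"""Signature scoring on patient cohorts and survival statistics.

The scoring convention: expression (or methylation) features are
z-transformed per feature across patients (mean 0, sample variance 1),
then averaged over signature members with weight +1 for upregulated and
-1 for downregulated genes:

    combined = (sum z_up - sum z_down) / (|up| + |down|)

Scores are dichotomized at the cohort median for Kaplan-Meier / log-rank
comparison, or entered continuously into Cox proportional-hazards
regression (Newton-Raphson on the partial likelihood with the Efron tie
correction — implemented here, not delegated).  Single features can
instead be stratified at the 25% / 75% quantiles, discarding the middle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import Signature

__all__ = [
    "SurvivalResult",
    "zscore",
    "signature_score",
    "dichotomize_median",
    "km_curve",
    "km_logrank",
    "cox_fit",
    "covariate_association",
    "quartile_stratify",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalResult:
    """Cox and/or log-rank summary for one analysis."""

    n: int
    n_events: int
    hazard_ratio: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_wald: float = np.nan
    beta: float = np.nan
    se: float = np.nan
    logrank_chi2: float = np.nan
    p_logrank: float = np.nan
    group_sizes: tuple[int, ...] = ()
    extra_betas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if np.isfinite(self.hazard_ratio):
            assert self.ci_low <= self.hazard_ratio <= self.ci_high


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature z-transformation across patients (mean 0, sample
    variance 1, n-1 denominator).  Zero-variance features are dropped with
    a warning rather than propagating NaNs."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 patients to z-transform")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} zero-variance feature(s)")
    kept = matrix.loc[~constant]
    return kept.sub(mean[~constant], axis=0).div(sd[~constant], axis=0)


def signature_score(
    z: pd.DataFrame, signature: Signature, mode: str = "combined"
) -> pd.DataFrame:
    """Per-patient signature scores from a z-transformed feature matrix.

    Returns a frame indexed by patient with ``up_score`` (mean z over up
    members), ``down_score`` and ``combined_score`` (weighted mean, +1 for
    up and -1 for down members).  Signature genes absent from the matrix
    are logged and ignored; with one member set empty the combined score
    equals the other set's mean.
    """
    if mode not in ("up", "down", "combined"):
        raise ValueError("mode must be up, down or combined")
    up = sorted(signature.up_ids & set(z.index))
    down = sorted(signature.down_ids & set(z.index))
    missing = (signature.up_ids | signature.down_ids) - set(z.index)
    if missing:
        log.info("signature %s: %d gene(s) absent from matrix", signature.name, len(missing))
    if not up and not down:
        raise ValueError(f"no genes of signature {signature.name!r} present in the matrix")
    up_score = z.loc[up].mean(axis=0) if up else pd.Series(np.nan, index=z.columns)
    down_score = z.loc[down].mean(axis=0) if down else pd.Series(np.nan, index=z.columns)
    n = len(up) + len(down)
    combined = (
        (z.loc[up].sum(axis=0) if up else 0.0) - (z.loc[down].sum(axis=0) if down else 0.0)
    ) / n
    out = pd.DataFrame(
        {"up_score": up_score, "down_score": down_score, "combined_score": combined}
    )
    out.index.name = "patient_id"
    out.attrs["signature"] = signature.name
    out.attrs["mode"] = mode
    return out


def dichotomize_median(scores: pd.Series) -> pd.Series:
    """Median split: score > median -> 'high', score <= median -> 'low'
    (ties go low)."""
    if len(scores) < 2:
        raise ValueError("need >= 2 patients")
    if scores.nunique() == 1:
        raise ValueError("all scores identical; median split undefined")
    med = scores.median()
    return pd.Series(np.where(scores > med, "high", "low"), index=scores.index)


def quartile_stratify(
    values: pd.Series, low_q: float = 0.25, high_q: float = 0.75
) -> pd.Series:
    """Strictly below the ``low_q`` quantile -> 'low', strictly above the
    ``high_q`` quantile -> 'high', the middle -> 'excluded'.  Quantiles use
    linear interpolation (numpy default)."""
    if len(values) < 8:
        raise ValueError("need >= 8 patients for quartile stratification")
    if values.nunique() == 1:
        raise ValueError("all values identical; stratification undefined")
    lo = np.quantile(values, low_q)
    hi = np.quantile(values, high_q)
    out = pd.Series("excluded", index=values.index, dtype=object)
    out[values < lo] = "low"
    out[values > hi] = "high"
    if (out == "low").sum() < 2 or (out == "high").sum() < 2:
        raise ValueError("fewer than 2 patients in a stratum")
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

def km_curve(time, event) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns a frame with columns ``time, n_at_risk, n_events, survival``
    at each distinct event time.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    out_rows = []
    n = len(time)
    surv = 1.0
    for t in np.unique(time[event == 1]):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        surv *= 1.0 - d / at_risk
        out_rows.append({"time": t, "n_at_risk": at_risk, "n_events": d, "survival": surv})
    return pd.DataFrame(out_rows, columns=["time", "n_at_risk", "n_events", "survival"])


def km_logrank(groups: pd.Series, time, event) -> tuple[SurvivalResult, dict[str, pd.DataFrame]]:
    """Two-group log-rank test plus per-group KM curves.

    chi2 = (sum(O - E))^2 / sum(V) over distinct event times, with the
    hypergeometric variance at each risk set; p from chi2 with 1 df.
    """
    groups = pd.Series(groups)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {labels}")
    g1 = (groups == labels[0]).to_numpy()
    if g1.sum() == 0 or (~g1).sum() == 0:
        raise ValueError("a group has zero patients")
    if event.sum() == 0:
        raise ValueError("no events")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_t = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d_t = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        e1 = d_t * n1 / n_t
        o_minus_e += d1 - e1
        if n_t > 1:
            var += d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
    chi2 = (o_minus_e**2) / var if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    curves = {
        lab: km_curve(time[groups.to_numpy() == lab], event[groups.to_numpy() == lab])
        for lab in labels
    }
    res = SurvivalResult(
        n=len(time),
        n_events=int(event.sum()),
        logrank_chi2=float(chi2),
        p_logrank=p,
        group_sizes=(int(g1.sum()), int((~g1).sum())),
    )
    return res, curves


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------

class ConvergenceError(RuntimeError):
    pass


def _cox_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Efron partial log-likelihood, gradient and information matrix."""
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    X, time, event = X[order], time[order], event[order]
    eta = X @ beta
    eta -= eta.max()  # guard overflow; cancels in all ratios
    theta = np.exp(eta)
    # suffix sums over the risk set (time >= t)
    s0 = np.cumsum(theta[::-1])[::-1]
    s1 = np.cumsum((theta[:, None] * X)[::-1], axis=0)[::-1]
    s2 = np.cumsum((theta[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[::-1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d_idx = [k for k in range(i, j) if event[k] == 1]
        if d_idx:
            d = len(d_idx)
            td = theta[d_idx].sum()
            xd = X[d_idx].sum(axis=0)
            s1d = (theta[d_idx, None] * X[d_idx]).sum(axis=0)
            s2d = (theta[d_idx, None, None] * (X[d_idx, :, None] * X[d_idx, None, :])).sum(axis=0)
            ll += eta[d_idx].sum()
            for ell in range(d):
                f = ell / d
                denom = s0[i] - f * td
                num1 = s1[i] - f * s1d
                num2 = s2[i] - f * s2d
                ll -= np.log(denom)
                grad_term = num1 / denom
                grad -= grad_term
                info += num2 / denom - np.outer(grad_term, grad_term)
            grad += xd
        i = j
    return ll, grad, info


def cox_fit(
    covariate,
    time,
    event,
    extra_covariates: pd.DataFrame | np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-7,
) -> SurvivalResult:
    """Cox proportional-hazards fit for one covariate of interest, with
    optional adjustment covariates.

    Newton-Raphson on the Efron partial likelihood with step-halving;
    reports HR = exp(beta), the 95% Wald CI and the Wald p-value for the
    first (interest) covariate.  Raises :class:`ConvergenceError` on
    non-convergence, a constant covariate, a singular information matrix
    or complete separation (diverging coefficient).
    """
    x = np.asarray(covariate, float).reshape(-1, 1)
    if extra_covariates is not None:
        extra = np.asarray(extra_covariates, float)
        if extra.ndim == 1:
            extra = extra.reshape(-1, 1)
        X = np.hstack([x, extra])
    else:
        X = x
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if np.ptp(X, axis=0).min() == 0:
        raise ValueError("constant covariate")
    n_events = int(event.sum())
    if n_events < 10:
        warnings.warn(f"only {n_events} events; estimates may be unstable")
    # standardize internally for numerical stability, back-transform after
    scale = X.std(axis=0, ddof=0)
    Xs = (X - X.mean(axis=0)) / scale
    beta = np.zeros(X.shape[1])
    ll, grad, info = _cox_loglik(beta, Xs, time, event)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}") from err
        if not np.all(np.isfinite(step)):
            raise ConvergenceError("non-finite Newton step")
        # step-halving on the partial likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = _cox_loglik(cand, Xs, time, event)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.abs(beta).max() > 50:
            raise ConvergenceError("coefficient diverging; likely complete separation")
        if np.abs(grad).max() < tol or np.abs(factor * step).max() < 1e-12:
            break
    else:
        raise ConvergenceError(f"no convergence in {max_iter} iterations (|grad|={np.abs(grad).max():.2e})")
    try:
        cov_beta = np.linalg.inv(info)
    except np.linalg.LinAlgError as err:
        raise ConvergenceError(f"singular information matrix: {err}") from err
    beta_orig = beta / scale
    se_orig = np.sqrt(np.diag(cov_beta)) / scale
    b, s = float(beta_orig[0]), float(se_orig[0])
    z = b / s
    return SurvivalResult(
        n=len(time),
        n_events=n_events,
        hazard_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - 1.959963984540054 * s)),
        ci_high=float(np.exp(b + 1.959963984540054 * s)),
        p_wald=float(2 * stats.norm.sf(abs(z))),
        beta=b,
        se=s,
        extra_betas=tuple(float(v) for v in beta_orig[1:]),
    )


# ---------------------------------------------------------------------------
# Covariate association
# ---------------------------------------------------------------------------

def covariate_association(score, covariate) -> tuple[float, float]:
    """Spearman rank correlation (ties handled by midranks) with two-sided
    p-value, for score vs a clinical covariate."""
    score = np.asarray(score, float)
    covariate = np.asarray(covariate, float)
    keep = np.isfinite(score) & np.isfinite(covariate)
    score, covariate = score[keep], covariate[keep]
    if len(score) < 5:
        raise ValueError("need >= 5 paired non-missing values")
    if np.ptp(score) == 0 or np.ptp(covariate) == 0:
        raise ValueError("constant input")
    rho, p = stats.spearmanr(score, covariate)
    return float(rho), float(p)
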