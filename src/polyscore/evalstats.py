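"""Covariate-adjusted performance metrics and cohort-description tests.

The central quantity is the incremental pseudo-R^2 of a polygenic score: the
difference in Nagelkerke R^2 between a logistic model containing covariates
plus the score and a covariates-only null model (for a binary diagnosis), or
the analogous OLS R^2 difference for a quantitative severity outcome.
Discrimination is summarized by the AUC (Mann-Whitney form) for binary
outcomes and the concordance index for quantitative ones, and stratified
effects by odds ratios / mean differences across score quantiles against the
lowest quantile.  Principal components of the LD-pruned dosage matrix provide
the population-stratification covariates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .dataio import GenotypeCohort, PhenotypeTable

__all__ = [
    "EvalReport",
    "QuantileContrast",
    "pca_covariates",
    "nagelkerke_delta_r2",
    "linear_delta_r2",
    "auc",
    "c_index",
    "quantile_effects",
    "pearson_chi2",
    "wilcoxon_rank_sum",
]


class SeparationError(RuntimeError):
    """Logistic fit failed (perfect or quasi-perfect separation)."""


@dataclass
class EvalReport:
    """Performance of a polygenic score on one cohort (or cohort stratum)."""

    nagelkerke_delta_r2: float | None
    p_diagnosis: float | None
    linear_delta_r2: float | None
    p_severity: float | None
    auc: float | None
    c_index: float | None
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "nagelkerke_delta_r2", "p_diagnosis", "linear_delta_r2",
            "p_severity", "auc", "c_index", "n")}


@dataclass
class QuantileContrast:
    """Per-quantile effect estimates against the lowest-score quantile.

    ``table`` columns: quantile (2..q), estimate (odds ratio for diagnosis,
    mean difference for severity), ci_low, ci_high, p.
    """

    q: int
    outcome: str
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# principal components


def pca_covariates(cohort: GenotypeCohort, k: int = 5, snp_set=None) -> np.ndarray:
    """Principal-component scores of the column-standardized dosage matrix.

    Restricted to ``snp_set`` (typically the LD-pruned variants), missing
    dosages mean-imputed, components ordered by decreasing variance explained.
    Sign convention: the largest-magnitude variant loading of each component
    is made positive, so results do not depend on numerical sign ambiguity.
    """
    if k == 0:
        return np.empty((cohort.n_samples, 0))
    idx = np.arange(cohort.n_variants) if snp_set is None else np.asarray(snp_set)
    X = cohort.dosage[:, idx].astype(float)
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("snp_set contains monomorphic variants; prune or QC first")
    Z = (X - mu) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int((S > S[0] * 1e-9).sum()) if S.size else 0
    if k > rank:
        raise ValueError(f"requested {k} components but matrix rank is {rank}")
    scores = U[:, :k] * S[:k]
    # deterministic sign: largest-|loading| positive
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            scores[:, c] = -scores[:, c]
    return scores


# ---------------------------------------------------------------------------
# incremental R^2


def _with_intercept(*blocks) -> np.ndarray:
    cols = [np.ones((blocks[0].shape[0], 1))]
    for b in blocks:
        if b is not None and b.size:
            cols.append(b if b.ndim == 2 else b[:, None])
    return np.hstack(cols)


def _fit_logit(y, X):
    last_exc = None
    for method in ("newton", "bfgs"):
        try:
            res = sm.Logit(y, X).fit(disp=0, method=method, maxiter=200)
        except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
            last_exc = exc
            continue
        if res.mle_retvals.get("converged", True) and np.abs(res.params).max() <= 1e3:
            return res
        last_exc = RuntimeError("fit did not converge (separation suspected)")
    raise SeparationError(f"logistic fit failed: {last_exc}") from last_exc


def nagelkerke_delta_r2(y, prs, covars=None) -> tuple[float, float]:
    """Incremental Nagelkerke pseudo-R^2 of a score for a binary outcome.

    Fits logistic regressions null (intercept + covariates) and full (null +
    score) by maximum likelihood.  Nagelkerke R^2 of a model with
    log-likelihood ``llm`` is ``(1 - exp(2 (ll0 - llm) / n)) / (1 - exp(2 ll0 / n))``
    with ``ll0`` the intercept-only log-likelihood.  Returns the full-minus-null
    difference and the Wald P value of the score coefficient.
    """
    y = np.asarray(y, dtype=float)
    prs = np.asarray(prs, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    covars = None if covars is None else np.asarray(covars, dtype=float)
    n = y.size
    X_null = _with_intercept(covars) if covars is not None else _with_intercept(np.empty((n, 0)))
    X_full = np.hstack([X_null, prs[:, None]])
    ll0 = _fit_logit(y, np.ones((n, 1))).llf
    res_null = _fit_logit(y, X_null)
    res_full = _fit_logit(y, X_full)
    denom = 1.0 - np.exp(2.0 * ll0 / n)

    def _nagelkerke(llm: float) -> float:
        return (1.0 - np.exp(2.0 * (ll0 - llm) / n)) / denom

    delta = _nagelkerke(res_full.llf) - _nagelkerke(res_null.llf)
    p_prs = float(res_full.pvalues[-1])
    return float(delta), p_prs


def linear_delta_r2(y, prs, covars=None) -> tuple[float, float]:
    """Incremental OLS R^2 of a score for a quantitative outcome.

    Returns (R^2_full - R^2_null, Wald P value of the score coefficient).
    """
    y = np.asarray(y, dtype=float)
    prs = np.asarray(prs, dtype=float)
    n = y.size
    covars = None if covars is None else np.asarray(covars, dtype=float)
    X_null = _with_intercept(covars) if covars is not None else _with_intercept(np.empty((n, 0)))
    X_full = np.hstack([X_null, prs[:, None]])
    if n <= X_full.shape[1] + 1:
        raise ValueError("too few observations for the requested model")
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res_null = sm.OLS(y, X_null).fit()
    res_full = sm.OLS(y, X_full).fit()
    return float(res_full.rsquared - res_null.rsquared), float(res_full.pvalues[-1])


# ---------------------------------------------------------------------------
# discrimination


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney form; score ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def c_index(scores, outcome) -> float:
    """Concordance over all pairs with distinct outcomes; score ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if np.unique(outcome).size < 2:
        raise ValueError("outcome is constant; concordance undefined")
    ds = np.sign(scores[:, None] - scores[None, :])
    do = np.sign(outcome[:, None] - outcome[None, :])
    usable = do != 0
    concordant = (ds == do) & usable
    tied = (ds == 0) & usable
    return float((concordant.sum() + 0.5 * tied.sum()) / usable.sum())


# ---------------------------------------------------------------------------
# quantile stratification


def _quantile_groups(prs, sample_ids, q: int) -> np.ndarray:
    """Group index (0 = lowest) per sample; sizes differ by <= 1, remainders
    allocated to the lower quantiles; ties broken by (score, sample id)."""
    n = len(prs)
    order = np.lexsort((np.asarray(sample_ids, dtype=object), np.asarray(prs)))
    base, rem = divmod(n, q)
    sizes = [base + 1 if g < rem else base for g in range(q)]
    groups = np.empty(n, dtype=int)
    start = 0
    for g, s in enumerate(sizes):
        groups[order[start:start + s]] = g
        start += s
    return groups


def quantile_effects(
    prs,
    phenotypes: PhenotypeTable,
    covars=None,
    q: int = 4,
    outcome: str = "diagnosis",
) -> QuantileContrast:
    """Effect of score quantile membership, lowest quantile as reference.

    Diagnosis: logistic regression on quantile indicators (+ covariates),
    estimates reported as odds ratios with 95% Wald CIs.  Severity: OLS,
    estimates are adjusted mean differences.
    """
    prs = np.asarray(prs, dtype=float)
    n = prs.size
    if n < 2 * q:
        raise ValueError(f"need at least {2 * q} samples for {q} quantiles")
    groups = _quantile_groups(prs, phenotypes.sample_ids, q)
    indicators = np.column_stack([(groups == g).astype(float) for g in range(1, q)])
    covars = None if covars is None else np.asarray(covars, dtype=float)
    X = _with_intercept(indicators, covars) if covars is not None else _with_intercept(indicators)
    if outcome == "diagnosis":
        y = phenotypes.diagnosis
        res = _fit_logit(y.astype(float), X)
        coefs = res.params[1:q]
        ses = res.bse[1:q]
        pvals = res.pvalues[1:q]
        est = np.exp(coefs)
        lo = np.exp(coefs - 1.959963984540054 * ses)
        hi = np.exp(coefs + 1.959963984540054 * ses)
    elif outcome == "severity":
        y = phenotypes.severity
        if y is None:
            raise ValueError("phenotype table has no severity column")
        res = sm.OLS(y, X).fit()
        coefs = res.params[1:q]
        ses = res.bse[1:q]
        pvals = res.pvalues[1:q]
        est = coefs
        lo = coefs - 1.959963984540054 * ses
        hi = coefs + 1.959963984540054 * ses
    else:
        raise ValueError("outcome must be 'diagnosis' or 'severity'")
    table = pd.DataFrame(
        {
            "quantile": np.arange(2, q + 1),
            "estimate": est,
            "ci_low": lo,
            "ci_high": hi,
            "p": pvals,
        }
    )
    return QuantileContrast(q=q, outcome=outcome, table=table)


# ---------------------------------------------------------------------------
# cohort-description tests


def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction; all expected counts must be positive.
    Returns (statistic, df, P value).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal total; drop empty rows/columns first")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df, float(stats.chi2.sf(stat, df))


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null distribution when both groups have <= 25 observations and no
    ties across the pooled sample; tie-corrected normal approximation without
    continuity correction otherwise.  Returns (U statistic of x, P value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    n1, n2 = x.size, y.size
    if not has_ties and max(n1, n2) <= 25:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    ranks = stats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * (n + 1 - tie_term / (n * (n - 1)))
    if var == 0:
        return float(u), 1.0
    z = (u - mu) / np.sqrt(var)
    return float(u), float(2.0 * stats.norm.sf(abs(z)))


def evaluate(prs_z, phenotypes: PhenotypeTable, covars=None) -> EvalReport:
    """One-stop evaluation: incremental R^2 (both flavors), AUC, C-index."""
    y = phenotypes.diagnosis
    out: dict = {"n": len(prs_z)}
    try:
        d, p = nagelkerke_delta_r2(y, prs_z, covars)
        out["nagelkerke_delta_r2"], out["p_diagnosis"] = d, p
    except (SeparationError, ValueError):
        out["nagelkerke_delta_r2"] = out["p_diagnosis"] = None
    try:
        out["auc"] = auc(prs_z, y)
    except ValueError:
        out["auc"] = None
    sev = phenotypes.severity
    if sev is not None and np.unique(sev).size >= 2:
        try:
            d, p = linear_delta_r2(sev, prs_z, covars)
            out["linear_delta_r2"], out["p_severity"] = d, p
        except ValueError:
            out["linear_delta_r2"] = out["p_severity"] = None
        out["c_index"] = c_index(prs_z, sev)
    else:
        out["linear_delta_r2"] = out["p_severity"] = out["c_index"] = None
    return EvalReport(**out)
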