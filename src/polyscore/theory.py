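"""Liability-threshold projections and single-variant GWAS power.

Under the liability-threshold model an individual is affected when a latent
standard-normal liability (genetic + environmental) exceeds the threshold
``T = Phi^{-1}(1 - K)`` implied by population prevalence ``K``.  A genomic
predictor explaining a fraction ``r2`` of liability variance then separates
future cases and controls with an AUC that follows from the truncated-normal
group means ``i_case = phi(T)/K`` and ``i_control = -phi(T)/(1-K)``:

    AUC = Phi( r2 (i_case - i_control)
               / sqrt(v_case + v_control) ),
    v_group = r2 (1 - r2 * i_group * (i_group - T)).

The expected liability variance explained by a predictor trained on ``N``
random population samples with ``M`` non-null markers uses the classical
expected-accuracy form ``r2 = h2 * N h2 / (N h2 + M)``, whose ``N -> inf``
limit recovers the heritability ceiling.

Single-variant power uses an additive-penetrance genotype-relative-risk model
(``f1 = lam f0``, ``f2 = (2 lam - 1) f0``, prevalence fixing ``f0``), HWE
genotype frequencies in cases and controls, and the 1-df additive trend test
approximated by a noncentral chi-square.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "TheoryParams",
    "PowerQuery",
    "liability_moments",
    "auc_given_variance_explained",
    "max_auc",
    "projection_r2",
    "projection_curve",
    "gwas_power",
    "detectable_grr",
]


@dataclass
class TheoryParams:
    """Liability-model parameters: heritability h2, prevalence K, non-null
    marker count M, training sample size N."""

    h2: float = 0.30
    K: float = 0.08
    M: int = 50_000
    N: int = 20_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0.0 < self.K < 1.0:
            raise ValueError("K must lie in (0, 1)")


@dataclass
class PowerQuery:
    """Inputs for a single-variant case-control power calculation."""

    n_case: int
    n_control: int
    daf: float  # disease (risk) allele frequency
    grr: float  # genotype relative risk lambda
    K: float = 0.08
    alpha: float = 5e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.daf < 1.0:
            raise ValueError("daf must lie in (0, 1)")
        if self.grr < 1.0:
            raise ValueError("grr must be >= 1 under the risk-allele convention")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def liability_moments(K: float) -> tuple[float, float, float]:
    """Threshold and truncated-normal mean liabilities for prevalence K.

    Returns ``(T, i_case, i_control)`` with ``T = Phi^{-1}(1-K)``,
    ``i_case = phi(T)/K`` (mean liability above T), and
    ``i_control = -phi(T)/(1-K)``.
    """
    if not 0.0 < K < 1.0:
        raise ValueError("prevalence K must lie in (0, 1)")
    T = stats.norm.isf(K)
    phi = stats.norm.pdf(T)
    return float(T), float(phi / K), float(-phi / (1.0 - K))


def auc_given_variance_explained(r2_liab: float, K: float) -> float:
    """AUC of a normal score explaining ``r2_liab`` of liability variance.

    Normal approximation to the case/control score distributions: group means
    ``r2 * i``, group variances ``r2 (1 - r2 * i (i - T))``.
    """
    if not 0.0 <= r2_liab <= 1.0:
        raise ValueError("r2_liab must lie in [0, 1]")
    if r2_liab == 0.0:
        return 0.5
    T, i1, i0 = liability_moments(K)
    mean_diff = r2_liab * (i1 - i0)
    v1 = r2_liab * (1.0 - r2_liab * i1 * (i1 - T))
    v0 = r2_liab * (1.0 - r2_liab * i0 * (i0 - T))
    if v1 + v0 <= 0:
        return 1.0
    return float(stats.norm.cdf(mean_diff / np.sqrt(v1 + v0)))


def max_auc(h2: float, K: float) -> float:
    """Infinite-training-data AUC ceiling: a predictor capturing all additive
    genetic liability variance ``h2``."""
    return auc_given_variance_explained(h2, K)


def projection_r2(N: float, M: float, h2: float, K: float) -> tuple[float, float]:
    """Expected performance of a profile trained on N samples, M markers.

    Expected liability variance explained ``r2 = h2 * N h2 / (N h2 + M)``
    and the corresponding AUC under the liability-threshold model.
    """
    if N < 1 or M < 1:
        raise ValueError("N and M must be at least 1")
    r2 = h2 * (N * h2) / (N * h2 + M)
    return float(r2), auc_given_variance_explained(r2, K)


def projection_curve(N_grid, M: float, h2: float, K: float):
    """Vectorized :func:`projection_r2` over a grid of training sizes.

    Returns an ``(len(N_grid), 3)`` array of (N, r2_liab, AUC) rows,
    the data behind a performance-projection curve.
    """
    rows = []
    for N in N_grid:
        r2, a = projection_r2(N, M, h2, K)
        rows.append((float(N), r2, a))
    return np.array(rows)


# ---------------------------------------------------------------------------
# single-variant power


def _genotype_freqs(q: PowerQuery) -> tuple[np.ndarray, np.ndarray]:
    """HWE genotype frequencies (index = risk-allele count) in cases/controls
    under the additive-penetrance GRR model."""
    p = q.daf
    lam = q.grr
    hwe = np.array([(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p * p])
    denom = hwe[0] + hwe[1] * lam + hwe[2] * (2.0 * lam - 1.0)
    f0 = q.K / denom
    pen = np.array([f0, lam * f0, (2.0 * lam - 1.0) * f0])
    if pen[2] > 1.0 or pen[2] < 0.0:
        raise ValueError(
            f"infeasible penetrance f2={pen[2]:.4f} for grr={lam}, daf={p}, K={q.K}"
        )
    p_case = hwe * pen / q.K
    p_control = hwe * (1.0 - pen) / (1.0 - q.K)
    return p_case, p_control


def gwas_power(q: PowerQuery) -> float:
    """Power of the 1-df additive (Cochran-Armitage trend) test.

    The trend test compares mean risk-allele dosage between cases and
    controls; its statistic is approximated by a noncentral chi-square with
    NCP ``(mu_case - mu_control)^2 / (v_case/n_case + v_control/n_control)``.
    """
    p1, p0 = _genotype_freqs(q)
    g = np.array([0.0, 1.0, 2.0])
    m1, m0 = p1 @ g, p0 @ g
    v1 = p1 @ g**2 - m1**2
    v0 = p0 @ g**2 - m0**2
    ncp = (m1 - m0) ** 2 / (v1 / q.n_case + v0 / q.n_control)
    crit = stats.chi2.isf(q.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


def detectable_grr(
    power_target: float,
    n_case: int,
    n_control: int,
    daf: float,
    K: float = 0.08,
    alpha: float = 5e-8,
    grr_max: float = 10.0,
    tol: float = 1e-4,
) -> float:
    """Smallest genotype relative risk reaching the target power.

    Bisection on the monotone analytic power curve, to absolute tolerance
    ``tol`` in lambda.
    """
    base = dict(n_case=n_case, n_control=n_control, daf=daf, K=K, alpha=alpha)
    if not alpha < power_target < 1.0:
        raise ValueError("power_target must lie in (alpha, 1)")

    def gap(lam: float) -> float:
        return gwas_power(PowerQuery(grr=lam, **base)) - power_target

    lo = 1.0 + 1e-9
    if gap(lo) >= 0:
        return lo
    if gap(grr_max) < 0:
        raise RuntimeError(f"target power {power_target} unreachable below grr={grr_max}")
    return float(brentq(gap, lo, grr_max, xtol=tol))
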