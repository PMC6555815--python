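"""Polygenic risk score computation and P-value threshold scanning.

The score of individual *j* is the unnormalized weighted allele sum
``PRS_j = sum_{i in S, p_i < P_T} beta_i * x_ij`` over the clumped SNP set S,
where ``beta_i`` is the harmonized discovery effect size and ``x_ij`` the
0/1/2 dosage (missing dosages mean-imputed per variant).  Raw scores are
standardized cohort-wide to z-scores.  ``threshold_scan`` evaluates the score
over a grid of inclusion thresholds P_T and picks the one maximizing the
covariate-adjusted incremental Nagelkerke R^2 for diagnosis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import GenotypeCohort, HarmonizedWeights, PhenotypeTable
from .evalstats import nagelkerke_delta_r2

__all__ = ["ScoreSet", "ThresholdScan", "compute_prs", "threshold_scan", "DEFAULT_GRID"]

# ten equally spaced thresholds 0.1..1.0 plus nominal significance 0.05
DEFAULT_GRID = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass
class ScoreSet:
    """Per-individual polygenic score at one inclusion threshold."""

    sample_ids: list[str]
    raw: np.ndarray
    z: np.ndarray
    threshold: float
    snp_indices: np.ndarray  # cohort variant columns contributing to the score
    n_variants: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_variants = int(len(self.snp_indices))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "raw": self.raw,
                "z": self.z,
                "threshold": self.threshold,
                "n_variants": self.n_variants,
            }
        )


@dataclass
class ThresholdScan:
    """Grid-scan result: one row per threshold, and the maximizing threshold."""

    table: pd.DataFrame  # threshold, n_variants, delta_r2, p
    best_threshold: float


def _included(weights: HarmonizedWeights, snp_set, threshold: float) -> pd.DataFrame:
    w = weights.table
    if snp_set is not None:
        w = w[w["variant_index"].isin(np.asarray(snp_set))]
    # strict inequality at interior thresholds; the endpoint 1.0 includes all
    if threshold >= 1.0:
        w = w[w["p"] <= 1.0]
    else:
        w = w[w["p"] < threshold]
    return w


def compute_prs(
    cohort: GenotypeCohort,
    weights: HarmonizedWeights,
    snp_set=None,
    threshold: float = 1.0,
) -> ScoreSet:
    """Weighted allele-dosage sum over the surviving SNP set.

    ``snp_set`` restricts to the clumped variants; only weights with
    p < ``threshold`` contribute (p <= 1 at the endpoint 1.0).  Missing
    dosages are imputed with the variant's mean dosage (2 x counted-allele
    frequency).  z-scores standardize raw scores across the cohort.
    """
    w = _included(weights, snp_set, threshold)
    if len(w) == 0:
        raise ValueError(f"no variants pass threshold {threshold}")
    idx = w["variant_index"].to_numpy()
    beta = w["beta_aligned"].to_numpy()
    X = cohort.dosage[:, idx].astype(float)
    mu = np.nanmean(X, axis=0)
    miss = np.where(np.isnan(X))
    X[miss] = np.take(mu, miss[1])
    raw = X @ beta
    sd = raw.std(ddof=1)
    z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    return ScoreSet(list(cohort.sample_ids), raw, z, float(threshold), idx)


def threshold_scan(
    cohort: GenotypeCohort,
    weights: HarmonizedWeights,
    phenotypes: PhenotypeTable,
    covars=None,
    grid=DEFAULT_GRID,
    snp_set=None,
) -> ThresholdScan:
    """Scan inclusion thresholds; best = maximal incremental Nagelkerke R^2.

    Ties and empty thresholds resolve to the smallest qualifying threshold.
    """
    grid = sorted(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    y = phenotypes.diagnosis
    rows = []
    for t in grid:
        try:
            ss = compute_prs(cohort, weights, snp_set=snp_set, threshold=t)
        except ValueError:
            rows.append((t, 0, np.nan, np.nan))
            continue
        delta, p = nagelkerke_delta_r2(y, ss.z, covars)
        rows.append((t, ss.n_variants, delta, p))
    table = pd.DataFrame(rows, columns=["threshold", "n_variants", "delta_r2", "p"])
    if table["delta_r2"].isna().all():
        raise ValueError("no threshold yielded a scoreable SNP set")
    best = float(table.loc[table["delta_r2"].idxmax(), "threshold"])
    return ThresholdScan(table=table, best_threshold=best)
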