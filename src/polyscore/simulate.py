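"""Synthetic GWAS study generator: LD-blocked genotypes, liability-threshold
phenotypes, a large discovery GWAS, and an ascertained case-control target.

The generator emulates the statistical structure a summary-statistics PRS
analysis assumes, at desk scale:

* Allele frequencies: ancestral ~ Uniform(0.05, 0.95); diverged populations
  drawn per variant from the Balding-Nichols Beta(p(1-F)/F, (1-p)(1-F)/F).
* Genotypes: two independent haplotypes per individual; each haplotype is a
  blockwise AR(1) Gaussian copula (within-block latent correlation
  ``rho^|i-j|``) thresholded at the variant's frequency quantile, giving
  LD blocks with tunable decay and no cross-block correlation.
* Phenotypes: additive liability from a sparse causal architecture whose
  standardized effects sum in squares to h2; disease when liability exceeds
  the prevalence threshold; a severity score produced by a monotone map of
  liability calibrated per group to clinician-scale ranges (cases ~ 37-102,
  median 65.5; controls ~ 0-24, median 2) on a 0-120 scale.
* Discovery summary statistics: per-variant logistic regression of diagnosis
  on dosage (vectorized Newton iterations), Wald P values.
* Target cohort: cases oversampled to a requested fraction (default 50/50),
  mimicking case-control ascertainment.

All functions are bit-reproducible given (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .dataio import GenotypeCohort, PhenotypeTable, SummaryStats

__all__ = [
    "SimConfig",
    "TrueArchitecture",
    "simulate_pop_freqs",
    "variant_table",
    "simulate_genotypes",
    "simulate_architecture",
    "assign_phenotypes",
    "discovery_gwas",
    "ascertain_target",
    "simulate_study",
    "SimStudy",
]

_BP_SPACING = 5_000  # base pairs between adjacent simulated variants


@dataclass
class SimConfig:
    """Study-generator configuration.

    Defaults are the scaled-down study conditions used throughout the test
    suite: liability heritability 0.30, prevalence 0.08, a sparse causal
    architecture (500 of 5,000 markers), a 20,000-sample discovery GWAS and a
    1,000-sample 50/50 ascertained target.
    """

    m: int = 5_000
    m_causal: int = 500
    h2: float = 0.30
    K: float = 0.08
    n_discovery: int = 20_000
    n_target: int = 1_000
    target_case_fraction: float = 0.5
    fst: float = 0.15  # divergence of any additional population
    ld_rho: float = 0.8
    block_size: int = 20
    severity_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_causal > self.m:
            raise ValueError("m_causal cannot exceed m")
        for name in ("h2", "K", "target_case_fraction", "ld_rho", "fst"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.ld_rho >= 1.0 or self.fst >= 1.0:
            raise ValueError("ld_rho and fst must be < 1")


@dataclass
class TrueArchitecture:
    """Ground-truth causal architecture behind a simulated phenotype."""

    causal_idx: np.ndarray          # sorted variant columns carrying effects
    beta_std: np.ndarray            # effects per standardized dosage; sum sq = h2
    beta_allele: np.ndarray         # effects per allele copy (ancestral scaling)
    h2: float
    freq_anc: np.ndarray = field(repr=False, default=None)  # ancestral freqs, all m


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_pop_freqs(m: int, fst: float, seed, n_pops: int = 1):
    """Ancestral and population allele frequencies (Balding-Nichols).

    Returns ``(ancestral, [pop_1, ..., pop_n_pops])``; each population draws
    per-variant frequencies from Beta(p(1-F)/F, (1-p)(1-F)/F) around the
    ancestral value p.  ``fst = 0`` returns the ancestral vector unchanged.
    """
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must lie in [0, 1)")
    rng = _rng(seed)
    anc = rng.uniform(0.05, 0.95, size=m)
    if fst == 0.0:
        return anc, [anc.copy() for _ in range(n_pops)]
    a = anc * (1.0 - fst) / fst
    b = (1.0 - anc) * (1.0 - fst) / fst
    pops = [np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4) for _ in range(n_pops)]
    return anc, pops


def variant_table(m: int) -> pd.DataFrame:
    """Shared variant metadata for all simulated cohorts: one chromosome,
    evenly spaced positions, unambiguous A/G alleles."""
    return pd.DataFrame(
        {
            "id": [f"snp{i}" for i in range(m)],
            "chrom": "1",
            "pos": 1 + _BP_SPACING * np.arange(m, dtype=np.int64),
            "allele_counted": "A",
            "allele_other": "G",
        }
    )


def simulate_genotypes(
    n: int,
    freqs: np.ndarray,
    ld_rho: float = 0.8,
    block_size: int = 20,
    seed=0,
    id_prefix: str = "s",
) -> GenotypeCohort:
    """LD-blocked diploid genotypes via a thresholded Gaussian copula.

    Per haplotype, a latent AR(1) Gaussian with lag-1 correlation ``ld_rho``
    inside each ``block_size``-variant block (independent across blocks) is
    thresholded at ``Phi^{-1}(freq)`` so each variant's allele frequency hits
    its target; the two haplotypes are summed into 0/1/2 dosages.
    """
    freqs = np.asarray(freqs, dtype=float)
    m = freqs.size
    rng = _rng(seed)
    thr = stats.norm.ppf(freqs).astype(np.float32)
    dosage = np.empty((n, m), dtype=np.float32)
    scale = np.float32(np.sqrt(1.0 - ld_rho**2))
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        width = stop - start
        z = rng.standard_normal((2 * n, width), dtype=np.float32)
        if ld_rho > 0:
            for j in range(1, width):
                z[:, j] = ld_rho * z[:, j - 1] + scale * z[:, j]
        alleles = (z < thr[start:stop]).astype(np.int8)
        dosage[:, start:stop] = alleles[:n] + alleles[n:]
    return GenotypeCohort(
        dosage,
        variant_table(m),
        [f"{id_prefix}{i}" for i in range(n)],
    )


def simulate_architecture(m: int, m_causal: int, h2: float, freq_anc, seed) -> TrueArchitecture:
    """Sparse additive architecture: causal set uniform without replacement,
    standardized effects normal, rescaled so their squares sum to h2 exactly.

    Per-allele effects divide by ``sqrt(2 p (1-p))`` at the *ancestral*
    frequency, so the same allelic effect applies in every derived population.
    """
    rng = _rng(seed)
    freq_anc = np.asarray(freq_anc, dtype=float)
    causal = np.sort(rng.choice(m, size=m_causal, replace=False))
    raw = rng.standard_normal(m_causal)
    if h2 == 0.0:
        beta_std = np.zeros(m_causal)
    else:
        beta_std = raw * np.sqrt(h2 / np.sum(raw**2))
    p = freq_anc[causal]
    beta_allele = beta_std / np.sqrt(2.0 * p * (1.0 - p))
    return TrueArchitecture(causal, beta_std, beta_allele, float(h2), freq_anc)


def _liability(cohort: GenotypeCohort, arch: TrueArchitecture) -> np.ndarray:
    X = cohort.dosage[:, arch.causal_idx].astype(np.float64)
    if np.isnan(X).any():
        mu = np.nanmean(X, axis=0)
        miss = np.where(np.isnan(X))
        X[miss] = np.take(mu, miss[1])
    g = X @ arch.beta_allele
    return g - g.mean()


def assign_phenotypes(
    cohort: GenotypeCohort,
    arch: TrueArchitecture,
    K: float = 0.08,
    seed=0,
    severity_noise_sd: float = 2.0,
) -> PhenotypeTable:
    """Liability-threshold diagnosis plus a calibrated 0-120 severity score.

    Liability = centered genetic value + N(0, 1 - h2) environment; case iff
    liability exceeds ``Phi^{-1}(1 - K)``.  Severity maps the conditional
    liability quantile monotonically into each group's clinical range
    (cases -> [37, 102] with median 65.5, controls -> [0, 24] with median 2),
    plus Gaussian measurement noise, truncated to [0, 120].
    """
    rng = _rng(seed)
    g = _liability(cohort, arch)
    e = rng.normal(0.0, np.sqrt(max(0.0, 1.0 - arch.h2)), size=g.size)
    liab = g + e
    T = stats.norm.isf(K)
    case = liab > T
    # conditional quantile of liability within each group, under N(0,1)
    u = stats.norm.cdf(liab)
    u_case = np.clip((u - (1.0 - K)) / K, 0.0, 1.0)
    u_ctrl = np.clip(u / (1.0 - K), 0.0, 1.0)
    # exponents solve  lo + span * 0.5^gamma = group median
    gamma_case = np.log((65.5 - 37.0) / 65.0) / np.log(0.5)
    gamma_ctrl = np.log(2.0 / 24.0) / np.log(0.5)
    severity = np.where(
        case,
        37.0 + 65.0 * u_case**gamma_case,
        24.0 * u_ctrl**gamma_ctrl,
    )
    severity = severity + rng.normal(0.0, severity_noise_sd, size=g.size)
    severity = np.clip(severity, 0.0, 120.0)
    table = pd.DataFrame(
        {"diagnosis": case.astype(int), "severity": severity},
        index=pd.Index(cohort.sample_ids, name="sample_id"),
    )
    return PhenotypeTable(table)


def discovery_gwas(
    cohort: GenotypeCohort,
    phenotypes: PhenotypeTable,
    chunk_size: int = 512,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> SummaryStats:
    """Per-variant univariate logistic GWAS (diagnosis ~ dosage).

    Newton-Raphson fits vectorized across variants in chunks (float32
    elementwise work, float64 accumulation); monomorphic variants are
    dropped.  Effect allele is each variant's counted allele.
    """
    y = phenotypes.reindex(cohort.sample_ids).diagnosis.astype(np.float32)
    if y.min() == y.max():
        raise ValueError("discovery cohort must contain both cases and controls")
    m = cohort.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    ybar = float(y.mean())
    b0_init = float(np.log(ybar / (1.0 - ybar)))
    for start in range(0, m, chunk_size):
        stop = min(start + chunk_size, m)
        X = cohort.dosage[:, start:stop].astype(np.float32)
        if np.isnan(X).any():
            mu = np.nanmean(X, axis=0)
            miss = np.where(np.isnan(X))
            X[miss] = np.take(mu, miss[1])
        poly = X.std(axis=0) > 0
        b0 = np.full(stop - start, b0_init)
        b1 = np.zeros(stop - start)
        h00 = h01 = h11 = det = None
        for _ in range(max_iter):
            eta = b0.astype(np.float32) + X * b1.astype(np.float32)
            mu_ = expit(eta)
            w = mu_ * (np.float32(1.0) - mu_)
            resid = y[:, None] - mu_
            g0 = resid.sum(axis=0, dtype=np.float64)
            g1 = (X * resid).sum(axis=0, dtype=np.float64)
            h00 = w.sum(axis=0, dtype=np.float64)
            wx = w * X
            h01 = wx.sum(axis=0, dtype=np.float64)
            h11 = (wx * X).sum(axis=0, dtype=np.float64)
            det = h00 * h11 - h01 * h01
            safe = poly & (det > 1e-12)
            db0 = np.where(safe, (h11 * g0 - h01 * g1) / np.where(det == 0, 1, det), 0.0)
            db1 = np.where(safe, (h00 * g1 - h01 * g0) / np.where(det == 0, 1, det), 0.0)
            b0 += db0
            b1 += db1
            if max(np.abs(db0).max(initial=0), np.abs(db1).max(initial=0)) < tol:
                break
        ok = poly & (det > 1e-12)
        beta[start:stop][ok] = b1[ok]
        se[start:stop][ok] = np.sqrt(h00[ok] / det[ok])
    keep = ~np.isnan(beta)
    z = beta[keep] / se[keep]
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    v = cohort.variants.loc[keep].reset_index(drop=True)
    table = pd.DataFrame(
        {
            "id": v["id"],
            "chrom": v["chrom"],
            "pos": v["pos"],
            "effect_allele": v["allele_counted"],
            "other_allele": v["allele_other"],
            "beta": beta[keep],
            "se": se[keep],
            "p": p,
        }
    )
    return SummaryStats(table, n_rejected=int((~keep).sum()))


def ascertain_target(
    cohort: GenotypeCohort,
    phenotypes: PhenotypeTable,
    n_target: int,
    case_fraction: float = 0.5,
    seed=0,
) -> tuple[GenotypeCohort, PhenotypeTable]:
    """Sample a case-enriched target cohort without replacement.

    Draws ``round(n_target * case_fraction)`` cases and the complement of
    controls uniformly from the pool; errors if either stratum is short.
    """
    rng = _rng(seed)
    phen = phenotypes.reindex(cohort.sample_ids)
    y = phen.diagnosis
    n_case = int(round(n_target * case_fraction))
    n_control = n_target - n_case
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if cases.size < n_case:
        raise ValueError(f"pool has {cases.size} cases, {n_case} requested (short {n_case - cases.size})")
    if controls.size < n_control:
        raise ValueError(
            f"pool has {controls.size} controls, {n_control} requested (short {n_control - controls.size})"
        )
    pick = np.sort(
        np.concatenate(
            [
                rng.choice(cases, size=n_case, replace=False),
                rng.choice(controls, size=n_control, replace=False),
            ]
        )
    )
    sub = cohort.subset_samples(pick)
    return sub, phen.reindex(sub.sample_ids)


@dataclass
class SimStudy:
    """Bundle of everything a scoring pipeline consumes."""

    sumstats: SummaryStats
    target: GenotypeCohort
    target_phen: PhenotypeTable
    architecture: TrueArchitecture
    freq_anc: np.ndarray
    discovery_prevalence: float


def simulate_study(config: SimConfig, target_fst: float = 0.0) -> SimStudy:
    """Generate a full study: discovery GWAS + ascertained target cohort.

    With ``target_fst > 0`` the target population is drawn from
    Balding-Nichols-diverged allele frequencies with independently realized
    LD, emulating a discovery/target ancestry mismatch.
    """
    ss = np.random.SeedSequence(config.seed)
    r_freq, r_geno_d, r_phen_d, r_geno_t, r_phen_t, r_asc = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    anc, pops = simulate_pop_freqs(config.m, target_fst, r_freq, n_pops=1)
    freq_target = pops[0] if target_fst > 0 else anc
    arch = simulate_architecture(config.m, config.m_causal, config.h2, anc, r_freq)

    disc = simulate_genotypes(
        config.n_discovery, anc, config.ld_rho, config.block_size, r_geno_d, id_prefix="d"
    )
    disc_phen = assign_phenotypes(disc, arch, config.K, r_phen_d, config.severity_noise_sd)
    sumstats = discovery_gwas(disc, disc_phen)
    prevalence = float(disc_phen.diagnosis.mean())
    del disc

    # pool large enough to supply the requested case/control strata
    cf = config.target_case_fraction
    need = max(cf / config.K if cf > 0 else 0.0, (1 - cf) / (1 - config.K))
    n_pool = int(np.ceil(config.n_target * need * 1.3)) + 100
    pool = simulate_genotypes(
        n_pool, freq_target, config.ld_rho, config.block_size, r_geno_t, id_prefix="t"
    )
    pool_phen = assign_phenotypes(pool, arch, config.K, r_phen_t, config.severity_noise_sd)
    target, target_phen = ascertain_target(
        pool, pool_phen, config.n_target, cf, r_asc
    )
    return SimStudy(sumstats, target, target_phen, arch, anc, prevalence)
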