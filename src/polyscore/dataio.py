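"""Genotype, summary-statistic and phenotype I/O, QC filtering, and allele harmonization.

The central container is :class:`GenotypeCohort`: an ``n_samples x m_variants``
additive dosage matrix (entries 0/1/2 counting copies of the *counted* allele,
``NaN`` for missing) plus per-variant metadata and sample ids.  Two on-disk
dialects are supported: PLINK 1 binary (``.bed``/``.bim``/``.fam``, SNP-major)
and a transparent text-dosage table (header row of variant ids; one row per
sample: sample id followed by dosages or ``NA``).  The text dialect carries an
optional ``<path>.vars`` sidecar with chrom/pos/allele metadata so that both
dialects round-trip losslessly.

Summary statistics are read from whitespace/tab-delimited GWAS tables with
configurable column names (consortium-style defaults: SNP, CHR, BP, A1, A2, OR or
BETA, SE, P).  ``harmonize`` aligns summary effect sizes to the cohort's
counted alleles, flipping signs for allele swaps, resolving strand flips via
base complement, and (by default) dropping strand-ambiguous A/T and C/G
variants.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeCohort",
    "SummaryStats",
    "PhenotypeTable",
    "HarmonizedWeights",
    "QcReport",
    "read_genotype_matrix",
    "write_genotypes",
    "read_summary_stats",
    "read_phenotypes",
    "write_phenotypes",
    "hwe_exact_p",
    "qc_filter",
    "harmonize",
]

VARIANT_COLUMNS = ["id", "chrom", "pos", "allele_counted", "allele_other"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input violates a domain constraint."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeCohort:
    """Additive dosage matrix with aligned variant and sample metadata.

    Parameters
    ----------
    dosage
        ``(n_samples, m_variants)`` float array; entries in {0, 1, 2} count
        copies of each variant's counted allele, ``NaN`` marks missing calls.
    variants
        DataFrame with columns ``id, chrom, pos, allele_counted, allele_other``.
    sample_ids
        Unique sample identifiers, one per dosage row.
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if not np.issubdtype(self.dosage.dtype, np.floating):
            self.dosage = self.dosage.astype(np.float64)
        if self.dosage.ndim != 2:
            raise ValidationError("dosage must be a 2-D matrix")
        self.variants = self.variants.reset_index(drop=True)
        missing_cols = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ValidationError(f"variant table missing columns: {sorted(missing_cols)}")
        n, m = self.dosage.shape
        if len(self.variants) != m:
            raise ValidationError(f"{m} dosage columns but {len(self.variants)} variant records")
        if len(self.sample_ids) != n:
            raise ValidationError(f"{n} dosage rows but {len(self.sample_ids)} sample ids")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids are not unique")
        if self.variants["id"].duplicated().any():
            dups = self.variants.loc[self.variants["id"].duplicated(), "id"].tolist()
            raise ValidationError(f"duplicated variant ids: {dups[:5]}")
        d = self.dosage
        with np.errstate(invalid="ignore"):
            bad = ~(np.isnan(d) | ((d >= 0) & (d <= 2) & (d == np.floor(d))))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage[{i},{j}] = {self.dosage[i, j]} not in {{0,1,2,missing}}"
            )

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def counted_allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per variant, from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant (non-missing calls only)."""
        f = self.counted_allele_freq()
        return np.minimum(f, 1.0 - f)

    def variant_missingness(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=1)

    def subset_variants(self, idx) -> "GenotypeCohort":
        idx = np.asarray(idx)
        return GenotypeCohort(
            self.dosage[:, idx].copy(),
            self.variants.iloc[idx].reset_index(drop=True),
            list(self.sample_ids),
        )

    def subset_samples(self, idx) -> "GenotypeCohort":
        idx = np.asarray(idx)
        return GenotypeCohort(
            self.dosage[idx, :].copy(),
            self.variants.copy(),
            [self.sample_ids[i] for i in idx],
        )

    def equals(self, other: "GenotypeCohort") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.variants[VARIANT_COLUMNS].equals(other.variants[VARIANT_COLUMNS])
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )


@dataclass
class SummaryStats:
    """Per-variant GWAS summary statistics.

    ``table`` has columns ``id, chrom, pos, effect_allele, other_allele, beta,
    se, p``; ``beta`` is on the log-odds (or linear-regression) scale,
    ``p`` in (0, 1].  ``n_rejected`` counts input rows dropped for invalid P.
    """

    table: pd.DataFrame
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        if self.table["id"].duplicated().any():
            raise ValidationError("duplicated variant ids in summary statistics")
        p = self.table["p"].to_numpy()
        if ((p <= 0) | (p > 1)).any():
            raise ValidationError("summary-statistic P values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PhenotypeTable:
    """Per-sample phenotypes: binary diagnosis, optional severity, covariates."""

    table: pd.DataFrame  # index: sample id; columns: diagnosis, severity, covariates

    def __post_init__(self) -> None:
        if "diagnosis" not in self.table.columns:
            raise ValidationError("phenotype table needs a 'diagnosis' column")
        d = self.table["diagnosis"]
        if d.isna().any():
            raise ValidationError("diagnosis must be non-missing for every sample")
        if not set(d.unique()) <= {0, 1}:
            raise ValidationError("diagnosis must be coded 0/1")
        if "severity" in self.table.columns:
            s = self.table["severity"].dropna()
            bad = s[(s < 0) | (s > 120)]
            if len(bad):
                raise ValidationError(
                    f"severity outside [0, 120] for samples: {list(bad.index[:10])}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def diagnosis(self) -> np.ndarray:
        return self.table["diagnosis"].to_numpy(dtype=int)

    @property
    def severity(self) -> np.ndarray | None:
        if "severity" not in self.table.columns:
            return None
        return self.table["severity"].to_numpy(dtype=float)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("diagnosis", "severity")]

    def covariates(self) -> np.ndarray:
        return self.table[self.covariate_names].to_numpy(dtype=float)

    def reindex(self, sample_ids) -> "PhenotypeTable":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"phenotypes missing for samples: {missing[:10]}")
        return PhenotypeTable(self.table.loc[list(sample_ids)].copy())


@dataclass
class HarmonizedWeights:
    """Summary-statistic effects aligned to a cohort's counted alleles.

    ``table`` columns: ``variant_index`` (column in the cohort dosage matrix),
    ``id``, ``beta_aligned`` (sign-flipped when the summary effect allele is
    the cohort's other allele), ``p``.  ``counts`` logs the fate of every
    summary variant (direct / swapped / strand-flipped / ambiguous-dropped /
    mismatched / unmatched).
    """

    table: pd.DataFrame
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table["variant_index"].duplicated().any():
            raise ValidationError("a cohort variant received more than one weight")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class QcReport:
    """Attrition accounting for :func:`qc_filter`.

    ``removed`` maps criterion name (in application order) to the number of
    variants/samples removed at that step; thresholds echo the filter values.
    """

    n_variants_in: int
    n_samples_in: int
    removed: dict[str, int]
    thresholds: dict[str, float]
    order: tuple[str, ...] = (
        "sample_missingness",
        "variant_missingness",
        "maf",
        "hwe",
    )

    @property
    def n_variants_out(self) -> int:
        return self.n_variants_in - sum(
            v for k, v in self.removed.items() if k != "sample_missingness"
        )

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.removed.get("sample_missingness", 0)


# ---------------------------------------------------------------------------
# genotype I/O


def read_genotype_matrix(path, dialect: str = "text-dosage") -> GenotypeCohort:
    """Read genotypes from ``plink-bed`` or ``text-dosage`` files.

    For ``plink-bed``, ``path`` may be the ``.bed`` file or the common prefix;
    counted allele is the ``.bim`` A1 allele.  For ``text-dosage``, variant
    metadata is taken from ``<path>.vars`` when present, otherwise synthesized
    (chrom "0", sequential positions, alleles A/B).
    """
    path = Path(path)
    if dialect == "plink-bed":
        return _read_plink_bed(path)
    if dialect == "text-dosage":
        return _read_text_dosage(path)
    raise ValueError(f"unknown genotype dialect: {dialect!r}")


def write_genotypes(cohort: GenotypeCohort, path, dialect: str = "text-dosage") -> None:
    path = Path(path)
    if dialect == "plink-bed":
        _write_plink_bed(cohort, path)
    elif dialect == "text-dosage":
        _write_text_dosage(cohort, path)
    else:
        raise ValueError(f"unknown genotype dialect: {dialect!r}")


def _read_text_dosage(path: Path) -> GenotypeCohort:
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise ParseError(f"{path}: empty file")
        variant_ids = header
        sample_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(variant_ids) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(variant_ids) + 1} fields, got {len(parts)}"
                )
            sample_ids.append(parts[0])
            try:
                rows.append(
                    np.array(
                        [np.nan if v == "NA" else float(v) for v in parts[1:]],
                        dtype=np.float64,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    dosage = np.vstack(rows) if rows else np.empty((0, len(variant_ids)))
    vars_path = Path(str(path) + ".vars")
    if vars_path.exists():
        variants = pd.read_csv(vars_path, sep="\t", dtype={"chrom": str})
        if list(variants["id"]) != variant_ids:
            raise ParseError(f"{vars_path}: variant ids disagree with {path} header")
    else:
        variants = pd.DataFrame(
            {
                "id": variant_ids,
                "chrom": "0",
                "pos": np.arange(1, len(variant_ids) + 1),
                "allele_counted": "A",
                "allele_other": "B",
            }
        )
    return GenotypeCohort(dosage, variants, sample_ids)


def _write_text_dosage(cohort: GenotypeCohort, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(cohort.variants["id"]) + "\n")
        for sid, row in zip(cohort.sample_ids, cohort.dosage):
            vals = " ".join("NA" if math.isnan(v) else str(int(v)) for v in row)
            fh.write(f"{sid} {vals}\n")
    cohort.variants[VARIANT_COLUMNS].to_csv(str(path) + ".vars", sep="\t", index=False)


_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes, SNP-major: 00=hom A1 (dosage 2 of counted A1), 01=missing,
# 10=het, 11=hom A2 (dosage 0)
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def _plink_prefix(path: Path) -> Path:
    return path.with_suffix("") if path.suffix == ".bed" else path


def _read_plink_bed(path: Path) -> GenotypeCohort:
    prefix = _plink_prefix(path)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ParseError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK v1.00)")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_variant * m:
        raise ParseError(
            f"{prefix}.bed: expected {bytes_per_variant * m} data bytes, got {body.size}"
        )
    body = body.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosage = _BED_CODE_TO_DOSAGE[codes[:, :n]].T
    variants = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(int),
            "allele_counted": bim["a1"],
            "allele_other": bim["a2"],
        }
    )
    return GenotypeCohort(dosage, variants, list(fam["iid"]))


def _write_plink_bed(cohort: GenotypeCohort, path: Path) -> None:
    prefix = _plink_prefix(path)
    n, m = cohort.dosage.shape
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in cohort.variants.itertuples(index=False):
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.allele_counted}\t{v.allele_other}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in cohort.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    dosage_to_code = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    bytes_per_variant = (n + 3) // 4
    out = bytearray(_BED_MAGIC)
    for j in range(m):
        buf = bytearray(bytes_per_variant)
        col = cohort.dosage[:, j]
        for i in range(n):
            code = 0b01 if math.isnan(col[i]) else dosage_to_code[col[i]]
            buf[i // 4] |= code << (2 * (i % 4))
        out.extend(buf)
    prefix.with_suffix(".bed").write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# summary statistics / phenotypes

DEFAULT_SUMSTAT_COLUMNS = {
    "id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "effect": None,  # resolved to OR or BETA from effect_scale
    "se": "SE",
    "p": "P",
}


def read_summary_stats(path, column_map: dict | None = None, effect_scale: str = "beta") -> SummaryStats:
    """Read a whitespace/tab-delimited GWAS summary-statistics table.

    ``column_map`` maps canonical names (``id, chrom, pos, effect_allele,
    other_allele, effect, se, p``) to the file's column headers; unmapped names
    use consortium-style defaults.  With ``effect_scale="odds-ratio"`` the effect
    column is log-transformed to the beta scale.  Rows with P outside (0, 1]
    are dropped and counted in ``n_rejected``.
    """
    if effect_scale not in ("beta", "odds-ratio"):
        raise ValueError(f"effect_scale must be 'beta' or 'odds-ratio', got {effect_scale!r}")
    cmap = dict(DEFAULT_SUMSTAT_COLUMNS)
    cmap.update(column_map or {})
    if cmap["effect"] is None:
        cmap["effect"] = "OR" if effect_scale == "odds-ratio" else "BETA"
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        # fall back to this package's own canonical column names
        canonical = {k: ("beta" if k == "effect" else k) for k in cmap}
        if column_map is None and all(v in df.columns for v in canonical.values()):
            cmap = canonical
        else:
            raise ValidationError(
                f"summary-statistics file lacks required columns {missing}; "
                f"available: {list(df.columns)}"
            )
    out = pd.DataFrame(
        {
            "id": df[cmap["id"]].astype(str),
            "chrom": df[cmap["chrom"]].astype(str),
            "pos": df[cmap["pos"]].astype(int),
            "effect_allele": df[cmap["effect_allele"]].astype(str).str.upper(),
            "other_allele": df[cmap["other_allele"]].astype(str).str.upper(),
            "beta": df[cmap["effect"]].astype(float),
            "se": df[cmap["se"]].astype(float),
            "p": df[cmap["p"]].astype(float),
        }
    )
    if effect_scale == "odds-ratio":
        out["beta"] = np.log(out["beta"])
    ok = (out["p"] > 0) & (out["p"] <= 1)
    n_rejected = int((~ok).sum())
    return SummaryStats(out[ok].reset_index(drop=True), n_rejected=n_rejected)


_DIAGNOSIS_CODES = {
    "0": 0, "1": 1, "control": 0, "case": 1, "ctrl": 0,
    "unaffected": 0, "affected": 1, "false": 0, "true": 1,
}


def read_phenotypes(path, id_col: str = "sample_id") -> PhenotypeTable:
    """Read a tab-delimited phenotype/covariate table.

    Requires an id column and a diagnosis column (0/1 or case/control labels);
    ``severity`` is optional and range-checked to [0, 120]; every other column
    is kept as a named numeric covariate.
    """
    df = pd.read_csv(path, sep="\t")
    if id_col not in df.columns:
        raise ValidationError(f"phenotype file lacks id column {id_col!r}")
    if "diagnosis" not in df.columns:
        raise ValidationError("phenotype file lacks a 'diagnosis' column")
    df = df.set_index(id_col)
    df.index = df.index.astype(str)

    def _code(v):
        key = str(v).strip().lower()
        if key not in _DIAGNOSIS_CODES:
            raise ValidationError(f"unrecognized diagnosis label {v!r}")
        return _DIAGNOSIS_CODES[key]

    df["diagnosis"] = [_code(v) for v in df["diagnosis"]]
    for c in df.columns:
        if c != "diagnosis":
            df[c] = pd.to_numeric(df[c])
    return PhenotypeTable(df)


def write_phenotypes(phen: PhenotypeTable, path, id_col: str = "sample_id") -> None:
    phen.table.rename_axis(id_col).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg equilibrium test P value.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts no more probable than the observed one (mid-p off).
    Returns a value in (0, 1].
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_hom1 + n_het  # copies of allele carried by hom1
    n_b = 2 * n_hom2 + n_het
    n_rare = min(n_a, n_b)
    # all possible het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(het = h | allele counts) up to a constant:
    #   2^h * n! / (n_aa! n_ab! n_bb!) with n_ab = h, n_aa = (n_a - h)/2 ...
    from scipy.special import gammaln

    n_aa = (n_rare - hets) // 2
    n_bb = (max(n_a, n_b) - hets) // 2
    logp = hets * math.log(2.0) - gammaln(n_aa + 1) - gammaln(hets + 1) - gammaln(n_bb + 1)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def _hwe_pvalues(cohort: GenotypeCohort) -> np.ndarray:
    out = np.ones(cohort.n_variants)
    d = cohort.dosage
    for j in range(cohort.n_variants):
        col = d[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        out[j] = hwe_exact_p(int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
    return out


# ---------------------------------------------------------------------------
# QC


def qc_filter(
    cohort: GenotypeCohort,
    maf_min: float = 0.01,
    var_miss_max: float = 0.1,
    sample_miss_max: float = 0.1,
    hwe_p_min: float = 0.001,
) -> tuple[GenotypeCohort, QcReport]:
    """Apply standard array-QC filters, in a fixed documented order.

    Order: sample missingness -> variant missingness -> MAF -> HWE exact test.
    Defaults follow common array-QC practice: MAF >= 0.01, missingness <= 0.1
    (per variant and per sample), HWE exact P >= 0.001.
    """
    if cohort.n_variants == 0 or cohort.n_samples == 0:
        raise ValidationError("cannot QC an empty cohort")
    removed: dict[str, int] = {}

    smiss = cohort.sample_missingness()
    keep_s = smiss <= sample_miss_max
    removed["sample_missingness"] = int((~keep_s).sum())
    cur = cohort.subset_samples(np.flatnonzero(keep_s)) if removed["sample_missingness"] else cohort

    vmiss = cur.variant_missingness()
    keep_v = vmiss <= var_miss_max
    removed["variant_missingness"] = int((~keep_v).sum())
    cur = cur.subset_variants(np.flatnonzero(keep_v))

    maf = cur.maf()
    keep_v = np.nan_to_num(maf) >= maf_min
    removed["maf"] = int((~keep_v).sum())
    cur = cur.subset_variants(np.flatnonzero(keep_v))

    hwe = _hwe_pvalues(cur)
    keep_v = hwe >= hwe_p_min
    removed["hwe"] = int((~keep_v).sum())
    cur = cur.subset_variants(np.flatnonzero(keep_v))

    if cur.n_variants == 0:
        raise ValidationError("empty after QC: every variant failed a filter")
    report = QcReport(
        n_variants_in=cohort.n_variants,
        n_samples_in=cohort.n_samples,
        removed=removed,
        thresholds={
            "maf_min": maf_min,
            "var_miss_max": var_miss_max,
            "sample_miss_max": sample_miss_max,
            "hwe_p_min": hwe_p_min,
        },
    )
    return cur, report


# ---------------------------------------------------------------------------
# harmonization


def _is_ambiguous(a: str, b: str) -> bool:
    return _COMPLEMENT.get(a) == b


def harmonize(
    sumstats: SummaryStats,
    cohort: GenotypeCohort,
    drop_ambiguous: bool = True,
    match_by: str = "chrom-pos",
) -> HarmonizedWeights:
    """Align summary-statistic effect sizes to the cohort's counted alleles.

    A summary variant is retained when its allele pair matches the cohort's
    pair directly or after strand complement; the effect sign is flipped when
    the summary effect allele corresponds to the cohort's *other* allele.
    Strand-ambiguous pairs (A/T, C/G) are dropped when ``drop_ambiguous``;
    unmatched and allele-mismatched variants are dropped with counts logged.
    """
    if len(sumstats) == 0 or cohort.n_variants == 0:
        raise ValidationError("harmonize requires non-empty summary statistics and cohort")
    if match_by == "chrom-pos":
        cohort_key = {
            (v.chrom, int(v.pos)): j for j, v in enumerate(cohort.variants.itertuples(index=False))
        }
        keys = zip(sumstats.table["chrom"], sumstats.table["pos"].astype(int))
    elif match_by == "id":
        cohort_key = {v: j for j, v in enumerate(cohort.variants["id"])}
        keys = iter(sumstats.table["id"])
    else:
        raise ValueError(f"match_by must be 'chrom-pos' or 'id', got {match_by!r}")

    counted = cohort.variants["allele_counted"].str.upper().to_numpy()
    other = cohort.variants["allele_other"].str.upper().to_numpy()
    counts = {k: 0 for k in ("direct", "swapped", "strand_direct", "strand_swapped",
                             "ambiguous_dropped", "mismatched", "unmatched")}
    rows = []
    seen: set[int] = set()
    for (key, rec) in zip(keys, sumstats.table.itertuples(index=False)):
        j = cohort_key.get(key)
        if j is None or j in seen:
            counts["unmatched"] += 1
            continue
        ea, oa = rec.effect_allele, rec.other_allele
        if drop_ambiguous and _is_ambiguous(ea, oa):
            counts["ambiguous_dropped"] += 1
            continue
        ca, co = counted[j], other[j]
        cea = _COMPLEMENT.get(ea, "?")
        coa = _COMPLEMENT.get(oa, "?")
        if (ea, oa) == (ca, co):
            sign, kind = 1.0, "direct"
        elif (ea, oa) == (co, ca):
            sign, kind = -1.0, "swapped"
        elif (cea, coa) == (ca, co):
            sign, kind = 1.0, "strand_direct"
        elif (cea, coa) == (co, ca):
            sign, kind = -1.0, "strand_swapped"
        else:
            counts["mismatched"] += 1
            continue
        counts[kind] += 1
        seen.add(j)
        rows.append((j, rec.id, sign * rec.beta, rec.p))
    if not rows:
        raise ValidationError("no summary-statistic variants could be matched to the cohort")
    table = pd.DataFrame(rows, columns=["variant_index", "id", "beta_aligned", "p"])
    return HarmonizedWeights(table, counts=counts)
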