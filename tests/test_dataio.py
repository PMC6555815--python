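"""I/O round trips, QC filtering, the exact HWE test, and allele harmonization."""
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from polyscore.dataio import (
    GenotypeCohort,
    SummaryStats,
    ValidationError,
    harmonize,
    hwe_exact_p,
    qc_filter,
    read_genotype_matrix,
    read_phenotypes,
    read_summary_stats,
    write_genotypes,
)
from polyscore.score import compute_prs

from conftest import make_cohort


# ---------------------------------------------------------------------------
# genotype I/O


def test_text_dosage_transcribes_known_fixture(tmp_path):
    path = tmp_path / "g.txt"
    path.write_text("rs1 rs2 rs3\nind1 0 1 2\nind2 2 NA 1\n")
    cohort = read_genotype_matrix(path, dialect="text-dosage")
    assert cohort.sample_ids == ["ind1", "ind2"]
    assert list(cohort.variants["id"]) == ["rs1", "rs2", "rs3"]
    expected = np.array([[0, 1, 2], [2, np.nan, 1]], dtype=float)
    assert np.array_equal(cohort.dosage, expected, equal_nan=True)


@pytest.mark.parametrize("dialect", ["text-dosage", "plink-bed"])
def test_round_trip_is_lossless(random_cohort, tmp_path, dialect):
    path = tmp_path / ("g.txt" if dialect == "text-dosage" else "g.bed")
    write_genotypes(random_cohort, path, dialect=dialect)
    back = read_genotype_matrix(path, dialect=dialect)
    assert back.equals(random_cohort)


def test_cross_dialect_equality(random_cohort, tmp_path):
    write_genotypes(random_cohort, tmp_path / "g.txt", dialect="text-dosage")
    write_genotypes(random_cohort, tmp_path / "g.bed", dialect="plink-bed")
    a = read_genotype_matrix(tmp_path / "g.txt", dialect="text-dosage")
    b = read_genotype_matrix(tmp_path / "g.bed", dialect="plink-bed")
    assert np.array_equal(a.dosage, b.dosage, equal_nan=True)
    assert a.sample_ids == b.sample_ids


def test_malformed_text_names_line(tmp_path):
    path = tmp_path / "g.txt"
    path.write_text("rs1 rs2\ns1 0 1\ns2 0\n")
    with pytest.raises(Exception, match="3"):
        read_genotype_matrix(path, dialect="text-dosage")


def test_duplicate_variant_ids_rejected():
    with pytest.raises(ValidationError, match="duplicated"):
        make_cohort(np.zeros((2, 2)), ids=["rs1", "rs1"])


# ---------------------------------------------------------------------------
# summary statistics


def _write_sumstats(tmp_path, rows, header="SNP CHR BP A1 A2 OR SE P"):
    path = tmp_path / "ss.txt"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


def test_odds_ratio_one_maps_to_beta_zero(tmp_path):
    path = _write_sumstats(tmp_path, ["rs1 1 100 A G 1.0 0.1 0.5"])
    ss = read_summary_stats(path, effect_scale="odds-ratio")
    assert ss.table.loc[0, "beta"] == pytest.approx(0.0)


def test_column_mapping_canonicalizes_shuffled_columns(tmp_path):
    path = tmp_path / "ss.txt"
    path.write_text(
        "pval other eff marker bp beta_hat stderr chrom\n"
        "0.01 G A rs9 500 0.3 0.05 2\n"
        "0.20 T C rs10 900 -0.1 0.04 2\n"
    )
    ss = read_summary_stats(
        path,
        column_map={
            "id": "marker", "chrom": "chrom", "pos": "bp",
            "effect_allele": "eff", "other_allele": "other",
            "effect": "beta_hat", "se": "stderr", "p": "pval",
        },
    )
    assert list(ss.table["id"]) == ["rs9", "rs10"]
    assert ss.table.loc[0, "beta"] == pytest.approx(0.3)
    assert ss.table.loc[1, "p"] == pytest.approx(0.20)


def test_invalid_p_rows_dropped_with_count(tmp_path):
    rows = [f"rs{i} 1 {100 * (i + 1)} A G 1.1 0.1 0.5" for i in range(4)]
    rows.append("rs4 1 900 A G 1.1 0.1 0.0")
    ss = read_summary_stats(_write_sumstats(tmp_path, rows), effect_scale="odds-ratio")
    assert len(ss) == 4
    assert ss.n_rejected == 1


def test_missing_column_is_configuration_error(tmp_path):
    path = tmp_path / "ss.txt"
    path.write_text("SNP CHR BP A1 A2 P\nrs1 1 1 A G 0.5\n")
    with pytest.raises(ValidationError, match="BETA"):
        read_summary_stats(path)


# ---------------------------------------------------------------------------
# phenotypes


def test_case_control_labels_recoded(tmp_path):
    path = tmp_path / "ph.tsv"
    path.write_text("sample_id\tdiagnosis\tseverity\ns1\tcase\t80\ns2\tcontrol\t3\n")
    phen = read_phenotypes(path)
    assert list(phen.diagnosis) == [1, 0]


def test_severity_out_of_range_names_samples(tmp_path):
    path = tmp_path / "ph.tsv"
    path.write_text("sample_id\tdiagnosis\tseverity\ns1\t1\t121\ns2\t0\t5\n")
    with pytest.raises(ValidationError, match="s1"):
        read_phenotypes(path)


def test_covariates_read(tmp_path):
    lines = ["sample_id\tdiagnosis\tage\tbmi"] + [
        f"s{i}\t{i % 2}\t{30 + i}\t{22.5 + i}" for i in range(6)
    ]
    path = tmp_path / "ph.tsv"
    path.write_text("\n".join(lines) + "\n")
    phen = read_phenotypes(path)
    assert phen.covariate_names == ["age", "bmi"]
    assert phen.covariates().shape == (6, 2)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_enumeration_oracle(n_hom1, n_het, n_hom2):
    """Exact two-sided HWE P by full rational enumeration over het counts."""
    n = n_hom1 + n_het + n_hom2
    na = 2 * n_hom1 + n_het
    denom = math.comb(2 * n, na)

    def prob(h):
        if (na - h) % 2 or h > na or h > 2 * n - na:
            return Fraction(0)
        aa = (na - h) // 2
        bb = (2 * n - na - h) // 2
        ways = Fraction(math.factorial(n), math.factorial(aa) * math.factorial(h) * math.factorial(bb))
        return ways * Fraction(2) ** h / denom

    p_obs = prob(n_het)
    total = sum(p for h in range(0, min(na, 2 * n - na) + 1) if (p := prob(h)) <= p_obs)
    return float(total)


def test_hwe_monomorphic_is_one():
    assert hwe_exact_p(0, 0, 50) == 1.0


@pytest.mark.parametrize(
    "counts",
    [(5, 10, 5), (10, 0, 10), (1, 8, 21), (0, 3, 97), (30, 40, 30), (2, 2, 2)],
)
def test_hwe_matches_full_enumeration(counts):
    assert hwe_exact_p(*counts) == pytest.approx(hwe_enumeration_oracle(*counts), abs=1e-12)


def test_hwe_extreme_het_deficit_is_significant():
    assert hwe_exact_p(10, 0, 10) < 0.001


from hypothesis import assume, given, settings
from hypothesis import strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
def test_hwe_property_valid_and_exact(aa, ab, bb):
    assume(aa + ab + bb >= 1)
    p = hwe_exact_p(aa, ab, bb)
    assert 0 < p <= 1
    assert p == pytest.approx(hwe_enumeration_oracle(aa, ab, bb), abs=1e-12)


def test_hwe_random_counts_match_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(3, 100))
        aa = int(rng.integers(0, n + 1))
        ab = int(rng.integers(0, n - aa + 1))
        bb = n - aa - ab
        assert hwe_exact_p(aa, ab, bb) == pytest.approx(
            hwe_enumeration_oracle(aa, ab, bb), abs=1e-12
        )


# ---------------------------------------------------------------------------
# QC


def test_qc_defaults_are_standard_thresholds():
    import inspect

    sig = inspect.signature(qc_filter)
    assert sig.parameters["maf_min"].default == 0.01
    assert sig.parameters["var_miss_max"].default == 0.1
    assert sig.parameters["sample_miss_max"].default == 0.1
    assert sig.parameters["hwe_p_min"].default == 0.001


def test_qc_removes_monomorphic_variant():
    dosage = np.column_stack([np.zeros(20), np.tile([0, 1, 2, 1], 5)])
    cohort = make_cohort(dosage)
    out, report = qc_filter(cohort)
    assert out.n_variants == 1
    assert report.removed["maf"] == 1


def test_qc_hand_enumerated_toy():
    """Hand-checked per-variant fates under the fixed filter order
    (sample missingness -> variant missingness -> MAF -> HWE)."""
    n = 40
    cols, expect_keep = [], []
    # ten well-behaved common variants (keep per-sample missingness low)
    for _ in range(10):
        cols.append(np.tile([0, 1, 2, 1], n // 4).astype(float))
        expect_keep.append(True)
    # monomorphic -> maf 0 -> removed
    cols.append(np.zeros(n)); expect_keep.append(False)
    # rare but above threshold: one het in 40 -> maf 1/80 = 0.0125 -> kept
    rare = np.zeros(n); rare[-1] = 1
    cols.append(rare); expect_keep.append(True)
    # 13/40 = 32.5% missing (> 0.1) -> removed; no sample exceeds 1/14 missing
    missing = np.tile([0, 1, 2, 1], n // 4).astype(float); missing[:13] = np.nan
    cols.append(missing); expect_keep.append(False)
    # HWE catastrophe: balanced alleles, zero heterozygotes -> p << 0.001
    cols.append(np.repeat([0.0, 2.0], n // 2)); expect_keep.append(False)
    cohort = make_cohort(np.column_stack(cols))
    out, report = qc_filter(cohort)
    assert report.removed["sample_missingness"] == 0
    kept_ids = set(out.variants["id"])
    for j, keep in enumerate(expect_keep):
        assert (f"v{j}" in kept_ids) == keep, f"variant v{j}"
    assert report.n_variants_out == sum(expect_keep)


def test_qc_is_idempotent(random_cohort):
    once, _ = qc_filter(random_cohort)
    twice, report = qc_filter(once)
    assert twice.equals(once)
    assert all(v == 0 for v in report.removed.values())


def test_qc_counts_reconcile(random_cohort):
    out, report = qc_filter(random_cohort)
    assert report.n_variants_out == out.n_variants
    assert report.n_samples_out == out.n_samples


# ---------------------------------------------------------------------------
# harmonization


def _sumstats(rows):
    return SummaryStats(
        pd.DataFrame(rows, columns=["id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p"])
    )


def test_direct_match_keeps_sign():
    cohort = make_cohort([[0, 1], [1, 2], [2, 0]], counted="A", other="G")
    ss = _sumstats([("v0", "1", 1000, "A", "G", 0.2, 0.1, 0.5)])
    hw = harmonize(ss, cohort)
    assert hw.table.loc[0, "beta_aligned"] == pytest.approx(0.2)


def test_allele_swap_flips_sign():
    cohort = make_cohort([[0, 1], [1, 2], [2, 0]], counted="A", other="G")
    ss = _sumstats([("v0", "1", 1000, "G", "A", 0.2, 0.1, 0.5)])
    hw = harmonize(ss, cohort)
    assert hw.table.loc[0, "beta_aligned"] == pytest.approx(-0.2)


def test_harmonize_truth_table():
    counted = ["A", "A", "A", "C", "C", "A", "A", "T"]
    other =   ["G", "G", "G", "T", "T", "G", "G", "C"]
    cohort = make_cohort(
        np.tile([0.0, 1.0, 2.0], (8, 1)).T, counted=counted, other=other
    )
    rows = [
        ("v0", "1", 1000, "A", "G", 0.1, 0.1, 0.5),   # direct          +0.1
        ("v1", "1", 2000, "G", "A", 0.2, 0.1, 0.5),   # swap            -0.2
        ("v2", "1", 3000, "T", "C", 0.3, 0.1, 0.5),   # strand direct   +0.3
        ("v3", "1", 4000, "A", "G", 0.4, 0.1, 0.5),   # strand swap     -0.4
        ("v4", "1", 5000, "C", "T", 0.5, 0.1, 0.5),   # strand... C/T vs cohort C/T direct +0.5
        ("v5", "1", 6000, "A", "C", 0.6, 0.1, 0.5),   # allele pair disagrees -> dropped
        ("v7", "1", 8000, "T", "A", 0.7, 0.1, 0.5),   # ambiguous A/T at cohort T/A -> dropped
        ("vX", "1", 9999, "A", "G", 0.8, 0.1, 0.5),   # unmatched position
    ]
    hw = harmonize(_sumstats(rows), cohort)
    got = dict(zip(hw.table["id"], hw.table["beta_aligned"]))
    assert got == {
        "v0": pytest.approx(0.1),
        "v1": pytest.approx(-0.2),
        "v2": pytest.approx(0.3),
        "v3": pytest.approx(-0.4),
        "v4": pytest.approx(0.5),
    }
    assert hw.counts["ambiguous_dropped"] == 1
    assert hw.counts["mismatched"] == 1
    assert hw.counts["unmatched"] == 1


def test_harmonize_of_own_output_is_identity():
    cohort = make_cohort([[0, 1], [1, 2], [2, 0]], counted="A", other="G")
    ss = _sumstats([
        ("v0", "1", 1000, "G", "A", 0.2, 0.1, 0.5),
        ("v1", "1", 2000, "A", "G", -0.4, 0.1, 0.9),
    ])
    hw1 = harmonize(ss, cohort)
    # express hw1 back as summary statistics with effect allele = counted allele
    back = _sumstats([
        (r.id, "1", int(cohort.variants.loc[r.variant_index, "pos"]), "A", "G",
         r.beta_aligned, 0.1, r.p)
        for r in hw1.table.itertuples(index=False)
    ])
    hw2 = harmonize(back, cohort)
    pd.testing.assert_frame_equal(
        hw1.table.reset_index(drop=True), hw2.table.reset_index(drop=True)
    )


def test_score_differences_invariant_under_allele_relabeling(rng):
    """Reflecting dosages (x -> 2-x) and swapping alleles at one variant must
    leave between-individual score differences unchanged."""
    dosage = rng.binomial(2, 0.4, size=(12, 5)).astype(float)
    cohort = make_cohort(dosage)
    ss = _sumstats([
        (f"v{j}", "1", (j + 1) * 1000, "A", "G", b, 0.1, 0.3)
        for j, b in enumerate([0.5, -0.2, 0.1, 0.3, -0.4])
    ])
    base = compute_prs(cohort, harmonize(ss, cohort)).raw

    flipped = dosage.copy()
    flipped[:, 2] = 2.0 - flipped[:, 2]
    counted = ["A"] * 5
    other = ["G"] * 5
    counted[2], other[2] = "G", "A"
    cohort2 = make_cohort(flipped, counted=counted, other=other)
    reflected = compute_prs(cohort2, harmonize(ss, cohort2)).raw
    diff_base = base - base[0]
    diff_refl = reflected - reflected[0]
    assert np.allclose(diff_base, diff_refl, atol=1e-10)


def test_zero_overlap_is_error():
    cohort = make_cohort([[0, 1], [1, 2], [2, 0]])
    ss = _sumstats([("zz", "9", 1, "A", "G", 0.1, 0.1, 0.5)])
    with pytest.raises(ValidationError, match="match"):
        harmonize(ss, cohort)
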