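"""End-to-end study orchestration: QC -> prune/PCA -> harmonize -> clump ->
threshold scan -> final PRS -> evaluation (overall, per ancestry cluster, and
by score quantile).

A :class:`RunConfig` names either on-disk inputs (genotypes, summary
statistics, phenotypes) or a synthetic-study block; :func:`run_study` executes
the fixed stage order, persists every intermediate as plain text under the
output directory, and returns a :class:`StudyReport` that is bit-reproducible
for an identical (config, seed) pair.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import cluster_ibs, ibs_matrix
from .dataio import (
    GenotypeCohort,
    PhenotypeTable,
    QcReport,
    harmonize,
    qc_filter,
    read_genotype_matrix,
    read_phenotypes,
    read_summary_stats,
    write_genotypes,
    write_phenotypes,
)
from .evalstats import EvalReport, SeparationError, evaluate, pca_covariates, quantile_effects
from .ld import ClumpParams, PruneParams, clump, prune
from .score import DEFAULT_GRID, ThresholdScan, compute_prs, threshold_scan
from .simulate import SimConfig, simulate_study

__all__ = ["RunConfig", "StudyReport", "run_study"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and a remedy."""


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of ``paths`` / ``sim`` is set.

    ``paths`` keys: genotypes (+ genotype_dialect), sumstats (+ optional
    sumstat_columns / effect_scale), phenotypes.
    """

    paths: dict | None = None
    sim: SimConfig | None = None
    clump_params: ClumpParams = field(default_factory=ClumpParams)
    prune_params: PruneParams = field(default_factory=PruneParams)
    grid: tuple = DEFAULT_GRID
    q_values: tuple = (4, 5, 10)
    k_pcs: int = 5
    k_clusters: int = 4
    target_fst: float = 0.0
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.paths is None) == (self.sim is None):
            raise ValueError("exactly one of 'paths' or 'sim' must be provided")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = dict(raw)
        if "sim" in kwargs and kwargs["sim"] is not None:
            kwargs["sim"] = SimConfig(**kwargs["sim"])
        if "clump_params" in kwargs:
            kwargs["clump_params"] = ClumpParams(**kwargs["clump_params"])
        if "prune_params" in kwargs:
            kwargs["prune_params"] = PruneParams(**kwargs["prune_params"])
        for key in ("grid", "q_values"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class StudyReport:
    """Everything the pipeline computed, JSON-serializable."""

    qc: dict
    scan: dict
    best_threshold: float
    n_variants_final: int
    overall: dict
    per_cluster: list[dict]
    quantiles: list[dict]
    provenance: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True, allow_nan=True)


def _stage(name: str, hint: str):
    """Decorator-free stage wrapper: re-raise with stage context."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"stage '{name}' failed: {exc} ({hint})") from exc
            return False

    return _Ctx()


def _load_inputs(config: RunConfig, outdir: Path | None):
    if config.sim is not None:
        study = simulate_study(config.sim, target_fst=config.target_fst)
        if outdir is not None:
            write_genotypes(study.target, outdir / "target_genotypes.txt")
            write_phenotypes(study.target_phen, outdir / "target_phenotypes.tsv")
            study.sumstats.table.to_csv(outdir / "discovery_sumstats.tsv", sep="\t", index=False)
        return study.target, study.sumstats, study.target_phen
    p = config.paths
    cohort = read_genotype_matrix(p["genotypes"], dialect=p.get("genotype_dialect", "text-dosage"))
    sumstats = read_summary_stats(
        p["sumstats"],
        column_map=p.get("sumstat_columns"),
        effect_scale=p.get("effect_scale", "beta"),
    )
    phen = read_phenotypes(p["phenotypes"], id_col=p.get("id_col", "sample_id"))
    return cohort, sumstats, phen


def _cluster_reports(cohort, phen, z, covars, labels, k) -> list[dict]:
    out = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        entry: dict = {"cluster": c, "n": int(members.size)}
        if members.size < 10 or len(set(phen.diagnosis[members])) < 2:
            entry["note"] = "too small or single-class; metrics skipped"
            out.append(entry)
            continue
        zc = z[members]
        sd = zc.std(ddof=1)
        zc = (zc - zc.mean()) / sd if sd > 0 else zc * 0.0
        sub_phen = PhenotypeTable(phen.table.iloc[members])
        sub_cov = covars[members] if covars is not None and covars.size else None
        try:
            rep = evaluate(zc, sub_phen, sub_cov)
            entry.update(rep.to_dict())
        except (SeparationError, ValueError, np.linalg.LinAlgError) as exc:
            entry["note"] = f"evaluation failed: {exc}"
        out.append(entry)
    return out


def run_study(config: RunConfig) -> StudyReport:
    """Run the full scoring study; see module docstring for stage order."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    with _stage("load", "check input paths / simulate block"):
        cohort, sumstats, phen = _load_inputs(config, outdir)
        phen = phen.reindex(cohort.sample_ids)

    with _stage("qc", "inspect QC thresholds; inputs may be too sparse"):
        cohort, qc_report = qc_filter(cohort)

    with _stage("prune+pca", "reduce k_pcs if the cohort is small"):
        pruned = prune(cohort, config.prune_params)
        covars = pca_covariates(cohort, k=config.k_pcs, snp_set=pruned)

    with _stage("cluster", "reduce k_clusters for small cohorts"):
        sim = ibs_matrix(cohort, snp_set=pruned)
        labels = cluster_ibs(sim, k=min(config.k_clusters, cohort.n_samples))

    with _stage("harmonize", "check allele columns and build coordinates"):
        weights = harmonize(sumstats, cohort)

    with _stage("clump", "check that positions/chromosomes are populated"):
        pmap = np.ones(cohort.n_variants)
        pmap[weights.table["variant_index"].to_numpy()] = weights.table["p"].to_numpy()
        clumped = clump(cohort, pmap, config.clump_params)
        # only variants that actually carry a weight can enter the score
        weighted = set(weights.table["variant_index"])
        clumped = np.array([j for j in clumped if j in weighted], dtype=int)

    with _stage("threshold-scan", "widen the grid or check phenotype coding"):
        scan: ThresholdScan = threshold_scan(
            cohort, weights, phen, covars, grid=config.grid, snp_set=clumped
        )

    with _stage("score", "empty SNP set at the chosen threshold"):
        final = compute_prs(cohort, weights, snp_set=clumped, threshold=scan.best_threshold)

    with _stage("evaluate", "separation or degenerate outcome"):
        overall = evaluate(final.z, phen, covars).to_dict()
        per_cluster = _cluster_reports(
            cohort, phen, final.z, covars, labels, int(labels.max()) + 1
        )
        quantiles = []
        for q in config.q_values:
            for outcome in ("diagnosis", "severity"):
                if outcome == "severity" and phen.severity is None:
                    continue
                try:
                    qc_ = quantile_effects(final.z, phen, covars, q=q, outcome=outcome)
                    quantiles.append(
                        {"q": q, "outcome": outcome, "table": qc_.table.to_dict("records")}
                    )
                except (SeparationError, ValueError) as exc:
                    quantiles.append({"q": q, "outcome": outcome, "error": str(exc)})

    report = StudyReport(
        qc={
            "n_variants_in": qc_report.n_variants_in,
            "n_samples_in": qc_report.n_samples_in,
            "removed": qc_report.removed,
            "thresholds": qc_report.thresholds,
            "order": list(qc_report.order),
        },
        scan=scan.table.to_dict("records"),
        best_threshold=scan.best_threshold,
        n_variants_final=final.n_variants,
        overall=overall,
        per_cluster=per_cluster,
        quantiles=quantiles,
        provenance={
            "polyscore_version": __version__,
            "seed": config.seed,
            "sim": None if config.sim is None else asdict(config.sim),
            "paths": config.paths,
            "clump_params": asdict(config.clump_params),
            "prune_params": asdict(config.prune_params),
            "grid": list(config.grid),
            "k_pcs": config.k_pcs,
            "k_clusters": config.k_clusters,
            "target_fst": config.target_fst,
        },
    )
    if outdir is not None:
        final.to_frame().to_csv(outdir / "scores.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"sample_id": cohort.sample_ids, "cluster": labels}
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        pd.DataFrame(scan.table).to_csv(outdir / "threshold_scan.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(report.to_json())
    return report
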