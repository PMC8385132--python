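"""End-to-end orchestration: colocalization -> DE -> meta -> GSEA ->
NEMG correlation -> count enrichment, with TSV reports.

The stages can run from an in-memory :class:`~ldcoloc.synthetic_data.Scenario`
(tests, acceptance) or from a YAML config pointing at the TSV/GMT inputs on
disk (CLI).  Reports mirror the analysis tables: a cis-NEMG listing with the
supporting locus and eQTL positions, a GSEA matrix over tissues and
comparisons, a count-enrichment matrix with both permutation nulls, and the
correlation-regression scatter data.  Every run records its seed; re-running
with the same config and seed reproduces the reports byte for byte.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import colocalization as coloc
from . import diffexpr, gsea, meta, nemg_correlation, set_enrichment
from .colocalization import ThresholdConfig
from .genetic_map import read_map_table
from .synthetic_data import Scenario

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_all",
    "run_scenario",
    "summarize",
    "summarize_counts",
    "truth_score",
]


@dataclass
class PipelineConfig:
    """Paths and settings for a file-based run."""

    map_path: str
    estimates_path: str
    annotation_path: str
    out_dir: str
    probe_map_path: str | None = None
    nemg_path: str | None = None
    sets_path: str | None = None
    expression_dir: str | None = None
    studies: list = field(default_factory=list)  # {study_id, tissue, family_history?}
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    n_perm: int = 10_000
    seed: int = 0
    n_random_nemg_sets: int = 3

    @classmethod
    def from_yaml(cls, path: str, out_dir: str | None = None, seed: int | None = None):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = ThresholdConfig(**raw.pop("thresholds", {}))
        if out_dir is not None:
            raw["out_dir"] = out_dir
        if seed is not None:
            raw["seed"] = seed
        return cls(thresholds=thr, **raw)


@dataclass
class PipelineResult:
    loci: list
    t2d_eqtls: list
    calls: list
    exclusions: list
    summary: dict
    study_tables: dict = field(default_factory=dict)
    meta_tables: dict = field(default_factory=dict)
    gsea_table: pd.DataFrame | None = None
    correlation_records: list = field(default_factory=list)
    correlation_fit: object = None
    enrichment: list = field(default_factory=list)
    log: list = field(default_factory=list)
    skipped: list = field(default_factory=list)


def summarize_counts(
    n_cis_genes: int,
    n_loci_with_calls: int,
    n_cis_nemgs: int = 0,
    n_european_specific: int = 0,
    n_cosmopolitan: int = 0,
) -> dict:
    """Derived summary statistics, 1-d.p. where the convention is percent/ratio.

    Safe on empty runs (zero counts give zeros, never a division error).
    """
    return {
        "n_cis_genes": n_cis_genes,
        "n_loci_with_calls": n_loci_with_calls,
        "n_cis_nemgs": n_cis_nemgs,
        "genes_per_locus": round(n_cis_genes / n_loci_with_calls, 1)
        if n_loci_with_calls
        else 0.0,
        "nemg_percent": round(100.0 * n_cis_nemgs / n_cis_genes, 1) if n_cis_genes else 0.0,
        "n_european_specific_loci": n_european_specific,
        "n_cosmopolitan_loci": n_cosmopolitan,
    }


def summarize(calls: list, loci: list) -> dict:
    """Summary statistics for one run's calls and loci."""
    called_loci = {id(locus) for c in calls for locus in c.loci}
    loci_with_calls = [lc for lc in loci if id(lc) in called_loci]
    return summarize_counts(
        n_cis_genes=len(calls),
        n_loci_with_calls=len(loci_with_calls),
        n_cis_nemgs=sum(c.nemg for c in calls),
        n_european_specific=sum(not lc.cosmopolitan for lc in loci_with_calls),
        n_cosmopolitan=sum(lc.cosmopolitan for lc in loci_with_calls),
    )


# ---------------------------------------------------------------------------


def _colocalize(scn, thresholds, res: PipelineResult):
    res.loci = coloc.replicate_loci(
        scn.estimates, scn.maps, thresholds, exclusions=res.exclusions
    )
    res.t2d_eqtls = coloc.call_t2d_eqtl(
        res.loci, scn.estimates, scn.maps, thresholds, exclusions=res.exclusions
    )
    res.calls = coloc.assign_cis_genes(
        res.t2d_eqtls, scn.annotation, scn.probe_map, thresholds, exclusions=res.exclusions
    )
    if scn.nemg:
        coloc.flag_nemg(res.calls, set(scn.nemg))
    res.log.append(
        f"colocalization: {len(res.loci)} loci, {len(res.t2d_eqtls)} locus-eQTL pairs, "
        f"{len(res.calls)} cis-genes ({sum(c.nemg for c in res.calls)} NEMG), "
        f"{len(res.exclusions)} exclusions"
    )


def _differential_expression(scn, res: PipelineResult):
    studies = list(scn.studies)
    if scn.fh_study is not None:
        studies.append(scn.fh_study)
    tissue_of = {}
    for study in studies:
        fh = study is scn.fh_study
        res.study_tables[study.study_id] = diffexpr.study_zscores(study, family_history=fh)
        # the family-history study is its own "tissue" for meta purposes
        tissue_of[study.study_id] = f"{study.tissue}_fh" if fh else study.tissue
    res.meta_tables = meta.meta_by_tissue(res.study_tables, tissue_of)
    res.log.append(
        f"diffexpr/meta: {len(studies)} studies -> {len(res.meta_tables)} tissues"
    )


def _gsea(scn, res: PipelineResult, n_perm: int, seed: int, n_random_sets: int):
    cis = [c.gene for c in res.calls]
    cis_nemg = [c.gene for c in res.calls if c.nemg]
    nemg = set(scn.nemg)
    comparisons = []
    if len(cis) >= 2:
        comparisons.append(("A_cis_vs_genome", gsea.GeneSet("cis_genes", cis), None))
    if len(cis_nemg) >= 2:
        comparisons.append(("B_cisnemg_vs_genome", gsea.GeneSet("cis_nemgs", cis_nemg), None))
        comparisons.append(("C_cisnemg_vs_nemg", gsea.GeneSet("cis_nemgs", cis_nemg), nemg))
        non_cis_nemg = sorted(nemg - set(cis))
        rng = np.random.default_rng(np.random.SeedSequence([seed, 915]))
        for i in range(n_random_sets):
            if len(non_cis_nemg) >= len(cis_nemg):
                rand = rng.choice(non_cis_nemg, size=len(cis_nemg), replace=False)
                comparisons.append(
                    (f"D_random_nemg_{i + 1}", gsea.GeneSet(f"random_nemg_{i + 1}", rand), nemg)
                )
    res.gsea_table = gsea.gsea_battery(res.meta_tables, comparisons, n_perm=n_perm, seed=seed)
    res.log.append(f"gsea: {len(comparisons)} comparisons x {len(res.meta_tables)} tissues")


def _correlation(scn, res: PipelineResult):
    cis_nemg = [c.gene for c in res.calls if c.nemg]
    non_cis = sorted(set(scn.nemg) - {c.gene for c in res.calls})
    adipose = [s for s in scn.studies if s.tissue == "adipose"]
    if not adipose or "adipose" not in res.meta_tables or len(cis_nemg) < 2:
        res.skipped.append("nemg_correlation")
        return
    # the adipose study with the most controls supplies the baseline matrix
    study = max(adipose, key=lambda s: int((s.phenotype == 0).sum()))
    controls = study.phenotype.index[study.phenotype == 0]
    tbl = res.meta_tables["adipose"]
    z = pd.Series(tbl["z_meta"].to_numpy(), index=tbl["gene"])
    res.correlation_records = nemg_correlation.mean_correlation_profile(
        study.expression[controls], study.probe_map, cis_nemg, non_cis, z
    )
    if len(res.correlation_records) >= 10:
        res.correlation_fit = nemg_correlation.correlation_de_regression(
            res.correlation_records, robust=True
        )
        res.log.append(
            f"nemg_correlation: {len(res.correlation_records)} non-cis NEMGs, "
            f"robust slope {res.correlation_fit.slope:.3f} "
            f"(p={res.correlation_fit.p_value:.2e}, "
            f"{res.correlation_fit.n_outliers_removed} outliers)"
        )
    else:
        res.skipped.append("nemg_correlation_fit")


def _enrichment(scn, res: PipelineResult, n_perm: int, seed: int):
    if not scn.sets or not res.calls:
        res.skipped.append("set_enrichment")
        return
    sets = scn.sets
    if scn.nemg:
        sets = set_enrichment.curate_mito_sets(sets, scn.nemg, min_overlap=0.0)
    cis = [c.gene for c in res.calls]
    locus_sizes = _locus_size_multiset(res.calls)
    res.enrichment = set_enrichment.count_enrichment(
        cis, sets, scn.annotation, locus_sizes, n_perm=n_perm, seed=seed
    )
    res.log.append(f"set_enrichment: {len(sets)} sets, {n_perm} permutations")


def _locus_size_multiset(calls: list) -> list:
    """Observed per-locus cis-gene counts (a gene counts toward each locus)."""
    sizes: dict[int, int] = {}
    for c in calls:
        for locus in c.loci:
            sizes[id(locus)] = sizes.get(id(locus), 0) + 1
    return sorted(sizes.values()) or [len(calls)]


def run_scenario(
    scn: Scenario,
    thresholds: ThresholdConfig = ThresholdConfig(),
    n_perm: int = 10_000,
    seed: int = 0,
    out_dir: str | None = None,
    n_random_nemg_sets: int = 3,
    stages: tuple = ("coloc", "de", "gsea", "correlate", "enrich"),
) -> PipelineResult:
    """Run the pipeline stages on an in-memory input bundle."""
    res = PipelineResult(loci=[], t2d_eqtls=[], calls=[], exclusions=[], summary={})
    res.log.append(f"seed={seed} n_perm={n_perm} thresholds={thresholds}")
    _colocalize(scn, thresholds, res)
    if "de" in stages and scn.studies:
        _differential_expression(scn, res)
        if "gsea" in stages:
            _gsea(scn, res, n_perm, seed, n_random_nemg_sets)
        if "correlate" in stages:
            _correlation(scn, res)
    else:
        res.skipped.extend(["diffexpr", "meta", "gsea", "nemg_correlation"])
        res.log.append("stages skipped: no expression studies supplied")
    if "enrich" in stages:
        _enrichment(scn, res, n_perm, seed)
    res.summary = summarize(res.calls, res.loci)
    if scn.truth is not None:
        scores = truth_score(res, scn)
        res.log.append(
            "truth: " + " ".join(f"{k}={v:.3f}" for k, v in scores.items())
        )
    if out_dir is not None:
        write_reports(res, out_dir)
    return res


# ---------------------------------------------------------------------------
# reports


def calls_frame(calls: list) -> pd.DataFrame:
    """Cis-gene listing with locus and eQTL positions (Table-1 style)."""
    rows = []
    for c in sorted(calls, key=lambda c: c.gene):
        for s in c.supporting:
            rows.append(
                {
                    "gene": c.gene,
                    "symbol": c.symbol,
                    "nemg": int(c.nemg),
                    "chrom": s.locus.chromosome,
                    "locus_id": s.locus.locus_id,
                    "locus_pos_bp": int(s.locus.position),
                    "locus_tier": s.locus.tier,
                    "cosmopolitan": int(s.locus.cosmopolitan),
                    "eqtl_pos_bp": int(s.eqtl.position),
                    "eqtl_p": s.eqtl.p_value,
                    "ldu_distance": round(s.ldu_distance, 4),
                    "n_loci": c.n_loci,
                }
            )
    return pd.DataFrame(rows)


def loci_frame(loci: list) -> pd.DataFrame:
    rows = []
    for lc in loci:
        rows.append(
            {
                "locus_id": lc.locus_id,
                "chrom": lc.chromosome,
                "pos_bp": int(lc.position),
                "n_members": len(lc.members),
                "cohorts": ",".join(sorted({m.cohort for m in lc.members})),
                "cosmopolitan": int(lc.cosmopolitan),
                "tier": lc.tier,
                "min_p": min(m.p_value for m in lc.members),
            }
        )
    return pd.DataFrame(rows)


def write_reports(res: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)

    def _w(df: pd.DataFrame, name: str):
        df.to_csv(os.path.join(out_dir, name), sep="\t", index=False, float_format="%.6g")

    _w(loci_frame(res.loci), "loci.tsv")
    _w(calls_frame(res.calls), "cis_genes.tsv")
    _w(
        pd.DataFrame(
            [(e.kind, e.identifier, e.reason) for e in res.exclusions],
            columns=["kind", "identifier", "reason"],
        ),
        "exclusions.tsv",
    )
    for sid, table in res.study_tables.items():
        _w(table, f"zscores_{sid}.tsv")
    for tissue, table in res.meta_tables.items():
        _w(table, f"meta_{tissue}.tsv")
    if res.gsea_table is not None and len(res.gsea_table):
        _w(res.gsea_table, "gsea.tsv")
    if res.correlation_records:
        _w(nemg_correlation.records_frame(res.correlation_records), "correlation_scatter.tsv")
    if res.correlation_fit is not None:
        f = res.correlation_fit
        _w(
            pd.DataFrame(
                [
                    {
                        "slope": f.slope,
                        "intercept": f.intercept,
                        "expr_coef": f.expr_coef,
                        "p_value": f.p_value,
                        "n_used": f.n_used,
                        "n_outliers_removed": f.n_outliers_removed,
                        "method": f.method,
                    }
                ]
            ),
            "correlation_fit.tsv",
        )
    if res.enrichment:
        _w(set_enrichment.enrichment_frame(res.enrichment), "enrichment.tsv")
    _w(pd.DataFrame([res.summary]), "summary.tsv")
    with open(os.path.join(out_dir, "run.log"), "w") as fh:
        for line in res.log:
            fh.write(line + "\n")
        if res.skipped:
            fh.write("stages skipped: " + ", ".join(res.skipped) + "\n")


# ---------------------------------------------------------------------------
# file-based entry point


def _load_scenario(config: PipelineConfig) -> Scenario:
    maps = read_map_table(config.map_path)
    estimates = coloc.read_estimates(config.estimates_path)
    annotation = pd.read_csv(config.annotation_path, sep="\t", dtype={"chrom": str})
    probe_map = (
        pd.read_csv(config.probe_map_path, sep="\t", dtype=str)
        if config.probe_map_path
        else pd.DataFrame(columns=["probe", "gene"])
    )
    nemg = []
    if config.nemg_path:
        with open(config.nemg_path) as fh:
            nemg = [line.strip() for line in fh if line.strip()]
    sets = gsea.read_gmt(config.sets_path) if config.sets_path else []
    studies, fh_study = [], None
    for spec in config.studies:
        study = diffexpr.read_expression_study(
            study_id=spec["study_id"],
            tissue=spec["tissue"],
            expression_path=os.path.join(
                config.expression_dir, f"{spec['study_id']}_expression.tsv"
            ),
            phenotype_path=os.path.join(
                config.expression_dir, f"{spec['study_id']}_phenotype.tsv"
            ),
            probe_map_path=config.probe_map_path,
        )
        if spec.get("family_history"):
            fh_study = study
        else:
            studies.append(study)
    return Scenario(
        cfg=None,
        maps=maps,
        estimates=estimates,
        annotation=annotation,
        probe_map=probe_map,
        studies=studies,
        fh_study=fh_study,
        nemg=nemg,
        sets=sets,
        truth=None,
    )


def run_all(config: PipelineConfig) -> PipelineResult:
    """Load every input named in the config and run all runnable stages.

    Missing optional inputs (expression studies, gene sets) skip their stages
    with an explicit log entry rather than aborting the run.
    """
    scn = _load_scenario(config)
    return run_scenario(
        scn,
        thresholds=config.thresholds,
        n_perm=config.n_perm,
        seed=config.seed,
        out_dir=config.out_dir,
        n_random_nemg_sets=config.n_random_nemg_sets,
    )


def truth_score(res: PipelineResult, scn: Scenario):
    """Sensitivity/false-fraction of loci and cis-gene calls vs ground truth."""
    if scn.truth is None:
        return None
    truth = scn.truth
    recovered = 0
    for _, t in truth.loci.iterrows():
        for lc in res.loci:
            if lc.chromosome == t["chrom"] and abs(
                scn.maps[lc.chromosome].ldu_at(lc.position) - t["ldu"]
            ) <= 1.0:
                recovered += 1
                break
    false_loci = len(res.loci) - recovered if len(res.loci) > recovered else 0
    called = {c.gene for c in res.calls}
    true_cis = set(truth.cis_genes)
    return {
        "locus_sensitivity": recovered / len(truth.loci) if len(truth.loci) else math.nan,
        "locus_false_fraction": false_loci / len(res.loci) if res.loci else 0.0,
        "cis_gene_sensitivity": len(called & true_cis) / len(true_cis)
        if true_cis
        else math.nan,
        "cis_gene_false_fraction": len(called - true_cis) / len(called) if called else 0.0,
    }
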