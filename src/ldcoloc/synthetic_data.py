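"""Seeded generators for every input the pipeline consumes.

The generators emulate, at desk scale, the data the pipeline was designed
for: block/step LDU genetic maps, per-cohort disease location estimates with
planted replicated loci plus single-cohort decoys, adipose-style eQTL
estimates for planted cis-genes, RMA-like log2 expression studies with a
shared co-expression factor among NEMGs and planted case effects, gene
annotation, a NEMG reference list, and GMT pathway sets with planted
enrichment among the cis-genes.  Every scenario carries a ground-truth
manifest sufficient to score the sensitivity and specificity of each stage.

All randomness flows from one seed through named ``SeedSequence`` spawns, so
a scenario is byte-identical across runs at a fixed seed.

Default scale (three 30-Mb chromosomes, ~630 genes, 20 true loci, three
cohorts, two studies per tissue at n = 30) is deliberately small: big enough
for the calibration and recovery suites, small enough to run on a laptop.
What the generator does *not* emulate: realistic LD-map estimation noise,
probe cross-hybridisation, batch effects, and non-Gaussian expression tails.
"""

from __future__ import annotations

import hashlib
import os
import shutil
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colocalization import LocationEstimate, write_estimates
from .diffexpr import ExpressionStudy
from .genetic_map import GeneticMap, write_map_table
from .gsea import GeneSet, write_gmt

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "Scenario",
    "simulate_map",
    "simulate_estimates",
    "simulate_expression",
    "simulate_gene_sets",
    "generate_scenario",
    "make_scenario",
]

_COHORTS = (("GWAS-E", "EUR"), ("metabo-E", "EUR"), ("GWAS-A", "AA"))
_STUDIES = (("adipose", 2), ("muscle", 2), ("liver", 2), ("pancreas", 2))


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of the synthetic study, with desk-scale defaults."""

    seed: int = 0
    # genome & maps
    n_chromosomes: int = 3
    chrom_length_bp: float = 30e6
    block_mean_kb: float = 50.0  # mean flat-block length
    step_mean_ldu: float = 0.8  # mean LDU jump per step
    step_span_bp: float = 2_000.0  # physical width of a step
    # disease estimates
    cohorts: tuple = _COHORTS
    n_true_loci: int = 20
    jitter_ldu: float = 0.2  # sd of per-cohort location error, LDU
    n_decoys: int = 20  # isolated single-cohort estimates
    decoy_min_ldu: float = 3.0  # min LDU from any true locus
    cosmopolitan_fraction: float = 0.65  # loci replicated in the AA cohort too
    # genes & eQTL
    genes_per_mb: float = 7.0
    gene_span_bp: float = 20_000.0
    cis_genes_per_locus: int = 2
    eqtl_max_ldu: float = 0.8  # planted eQTL distance from locus
    n_noncis_eqtl: int = 60  # decoy eQTL: far away, or non-significant
    nemg_fraction: float = 0.25
    # expression model
    studies: tuple = _STUDIES
    samples_per_study: int = 30
    fh_group_sizes: tuple = (10, 15, 10)  # 0/1/2 affected parents
    probes_per_gene_max: int = 3
    baseline_mean: float = 8.0  # RMA-like log2 scale
    baseline_sd: float = 1.5
    gene_sd: float = 0.6  # biological sd of a gene score
    probe_offset_sd: float = 0.3
    probe_noise_sd: float = 0.3
    cis_effect_mean: float = -0.5  # planted case shift (log2) for cis genes
    cis_effect_sd: float = 0.15
    fh_effect_ratio: float = 0.5  # dosage effect = ratio * case effect
    nemg_loading_range: tuple = (0.2, 0.8)  # shared-factor loading per NEMG
    factor_case_shift: float = -0.4  # case shift of the NEMG factor itself
    age_effect: float = 0.005  # log2 per year
    bmi_effect: float = 0.01  # log2 per kg/m^2
    case_age_shift: float = 3.0  # confounding: cases older/heavier
    case_bmi_shift: float = 2.0
    # pathway sets
    n_sets: int = 12
    set_size: int = 30
    n_enriched_sets: int = 3
    enrichment_factor: float = 4.0

    def __post_init__(self):
        if self.jitter_ldu < 0:
            raise ValueError("jitter_ldu must be >= 0")
        lo, hi = self.nemg_loading_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("nemg_loading_range must lie within [0, 1]")
        for name in ("n_chromosomes", "n_true_loci", "samples_per_study", "probes_per_gene_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """What was planted, for scoring every stage."""

    loci: pd.DataFrame  # chrom, pos_bp, ldu
    cis_genes: list
    de_effects: dict  # gene -> planted case shift (log2)
    nemg: list
    enriched_sets: list
    locus_sizes: list  # per-locus planted cis-gene counts


@dataclass
class Scenario:
    """A full in-memory input bundle plus its ground truth."""

    cfg: ScenarioConfig
    maps: dict
    estimates: list
    annotation: pd.DataFrame
    probe_map: pd.DataFrame
    studies: list = field(default_factory=list)  # ExpressionStudy
    fh_study: ExpressionStudy | None = None
    nemg: list = field(default_factory=list)
    sets: list = field(default_factory=list)
    truth: GroundTruth | None = None

    @property
    def tissue_of(self) -> dict:
        return {s.study_id: s.tissue for s in self.studies}


# ---------------------------------------------------------------------------
# maps


def simulate_map(cfg: ScenarioConfig, chromosome: str, rng) -> GeneticMap:
    """One block/step map: flat LD blocks separated by short steep steps."""
    positions = [1.0]
    ldu = [0.0]
    pos, cum = 1.0, 0.0
    while pos < cfg.chrom_length_bp:
        block = max(5_000.0, rng.exponential(cfg.block_mean_kb * 1e3))
        pos = min(pos + block, cfg.chrom_length_bp)
        positions.append(pos)
        ldu.append(cum)  # flat block
        if pos >= cfg.chrom_length_bp:
            break
        jump = rng.exponential(cfg.step_mean_ldu)
        pos = min(pos + cfg.step_span_bp, cfg.chrom_length_bp)
        cum += jump
        positions.append(pos)
        ldu.append(cum)
    return GeneticMap(chromosome, positions, ldu)


def _simulate_maps(cfg: ScenarioConfig, rng) -> dict:
    return {
        str(c + 1): simulate_map(cfg, str(c + 1), rng) for c in range(cfg.n_chromosomes)
    }


# ---------------------------------------------------------------------------
# annotation


def _simulate_annotation(cfg: ScenarioConfig, rng) -> pd.DataFrame:
    rows = []
    gid = 0
    for c in range(cfg.n_chromosomes):
        chrom = str(c + 1)
        n_genes = int(round(cfg.genes_per_mb * cfg.chrom_length_bp / 1e6))
        starts = np.sort(rng.uniform(1e4, cfg.chrom_length_bp - 1e5, size=n_genes))
        spans = rng.exponential(cfg.gene_span_bp, size=n_genes) + 1_000
        for s, w in zip(starts, spans):
            gid += 1
            gene = f"G{gid:05d}"
            rows.append((chrom, int(s), int(min(s + w, cfg.chrom_length_bp)), gene, gene))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "hgnc"])


# ---------------------------------------------------------------------------
# location estimates


def _ldu_to_bp(gmap: GeneticMap, ldu: float) -> float:
    target = min(max(ldu, gmap.cum_ldu[0]), gmap.cum_ldu[-1])
    return gmap._bp_at_ldu_left(target)


def simulate_estimates(
    cfg: ScenarioConfig, maps: dict, annotation: pd.DataFrame, rng
) -> tuple[list, GroundTruth]:
    """Disease and eQTL location estimates with planted truth.

    True loci are placed in LDU with pairwise separation > 2 x decoy_min_ldu
    so that clusters never merge; each cohort contributes an estimate at
    truth + N(0, jitter) LDU.  Decoys are isolated single-cohort estimates.
    Cis-gene eQTL sit within ``eqtl_max_ldu`` of their locus; decoy eQTL are
    either genetically distant or non-significant.
    """
    chroms = sorted(maps, key=lambda c: (len(c), c))
    estimates: list[LocationEstimate] = []
    loci_rows = []
    cis_genes: list[str] = []
    locus_sizes: list[int] = []

    # spread true loci across chromosomes, well separated in LDU
    per_chrom = np.array_split(np.arange(cfg.n_true_loci), len(chroms))
    margin = 1.5
    for chrom, idx in zip(chroms, per_chrom):
        gmap = maps[chrom]
        n = len(idx)
        if n == 0:
            continue
        lo, hi = margin, gmap.total_ldu - margin
        sep = cfg.decoy_min_ldu + 4 * cfg.jitter_ldu + 2.0
        ldu_positions = lo + np.arange(n) * sep + rng.uniform(0, sep * 0.3, size=n)
        ldu_positions = ldu_positions[ldu_positions < hi]
        for ldu_c in ldu_positions:
            pos = _ldu_to_bp(gmap, ldu_c)
            loci_rows.append((chrom, pos, float(ldu_c)))
            europeans = [c for c in cfg.cohorts if c[1] != "AA"]
            africans = [c for c in cfg.cohorts if c[1] == "AA"]
            cohort_subset = list(europeans)
            if africans and rng.random() < cfg.cosmopolitan_fraction:
                cohort_subset += africans
            for cohort, population in cohort_subset:
                jit = rng.normal(0.0, cfg.jitter_ldu)
                est_pos = _ldu_to_bp(gmap, ldu_c + jit)
                logp = rng.uniform(4.0, 8.0)  # nominal..bonferroni tiers
                estimates.append(
                    LocationEstimate(
                        trait="disease",
                        cohort=cohort,
                        population=population,
                        chromosome=chrom,
                        position=est_pos,
                        p_value=10.0 ** (-logp),
                    )
                )
    truth_loci = pd.DataFrame(loci_rows, columns=["chrom", "pos_bp", "ldu"])

    # decoys: isolated, single-cohort
    n_placed = 0
    attempts = 0
    while n_placed < cfg.n_decoys and attempts < cfg.n_decoys * 50:
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        gmap = maps[chrom]
        ldu_c = rng.uniform(0.5, gmap.total_ldu - 0.5)
        truth_here = truth_loci.loc[truth_loci["chrom"] == chrom, "ldu"]
        occupied = list(truth_here) + [
            maps[e.chromosome].ldu_at(e.position)
            for e in estimates
            if e.chromosome == chrom
        ]
        if occupied and min(abs(ldu_c - o) for o in occupied) < cfg.decoy_min_ldu:
            continue
        cohort, population = cfg.cohorts[rng.integers(len(cfg.cohorts))]
        estimates.append(
            LocationEstimate(
                trait="disease",
                cohort=cohort,
                population=population,
                chromosome=chrom,
                position=_ldu_to_bp(gmap, ldu_c),
                p_value=10.0 ** (-rng.uniform(3.1, 6.0)),
            )
        )
        n_placed += 1

    # planted cis-genes and their eQTL
    ann_by_chrom = {c: g for c, g in annotation.groupby("chrom")}
    for chrom, pos, ldu_c in loci_rows:
        gmap = maps[chrom]
        genes = ann_by_chrom.get(chrom)
        window = genes[
            (genes["start"] - 1.5e6 <= pos) & (genes["end"] + 1.5e6 >= pos)
        ]
        pick = window.loc[~window["gene_id"].isin(cis_genes)]
        k = min(cfg.cis_genes_per_locus, len(pick))
        chosen = pick.sample(n=k, random_state=rng.integers(2**31)) if k else pick
        locus_sizes.append(len(chosen))
        for gene in chosen["gene_id"]:
            cis_genes.append(gene)
            offset = rng.uniform(-cfg.eqtl_max_ldu, cfg.eqtl_max_ldu)
            estimates.append(
                LocationEstimate(
                    trait="expression",
                    cohort="MuTHER",
                    population="EUR",
                    chromosome=chrom,
                    position=_ldu_to_bp(gmap, ldu_c + offset),
                    p_value=10.0 ** (-rng.uniform(1.5, 6.0)),
                    target=gene,
                )
            )

    # decoy eQTL for non-cis genes
    non_cis = annotation.loc[~annotation["gene_id"].isin(cis_genes)]
    decoy_genes = non_cis.sample(
        n=min(cfg.n_noncis_eqtl, len(non_cis)), random_state=int(rng.integers(2**31))
    )
    for row in decoy_genes.itertuples(index=False):
        gmap = maps[row.chrom]
        truth_here = truth_loci.loc[truth_loci["chrom"] == row.chrom, "ldu"].to_numpy()
        if rng.random() < 0.5 and len(truth_here):
            # genetically distant but possibly significant
            for _ in range(50):
                ldu_c = rng.uniform(0.2, gmap.total_ldu - 0.2)
                if len(truth_here) == 0 or np.min(np.abs(truth_here - ldu_c)) > 2.0:
                    break
            p = 10.0 ** (-rng.uniform(1.4, 4.0))
        else:
            # physically anywhere but non-significant
            ldu_c = rng.uniform(0.2, gmap.total_ldu - 0.2)
            p = rng.uniform(0.05, 1.0)
        estimates.append(
            LocationEstimate(
                trait="expression",
                cohort="MuTHER",
                population="EUR",
                chromosome=row.chrom,
                position=_ldu_to_bp(gmap, ldu_c),
                p_value=float(p),
                target=row.gene_id,
            )
        )

    nemg_mask = rng.random(len(annotation)) < cfg.nemg_fraction
    nemg = annotation.loc[nemg_mask, "gene_id"].tolist()
    truth = GroundTruth(
        loci=truth_loci,
        cis_genes=cis_genes,
        de_effects={},
        nemg=nemg,
        enriched_sets=[],
        locus_sizes=locus_sizes,
    )
    return estimates, truth


# ---------------------------------------------------------------------------
# expression


def _simulate_probe_map(cfg: ScenarioConfig, annotation: pd.DataFrame, rng) -> pd.DataFrame:
    rows = []
    pid = 0
    for gene in annotation["gene_id"]:
        for _ in range(int(rng.integers(1, cfg.probes_per_gene_max + 1))):
            pid += 1
            rows.append((f"P{pid:06d}", gene))
    return pd.DataFrame(rows, columns=["probe", "gene"])


def _study_matrix(cfg, annotation, probe_map, loadings, de_effects, phenotype, dosage, rng):
    """Probe x sample matrix for one study.

    Gene score = baseline + gene_sd * (lambda * F + sqrt(1-lambda^2) * eps)
    + covariate effects + planted case (or dosage) shift; the NEMG factor F
    itself shifts in cases, so a gene's induced case effect is proportional
    to its loading.  Probe value = gene score + probe offset + noise.
    """
    genes = annotation["gene_id"].to_numpy()
    n_samples = len(phenotype)
    case = phenotype if dosage is None else (dosage > 0).astype(float)
    age = rng.normal(50.0, 8.0, n_samples) + cfg.case_age_shift * case
    bmi = rng.normal(30.0, 4.0, n_samples) + cfg.case_bmi_shift * case
    factor = rng.normal(0.0, 1.0, n_samples) + cfg.factor_case_shift * (
        phenotype if dosage is None else dosage * cfg.fh_effect_ratio
    )
    lam = np.array([loadings.get(g, 0.0) for g in genes])
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, len(genes))
    eps = rng.normal(0.0, 1.0, (len(genes), n_samples))
    score = (
        baseline[:, None]
        + cfg.gene_sd * (lam[:, None] * factor[None, :] + np.sqrt(1 - lam**2)[:, None] * eps)
        + cfg.age_effect * (age - 50.0)[None, :]
        + cfg.bmi_effect * (bmi - 30.0)[None, :]
    )
    shift = np.array([de_effects.get(g, 0.0) for g in genes])
    dose = phenotype if dosage is None else dosage * cfg.fh_effect_ratio
    score = score + shift[:, None] * dose[None, :]
    gene_idx = {g: i for i, g in enumerate(genes)}
    pm = probe_map[probe_map["gene"].isin(gene_idx)]
    offsets = rng.normal(0.0, cfg.probe_offset_sd, len(pm))
    noise = rng.normal(0.0, cfg.probe_noise_sd, (len(pm), n_samples))
    rows = score[[gene_idx[g] for g in pm["gene"]], :] + offsets[:, None] + noise
    samples = [f"s{i + 1:03d}" for i in range(n_samples)]
    expr = pd.DataFrame(np.round(rows, 6), index=pd.Index(pm["probe"], name="probe"),
                        columns=samples)
    covars = pd.DataFrame({"age": np.round(age, 3), "bmi": np.round(bmi, 3)}, index=samples)
    return expr, covars


def simulate_expression(
    cfg: ScenarioConfig,
    annotation: pd.DataFrame,
    probe_map: pd.DataFrame,
    truth: GroundTruth,
    rng,
) -> tuple[list, ExpressionStudy]:
    """Case/control studies per tissue plus one family-history study.

    Plants a case shift (log2) for every cis-gene and fills
    ``truth.de_effects``.  NEMGs share a per-sample factor whose loading is
    drawn per gene; the factor shifts in cases, mimicking the generalized
    down-regulation of the mitochondrial proteome.
    """
    lo, hi = cfg.nemg_loading_range
    loadings = {g: float(rng.uniform(lo, hi)) for g in truth.nemg}
    de_effects = {
        g: float(rng.normal(cfg.cis_effect_mean, cfg.cis_effect_sd)) for g in truth.cis_genes
    }
    truth.de_effects = de_effects

    studies = []
    for tissue, n_studies in cfg.studies:
        for j in range(n_studies):
            n = cfg.samples_per_study
            phenotype = np.zeros(n)
            phenotype[n // 2:] = 1.0
            expr, covars = _study_matrix(
                cfg, annotation, probe_map, loadings, de_effects, phenotype, None, rng
            )
            studies.append(
                ExpressionStudy(
                    study_id=f"{tissue}_{j + 1}",
                    tissue=tissue,
                    expression=expr,
                    phenotype=pd.Series(phenotype, index=expr.columns),
                    probe_map=probe_map,
                    covariates=covars,
                )
            )
    # family-history study: dosage 0/1/2 affected parents, muscle
    dosage = np.repeat([0.0, 1.0, 2.0], cfg.fh_group_sizes)
    expr, covars = _study_matrix(
        cfg, annotation, probe_map, loadings, de_effects, dosage, dosage, rng
    )
    fh_study = ExpressionStudy(
        study_id="muscle_fh",
        tissue="muscle",
        expression=expr,
        phenotype=pd.Series(dosage, index=expr.columns),
        probe_map=probe_map,
        covariates=covars,
    )
    return studies, fh_study


# ---------------------------------------------------------------------------
# gene sets


def simulate_gene_sets(
    cfg: ScenarioConfig, annotation: pd.DataFrame, truth: GroundTruth, rng
) -> list:
    """Pathway sets: a few enriched for cis-genes, the rest uniform draws."""
    genes = annotation["gene_id"].to_numpy()
    is_cis = np.isin(genes, truth.cis_genes)
    sets = []
    for i in range(cfg.n_sets):
        enriched = i < cfg.n_enriched_sets
        w = np.where(is_cis, cfg.enrichment_factor if enriched else 1.0, 1.0)
        members = rng.choice(genes, size=cfg.set_size, replace=False, p=w / w.sum())
        name = f"SET_{i + 1:02d}"
        sets.append(GeneSet(name, members.tolist(), source="enriched" if enriched else "null"))
        if enriched:
            truth.enriched_sets.append(name)
    return sets


# ---------------------------------------------------------------------------
# scenario assembly & serialization


def generate_scenario(cfg: ScenarioConfig = ScenarioConfig()) -> Scenario:
    """Build the full in-memory input bundle from one seed."""
    root = np.random.SeedSequence(cfg.seed)
    keys = ("maps", "annotation", "estimates", "probes", "expression", "sets")
    rngs = dict(zip(keys, map(np.random.default_rng, root.spawn(len(keys)))))
    maps = _simulate_maps(cfg, rngs["maps"])
    annotation = _simulate_annotation(cfg, rngs["annotation"])
    estimates, truth = simulate_estimates(cfg, maps, annotation, rngs["estimates"])
    probe_map = _simulate_probe_map(cfg, annotation, rngs["probes"])
    studies, fh_study = simulate_expression(cfg, annotation, probe_map, truth, rngs["expression"])
    sets = simulate_gene_sets(cfg, annotation, truth, rngs["sets"])
    return Scenario(
        cfg=cfg,
        maps=maps,
        estimates=estimates,
        annotation=annotation,
        probe_map=probe_map,
        studies=studies,
        fh_study=fh_study,
        nemg=truth.nemg,
        sets=sets,
        truth=truth,
    )


def make_scenario(cfg: ScenarioConfig = ScenarioConfig(), out_dir: str = "scenario") -> Scenario:
    """Generate a scenario and write the full file bundle.

    Files are written to a temporary sibling directory and atomically renamed
    into place, so a partial write never leaves a manifest behind.  Re-running
    with the same seed reproduces the bundle byte for byte.
    """
    scn = generate_scenario(cfg)
    parent = os.path.dirname(os.path.abspath(out_dir)) or "."
    os.makedirs(parent, exist_ok=True)
    tmp = tempfile.mkdtemp(prefix=".scenario-", dir=parent)
    try:
        write_map_table(scn.maps, os.path.join(tmp, "map.tsv"))
        write_estimates(scn.estimates, os.path.join(tmp, "estimates.tsv"))
        scn.annotation.to_csv(os.path.join(tmp, "annotation.tsv"), sep="\t", index=False)
        scn.probe_map.to_csv(os.path.join(tmp, "probes.tsv"), sep="\t", index=False)
        with open(os.path.join(tmp, "nemg.txt"), "w") as fh:
            fh.write("\n".join(scn.nemg) + "\n")
        write_gmt(scn.sets, os.path.join(tmp, "sets.gmt"))
        expr_dir = os.path.join(tmp, "expression")
        os.makedirs(expr_dir)
        for study in [*scn.studies, scn.fh_study]:
            study.expression.to_csv(
                os.path.join(expr_dir, f"{study.study_id}_expression.tsv"),
                sep="\t", float_format="%.6f",
            )
            pheno = pd.DataFrame(
                {"sample": study.expression.columns, "phenotype": study.phenotype.to_numpy()}
            )
            if study.covariates is not None:
                for c in study.covariates.columns:
                    pheno[c] = study.covariates[c].to_numpy()
            pheno.to_csv(os.path.join(expr_dir, f"{study.study_id}_phenotype.tsv"),
                         sep="\t", index=False, float_format="%.3f")
        # ground truth
        scn.truth.loci.to_csv(os.path.join(tmp, "truth_loci.tsv"), sep="\t",
                              index=False, float_format="%.4f")
        with open(os.path.join(tmp, "truth_cis_genes.txt"), "w") as fh:
            fh.write("\n".join(scn.truth.cis_genes) + "\n")
        pd.DataFrame(
            sorted(scn.truth.de_effects.items()), columns=["gene", "effect"]
        ).to_csv(os.path.join(tmp, "truth_de_effects.tsv"), sep="\t", index=False,
                 float_format="%.4f")
        manifest = {
            "seed": cfg.seed,
            "n_chromosomes": cfg.n_chromosomes,
            "n_true_loci": len(scn.truth.loci),
            "n_cis_genes": len(scn.truth.cis_genes),
            "n_nemg": len(scn.nemg),
            "n_studies": len(scn.studies) + 1,
            "enriched_sets": ",".join(scn.truth.enriched_sets),
            "locus_sizes": ",".join(map(str, scn.truth.locus_sizes)),
        }
        with open(os.path.join(tmp, "manifest.txt"), "w") as fh:
            for k, v in manifest.items():
                fh.write(f"{k}={v}\n")
        if os.path.isdir(out_dir):
            shutil.rmtree(out_dir)
        os.replace(tmp, out_dir)
    except BaseException:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    return scn


def bundle_digest(out_dir: str) -> str:
    """SHA-256 over the sorted file contents of a scenario bundle."""
    h = hashlib.sha256()
    for root, _, files in sorted(os.walk(out_dir)):
        for name in sorted(files):
            path = os.path.join(root, name)
            h.update(os.path.relpath(path, out_dir).encode())
            with open(path, "rb") as fh:
                h.update(fh.read())
    return h.hexdigest()
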