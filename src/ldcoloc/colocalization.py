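"""Disease/eQTL colocalization on LDU maps and cis-gene assignment.

The pipeline stage implemented here takes causal-variant location estimates
for a disease (one per cohort, from an LDU-based multi-marker association
scan) and for gene expression (eQTL, one per probe/gene), and:

1. clusters disease estimates into *replicated loci* — two or more estimates
   from distinct cohorts co-located within a small genetic distance
   (default 1 LDU), by single-linkage clustering on the LDU coordinate;
2. calls *disease-eQTL* where an expression estimate lies within the same
   LDU threshold of any member estimate of a replicated locus;
3. assigns *cis-genes* to each called eQTL within a physical cis window
   (default +/-1.5 Mb) of the locus's representative position; and
4. flags which cis-genes are nuclear-encoded mitochondrial genes (NEMGs)
   against a MitoCarta-style reference list.

Everything is decided in LDU: two estimates a few kb apart across an LD
"step" are never co-located, while estimates tens of kb apart inside a
block are.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .genetic_map import GeneticMap

__all__ = [
    "LocationEstimate",
    "ReplicatedLocus",
    "T2DeQTL",
    "CisGeneCall",
    "ThresholdConfig",
    "Exclusion",
    "convert_population",
    "replicate_loci",
    "call_t2d_eqtl",
    "assign_cis_genes",
    "flag_nemg",
    "nemg_proportion_test",
    "normalize_symbol",
    "read_estimates",
]


@dataclass(frozen=True)
class LocationEstimate:
    """One mapped causal-variant location (S-hat).

    ``trait`` is "disease" or "expression"; expression estimates carry a
    ``target`` (probe or gene id), disease estimates do not.  ``ldu`` is the
    coordinate on the analysis (European) map, filled by
    :func:`convert_population`.
    """

    trait: str
    cohort: str
    population: str
    chromosome: str
    position: float
    p_value: float
    target: str | None = None
    ldu: float | None = None

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if self.position <= 0:
            raise ValueError("position must be positive")
        if self.trait == "expression" and not self.target:
            raise ValueError("expression estimates must carry a target gene/probe")
        if self.trait == "disease" and self.target:
            raise ValueError("disease estimates must not carry a target")


@dataclass
class ReplicatedLocus:
    """Two or more disease estimates from distinct cohorts within threshold."""

    members: list[LocationEstimate]
    representative: LocationEstimate
    cosmopolitan: bool
    tier: str  # "bonferroni" | "nominal"
    locus_id: str = ""

    @property
    def chromosome(self) -> str:
        return self.representative.chromosome

    @property
    def position(self) -> float:
        return self.representative.position


@dataclass
class T2DeQTL:
    """An expression estimate co-located (<= threshold LDU) with a locus."""

    locus: ReplicatedLocus
    eqtl: LocationEstimate
    ldu_distance: float
    gene: str | None = None


@dataclass
class CisGeneCall:
    """A gene supported by at least one disease-eQTL."""

    gene: str
    symbol: str
    supporting: list[T2DeQTL] = field(default_factory=list)
    nemg: bool = False

    @property
    def loci(self) -> list[ReplicatedLocus]:
        seen, out = set(), []
        for s in self.supporting:
            if id(s.locus) not in seen:
                seen.add(id(s.locus))
                out.append(s.locus)
        return out

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class ThresholdConfig:
    """All thresholds of the colocalization stage, in their native units."""

    coloc_threshold: float = 1.0  # LDU
    t2d_p_nominal: float = 1e-3
    t2d_p_bonferroni: float = 1e-5  # ~5,000 independent genomic tests
    eqtl_p: float = 0.05
    cis_window: float = 1.5e6  # bp
    min_cohorts: int = 2
    require_all_members: bool = False  # eQTL within threshold of ALL members

    def __post_init__(self):
        for name in ("coloc_threshold", "t2d_p_nominal", "t2d_p_bonferroni", "eqtl_p", "cis_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t2d_p_bonferroni > self.t2d_p_nominal:
            raise ValueError("bonferroni threshold must be <= nominal threshold")


@dataclass(frozen=True)
class Exclusion:
    """A record dropped from the analysis, with the reason."""

    kind: str
    identifier: str
    reason: str


# ---------------------------------------------------------------------------
# population conversion


def convert_population(
    estimate: LocationEstimate, target_map: GeneticMap
) -> LocationEstimate | Exclusion:
    """Place an estimate on the analysis LDU map via its physical position.

    Estimates mapped in another population (e.g. African American) are
    compared on the European map through their shared b37 coordinate; the
    physical position is unchanged, only the LDU coordinate is annotated.
    Positions outside the target map are returned as an :class:`Exclusion`.
    """
    if estimate.chromosome != target_map.chromosome:
        return Exclusion(
            "estimate",
            f"{estimate.cohort}:{estimate.chromosome}:{estimate.position:.0f}",
            f"chromosome {estimate.chromosome} does not match map chr{target_map.chromosome}",
        )
    if not target_map.contains(estimate.position):
        return Exclusion(
            "estimate",
            f"{estimate.cohort}:{estimate.chromosome}:{estimate.position:.0f}",
            f"position outside map extent [{target_map.start:.0f}, {target_map.end:.0f}]",
        )
    return LocationEstimate(
        trait=estimate.trait,
        cohort=estimate.cohort,
        population=estimate.population,
        chromosome=estimate.chromosome,
        position=estimate.position,
        p_value=estimate.p_value,
        target=estimate.target,
        ldu=target_map.ldu_at(estimate.position),
    )


def _annotate(estimates, maps, exclusions):
    """Attach LDU coordinates; route unmappable estimates to exclusions."""
    out = []
    for est in estimates:
        gmap = maps.get(est.chromosome)
        if gmap is None:
            exclusions.append(
                Exclusion(
                    "estimate",
                    f"{est.cohort}:{est.chromosome}:{est.position:.0f}",
                    f"no LDU map for chromosome {est.chromosome}",
                )
            )
            continue
        res = convert_population(est, gmap)
        if isinstance(res, Exclusion):
            exclusions.append(res)
        else:
            out.append(res)
    return out


# ---------------------------------------------------------------------------
# replicated loci


def replicate_loci(
    estimates: list[LocationEstimate],
    maps: dict[str, GeneticMap],
    cfg: ThresholdConfig = ThresholdConfig(),
    exclusions: list[Exclusion] | None = None,
) -> list[ReplicatedLocus]:
    """Single-linkage clusters of disease estimates within the LDU threshold.

    Estimates are first filtered to the nominal disease significance level,
    placed on the per-chromosome map, then chained: along one chromosome any
    two estimates whose LDU distance is <= ``coloc_threshold`` join one
    cluster (transitive closure of the pairwise co-location rule).  A cluster
    becomes a replicated locus when it spans at least ``min_cohorts`` distinct
    cohorts.  The representative is the most significant member; tier is
    "bonferroni" iff any member clears the Bonferroni level; a locus is
    cosmopolitan iff any member is from an AA (African-ancestry) cohort.
    """
    if exclusions is None:
        exclusions = []
    disease = [e for e in estimates if e.trait == "disease" and e.p_value < cfg.t2d_p_nominal]
    disease = _annotate(disease, maps, exclusions)
    loci: list[ReplicatedLocus] = []
    by_chrom: dict[str, list[LocationEstimate]] = {}
    for est in disease:
        by_chrom.setdefault(est.chromosome, []).append(est)
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda e: (e.ldu, e.position))
        cluster: list[LocationEstimate] = []
        for est in members + [None]:
            if cluster and (est is None or est.ldu - cluster[-1].ldu > cfg.coloc_threshold):
                cohorts = {m.cohort for m in cluster}
                if len(cohorts) >= cfg.min_cohorts:
                    rep = min(cluster, key=lambda m: (m.p_value, m.position))
                    loci.append(
                        ReplicatedLocus(
                            members=list(cluster),
                            representative=rep,
                            cosmopolitan=any(m.population == "AA" for m in cluster),
                            tier="bonferroni"
                            if any(m.p_value < cfg.t2d_p_bonferroni for m in cluster)
                            else "nominal",
                        )
                    )
                cluster = []
            if est is not None:
                cluster.append(est)
    for i, locus in enumerate(loci, start=1):
        locus.locus_id = f"L{i:03d}"
    return loci


# ---------------------------------------------------------------------------
# disease-eQTL calls


def call_t2d_eqtl(
    loci: list[ReplicatedLocus],
    eqtls: list[LocationEstimate],
    maps: dict[str, GeneticMap],
    cfg: ThresholdConfig = ThresholdConfig(),
    exclusions: list[Exclusion] | None = None,
) -> list[T2DeQTL]:
    """Call eQTL within the LDU threshold of a replicated locus.

    By default an eQTL qualifies if it lies within ``coloc_threshold`` LDU of
    *any* member estimate of the locus (each member carries its own +/-1-LDU
    window); set ``require_all_members`` for the strict all-members reading.
    The recorded distance is the minimum over members.  One call is emitted
    per (locus, eQTL) pair.
    """
    if exclusions is None:
        exclusions = []
    expr = [e for e in eqtls if e.trait == "expression" and e.p_value < cfg.eqtl_p]
    expr = _annotate(expr, maps, exclusions)
    calls: list[T2DeQTL] = []
    for eqtl in expr:
        for locus in loci:
            if locus.chromosome != eqtl.chromosome:
                continue
            dists = [abs(eqtl.ldu - m.ldu) for m in locus.members]
            hit = (
                max(dists) <= cfg.coloc_threshold
                if cfg.require_all_members
                else min(dists) <= cfg.coloc_threshold
            )
            if hit:
                calls.append(T2DeQTL(locus=locus, eqtl=eqtl, ldu_distance=min(dists)))
    return calls


# ---------------------------------------------------------------------------
# cis-gene assignment


def assign_cis_genes(
    t2d_eqtls: list[T2DeQTL],
    annotation: pd.DataFrame,
    probe_map: pd.DataFrame | None = None,
    cfg: ThresholdConfig = ThresholdConfig(),
    exclusions: list[Exclusion] | None = None,
) -> list[CisGeneCall]:
    """Attach each called eQTL's gene if it lies in the locus's cis window.

    ``annotation`` is a BED-like table with columns ``chrom start end gene_id
    hgnc``; ``probe_map`` maps probe ids to their annotated gene (probes
    overlapping several genes resolve to that designated gene).  A gene is
    attached iff its span, padded by ``cis_window`` on both sides, covers the
    representative position of the locus.  Genes supported by several loci
    yield one call with ``n_loci`` > 1.
    """
    if exclusions is None:
        exclusions = []
    spans: dict[str, list] = {}  # a gene may have several annotated spans
    for row in annotation.itertuples(index=False):
        spans.setdefault(str(row.gene_id), []).append(
            (str(row.chrom), float(row.start), float(row.end), str(row.hgnc))
        )
    probe_to_gene = (
        dict(zip(probe_map["probe"], probe_map["gene"])) if probe_map is not None else {}
    )
    calls: dict[str, CisGeneCall] = {}
    for hit in t2d_eqtls:
        target = hit.eqtl.target
        gene = probe_to_gene.get(target, target)
        if gene not in spans:
            exclusions.append(
                Exclusion("probe", str(target), f"target {gene!r} not in annotation")
            )
            continue
        same_chrom = [s for s in spans[gene] if s[0] == hit.locus.chromosome]
        if not same_chrom:
            exclusions.append(
                Exclusion("gene", gene, "annotated on a different chromosome than the locus")
            )
            continue
        in_window = [
            s
            for s in same_chrom
            if s[1] - cfg.cis_window <= hit.locus.position <= s[2] + cfg.cis_window
        ]
        if not in_window:
            exclusions.append(
                Exclusion("gene", gene, f"outside +/-{cfg.cis_window:.0f} bp cis window of locus")
            )
            continue
        hit.gene = gene
        call = calls.setdefault(gene, CisGeneCall(gene=gene, symbol=in_window[0][3]))
        call.supporting.append(hit)
    return list(calls.values())


# ---------------------------------------------------------------------------
# NEMG flagging

# Spreadsheet date-mangling of gene symbols (MARCH5 -> "Mar-05" etc.) plus the
# MARCHF/SEPTIN renames; applied case-insensitively after stripping.
_EXCEL_MONTHS = {"MAR": "MARCH", "SEP": "SEPT", "SEPT": "SEPT", "DEC": "DEC", "OCT": "OCT"}
_EXCEL_RE = re.compile(r"^(MAR|SEPT?|DEC|OCT)[-/ ]0*(\d+)$", re.IGNORECASE)

DEFAULT_ALIASES = {
    "MARCHF5": "MARCH5",
    "SEPTIN7": "SEPT7",
    "CARKD": "NAXD",
}


def normalize_symbol(symbol: str, aliases: dict[str, str] | None = None) -> str:
    """Uppercase, undo Excel date-mangling, and apply the alias table."""
    s = str(symbol).strip().upper()
    m = _EXCEL_RE.match(s)
    if m:
        s = f"{_EXCEL_MONTHS[m.group(1).upper()]}{int(m.group(2))}"
    table = DEFAULT_ALIASES if aliases is None else {**DEFAULT_ALIASES, **aliases}
    return table.get(s, s)


def flag_nemg(
    calls: list[CisGeneCall],
    nemg_list: set[str],
    aliases: dict[str, str] | None = None,
) -> int:
    """Flag calls whose symbol or gene id matches the NEMG reference list.

    Matching is case-insensitive on normalized symbols (undoing
    spreadsheet-mangled names such as ``Mar-05`` for *MARCH5*).  Returns the
    number of flagged calls.
    """
    if not nemg_list:
        for c in calls:
            c.nemg = False
        return 0
    norm = {normalize_symbol(g, aliases) for g in nemg_list}
    n = 0
    for c in calls:
        c.nemg = (
            normalize_symbol(c.symbol, aliases) in norm
            or normalize_symbol(c.gene, aliases) in norm
        )
        n += c.nemg
    return n


def nemg_proportion_test(
    n_cis: int, n_cis_nemg: int, background_total: int, background_nemg: int
) -> dict[str, float]:
    """Two-sided Fisher exact comparison of cis vs background NEMG fractions.

    ``background_total``/``background_nemg`` describe the genomic background
    the cis list is compared against (conventionally the full annotated gene
    universe).  Returns the two percentages and the exact p-value from the
    hypergeometric tail sum.
    """
    a, b = n_cis_nemg, n_cis - n_cis_nemg
    c, d = background_nemg, background_total - background_nemg
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 table cells must be non-negative")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "cis_nemg_percent": 100.0 * a / (a + b) if a + b else math.nan,
        "background_nemg_percent": 100.0 * c / (c + d) if c + d else math.nan,
        "p_value": float(p),
    }


# ---------------------------------------------------------------------------
# I/O

_EST_COLS = ["trait", "cohort", "population", "chrom", "pos_bp", "p_value", "target"]


def read_estimates(path_or_buf) -> list[LocationEstimate]:
    """Load location estimates from TSV (columns: trait cohort population
    chrom pos_bp p_value target; empty target for disease rows)."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"chrom": str, "target": str})
    missing = set(_EST_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"estimate table missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        target = None if pd.isna(row.target) or row.target == "" else str(row.target)
        out.append(
            LocationEstimate(
                trait=row.trait,
                cohort=row.cohort,
                population=row.population,
                chromosome=str(row.chrom),
                position=float(row.pos_bp),
                p_value=float(row.p_value),
                target=target,
            )
        )
    return out


def write_estimates(estimates: list[LocationEstimate], path) -> None:
    pd.DataFrame(
        {
            "trait": [e.trait for e in estimates],
            "cohort": [e.cohort for e in estimates],
            "population": [e.population for e in estimates],
            "chrom": [e.chromosome for e in estimates],
            "pos_bp": [int(e.position) for e in estimates],
            "p_value": [e.p_value for e in estimates],
            "target": [e.target or "" for e in estimates],
        }
    ).to_csv(path, sep="\t", index=False)
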