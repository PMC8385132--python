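"""Competitive gene-set enrichment with gene-sampling permutation nulls.

The observed statistic is the Wilcoxon rank-sum of the set's members among a
background of genewise z-scores (midranks for ties).  Direction classes:

* ``down``  — ranks of z itself; a small rank-sum means the set sits in the
  down-regulated tail;
* ``up``    — ranks of -z;
* ``mixed`` — ranks of |z|, where a *large* rank-sum means the set is
  enriched for extreme effects of either sign.

Significance is competitive: random gene sets of the same size are drawn from
the background (gene-level sampling, without replacement), and the one-sided
empirical p uses the add-one rule p = (1 + #{null at least as extreme}) /
(n_perm + 1), which can never be zero.  Benjamini–Hochberg FDR is applied
within each comparison family.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "GseaResult",
    "wilcoxon_set_stat",
    "permutation_p",
    "gsea_battery",
    "read_gmt",
    "write_gmt",
]

DIRECTIONS = ("down", "up", "mixed")


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated set of gene ids."""

    name: str
    members: frozenset
    source: str = ""

    def __init__(self, name: str, members, source: str = ""):
        members = frozenset(members)
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "source", source)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GseaResult:
    set_name: str
    background: str
    tissue: str
    n_set: int
    n_background: int
    direction: str  # class with the smallest p
    stat: float
    p_down: float
    p_up: float
    p_mixed: float
    p: float
    fdr: float = float("nan")


def _oriented(z: np.ndarray, direction: str) -> np.ndarray:
    if direction == "down":
        return z
    if direction == "up":
        return -z
    if direction == "mixed":
        return np.abs(z)
    raise ValueError(f"unknown direction {direction!r}")


def wilcoxon_set_stat(
    stats: pd.Series, set_genes, background, direction: str = "down"
) -> float:
    """Rank-sum of the set members among the background, midranks for ties.

    ``stats`` maps gene id -> z.  For ``down``/``up`` small values of the
    statistic indicate enrichment; for ``mixed`` large values do.
    """
    bg = [g for g in background if g in stats.index]
    members = set(set_genes) & set(bg)
    if len(members) < 2 or len(bg) - len(members) < 2:
        raise ValueError("need >=2 set genes and >=2 non-set genes in the background")
    z = _oriented(stats.loc[bg].to_numpy(dtype=float), direction)
    ranks = rankdata(z)
    in_set = np.fromiter((g in members for g in bg), dtype=bool, count=len(bg))
    return float(ranks[in_set].sum())


def _null_ranksums(ranks: np.ndarray, n_set: int, n_perm: int, rng) -> np.ndarray:
    """Rank-sums of ``n_perm`` random size-``n_set`` subsets of the background."""
    N = len(ranks)
    # vectorised sampling without replacement: first n_set of a random order
    order = np.argsort(rng.random((n_perm, N)), axis=1)[:, :n_set]
    return ranks[order].sum(axis=1)


def permutation_p(
    stats: pd.Series,
    set_genes,
    background,
    direction: str = "down",
    n_perm: int = 10_000,
    rng=None,
) -> tuple[float, float]:
    """Gene-sampling permutation p for one set and direction.

    Returns ``(observed rank-sum, p)``.  Null sets are drawn uniformly
    without replacement from the background at the intersected set size.
    ``rng`` is a :class:`numpy.random.Generator` (or a seed).
    """
    rng = np.random.default_rng(rng)
    bg = [g for g in background if g in stats.index]
    members = set(set_genes) & set(bg)
    if len(members) == len(bg):
        # the set IS the background: every null draw reproduces it exactly
        ranks = rankdata(_oriented(stats.loc[bg].to_numpy(dtype=float), direction))
        return float(ranks.sum()), 1.0
    if len(members) < 2 or len(bg) - len(members) < 2:
        raise ValueError("need >=2 set genes and >=2 non-set genes in the background")
    z = _oriented(stats.loc[bg].to_numpy(dtype=float), direction)
    ranks = rankdata(z)
    in_set = np.fromiter((g in members for g in bg), dtype=bool, count=len(bg))
    obs = float(ranks[in_set].sum())
    null = _null_ranksums(ranks, int(in_set.sum()), n_perm, rng)
    if direction == "mixed":
        extreme = int(np.sum(null >= obs))
    else:
        extreme = int(np.sum(null <= obs))
    return obs, (1 + extreme) / (n_perm + 1)


def gsea_battery(
    meta_tables: dict[str, pd.DataFrame],
    comparisons: list[tuple[str, object, object]],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run every (set, background) comparison in every tissue.

    ``meta_tables`` maps tissue -> DataFrame with ``gene`` and ``z_meta``
    columns.  Each comparison is ``(name, GeneSet, background)`` where the
    background is an iterable of gene ids or ``None`` for all scored genes.
    For each tissue x comparison all three direction classes are tested; the
    reported class is the one with the smallest p and BH-FDR is computed
    within the comparison family across tissues and directions.  Undersized
    comparisons are skipped (logged as absent rows).
    """
    rows = []
    for tissue in sorted(meta_tables):
        table = meta_tables[tissue]
        stats = pd.Series(table["z_meta"].to_numpy(dtype=float), index=table["gene"])
        for i, (name, gene_set, background) in enumerate(comparisons):
            bg = list(stats.index) if background is None else [
                g for g in background if g in stats.index
            ]
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, zlib.crc32(tissue.encode()) % 2**31, i])
            )
            try:
                res = {}
                for direction in DIRECTIONS:
                    obs, p = permutation_p(
                        stats, gene_set.members, bg, direction, n_perm=n_perm, rng=rng
                    )
                    res[direction] = (obs, p)
            except ValueError:
                continue  # undersized after intersection
            best = min(DIRECTIONS, key=lambda d: res[d][1])
            rows.append(
                {
                    "tissue": tissue,
                    "comparison": name,
                    "set_name": gene_set.name,
                    "n_set": len(set(gene_set.members) & set(bg)),
                    "n_background": len(bg),
                    "direction": best,
                    "stat": res[best][0],
                    "p_down": res["down"][1],
                    "p_up": res["up"][1],
                    "p_mixed": res["mixed"][1],
                    "p": res[best][1],
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = np.nan
        for name, idx in out.groupby("comparison").groups.items():
            out.loc[idx, "fdr"] = multipletests(out.loc[idx, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets.append(GeneSet(parts[0], [g for g in parts[2:] if g], source=parts[1]))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source, *sorted(s.members)]) + "\n")
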