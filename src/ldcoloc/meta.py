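"""Random-effects combination of per-gene Z-scores across studies.

Within each tissue, the per-study gene-centric Z-scores are combined with the
DerSimonian–Laird moment estimator.  Each Z is treated as an effect on the
standard-normal scale with within-study variance 1, so with no heterogeneity
the combined statistic reduces to mean(z) * sqrt(k) — Stouffer's rule — while
between-study heterogeneity (tau^2 > 0) widens the weights and shrinks the
combined Z.

Formulas (effects z_i, variances v_i, k studies):

    w_i   = 1 / v_i
    z_bar = sum(w_i z_i) / sum(w_i)
    Q     = sum(w_i (z_i - z_bar)^2)
    tau2  = max(0, (Q - (k - 1)) / (sum(w_i) - sum(w_i^2)/sum(w_i)))
    w*_i  = 1 / (v_i + tau2)
    mu    = sum(w*_i z_i) / sum(w*_i)
    z_meta = mu * sqrt(sum(w*_i))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MetaResult", "random_effects_combine", "meta_by_tissue"]


@dataclass(frozen=True)
class MetaResult:
    """DerSimonian–Laird summary for one gene in one tissue."""

    gene: str
    tissue: str
    k: int
    Q: float
    tau2: float
    mu: float
    z_meta: float


def random_effects_combine(
    effects,
    variances=None,
    gene: str = "",
    tissue: str = "",
) -> MetaResult:
    """DerSimonian–Laird random-effects combination of one gene's effects.

    ``effects`` are per-study z-scores; ``variances`` default to 1 for every
    study (z-scale effects).  Non-finite effects are dropped.  k = 1 returns
    the effect unchanged with Q = tau2 = 0.
    """
    z = np.asarray(effects, dtype=float)
    v = np.ones_like(z) if variances is None else np.asarray(variances, dtype=float)
    keep = np.isfinite(z) & np.isfinite(v) & (v > 0)
    z, v = z[keep], v[keep]
    k = len(z)
    if k == 0:
        raise ValueError(f"no usable effects to combine for gene {gene!r}")
    w = 1.0 / v
    z_bar = float(np.sum(w * z) / np.sum(w))
    Q = float(np.sum(w * (z - z_bar) ** 2))
    if k == 1:
        tau2 = 0.0
    else:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    mu = float(np.sum(w_star * z) / np.sum(w_star))
    z_meta = mu * float(np.sqrt(np.sum(w_star)))
    return MetaResult(gene=gene, tissue=tissue, k=k, Q=Q, tau2=tau2, mu=mu, z_meta=z_meta)


def meta_by_tissue(
    study_tables: dict[str, pd.DataFrame],
    tissue_of: dict[str, str],
) -> dict[str, pd.DataFrame]:
    """Genewise DL combination of per-study z tables, grouped by tissue.

    ``study_tables`` maps study id -> DataFrame with columns ``gene z`` (the
    output of :func:`ldcoloc.diffexpr.study_zscores`); ``tissue_of`` maps
    study id -> tissue label.  Genes are combined over the *union* of studies
    within a tissue (k records how many actually contributed; array platforms
    differ, so requiring intersection would silently shrink coverage).

    Returns tissue -> DataFrame ``gene k Q tau2 z_meta``.
    """
    by_tissue: dict[str, list[tuple[str, pd.DataFrame]]] = {}
    for sid, table in study_tables.items():
        by_tissue.setdefault(tissue_of[sid], []).append((sid, table))
    out: dict[str, pd.DataFrame] = {}
    for tissue in sorted(by_tissue):
        pergene: dict[str, list[float]] = {}
        for _, table in by_tissue[tissue]:
            for gene, z in zip(table["gene"], table["z"]):
                if np.isfinite(z):
                    pergene.setdefault(gene, []).append(float(z))
        rows = []
        for gene in sorted(pergene):
            r = random_effects_combine(pergene[gene], gene=gene, tissue=tissue)
            rows.append((r.gene, r.k, r.Q, r.tau2, r.z_meta))
        out[tissue] = pd.DataFrame(rows, columns=["gene", "k", "Q", "tau2", "z_meta"])
    return out
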