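"""Relating non-cis NEMG differential expression to their co-expression with
the cis-NEMG group.

Nuclear-encoded mitochondrial genes are strongly co-expressed, which limits
the power of competitive enrichment within the NEMG background.  This stage
asks the stratified question instead: among NEMGs *not* called as cis-genes,
is the case/control differential-expression Z related to how strongly the
gene's baseline (control-sample) expression correlates with the cis-NEMG
group?  A negative slope means NEMGs tracking the disease-locus-regulated
subset are themselves more down-regulated in cases.

For each non-cis NEMG the profile is its mean Pearson correlation, over
control samples only, with every cis-NEMG (gene-level expression = mean of
annotated probes).  The regression is z ~ mean_r + mean_expr, where mean
control expression enters as a covariate so that the correlation term is not
a proxy for absolute abundance.  A robust variant mirrors Stata's ``rreg``:
drop points with Cook's distance > 1, then iteratively reweighted least
squares with Huber weights (c = 1.345) followed by Tukey biweight
(c = 4.685); points with final weight < 0.01 are reported as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.robust.norms import HuberT, TukeyBiweight

__all__ = [
    "CorrelationRecord",
    "RegressionFit",
    "mean_correlation_profile",
    "correlation_de_regression",
]


@dataclass(frozen=True)
class CorrelationRecord:
    """One non-cis NEMG: co-expression profile and DE summary."""

    gene: str
    mean_r: float
    z: float
    mean_expr: float
    n_cis_used: int


@dataclass(frozen=True)
class RegressionFit:
    """Fit of z ~ mean_r + mean_expr, plain or robust."""

    slope: float
    intercept: float
    expr_coef: float
    p_value: float  # two-sided, for the mean_r slope
    n_used: int
    n_outliers_removed: int
    method: str  # "plain" | "robust"
    outliers: tuple = ()


def _gene_level(expr: pd.DataFrame, probe_map: pd.DataFrame, genes) -> pd.DataFrame:
    """Gene x sample matrix: mean over each gene's annotated probes."""
    pm = probe_map[probe_map["gene"].isin(set(genes)) & probe_map["probe"].isin(expr.index)]
    if pm.empty:
        return pd.DataFrame(columns=expr.columns)
    mat = expr.loc[pm["probe"]].to_numpy(dtype=float)
    return (
        pd.DataFrame(mat, index=pm["gene"].to_numpy(), columns=expr.columns)
        .groupby(level=0)
        .mean()
    )


def mean_correlation_profile(
    control_expression: pd.DataFrame,
    probe_map: pd.DataFrame,
    cis_nemgs,
    non_cis_nemgs,
    z_scores: pd.Series,
) -> list[CorrelationRecord]:
    """Mean control-sample Pearson correlation of each non-cis NEMG with the
    cis-NEMG group.

    ``control_expression`` is a probe x sample matrix restricted to control
    samples (>= 3 required).  Genes with zero variance across controls have
    undefined correlations and are excluded pairwise.  ``z_scores`` maps gene
    -> meta-analysis z (genes without a z are skipped).
    """
    if control_expression.shape[1] < 3:
        raise ValueError("need at least 3 control samples to estimate correlations")
    cis = _gene_level(control_expression, probe_map, cis_nemgs)
    non = _gene_level(control_expression, probe_map, non_cis_nemgs)
    cis = cis.loc[cis.std(axis=1) > 0]
    records = []
    for gene, row in non.iterrows():
        if gene not in z_scores.index or not np.isfinite(z_scores[gene]):
            continue
        x = row.to_numpy(dtype=float)
        if x.std() == 0 or cis.empty:
            continue
        r = np.corrcoef(x, cis.to_numpy(dtype=float))[0, 1:]
        r = r[np.isfinite(r)]
        if len(r) == 0:
            continue
        records.append(
            CorrelationRecord(
                gene=gene,
                mean_r=float(r.mean()),
                z=float(z_scores[gene]),
                mean_expr=float(x.mean()),
                n_cis_used=len(r),
            )
        )
    return records


def _as_xy(records):
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "mean_r": [r.mean_r for r in records],
            "mean_expr": [r.mean_expr for r in records],
            "z": [r.z for r in records],
        }
    )
    X = sm.add_constant(df[["mean_r", "mean_expr"]])
    return df, X, df["z"]


def correlation_de_regression(records, robust: bool = False) -> RegressionFit:
    """Regress DE z on the mean cis-NEMG correlation, expression-adjusted.

    Plain: OLS with the two-sided slope p.  Robust: Cook's-distance pre-drop
    (D > 1) followed by Huber-then-biweight IRLS; the slope p comes from the
    final weighted fit and points with weight < 0.01 are flagged as outliers.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records to fit the regression")
    df, X, y = _as_xy(records)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear predictors: mean_r and mean_expr (with intercept)")
    if not robust:
        fit = sm.OLS(y, X).fit()
        return RegressionFit(
            slope=float(fit.params["mean_r"]),
            intercept=float(fit.params["const"]),
            expr_coef=float(fit.params["mean_expr"]),
            p_value=float(fit.pvalues["mean_r"]),
            n_used=len(df),
            n_outliers_removed=0,
            method="plain",
        )
    # rreg-style: drop gross influence points, then Huber -> biweight IRLS
    ols = sm.OLS(y, X).fit()
    cooks = ols.get_influence().cooks_distance[0]
    keep = cooks <= 1.0
    dfk, Xk, yk = df[keep], X[keep], y[keep]
    huber = sm.RLM(yk, Xk, M=HuberT(t=1.345)).fit(conv="weights", tol=1e-6, maxiter=200)
    fit = sm.RLM(yk, Xk, M=TukeyBiweight(c=4.685)).fit(
        conv="weights", tol=1e-6, maxiter=200, start_params=huber.params
    )
    w = np.asarray(fit.weights)
    flagged = dfk.loc[w < 0.01, "gene"].tolist() + df.loc[~keep, "gene"].tolist()
    return RegressionFit(
        slope=float(fit.params["mean_r"]),
        intercept=float(fit.params["const"]),
        expr_coef=float(fit.params["mean_expr"]),
        p_value=float(fit.pvalues["mean_r"]),
        n_used=int(len(dfk) - np.sum(w < 0.01)),
        n_outliers_removed=int(np.sum(~keep) + np.sum(w < 0.01)),
        method="robust",
        outliers=tuple(flagged),
    )


def records_frame(records) -> pd.DataFrame:
    """CorrelationRecords as a DataFrame (scatter data for plotting)."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "mean_r": [r.mean_r for r in records],
            "z": [r.z for r in records],
            "mean_expr": [r.mean_expr for r in records],
            "n_cis_used": [r.n_cis_used for r in records],
        }
    )
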