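"""Per-gene case/control differential-expression Z-scores.

Input is a probe x sample matrix of normalized log-scale intensities (RMA-like
log2 values) with a 0/1 disease phenotype — or a 0/1/2 "number of affected
parents" dosage — and optional age/BMI covariates.  Each gene gets one signed
Z on the standard-normal scale, positive when expression is higher in cases:

* single annotated probe: ordinary least squares of expression on phenotype
  (plus covariates); Z is the coefficient over its standard error;
* several probes: a linear mixed model over the long (probe, sample) layout
  with fixed phenotype (and covariate) effects and crossed random intercepts
  for probe and for sample; Z is the Wald statistic of the phenotype
  coefficient.  The shared fixed slope is a conservative choice: probes of a
  gene are assumed to move in the same direction, and where they do not the
  gene-level effect shrinks toward zero.
* if the mixed fit fails to converge, probes are averaged per sample and the
  OLS route is used, flagged as ``fallback``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ExpressionStudy",
    "GeneEffect",
    "gene_zscore",
    "family_history_zscore",
    "study_zscores",
    "read_expression_study",
]


@dataclass
class ExpressionStudy:
    """One expression dataset: probe x sample matrix plus sample metadata.

    ``expression`` is a DataFrame indexed by probe id with sample columns;
    ``phenotype`` a Series over the same samples (0/1 case-control or 0/1/2
    parental dosage); ``covariates`` an optional DataFrame (e.g. age, bmi);
    ``probe_map`` a DataFrame with columns ``probe`` and ``gene``.
    """

    study_id: str
    tissue: str
    expression: pd.DataFrame
    phenotype: pd.Series
    probe_map: pd.DataFrame
    covariates: pd.DataFrame | None = None
    use_covariates: bool = True
    probe_random_only: bool = False

    def __post_init__(self):
        samples = list(self.expression.columns)
        if list(self.phenotype.index) != samples:
            self.phenotype = self.phenotype.reindex(samples)
        if self.phenotype.isna().any():
            raise ValueError(f"{self.study_id}: missing phenotype for some samples")
        if not np.isfinite(self.expression.to_numpy()).all():
            raise ValueError(f"{self.study_id}: expression matrix contains non-finite values")
        if self.covariates is not None:
            self.covariates = self.covariates.reindex(samples)

    def probes_for(self, gene: str) -> list[str]:
        probes = self.probe_map.loc[self.probe_map["gene"] == gene, "probe"]
        return [p for p in probes if p in self.expression.index]

    @property
    def genes(self) -> list[str]:
        present = self.probe_map["probe"].isin(self.expression.index)
        return sorted(self.probe_map.loc[present, "gene"].unique())


@dataclass
class GeneEffect:
    """Per-study, per-gene differential-expression summary."""

    study_id: str
    gene: str
    z: float
    n_probes: int
    model: str  # "single-probe" | "mixed" | "fallback"
    note: str = ""


def _design(study: ExpressionStudy, pheno: np.ndarray) -> pd.DataFrame:
    X = pd.DataFrame({"phenotype": pheno}, index=study.expression.columns)
    if study.use_covariates and study.covariates is not None:
        for c in study.covariates.columns:
            col = study.covariates[c]
            if col.notna().all() and np.ptp(col.to_numpy(dtype=float)) > 0:
                X[c] = col.to_numpy(dtype=float)
    return sm.add_constant(X, has_constant="add")


def _ols_z(y: np.ndarray, X: pd.DataFrame) -> float:
    fit = sm.OLS(y, X).fit()
    se = fit.bse["phenotype"]
    if not np.isfinite(se) or se == 0:
        raise ValueError("zero residual variance: z-score undefined")
    return float(fit.params["phenotype"] / se)


def _mixed_z(study: ExpressionStudy, probes: list[str], X: pd.DataFrame) -> float:
    """Wald z from a crossed random-intercept model on the long layout."""
    long = (
        study.expression.loc[probes]
        .reset_index(names="probe")
        .melt(id_vars="probe", var_name="sample", value_name="expr")
    )
    long = long.merge(X.reset_index(names="sample"), on="sample")
    # centring (and rounding away the subtraction's float dust) makes the fit
    # invariant to constant offsets: the optimizer's path, unlike the
    # estimand, is location sensitive on knife-edge small-sample fits
    long["expr"] = np.round(long["expr"] - long["expr"].mean(), 8)
    vc = {"probe": "0 + C(probe)"}
    if not study.probe_random_only:
        vc["sample"] = "0 + C(sample)"
    fixed = " + ".join(c for c in X.columns if c != "const")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            f"expr ~ {fixed}",
            groups=np.ones(len(long)),
            vc_formula=vc,
            data=long,
        )
        fit = model.fit(reml=True, method="lbfgs", maxiter=200)
    if not fit.converged:
        raise RuntimeError("mixed model did not converge")
    se = fit.bse_fe["phenotype"]
    if not np.isfinite(se) or se == 0:
        raise RuntimeError("mixed model produced a degenerate standard error")
    return float(fit.fe_params["phenotype"] / se)


def gene_zscore(study: ExpressionStudy, gene: str) -> GeneEffect:
    """Signed Z-score of case-vs-control differential expression for a gene.

    Positive Z means higher expression in cases.  Raises if the phenotype has
    no variance or the gene has no probes in the matrix.
    """
    pheno = study.phenotype.to_numpy(dtype=float)
    if np.ptp(pheno) == 0:
        raise ValueError(f"{study.study_id}: phenotype has zero variance")
    probes = study.probes_for(gene)
    if not probes:
        raise KeyError(f"{study.study_id}: gene {gene!r} has no probes in the matrix")
    X = _design(study, pheno)
    if len(probes) == 1:
        y = study.expression.loc[probes[0]].to_numpy(dtype=float)
        return GeneEffect(study.study_id, gene, _ols_z(y, X), 1, "single-probe")
    try:
        z = _mixed_z(study, probes, X)
        return GeneEffect(study.study_id, gene, z, len(probes), "mixed")
    except Exception as exc:  # convergence / degenerate fits
        y = study.expression.loc[probes].mean(axis=0).to_numpy(dtype=float)
        return GeneEffect(
            study.study_id, gene, _ols_z(y, X), len(probes), "fallback", note=str(exc)
        )


def family_history_zscore(study: ExpressionStudy, gene: str) -> GeneEffect:
    """Z from regressing expression on parental-T2D dosage (0, 1 or 2).

    The dosage coding probes genetic susceptibility in normoglycemic
    individuals, free of confounding by disease onset.
    """
    levels = set(study.phenotype.astype(float))
    if not levels <= {0.0, 1.0, 2.0}:
        raise ValueError("family-history phenotype must be coded 0/1/2")
    if len(levels) < 2:
        raise ValueError("need at least two distinct parental-dosage levels")
    return gene_zscore(study, gene)


def study_zscores(study: ExpressionStudy, family_history: bool = False) -> pd.DataFrame:
    """Z-scores for every gene of a study; degenerate genes flagged, not fatal.

    Returns a DataFrame ``gene z n_probes model note``; genes whose fit raised
    are kept as rows with NaN z and the error message in ``note``.
    """
    score = family_history_zscore if family_history else gene_zscore
    rows = []
    for gene in study.genes:
        try:
            eff = score(study, gene)
        except Exception as exc:
            eff = GeneEffect(study.study_id, gene, np.nan, len(study.probes_for(gene)),
                             "error", note=str(exc))
        rows.append((eff.gene, eff.z, eff.n_probes, eff.model, eff.note))
    return pd.DataFrame(rows, columns=["gene", "z", "n_probes", "model", "note"])


def read_expression_study(
    study_id: str,
    tissue: str,
    expression_path,
    phenotype_path,
    probe_map_path,
    use_covariates: bool = True,
) -> ExpressionStudy:
    """Assemble a study from its TSV parts.

    ``expression``: probes x samples with a ``probe`` index column;
    ``phenotype``: columns ``sample phenotype [age bmi ...]``;
    ``probe_map``: columns ``probe gene``.
    """
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    pheno_df = pd.read_csv(phenotype_path, sep="\t", dtype={"sample": str}).set_index("sample")
    probe_map = pd.read_csv(probe_map_path, sep="\t", dtype=str)
    covars = pheno_df.drop(columns=["phenotype"])
    return ExpressionStudy(
        study_id=study_id,
        tissue=tissue,
        expression=expr,
        phenotype=pheno_df["phenotype"].astype(float),
        probe_map=probe_map,
        covariates=covars if len(covars.columns) else None,
        use_covariates=use_covariates,
    )
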