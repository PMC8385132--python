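"""Per-gene Z-scores: OLS reduction, mixed-model probes, calibration."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ldcoloc.diffexpr import (
    ExpressionStudy,
    family_history_zscore,
    gene_zscore,
    study_zscores,
)


def make_study(probe_values: dict, phenotype, probe_map=None, covariates=None, **kw):
    samples = [f"s{i}" for i in range(len(phenotype))]
    expr = pd.DataFrame(probe_values, index=samples).T
    expr.columns = samples
    if probe_map is None:
        probe_map = pd.DataFrame({"probe": list(probe_values), "gene": "GENE"})
    return ExpressionStudy(
        study_id="t",
        tissue="adipose",
        expression=expr,
        phenotype=pd.Series(phenotype, index=samples, dtype=float),
        probe_map=probe_map,
        covariates=covariates,
        **kw,
    )


def simulate_single_probe(rng, n=20, shift=0.0, sd=0.5):
    pheno = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    y = 8.0 + shift * pheno + rng.normal(0, sd, n)
    return make_study({"p1": y}, pheno)


class TestGeneZscore:
    def test_single_probe_equals_ols_t(self):
        rng = np.random.default_rng(0)
        study = simulate_single_probe(rng, shift=-1.0)
        eff = gene_zscore(study, "GENE")
        assert eff.model == "single-probe"
        y = study.expression.loc["p1"].to_numpy()
        X = sm.add_constant(study.phenotype.to_numpy())
        t = sm.OLS(y, X).fit().tvalues[1]
        assert eff.z == pytest.approx(t)
        assert eff.z < -3  # strongly negative for the planted down-shift

    def test_positive_z_means_up_in_cases(self):
        rng = np.random.default_rng(1)
        study = simulate_single_probe(rng, shift=+1.5)
        assert gene_zscore(study, "GENE").z > 3

    def test_multiprobe_close_to_probe_average_oracle(self):
        rng = np.random.default_rng(2)
        n = 30
        pheno = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        base = 8.0 - 0.8 * pheno + rng.normal(0, 0.4, n)
        probes = {
            f"p{k}": base + off + rng.normal(0, 0.3, n)
            for k, off in enumerate([-1.0, 0.0, 1.0])
        }
        study = make_study(probes, pheno,
                           probe_map=pd.DataFrame({"probe": list(probes), "gene": "GENE"}))
        eff = gene_zscore(study, "GENE")
        assert eff.model == "mixed" and eff.n_probes == 3
        avg = np.mean([probes[p] for p in probes], axis=0)
        z_avg = sm.OLS(avg, sm.add_constant(pheno)).fit().tvalues[1]
        assert eff.z == pytest.approx(z_avg, abs=0.2)

    def test_null_z_sd_near_one(self):
        rng = np.random.default_rng(3)
        zs = [gene_zscore(simulate_single_probe(rng), "GENE").z for _ in range(1000)]
        assert 0.9 <= np.std(zs) <= 1.1

    def test_invariance_to_probe_order_and_constant_shift(self):
        rng = np.random.default_rng(4)
        n = 20
        pheno = np.r_[np.zeros(10), np.ones(10)]
        probes = {f"p{k}": rng.normal(8, 1, n) - 0.5 * pheno for k in range(2)}
        pm = pd.DataFrame({"probe": ["p0", "p1"], "gene": "GENE"})
        z1 = gene_zscore(make_study(probes, pheno, probe_map=pm), "GENE").z
        swapped = {"p1": probes["p1"], "p0": probes["p0"]}
        z2 = gene_zscore(make_study(swapped, pheno, probe_map=pm.iloc[::-1]), "GENE").z
        shifted = {k: v + 100.0 for k, v in probes.items()}
        z3 = gene_zscore(make_study(shifted, pheno, probe_map=pm), "GENE").z
        assert z1 == pytest.approx(z2, abs=1e-6)
        assert z1 == pytest.approx(z3, abs=1e-4)

    def test_zero_phenotype_variance_errors(self):
        study = make_study({"p1": np.random.default_rng(0).normal(8, 1, 10)}, np.zeros(10))
        with pytest.raises(ValueError, match="zero variance"):
            gene_zscore(study, "GENE")

    def test_null_z_standard_normal_with_covariates(self):
        """With age/BMI covariates present, null z stays ~N(0,1)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(5)
        n = 24
        pheno = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        zs = []
        for _ in range(2000):
            age = rng.normal(50, 8, n) + 2 * pheno
            bmi = rng.normal(30, 4, n)
            samples = [f"s{i}" for i in range(n)]
            cov = pd.DataFrame({"age": age, "bmi": bmi}, index=samples)
            y = 8.0 + 0.01 * age + 0.02 * bmi + rng.normal(0, 0.5, n)
            study = make_study({"p1": y}, pheno, covariates=cov)
            zs.append(gene_zscore(study, "GENE").z)
        assert kstest(zs, "norm").pvalue > 0.01


class TestFamilyHistory:
    def fh_study(self, rng, slope=0.0):
        dosage = np.repeat([0.0, 1.0, 2.0], [10, 15, 10])
        y = 8.0 + slope * dosage + rng.normal(0, 0.4, len(dosage))
        return make_study({"p1": y}, dosage)

    def test_planted_per_parent_decrement_recovered(self):
        eff = family_history_zscore(self.fh_study(np.random.default_rng(0), -0.5), "GENE")
        assert eff.z < -3

    def test_null_dosage_rarely_extreme(self):
        rng = np.random.default_rng(1)
        zs = [family_history_zscore(self.fh_study(rng), "GENE").z for _ in range(1000)]
        assert np.mean(np.abs(zs) <= 3) >= 0.99

    def test_single_dosage_level_errors(self):
        study = make_study({"p1": np.random.default_rng(0).normal(8, 1, 10)}, np.ones(10))
        with pytest.raises(ValueError, match="distinct"):
            family_history_zscore(study, "GENE")

    def test_non_dosage_coding_rejected(self):
        study = make_study({"p1": np.random.default_rng(0).normal(8, 1, 10)},
                           np.r_[np.zeros(5), 3 * np.ones(5)])
        with pytest.raises(ValueError, match="0/1/2"):
            family_history_zscore(study, "GENE")


class TestStudyZscores:
    def build_multigene_study(self, rng, n_genes=30, n=20):
        pheno = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        probes, rows = {}, []
        for g in range(n_genes):
            gene = f"G{g:03d}"
            for k in range(rng.integers(1, 3)):
                pid = f"p{g}_{k}"
                probes[pid] = rng.normal(8, 1, n)
                rows.append((pid, gene))
        # one degenerate gene: constant expression
        probes["p_const"] = np.full(n, 5.0)
        rows.append(("p_const", "G_CONST"))
        pm = pd.DataFrame(rows, columns=["probe", "gene"])
        return make_study(probes, pheno, probe_map=pm)

    def test_all_genes_scored_degenerate_flagged(self):
        study = self.build_multigene_study(np.random.default_rng(0))
        tbl = study_zscores(study)
        assert len(tbl) == len(study.genes)
        flagged = tbl.loc[tbl["gene"] == "G_CONST"]
        assert flagged["model"].iloc[0] == "error"
        assert np.isnan(flagged["z"].iloc[0])
        assert tbl.loc[tbl["gene"] != "G_CONST", "z"].notna().all()

    def test_permuted_labels_decorrelate(self):
        rng = np.random.default_rng(1)
        n, n_genes = 40, 150
        pheno = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        probes = {f"p{g}": rng.normal(8, 1, n) - 0.7 * pheno for g in range(n_genes)}
        pm = pd.DataFrame({"probe": list(probes), "gene": [f"G{g}" for g in range(n_genes)]})
        study = make_study(probes, pheno, probe_map=pm)
        z_orig = study_zscores(study).set_index("gene")["z"]
        # a permutation orthogonal to the case/control labels, so residual
        # chance overlap of the labels does not masquerade as correlation
        while True:
            perm = rng.permutation(n)
            if abs(np.corrcoef(pheno, pheno[perm])[0, 1]) < 1e-9:
                break
        study_perm = make_study(
            {k: v[perm] for k, v in probes.items()}, pheno, probe_map=pm
        )
        z_perm = study_zscores(study_perm).set_index("gene")["z"]
        assert abs(np.corrcoef(z_orig, z_perm.loc[z_orig.index])[0, 1]) < 0.2

    def test_covariates_matter_only_when_confounded(self):
        rng = np.random.default_rng(2)
        n = 40
        pheno = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        samples = [f"s{i}" for i in range(n)]
        # confounded gene: expression driven by age, age differs by group
        age = rng.normal(50, 5, n) + 8 * pheno
        y_conf = 8.0 + 0.05 * age + rng.normal(0, 0.3, n)
        y_clean = 8.0 + rng.normal(0, 0.3, n)
        cov = pd.DataFrame({"age": age}, index=samples)
        pm = pd.DataFrame({"probe": ["pc", "pu"], "gene": ["CONF", "CLEAN"]})
        with_cov = make_study({"pc": y_conf, "pu": y_clean}, pheno, probe_map=pm,
                              covariates=cov)
        without = make_study({"pc": y_conf, "pu": y_clean}, pheno, probe_map=pm,
                             covariates=cov, use_covariates=False)
        d_conf = abs(gene_zscore(with_cov, "CONF").z - gene_zscore(without, "CONF").z)
        d_clean = abs(gene_zscore(with_cov, "CLEAN").z - gene_zscore(without, "CLEAN").z)
        assert d_conf > 1.0  # adjusting removes the spurious signal
        assert d_clean < 1.0
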