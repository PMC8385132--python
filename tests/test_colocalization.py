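"""Replicated loci, disease-eQTL calls, cis-gene assignment, NEMG flagging."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from ldcoloc import pipeline
from ldcoloc.colocalization import (
    Exclusion,
    LocationEstimate,
    ThresholdConfig,
    assign_cis_genes,
    call_t2d_eqtl,
    convert_population,
    flag_nemg,
    nemg_proportion_test,
    normalize_symbol,
    read_estimates,
    replicate_loci,
)
from ldcoloc.genetic_map import GeneticMap
from ldcoloc.synthetic_data import ScenarioConfig, generate_scenario


def disease(cohort, pos, p=1e-6, chrom="13", population="EUR"):
    return LocationEstimate("disease", cohort, population, chrom, pos, p)


def eqtl(target, pos, p=1e-3, chrom="13"):
    return LocationEstimate("expression", "MuTHER", "EUR", chrom, pos, p, target=target)


@pytest.fixture
def chr13_map():
    """Fixture map around the PCCA region: the two disease estimates
    (102408534, 102452781) fall inside one extended-LD block, with LD
    breakdown on either side."""
    return GeneticMap(
        "13",
        [102_000_000, 102_400_000, 102_480_000, 102_500_000, 103_000_000],
        [0.0, 5.0, 5.2, 8.0, 20.0],
    )


class TestConvertPopulation:
    def test_aa_estimate_gets_european_ldu_same_bp(self, chr13_map):
        est = disease("GWAS-A", 102_452_781, population="AA")
        out = convert_population(est, chr13_map)
        assert out.position == 102_452_781  # physical position unchanged
        assert out.ldu == pytest.approx(chr13_map.ldu_at(102_452_781))

    def test_identity_when_already_annotated(self, chr13_map):
        est = disease("GWAS-E", 102_408_534)
        once = convert_population(est, chr13_map)
        twice = convert_population(once, chr13_map)
        assert twice == once

    def test_position_beyond_map_yields_exclusion(self, chr13_map):
        out = convert_population(disease("GWAS-E", 104_000_000), chr13_map)
        assert isinstance(out, Exclusion)
        assert "extent" in out.reason


class TestReplicateLoci:
    def test_two_cohorts_in_one_block_form_cosmopolitan_locus(self, chr13_map):
        ests = [
            disease("GWAS-E", 102_408_534, p=1e-6),
            disease("GWAS-A", 102_452_781, p=1e-6, population="AA"),
        ]
        loci = replicate_loci(ests, {"13": chr13_map})
        assert len(loci) == 1
        assert loci[0].cosmopolitan
        assert loci[0].tier == "bonferroni"
        assert loci[0].position == 102_408_534  # most significant (tie: first)

    def test_same_cohort_twice_is_not_replication(self, chr13_map):
        ests = [disease("GWAS-E", 102_408_534), disease("GWAS-E", 102_452_781)]
        assert replicate_loci(ests, {"13": chr13_map}) == []

    def test_single_linkage_chains_three_cohorts(self):
        # uniform map; pairwise LDU distances 0.6 / 0.6 / 1.2
        gmap = GeneticMap("1", [0, 1_000_000], [0.0, 100.0])
        ests = [
            disease("A", 10_000, chrom="1"),
            disease("B", 16_000, chrom="1"),
            disease("C", 22_000, chrom="1"),
        ]
        # brute-force single-linkage oracle over all pairs
        def oracle_clusters(positions, thr):
            n = len(positions)
            parent = list(range(n))
            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i
            for i, j in itertools.combinations(range(n), 2):
                if abs(gmap.ldu_at(positions[i]) - gmap.ldu_at(positions[j])) <= thr:
                    parent[find(i)] = find(j)
            return len({find(i) for i in range(n)})

        assert oracle_clusters([10_000, 16_000, 22_000], 1.0) == 1
        loci = replicate_loci(ests, {"1": gmap})
        assert len(loci) == 1 and len(loci[0].members) == 3

    def test_estimates_without_map_are_excluded_with_reason(self, chr13_map):
        excl = []
        loci = replicate_loci(
            [disease("A", 100, chrom="5"), disease("B", 200, chrom="5")],
            {"13": chr13_map},
            exclusions=excl,
        )
        assert loci == []
        assert excl and "no LDU map" in excl[0].reason

    def test_empty_input_gives_empty_result(self, chr13_map):
        assert replicate_loci([], {"13": chr13_map}) == []

    def test_nominal_filter_applied(self, chr13_map):
        ests = [
            disease("GWAS-E", 102_408_534, p=0.01),  # above nominal 1e-3
            disease("GWAS-A", 102_452_781, p=1e-6),
        ]
        assert replicate_loci(ests, {"13": chr13_map}) == []


class TestCallT2DeQTL:
    def make_locus(self, chr13_map):
        return replicate_loci(
            [
                disease("GWAS-E", 102_408_534, p=1e-6),
                disease("GWAS-A", 102_452_781, p=1e-6, population="AA"),
            ],
            {"13": chr13_map},
        )

    def test_pcca_eqtl_between_members_is_called(self, chr13_map):
        loci = self.make_locus(chr13_map)
        calls = call_t2d_eqtl(loci, [eqtl("PCCA", 102_428_282)], {"13": chr13_map})
        assert len(calls) == 1
        assert calls[0].ldu_distance <= 1.0

    def test_distant_eqtl_not_called(self, chr13_map):
        loci = self.make_locus(chr13_map)
        # 102_496_000 is ~2.8 LDU past the block
        calls = call_t2d_eqtl(loci, [eqtl("X", 102_496_000)], {"13": chr13_map})
        assert calls == []

    def test_ldu_not_bp_decides(self):
        # locus member at 100_000 inside a long block [0, 200_000];
        # eQTL A: 90 kb away in bp but same block -> called;
        # eQTL B: 2.5 kb away in bp but across a sharp step -> not called
        gmap = GeneticMap("1", [0, 200_000, 201_000, 300_000], [0.0, 0.0, 4.0, 4.0])
        loci = replicate_loci(
            [disease("A", 100_000, chrom="1"), disease("B", 199_000, chrom="1")],
            {"1": gmap},
        )
        calls = call_t2d_eqtl(
            loci,
            [eqtl("near_in_ldu", 10_000, chrom="1"), eqtl("near_in_bp", 200_500, chrom="1")],
            {"1": gmap},
        )
        called = {c.eqtl.target for c in calls}
        assert called == {"near_in_ldu"}

    def test_nonsignificant_eqtl_filtered(self, chr13_map):
        loci = self.make_locus(chr13_map)
        calls = call_t2d_eqtl(loci, [eqtl("PCCA", 102_428_282, p=0.2)], {"13": chr13_map})
        assert calls == []


class TestAssignCisGenes:
    def annotation(self):
        return pd.DataFrame(
            {
                "chrom": ["13", "13", "6", "10"],
                "start": [102_400_000, 105_000_000, 112_750_000, 112_900_000],
                "end": [102_500_000, 105_050_000, 112_850_000, 112_960_000],
                "gene_id": ["PCCA", "FARAWAY", "GPAM", "GPAM"],
                "hgnc": ["PCCA", "FARAWAY", "GPAM", "GPAM"],
            }
        )

    def test_gene_supported_by_two_loci_is_one_call(self):
        # ~1 LDU per 100 kb: the paired estimates sit ~0.6 LDU apart
        maps = {
            "6": GeneticMap("6", [112_000_000, 113_500_000], [0.0, 15.0]),
            "10": GeneticMap("10", [112_000_000, 113_500_000], [0.0, 15.0]),
        }
        ests = [
            disease("GWAS-E", 112_808_197, chrom="6"),
            disease("GWAS-A", 112_750_188, chrom="6", population="AA"),
            disease("GWAS-E", 112_924_900, chrom="10"),
            disease("GWAS-A", 112_866_891, chrom="10", population="AA"),
        ]
        loci = replicate_loci(ests, maps)
        eqtls = [eqtl("GPAM", 112_800_751, chrom="6"), eqtl("GPAM", 112_917_454, chrom="10")]
        hits = call_t2d_eqtl(loci, eqtls, maps)
        calls = assign_cis_genes(hits, self.annotation(), cfg=ThresholdConfig())
        gpam = [c for c in calls if c.gene == "GPAM"]
        assert len(gpam) == 1  # one call despite support from two loci
        assert gpam[0].n_loci == 2

    def test_gene_outside_cis_window_excluded(self, chr13_map):
        loci = replicate_loci(
            [
                disease("GWAS-E", 102_408_534, p=1e-6),
                disease("GWAS-A", 102_452_781, p=1e-6),
            ],
            {"13": chr13_map},
        )
        hits = call_t2d_eqtl(loci, [eqtl("FARAWAY", 102_428_282)], {"13": chr13_map})
        excl = []
        calls = assign_cis_genes(hits, self.annotation(), exclusions=excl)
        assert calls == []
        assert excl and "cis window" in excl[0].reason

    def test_unresolvable_probe_logged(self, chr13_map):
        loci = replicate_loci(
            [disease("A", 102_408_534), disease("B", 102_452_781)], {"13": chr13_map}
        )
        hits = call_t2d_eqtl(loci, [eqtl("UNKNOWN_PROBE", 102_428_282)], {"13": chr13_map})
        excl = []
        calls = assign_cis_genes(hits, self.annotation(), exclusions=excl)
        assert calls == [] and "not in annotation" in excl[0].reason


class TestFlagNemg:
    def make_call(self, symbol):
        from ldcoloc.colocalization import CisGeneCall

        return CisGeneCall(gene=symbol, symbol=symbol)

    def test_direct_match(self):
        calls = [self.make_call("PCCA")]
        assert flag_nemg(calls, {"PCCA", "MCCC1"}) == 1
        assert calls[0].nemg

    def test_empty_list_zero_flags(self):
        calls = [self.make_call("PCCA")]
        assert flag_nemg(calls, set()) == 0
        assert not calls[0].nemg

    def test_excel_mangled_symbol_resolved(self):
        calls = [self.make_call("Mar-05")]
        assert flag_nemg(calls, {"MARCH5"}) == 1

    @pytest.mark.parametrize(
        "raw,expected",
        [("Mar-05", "MARCH5"), ("SEP-07", "SEPT7"), ("pcca", "PCCA"), ("MARCHF5", "MARCH5")],
    )
    def test_normalize_symbol(self, raw, expected):
        assert normalize_symbol(raw) == expected


class TestNemgProportionTest:
    def test_paper_scale_percentages(self):
        r = nemg_proportion_test(763, 50, 21_215, 1_155)
        assert round(r["cis_nemg_percent"], 1) == 6.6
        assert round(r["background_nemg_percent"], 1) == 5.4
        assert 0.05 < r["p_value"] < 0.5  # not significant

    def test_identical_proportions_p_one(self):
        r = nemg_proportion_test(100, 10, 1_000, 100)
        assert r["p_value"] == pytest.approx(1.0)

    def test_small_table_matches_enumeration(self):
        # 2x2 = [[3,7],[10,80]]; enumerate all tables with fixed margins
        a, b, c, d = 3, 7, 10, 80
        n1, n2, m1 = a + b, c + d, a + c
        def prob(x):
            return (
                comb(n1, x, exact=True)
                * comb(n2, m1 - x, exact=True)
                / comb(n1 + n2, m1, exact=True)
            )
        p_obs = prob(a)
        exact = sum(prob(x) for x in range(0, min(n1, m1) + 1) if prob(x) <= p_obs + 1e-12)
        r = nemg_proportion_test(a + b, a, c + d, c)
        assert r["p_value"] == pytest.approx(exact, rel=1e-9)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            nemg_proportion_test(5, 10, 100, 5)


class TestInvariantsAndRecovery:
    def test_bp_rescale_invariance(self, chr13_map):
        """Co-location is decided purely in LDU: warping the bp axis while
        preserving the (bp -> LDU) pairing leaves calls unchanged."""
        def warp(p):  # strictly monotone bp warp
            return 102_000_000 + (p - 102_000_000) * 2.0

        warped_map = GeneticMap(
            "13", [warp(p) for p in chr13_map.positions], chr13_map.cum_ldu
        )
        ests = [
            disease("GWAS-E", 102_408_534, p=1e-6),
            disease("GWAS-A", 102_452_781, p=1e-6),
        ]
        warped_ests = [
            disease(e.cohort, warp(e.position), p=e.p_value) for e in ests
        ]
        q = eqtl("PCCA", 102_428_282)
        loci = replicate_loci(ests, {"13": chr13_map})
        loci_w = replicate_loci(warped_ests, {"13": warped_map})
        calls = call_t2d_eqtl(loci, [q], {"13": chr13_map})
        calls_w = call_t2d_eqtl(
            loci_w, [eqtl("PCCA", warp(q.position))], {"13": warped_map}
        )
        assert len(loci) == len(loci_w) == 1
        assert len(calls) == len(calls_w) == 1
        assert calls[0].ldu_distance == pytest.approx(calls_w[0].ldu_distance)

    def test_threshold_monotonicity(self, default_scenario):
        scn = default_scenario
        res1 = pipeline.run_scenario(scn, ThresholdConfig(coloc_threshold=1.0), stages=("coloc",))
        res2 = pipeline.run_scenario(scn, ThresholdConfig(coloc_threshold=2.0), stages=("coloc",))
        assert {c.gene for c in res1.calls} <= {c.gene for c in res2.calls}

    def test_referential_closure(self, default_scenario):
        res = pipeline.run_scenario(default_scenario, stages=("coloc",))
        for call in res.calls:
            assert call.supporting
            for s in call.supporting:
                assert len(s.locus.members) >= 2
                assert s.ldu_distance <= 1.0

    def test_planted_recovery(self, default_scenario):
        """Planted loci (jitter 0.2 LDU) recovered; decoys >= 3 LDU away
        produce no false calls: sensitivity >= 0.9, false fraction <= 0.1."""
        res = pipeline.run_scenario(default_scenario, stages=("coloc",))
        score = pipeline.truth_score(res, default_scenario)
        assert score["locus_sensitivity"] >= 0.9
        assert score["locus_false_fraction"] <= 0.1
        assert score["cis_gene_sensitivity"] >= 0.9
        assert score["cis_gene_false_fraction"] <= 0.1


class TestEstimateIO:
    def test_round_trip(self, tmp_path):
        text = (
            "trait\tcohort\tpopulation\tchrom\tpos_bp\tp_value\ttarget\n"
            "disease\tGWAS-E\tEUR\t13\t102408534\t1e-06\t\n"
            "expression\tMuTHER\tEUR\t13\t102428282\t0.001\tPCCA\n"
        )
        ests = read_estimates(io.StringIO(text))
        assert ests[0].trait == "disease" and ests[0].target is None
        assert ests[1].target == "PCCA"

    def test_invalid_p_value_rejected(self):
        with pytest.raises(ValueError, match="p_value"):
            LocationEstimate("disease", "A", "EUR", "1", 100, 0.0)
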