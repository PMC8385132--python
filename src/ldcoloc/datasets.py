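"""Packaged reference data.

``cis_nemg_locations.tsv`` is the curated listing of the 50 cis-regulated
nuclear-encoded mitochondrial genes identified by LDU-based colocalization of
T2D association signals (WTCCC1 European, WTCCC2 MetaboChip European, NIDDK
African American cohorts) with MuTHER subcutaneous-adipose eQTL, with the b37
causal-variant location estimates per cohort and the eQTL location per gene.
An empty cohort cell means the signal did not replicate in that cohort;
``NA`` means the region had SNP coverage too low to analyse.  One symbol
(*MARCH5*) appears in its spreadsheet-mangled form ``Mar-05`` exactly as
curated upstream; :func:`ldcoloc.colocalization.normalize_symbol` undoes it.

``mito_pathway_sets.gmt`` holds the four focal mitochondrial pathway sets
(KEGG branched-chain amino-acid degradation, propanoate and butanoate
metabolism, and the manually-defined biotin-dependent carboxylase genes).

The module also exposes the published discovery-scale counts used as inputs
to the summary arithmetic (cis-gene totals, locus counts, the annotated
array background); they are inputs to :func:`ldcoloc.pipeline.summarize_counts`
and the NEMG proportion test, not quantities this package re-estimates.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .colocalization import normalize_symbol
from .gsea import GeneSet, read_gmt

__all__ = [
    "load_cis_nemg_table",
    "cis_nemg_symbols",
    "load_focal_pathway_sets",
    "REFERENCE_COUNTS",
]

# Discovery-scale counts from the original LDU-mapping analysis (inputs).
REFERENCE_COUNTS = {
    "n_replicated_loci": 174,
    "n_loci_with_calls": 167,
    "n_cis_genes": 763,
    "n_cis_nemgs": 50,
    "n_european_specific_loci": 59,
    "n_cosmopolitan_loci": 108,
    "background_genes": 21_215,  # all genes annotated to the eQTL array
    "background_nemgs": 1_155,  # NEMGs among the annotated array genes
}


def _data(name: str):
    return resources.files("ldcoloc.data").joinpath(name)


def load_cis_nemg_table() -> pd.DataFrame:
    """The curated 50 cis-NEMG location table (one row per locus-eQTL pair)."""
    with resources.as_file(_data("cis_nemg_locations.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def cis_nemg_symbols(normalized: bool = True) -> list[str]:
    """The 50 distinct cis-NEMG symbols, optionally alias-normalized."""
    symbols = load_cis_nemg_table()["cis_nemg"]
    out = {normalize_symbol(s) if normalized else s for s in symbols}
    return sorted(out)


def load_focal_pathway_sets() -> list[GeneSet]:
    """The four focal mitochondrial pathway gene sets."""
    with resources.as_file(_data("mito_pathway_sets.gmt")) as path:
        return read_gmt(path)
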