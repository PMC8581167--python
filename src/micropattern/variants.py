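"""Rare/deleterious nsSNV selection and cell-line categorisation.

A candidate non-synonymous SNV qualifies when it is rare — minor allele
frequency below 0.005 in both the 1000 Genomes and ExAC population
databases AND carried by fewer than five lines of the iPSC bank — and
predicted deleterious by Condel. All inequalities are strict. Lines are
then categorised by where their qualifying variants fall: genes related to
cell adhesion, to germ-layer differentiation, both, or neither (controls).

Condel and DUET scores are consumed as input annotations; they are never
computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GeneSet", "DEFAULT_GENE_SETS", "MAF_THRESHOLD", "MAX_HIPSCI_LINES",
           "filter_rare", "filter_deleterious", "classify_lines", "summarize",
           "read_variant_table"]

MAF_THRESHOLD = 0.005     # strict: MAF must be < this in both databases
MAX_HIPSCI_LINES = 5      # strict: carried by fewer than this many lines


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set must be non-empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


DEFAULT_GENE_SETS = {
    "cell_adhesion": GeneSet("cell_adhesion", frozenset({"ITGB1", "ITGA6", "FHL2"})),
    "germ_layer": GeneSet("germ_layer", frozenset({"SMAD2", "FGFR1", "TBXT"})),
}

REQUIRED_COLUMNS = ["gene", "maf_1000g", "maf_exac", "n_hipsci_lines", "condel_class"]


def _check_mafs(variants: pd.DataFrame) -> None:
    for col in ("maf_1000g", "maf_exac"):
        vals = variants[col]
        bad = vals.notna() & ((vals < 0) | (vals > 1))
        if bad.any():
            idx = variants.index[bad][0]
            raise ValueError(
                f"malformed MAF in column {col} for record {idx} "
                f"(gene {variants.loc[idx, 'gene']}): {vals.loc[idx]}")


def filter_rare(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep variants rare in both population databases and in the line bank.

    MAF < 0.005 in 1000 Genomes AND in ExAC, AND carried by fewer than five
    lines. Missing MAF counts as failing the rarity test (conservative) and
    is logged.
    """
    _check_mafs(variants)
    missing = variants["maf_1000g"].isna() | variants["maf_exac"].isna()
    if missing.any():
        logger.warning("%d variants with missing MAF treated as not rare", int(missing.sum()))
    keep = ((variants["maf_1000g"] < MAF_THRESHOLD)
            & (variants["maf_exac"] < MAF_THRESHOLD)
            & (variants["n_hipsci_lines"] < MAX_HIPSCI_LINES))
    return variants[keep.fillna(False)].reset_index(drop=True)


def filter_deleterious(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep Condel-deleterious variants; missing predictions drop with a warning."""
    missing = variants["condel_class"].isna() | (variants["condel_class"] == "missing")
    if missing.any():
        logger.warning("%d variants without Condel prediction dropped", int(missing.sum()))
    return variants[(variants["condel_class"] == "deleterious")].reset_index(drop=True)


def _carrier_lines(row: pd.Series) -> list[str]:
    raw = row.get("carrier_lines", "")
    if pd.isna(raw) or not str(raw).strip():
        return []
    return [s.strip() for s in str(raw).split(";") if s.strip()]


def classify_lines(qualifying: pd.DataFrame,
                   gene_sets: dict[str, GeneSet] | None = None,
                   outlier_flags: dict[str, bool] | None = None) -> pd.DataFrame:
    """Categorise lines by their qualifying variants' gene-set membership.

    Categories: ``adhesion`` (qualifying variant in a cell-adhesion gene
    only), ``germ_layer`` (germ-layer gene only), ``both``, ``control`` (no
    qualifying variant in either set). Phenotypic outlier flags, when
    supplied, are carried through; a line flagged as a phenotypic outlier
    that carries no qualifying variant is logged as an inconsistency, not an
    error.
    """
    gene_sets = gene_sets or DEFAULT_GENE_SETS
    adhesion = gene_sets["cell_adhesion"]
    germ = gene_sets["germ_layer"]
    flags = outlier_flags or {}
    hits: dict[str, set[str]] = {line: set() for line in flags}
    for _, row in qualifying.iterrows():
        for line in _carrier_lines(row):
            hits.setdefault(line, set())
            if row["gene"] in adhesion:
                hits[line].add("adhesion")
            if row["gene"] in germ:
                hits[line].add("germ_layer")
    rows = []
    for line in sorted(hits):
        sets = hits[line]
        if {"adhesion", "germ_layer"} <= sets:
            cat = "both"
        elif "adhesion" in sets:
            cat = "adhesion"
        elif "germ_layer" in sets:
            cat = "germ_layer"
        else:
            cat = "control"
        flagged = bool(flags.get(line, False))
        if flagged and cat == "control":
            logger.warning("line %s is a phenotypic outlier but has no qualifying "
                           "variant in either gene set", line)
        rows.append({"line": line, "category": cat, "phenotypic_outlier": flagged})
    return pd.DataFrame(rows, columns=["line", "category", "phenotypic_outlier"])


def summarize(variants: pd.DataFrame) -> dict[str, int]:
    """Distinct counts: variants, carrier lines, donors."""
    if variants.empty:
        return {"n_variants": 0, "n_lines": 0, "n_donors": 0}
    keys = variants[["gene", "substitution"]].apply(tuple, axis=1) \
        if "substitution" in variants.columns else variants["gene"]
    lines: set[str] = set()
    for _, row in variants.iterrows():
        lines.update(_carrier_lines(row))
    if "donor" in variants.columns:
        donors = set(variants["donor"].dropna())
    else:
        # HipSci convention: clonal lines of a donor share the 4-letter prefix
        donors = {ln.split("_")[0] for ln in lines}
    return {"n_variants": int(keys.nunique()), "n_lines": len(lines),
            "n_donors": len(donors)}


def read_variant_table(path) -> pd.DataFrame:
    """Read a tab-separated annotated variant table; validates required columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing required columns: {missing}")
    return df
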