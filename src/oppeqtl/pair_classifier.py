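"""The core procedure: 2×2 per-gene per-tissue-pair analysis tables.

For a gene significant in two tissues x and y, let SNP-x / SNP-y be the
top-eQTL-SNPs of the gene in each tissue and β_ij the effect of SNP-i on the
gene in tissue-j, with 0 encoding "not significant in that tissue".  The
table is eligible when the SNPs are identical or at least one of them is
significant in both tissues.  Direction is *opposite* iff

    β_xx·β_xy ≤ 0  and  β_yx·β_yy ≤ 0

(zero cross-terms satisfy "≤ 0"), and the four groups are

    1a: opposite, r² > 0.8      1b: opposite, r² ≤ 0.8
    2a: same,     r² > 0.8      2b: same,     r² ≤ 0.8

with r² between SNP-x and SNP-y over the reference panel (1 when
identical).  Genes/SNPs in any 1a or 2a table are the multi-eQTL sets;
those in any 1a table are the opp-multi-eQTL sets.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from . import ld_engine
from .eqtl_io import SignificanceIndex, TissueTable, TopEqtlMap

INELIGIBLE = "ineligible"   # gene lacks a significant signal in one tissue
EXCLUDED = "excluded"       # distinct top SNPs, neither cross-significant
GROUP_1A = "1a"
GROUP_1B = "1b"
GROUP_2A = "2a"
GROUP_2B = "2b"
GROUPS = (GROUP_1A, GROUP_1B, GROUP_2A, GROUP_2B)
MULTI_GROUPS = frozenset({GROUP_1A, GROUP_2A})

OPPOSITE = "opposite"
SAME = "same"


@dataclass
class AnalysisTable:
    """One gene's 2×2 direction/LD analysis for one unordered tissue pair."""

    gene_id: str
    tissue_x: str
    tissue_y: str
    snp_x: str = ""
    snp_y: str = ""
    beta_xx: float = 0.0
    beta_xy: float = 0.0
    beta_yx: float = 0.0
    beta_yy: float = 0.0
    pval_x: float = math.nan   # top-SNP p-value in tissue_x
    pval_y: float = math.nan   # top-SNP p-value in tissue_y
    r2: float | None = None
    status: str = INELIGIBLE


def build_analysis_table(gene_id: str, tissue_x: str, tissue_y: str,
                         top: TopEqtlMap,
                         sig: SignificanceIndex) -> AnalysisTable:
    """Fill the 2×2 β table for one gene and tissue pair (no LD yet).

    ``status`` is ``ineligible`` when the gene has no significant signal in
    one of the tissues (β_xx = 0 or β_yy = 0); LD grouping is applied later
    by :func:`classify_tables`.
    """
    t = AnalysisTable(gene_id, tissue_x, tissue_y)
    per = top.entries.get(gene_id, {})
    ex, ey = per.get(tissue_x), per.get(tissue_y)
    if ex is None or ey is None:
        return t
    t.snp_x, t.snp_y = ex.rsid, ey.rsid
    t.beta_xx, t.pval_x = ex.beta, ex.pval
    t.beta_yy, t.pval_y = ey.beta, ey.pval
    if t.snp_x == t.snp_y:
        # identical top SNP: cross cells are the own cells by construction
        t.beta_xy, t.beta_yx = t.beta_yy, t.beta_xx
        t.r2 = 1.0
    else:
        t.beta_xy = sig.beta(tissue_y, gene_id, t.snp_x)
        t.beta_yx = sig.beta(tissue_x, gene_id, t.snp_y)
    t.status = "pending"
    return t


def eligibility(table: AnalysisTable) -> bool:
    """Identical top SNPs, or at least one of them significant in both tissues."""
    if table.beta_xx == 0.0 or table.beta_yy == 0.0:
        raise ValueError("eligibility is undefined for ineligible tables")
    return (table.snp_x == table.snp_y
            or table.beta_xy != 0.0 or table.beta_yx != 0.0)


def classify_direction(table: AnalysisTable) -> str:
    """``opposite`` iff β_xx·β_xy ≤ 0 and β_yx·β_yy ≤ 0, else ``same``."""
    if (table.beta_xx * table.beta_xy <= 0.0
            and table.beta_yx * table.beta_yy <= 0.0):
        return OPPOSITE
    return SAME


def assign_group(direction: str, r2: float | None,
                 threshold: float = ld_engine.DEFAULT_R2_THRESHOLD) -> str:
    """Map (direction, r²) to group 1a/1b/2a/2b; undefined r² = not in LD."""
    strong = r2 is not None and r2 > threshold
    if direction == OPPOSITE:
        return GROUP_1A if strong else GROUP_1B
    return GROUP_2A if strong else GROUP_2B


def classify_tables(top: TopEqtlMap, tables: Iterable[TissueTable],
                    panel: ld_engine.HaplotypePanel,
                    threshold: float = ld_engine.DEFAULT_R2_THRESHOLD,
                    ) -> list[AnalysisTable]:
    """Build and classify every (gene, unordered tissue pair) analysis table.

    One table per (gene, unordered tissue pair) — genes × C(n_tissues, 2)
    in total, in deterministic sorted order; tables for pairs where the gene
    lacks a significant signal in either tissue stay ``ineligible``.
    """
    tables = list(tables)
    sig = SignificanceIndex(tables)
    tissue_order = sorted(t.tissue for t in tables)
    out: list[AnalysisTable] = []
    r2_cache: dict[tuple[str, str], float | None] = {}
    for gene_id in sorted(top.entries):
        for tx, ty in itertools.combinations(tissue_order, 2):
            t = build_analysis_table(gene_id, tx, ty, top, sig)
            if t.status == INELIGIBLE:
                out.append(t)
                continue
            if not eligibility(t):
                t.status = EXCLUDED
                out.append(t)
                continue
            if t.r2 is None:  # distinct SNPs: compute panel r² (cached)
                key = (t.snp_x, t.snp_y) if t.snp_x < t.snp_y else (t.snp_y, t.snp_x)
                if key not in r2_cache:
                    r2_cache[key] = ld_engine.r2(key[0], key[1], panel).r2
                t.r2 = r2_cache[key]
            t.status = assign_group(classify_direction(t), t.r2, threshold)
            out.append(t)
    return out


@dataclass
class DesignationSets:
    """Nested designations: opp ⊆ multi ⊆ all, for genes and top SNPs.

    ``gene_evidence`` / ``snp_evidence`` keep, for every designated gene/SNP,
    every qualifying (tissue_x, tissue_y, group) pair — needed for per-tissue
    counting downstream.
    """

    eqtl_genes: set[str]
    top_eqtl_snps: set[str]
    multi_genes: set[str]
    multi_snps: set[str]
    opp_genes: set[str]
    opp_snps: set[str]
    gene_evidence: dict[str, list[tuple[str, str, str]]]
    snp_evidence: dict[str, list[tuple[str, str, str]]]
    per_tissue_eqtl_genes: dict[str, set[str]]
    multi_pairs: set[tuple[str, str]] = field(default_factory=set)
    opp_pairs: set[tuple[str, str]] = field(default_factory=set)

    @property
    def n_multi_pairs(self) -> int:
        return len(self.multi_pairs)

    @property
    def n_opp_pairs(self) -> int:
        return len(self.opp_pairs)

    def __post_init__(self) -> None:
        if not (self.opp_genes <= self.multi_genes <= self.eqtl_genes):
            raise AssertionError("gene designation chain violated")
        if not (self.opp_snps <= self.multi_snps <= self.top_eqtl_snps):
            raise AssertionError("SNP designation chain violated")

    def summary(self) -> dict:
        return {
            "n_eqtl_genes": len(self.eqtl_genes),
            "n_top_eqtl_snps": len(self.top_eqtl_snps),
            "n_multi_genes": len(self.multi_genes),
            "n_multi_snps": len(self.multi_snps),
            "n_opp_genes": len(self.opp_genes),
            "n_opp_snps": len(self.opp_snps),
            "n_multi_pairs": self.n_multi_pairs,
            "n_opp_pairs": self.n_opp_pairs,
        }

    def to_json(self, path) -> None:
        payload = self.summary() | {
            "multi_genes": sorted(self.multi_genes),
            "multi_snps": sorted(self.multi_snps),
            "opp_genes": sorted(self.opp_genes),
            "opp_snps": sorted(self.opp_snps),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def aggregate_designations(analysis_tables: Iterable[AnalysisTable],
                           top: TopEqtlMap) -> DesignationSets:
    """Collapse classified tables into the nested gene/SNP designation sets.

    A gene (and both its top SNPs) is *multi* if any of its tables is in
    group 1a or 2a, and *opp* if any is in group 1a — i.e., opposite effects
    detected in at least one tissue pair.
    """
    gene_evidence: dict[str, list[tuple[str, str, str]]] = {}
    snp_evidence: dict[str, list[tuple[str, str, str]]] = {}
    multi_genes: set[str] = set()
    multi_snps: set[str] = set()
    opp_genes: set[str] = set()
    opp_snps: set[str] = set()
    multi_pairs: set[tuple[str, str]] = set()
    opp_pairs: set[tuple[str, str]] = set()
    for t in analysis_tables:
        if t.status not in MULTI_GROUPS:
            continue
        ev = (t.tissue_x, t.tissue_y, t.status)
        gene_evidence.setdefault(t.gene_id, []).append(ev)
        multi_genes.add(t.gene_id)
        for s in (t.snp_x, t.snp_y):
            snp_evidence.setdefault(s, []).append(ev)
            multi_snps.add(s)
            multi_pairs.add((t.gene_id, s))
        if t.status == GROUP_1A:
            opp_genes.add(t.gene_id)
            opp_snps.update((t.snp_x, t.snp_y))
            opp_pairs.update({(t.gene_id, t.snp_x), (t.gene_id, t.snp_y)})
    return DesignationSets(
        eqtl_genes=top.genes(),
        top_eqtl_snps=top.all_top_snps(),
        multi_genes=multi_genes,
        multi_snps=multi_snps,
        opp_genes=opp_genes,
        opp_snps=opp_snps,
        gene_evidence=gene_evidence,
        snp_evidence=snp_evidence,
        per_tissue_eqtl_genes=top.per_tissue_gene_sets(),
        multi_pairs=multi_pairs,
        opp_pairs=opp_pairs,
    )


def count_analysis_tables(n_genes: int, n_tissues: int) -> int:
    """Total analysis tables for a cohort: n_genes × C(n_tissues, 2)."""
    return n_genes * math.comb(n_tissues, 2)


def tables_to_frame(analysis_tables: Iterable[AnalysisTable]) -> pd.DataFrame:
    rows = [(t.gene_id, t.tissue_x, t.tissue_y, t.snp_x, t.snp_y,
             t.beta_xx, t.beta_xy, t.beta_yx, t.beta_yy,
             t.pval_x, t.pval_y,
             float("nan") if t.r2 is None else t.r2, t.status)
            for t in analysis_tables]
    return pd.DataFrame(rows, columns=[
        "gene_id", "tissue_x", "tissue_y", "snp_x", "snp_y",
        "beta_xx", "beta_xy", "beta_yx", "beta_yy",
        "pval_x", "pval_y", "r2", "status"])
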