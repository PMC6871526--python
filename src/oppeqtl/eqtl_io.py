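"""Reading, filtering and indexing per-tissue significant cis-eQTL tables.

The input dialect is the tab-separated "significant variant-gene pairs"
format used by multi-tissue eQTL releases: one row per significant
association, columns ``gene_id``, ``variant_id`` (``chr_pos_ref_alt_build``),
``rs_id_dbSNP``, ``tss_distance``, ``slope`` and ``pval_nominal``.
Significance is extensional: a (gene, SNP, tissue) triple is significant iff
it appears in that tissue's file; no threshold is re-derived here.

Coordinates are 1-based GRCh37 throughout and ``tss_distance`` is taken
verbatim from the input (negative = upstream of the TSS in gene
orientation); no gene model is consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

REQUIRED_COLUMNS = (
    "gene_id",
    "variant_id",
    "rs_id_dbSNP",
    "tss_distance",
    "slope",
    "pval_nominal",
)

#: cis window: a variant more than 1 Mbp from the TSS is not a cis candidate.
CIS_WINDOW_BP = 1_000_000

_BASES = frozenset("ACGT")


class VariantKey(NamedTuple):
    """Parsed ``chr_pos_ref_alt_build`` variant identifier."""

    chrom: str
    pos: int
    ref: str
    alt: str
    build: str

    def __str__(self) -> str:  # round-trips the input key
        return f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}_{self.build}"


def parse_variant_key(key: str) -> VariantKey:
    """Parse a ``chr_pos_ref_alt_build`` string.

    Raises ``ValueError`` if the key does not have five underscore-separated
    fields or the position is not a positive integer.
    """
    parts = key.split("_")
    if len(parts) != 5:
        raise ValueError(f"variant key {key!r} is not chr_pos_ref_alt_build")
    chrom, pos_s, ref, alt, build = parts
    pos = int(pos_s)
    if pos <= 0:
        raise ValueError(f"variant key {key!r} has non-positive position")
    return VariantKey(chrom, pos, ref.upper(), alt.upper(), build)


def is_biallelic_snp(key: str) -> bool:
    """True iff the key parses and ref/alt are single A/C/G/T bases."""
    try:
        vk = parse_variant_key(key)
    except (ValueError, TypeError):
        return False
    return vk.ref in _BASES and vk.alt in _BASES and vk.ref != vk.alt


class EqtlRecord(NamedTuple):
    """One significant variant-gene association in one tissue."""

    gene_id: str
    variant_key: str
    rsid: str
    tissue: str
    beta: float
    pval: float
    tss_distance: int


@dataclass
class TissueTable:
    """Significant cis-eQTL records for one tissue.

    ``df`` holds one row per record with columns ``gene_id``, ``variant_key``,
    ``rsid``, ``beta``, ``pval``, ``tss_distance``.  (gene_id, variant_key) is
    unique within the table.
    """

    tissue: str
    df: pd.DataFrame
    organ_system: str = ""
    n_rejected: int = 0

    def __post_init__(self) -> None:
        dup = self.df.duplicated(subset=["gene_id", "variant_key"])
        if dup.any():
            pair = self.df.loc[dup.idxmax(), ["gene_id", "variant_key"]]
            raise ValueError(
                f"duplicate (gene, variant) in tissue {self.tissue}: "
                f"{pair.gene_id}/{pair.variant_key}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[EqtlRecord]:
        return [
            EqtlRecord(r.gene_id, r.variant_key, r.rsid, self.tissue,
                       float(r.beta), float(r.pval), int(r.tss_distance))
            for r in self.df.itertuples(index=False)
        ]

    def genes(self) -> set[str]:
        return set(self.df["gene_id"])


class TopEntry(NamedTuple):
    rsid: str
    variant_key: str
    beta: float
    pval: float
    tss_distance: int


@dataclass
class TopEqtlMap:
    """gene_id -> tissue -> the single top-eQTL-SNP for that (gene, tissue).

    The top SNP is the significant record with the smallest nominal p-value;
    ties are broken by byte-wise string order of the rsID (so "rs10" < "rs2").
    """

    entries: dict[str, dict[str, TopEntry]] = field(default_factory=dict)

    def genes(self) -> set[str]:
        return set(self.entries)

    def tissues_for_gene(self, gene_id: str) -> list[str]:
        return sorted(self.entries.get(gene_id, {}))

    def all_top_snps(self) -> set[str]:
        return {e.rsid for per in self.entries.values() for e in per.values()}

    def per_tissue_gene_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, per in self.entries.items():
            for tissue in per:
                out.setdefault(tissue, set()).add(gene)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, t, e.rsid, e.variant_key, e.beta, e.pval, e.tss_distance)
            for g, per in sorted(self.entries.items())
            for t, e in sorted(per.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["gene_id", "tissue", "rsid", "variant_key", "beta",
                     "pval", "tss_distance"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TopEqtlMap":
        entries: dict[str, dict[str, TopEntry]] = {}
        for r in df.itertuples(index=False):
            entries.setdefault(r.gene_id, {})[r.tissue] = TopEntry(
                r.rsid, r.variant_key, float(r.beta), float(r.pval),
                int(r.tss_distance))
        return cls(entries)


def _validate_columns(df: pd.DataFrame, path: str) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")


def load_significant_pairs(path, tissue: str,
                           organ_system: str = "") -> TissueTable:
    """Read one tissue's significant-pair TSV into a :class:`TissueTable`.

    Rows failing any of the record invariants are rejected and counted in
    ``TissueTable.n_rejected``: non-finite or non-positive p-value, β exactly
    0 (0 is reserved downstream to encode "not significant"), |tss_distance|
    beyond the 1 Mbp cis window, a variant key that is not a parseable
    biallelic SNP, or a missing rsID.  A missing mandatory column or an empty
    table is a hard error; a duplicated (gene, variant) pair is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    _validate_columns(df, str(path))
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")

    beta = pd.to_numeric(df["slope"], errors="coerce")
    pval = pd.to_numeric(df["pval_nominal"], errors="coerce")
    tss = pd.to_numeric(df["tss_distance"], errors="coerce")
    rsid = df["rs_id_dbSNP"].fillna("").str.strip()

    ok = (
        beta.notna() & (beta != 0.0)
        & pval.notna() & (pval > 0.0) & (pval <= 1.0)
        & tss.notna() & (tss.abs() <= CIS_WINDOW_BP)
        & rsid.ne("") & rsid.ne(".")
        & df["variant_id"].map(is_biallelic_snp)
        & df["gene_id"].notna()
    )
    clean = pd.DataFrame({
        "gene_id": df.loc[ok, "gene_id"],
        "variant_key": df.loc[ok, "variant_id"],
        "rsid": rsid[ok],
        "beta": beta[ok],
        "pval": pval[ok],
        "tss_distance": tss[ok].astype(int),
    }).reset_index(drop=True)
    return TissueTable(tissue=tissue, df=clean, organ_system=organ_system,
                       n_rejected=int((~ok).sum()))


def write_tissue_table(table: TissueTable, path) -> None:
    """Write a table back in the input dialect (round-trips the rows)."""
    out = pd.DataFrame({
        "gene_id": table.df["gene_id"],
        "variant_id": table.df["variant_key"],
        "rs_id_dbSNP": table.df["rsid"],
        "tss_distance": table.df["tss_distance"],
        "slope": table.df["beta"],
        "pval_nominal": table.df["pval"],
    })
    out.to_csv(path, sep="\t", index=False)


@dataclass
class FilterReport:
    n_input: int
    n_indel_or_nonsnp: int
    n_multiallelic: int
    n_not_in_panel: int
    n_kept: int


def filter_variants(table: TissueTable, panel_keys: set[str],
                    multiallelic: set[str] | frozenset[str] = frozenset(),
                    ) -> tuple[TissueTable, FilterReport]:
    """Keep only biallelic SNPs present in the reference panel.

    Removal categories mirror the usual reference-panel harmonisation: indels
    / non-SNP keys, variants flagged multi-allelic, and variants absent from
    the panel.  A record is tallied in the first category it violates.
    Filtering is idempotent; an empty result is allowed.
    """
    keys = table.df["variant_key"]
    snp_ok = keys.map(is_biallelic_snp)
    multi = keys.isin(multiallelic) & snp_ok
    in_panel = keys.isin(panel_keys)
    keep = snp_ok & ~multi & in_panel
    report = FilterReport(
        n_input=len(table.df),
        n_indel_or_nonsnp=int((~snp_ok).sum()),
        n_multiallelic=int(multi.sum()),
        n_not_in_panel=int((snp_ok & ~multi & ~in_panel).sum()),
        n_kept=int(keep.sum()),
    )
    out = TissueTable(
        tissue=table.tissue,
        df=table.df.loc[keep].reset_index(drop=True),
        organ_system=table.organ_system,
        n_rejected=table.n_rejected,
    )
    return out, report


def extract_top_eqtl(tables: Iterable[TissueTable]) -> TopEqtlMap:
    """Select the top-eQTL-SNP for every (gene, tissue) with ≥1 record.

    Minimum nominal p-value wins; exact p ties are broken by plain byte-wise
    string order of the rsID.
    """
    entries: dict[str, dict[str, TopEntry]] = {}
    for table in tables:
        if len(table.df) == 0:
            continue
        best = (
            table.df.sort_values(["pval", "rsid"], kind="mergesort")
            .drop_duplicates("gene_id", keep="first")
        )
        for r in best.itertuples(index=False):
            entries.setdefault(r.gene_id, {})[table.tissue] = TopEntry(
                r.rsid, r.variant_key, float(r.beta), float(r.pval),
                int(r.tss_distance))
    return TopEqtlMap(entries)


class SignificanceIndex:
    """Fast β lookup: (tissue, gene_id, rsid) -> β, 0.0 when not significant."""

    def __init__(self, tables: Iterable[TissueTable]):
        self._beta: dict[tuple[str, str, str], float] = {}
        self.tissues: list[str] = []
        for t in tables:
            self.tissues.append(t.tissue)
            for r in t.df.itertuples(index=False):
                self._beta[(t.tissue, r.gene_id, r.rsid)] = float(r.beta)

    def beta(self, tissue: str, gene_id: str, rsid: str) -> float:
        return self._beta.get((tissue, gene_id, rsid), 0.0)
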