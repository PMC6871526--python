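"""Per-tissue designation statistics, the opposite-fraction matrix and
tissue clustering, and the paired p-value deviation densities.

The opposite-fraction matrix compares, for every unordered tissue pair, the
signed effects of all (gene, SNP) records significant in *both* tissues and
reports the proportion with strictly opposite β signs.  The sharing unit is
the (gene, SNP) record rather than the bare SNP, because one SNP can be an
eQTL for several genes with different signs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .eqtl_io import TissueTable
from .pair_classifier import AnalysisTable, DesignationSets, GROUP_1A, MULTI_GROUPS


@dataclass
class TissueSummary:
    """Per-tissue gene counts/ratios plus cohort-level dispersion statistics."""

    table: pd.DataFrame              # index: tissue
    cv: dict[str, float]             # sample CV per count column
    pearson: dict[str, float]        # correlations between ratio columns
    undefined_tissues: list[str]     # tissues with 0 eQTL genes (ratios NaN)


def _sample_cv(x: pd.Series) -> float:
    x = x.dropna()
    m = x.mean()
    return float(x.std(ddof=1) / m) if len(x) > 1 and m != 0 else float("nan")


def per_tissue_counts(designations: DesignationSets) -> TissueSummary:
    """Count eQTL-, multi- and opp-multi genes per tissue with ratios.

    A gene tallies for a tissue's multi (opp) count iff that tissue
    participates in at least one qualifying group-1a/2a (group-1a) pair for
    the gene.  CV is the sample (n−1) standard deviation over tissues divided
    by the mean; Pearson correlations relate the three ratio columns.
    """
    tissues = sorted(designations.per_tissue_eqtl_genes)
    multi_by_tissue: dict[str, set[str]] = {t: set() for t in tissues}
    opp_by_tissue: dict[str, set[str]] = {t: set() for t in tissues}
    for gene, evs in designations.gene_evidence.items():
        for tx, ty, grp in evs:
            for t in (tx, ty):
                multi_by_tissue.setdefault(t, set()).add(gene)
                if grp == GROUP_1A:
                    opp_by_tissue.setdefault(t, set()).add(gene)
    rows = []
    undefined = []
    for t in tissues:
        n_eqtl = len(designations.per_tissue_eqtl_genes[t])
        n_multi = len(multi_by_tissue[t])
        n_opp = len(opp_by_tissue[t])
        if n_eqtl == 0:
            undefined.append(t)
        rows.append({
            "tissue": t,
            "n_eqtl_genes": n_eqtl,
            "n_multi_genes": n_multi,
            "n_opp_genes": n_opp,
            "multi_over_eqtl": n_multi / n_eqtl if n_eqtl else np.nan,
            "opp_over_eqtl": n_opp / n_eqtl if n_eqtl else np.nan,
            "opp_over_multi": n_opp / n_multi if n_multi else np.nan,
        })
    df = pd.DataFrame(rows).set_index("tissue")
    cv = {c: _sample_cv(df[c])
          for c in ("n_eqtl_genes", "n_multi_genes", "n_opp_genes")}

    def _corr(a: str, b: str) -> float:
        sub = df[[a, b]].dropna()
        if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            return float("nan")
        return float(pearsonr(sub[a], sub[b]).statistic)

    pear = {
        "multi_over_eqtl~opp_over_eqtl": _corr("multi_over_eqtl", "opp_over_eqtl"),
        "multi_over_eqtl~opp_over_multi": _corr("multi_over_eqtl", "opp_over_multi"),
    }
    return TissueSummary(table=df, cv=cv, pearson=pear,
                         undefined_tissues=undefined)


@dataclass
class OppositeFractionMatrix:
    tissues: list[str]
    fraction: pd.DataFrame   # symmetric, diagonal 0, NaN where no sharing
    n_shared: pd.DataFrame   # companion count matrix

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, a in enumerate(self.tissues):
            for b in self.tissues[i + 1:]:
                if np.isnan(self.fraction.loc[a, b]):
                    out.append((a, b))
        return out


def opposite_fraction_matrix(tables: Iterable[TissueTable],
                             ) -> OppositeFractionMatrix:
    """Proportion of shared significant (gene, SNP) records with opposite β.

    For each unordered tissue pair, records significant in both tissues are
    matched on (gene_id, variant_key); the entry is #(β_i·β_j < 0) / #shared.
    Pairs sharing no record get NaN; the diagonal is 0 by convention.
    """
    tables = sorted(tables, key=lambda t: t.tissue)
    names = [t.tissue for t in tables]
    frames = {t.tissue: t.df.set_index(["gene_id", "variant_key"])["beta"]
              for t in tables}
    frac = pd.DataFrame(0.0, index=names, columns=names)
    nsh = pd.DataFrame(0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            joined = pd.concat([frames[a], frames[b]], axis=1,
                               join="inner", keys=["a", "b"])
            n = len(joined)
            nsh.loc[a, b] = nsh.loc[b, a] = n
            if n == 0:
                frac.loc[a, b] = frac.loc[b, a] = np.nan
            else:
                opp = int((joined["a"] * joined["b"] < 0).sum())
                frac.loc[a, b] = frac.loc[b, a] = opp / n
    return OppositeFractionMatrix(names, frac, nsh)


@dataclass
class ClusterResult:
    tissues: list[str]
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str
    imputed_pairs: list[tuple[str, str]]


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)

    def node(i: int, parent_h: float) -> str:
        if i < n:
            return f"{labels[i]}:{parent_h:.6g}"
        row = Z[i - n]
        h = row[2]
        left = node(int(row[0]), h / 2)
        right = node(int(row[1]), h / 2)
        return f"({left},{right}):{max(parent_h - h, 0.0) / 2:.6g}"

    root_h = Z[-1, 2] if len(Z) else 0.0
    return node(2 * n - 2, root_h) + ";" if n > 1 else f"{labels[0]};"


def cluster_tissues(matrix: OppositeFractionMatrix,
                    method: str = "complete",
                    metric: str = "euclidean") -> ClusterResult:
    """Agglomerative clustering of tissues on their opposite-fraction rows.

    Complete linkage over Euclidean distances between matrix rows by default
    (the conventional heatmap setting); undefined entries are imputed with
    the column mean and flagged.  Deterministic for identical input.
    """
    if len(matrix.tissues) < 2:
        raise ValueError("clustering needs at least 2 tissues")
    X = matrix.fraction.to_numpy(dtype=float).copy()
    imputed = matrix.undefined_pairs()
    if imputed:
        col_means = np.nanmean(np.where(np.eye(len(X), dtype=bool), np.nan, X),
                               axis=0)
        col_means = np.nan_to_num(col_means)
        idx = np.where(np.isnan(X))
        X[idx] = col_means[idx[1]]
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    order = [matrix.tissues[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(matrix.tissues, Z, order,
                         _linkage_to_newick(Z, matrix.tissues), imputed)


@dataclass
class PvalueDeviationDensity:
    """Normalized 2D histograms of (−log10 p₁, −log10 p₂) and their difference.

    p₁ is the lower of the two top-SNP p-values of a qualifying tissue pair
    and p₂ the higher, so −log10 p₁ ≥ −log10 p₂ and all mass lies on one side
    of the diagonal.  Grid: 0.25-unit bins on [0, 30], overflow clipped into
    the last bin.
    """

    bin_edges: np.ndarray
    hist_multi: np.ndarray
    hist_opp: np.ndarray

    @property
    def difference(self) -> np.ndarray:
        return self.hist_opp - self.hist_multi


PV_GRID_MAX = 30.0
PV_BIN_WIDTH = 0.25


def _hist2d(tables: list[AnalysisTable], edges: np.ndarray) -> np.ndarray:
    lo_hi = np.array([sorted((t.pval_x, t.pval_y)) for t in tables])
    if len(lo_hi) == 0:
        return np.zeros((len(edges) - 1, len(edges) - 1))
    x = -np.log10(lo_hi[:, 0])  # p-value_1: the lower p, larger −log10
    y = -np.log10(lo_hi[:, 1])
    eps = 1e-9
    x = np.clip(x, 0.0, PV_GRID_MAX - eps)
    y = np.clip(y, 0.0, PV_GRID_MAX - eps)
    h, _, _ = np.histogram2d(x, y, bins=(edges, edges))
    return h / h.sum()


def pvalue_deviation_density(analysis_tables: Iterable[AnalysisTable],
                             ) -> PvalueDeviationDensity:
    """Build the multi (groups 1a∪2a) and opp (group 1a) p-value densities."""
    edges = np.arange(0.0, PV_GRID_MAX + PV_BIN_WIDTH, PV_BIN_WIDTH)
    multi = [t for t in analysis_tables if t.status in MULTI_GROUPS]
    opp = [t for t in multi if t.status == GROUP_1A]
    return PvalueDeviationDensity(edges, _hist2d(multi, edges),
                                  _hist2d(opp, edges))
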