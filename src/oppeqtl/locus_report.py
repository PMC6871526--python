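"""Locus views: allele-harmonized β/p landscapes of all tested SNPs around a
gene's TSS for one tissue pair.

To make the direction contrast visible, reference/alternative alleles are
reassigned per SNP so that every β in the *anchor* tissue is non-negative;
the same swap is applied to the other tissue's β, so joint sign structure
(and hence the opposite/same call) is untouched.  Reassignment is an
involution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .eqtl_io import parse_variant_key

WINDOW_BP = 1_000_000


@dataclass
class LocusView:
    gene_id: str
    anchor_tissue: str
    other_tissue: str
    rows: pd.DataFrame  # rsid, position, beta_anchor, beta_other,
                        # mlog10p_anchor, mlog10p_other, flipped, highlighted


def build_locus_view(gene_id: str, anchor_tissue: str, other_tissue: str,
                     assoc: Mapping[str, pd.DataFrame],
                     highlight_snps: Iterable[str] = (),
                     window_bp: int = WINDOW_BP) -> LocusView:
    """Assemble the harmonized locus table for one gene and tissue pair.

    ``assoc`` maps tissue code to an all-tested-associations table in the
    significant-pair dialect (columns ``gene_id``, ``variant_key``/
    ``variant_id``, ``rsid``/``rs_id_dbSNP``, ``beta``/``slope``,
    ``pval``/``pval_nominal``, ``tss_distance``) — i.e., the same columns
    without the significance filter.  SNPs are matched across tissues on the
    variant key; a SNP untested in one tissue keeps NaN there, and a SNP
    with NaN/0 anchor β is left unflipped.  Raises if the gene is absent
    from either tissue.
    """
    def norm(df: pd.DataFrame) -> pd.DataFrame:
        ren = {"variant_id": "variant_key", "rs_id_dbSNP": "rsid",
               "slope": "beta", "pval_nominal": "pval"}
        df = df.rename(columns={k: v for k, v in ren.items() if k in df.columns})
        sub = df[df["gene_id"] == gene_id]
        sub = sub[sub["tss_distance"].abs() <= window_bp]
        return sub.set_index("variant_key")

    a = norm(assoc[anchor_tissue])
    b = norm(assoc[other_tissue])
    if len(a) == 0:
        raise ValueError(f"gene {gene_id} absent in tissue {anchor_tissue}")
    if len(b) == 0:
        raise ValueError(f"gene {gene_id} absent in tissue {other_tissue}")

    keys = a.index.union(b.index)
    rsid = a["rsid"].reindex(keys).fillna(b["rsid"].reindex(keys))
    beta_a = pd.to_numeric(a["beta"].reindex(keys))
    beta_b = pd.to_numeric(b["beta"].reindex(keys))
    p_a = pd.to_numeric(a["pval"].reindex(keys))
    p_b = pd.to_numeric(b["pval"].reindex(keys))

    flip = (beta_a < 0).fillna(False)  # NaN/0 anchor β: leave unflipped
    sign = np.where(flip, -1.0, 1.0)
    highlight = set(highlight_snps)
    rows = pd.DataFrame({
        "rsid": rsid.to_numpy(),
        "position": [parse_variant_key(k).pos for k in keys],
        "beta_anchor": beta_a.to_numpy() * sign,
        "beta_other": beta_b.to_numpy() * sign,
        "mlog10p_anchor": -np.log10(p_a.to_numpy(dtype=float)),
        "mlog10p_other": -np.log10(p_b.to_numpy(dtype=float)),
        "flipped": flip.to_numpy(),
        "highlighted": [r in highlight for r in rsid],
    }).sort_values("position", kind="mergesort").reset_index(drop=True)
    return LocusView(gene_id, anchor_tissue, other_tissue, rows)


def render_locus_figure(view: LocusView, path) -> None:
    """Two stacked position-vs-β panels (anchor red, other blue), colored by
    −log10 p, with highlighted SNPs ringed and in the legend.  Output is
    deterministic for fixed input."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(view.rows) == 0:
        raise ValueError("empty locus view")
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 6))
    panels = [
        (ax1, "beta_anchor", "mlog10p_anchor", "Reds", view.anchor_tissue),
        (ax2, "beta_other", "mlog10p_other", "Blues", view.other_tissue),
    ]
    for ax, bcol, pcol, cmap, tissue in panels:
        r = view.rows
        sc = ax.scatter(r["position"], r[bcol], c=r[pcol], cmap=cmap,
                        s=18, edgecolors="none")
        hi = r[r["highlighted"]]
        if len(hi):
            ax.scatter(hi["position"], hi[bcol], facecolors="none",
                       edgecolors="black", s=70,
                       label="opp-multi-eQTL-SNP")
            ax.legend(loc="upper right", frameon=False)
        ax.axhline(0.0, lw=0.6, color="grey")
        ax.set_ylabel(f"beta ({tissue})")
        fig.colorbar(sc, ax=ax, label="-log10 p")
    ax2.set_xlabel(f"position (bp), {view.gene_id}")
    fig.savefig(path, dpi=150, metadata={"Software": "oppeqtl"})
    plt.close(fig)
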