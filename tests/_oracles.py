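"""Independent brute-force re-implementations used as test oracles.

Deliberately naive and dictionary-based: no shared code with the package
beyond reading its public data containers.  The LD oracle uses numpy's
Pearson correlation rather than haplotype-frequency counting.
"""

import itertools

import numpy as np


def naive_top_snps(tables):
    """{(gene, tissue): (rsid, beta, pval)} by exhaustive scan with
    min-p / lexicographic-rsid tie-break."""
    best = {}
    for table in tables:
        for r in table.df.itertuples(index=False):
            key = (r.gene_id, table.tissue)
            cur = best.get(key)
            if (cur is None or r.pval < cur[2]
                    or (r.pval == cur[2] and r.rsid < cur[0])):
                best[key] = (r.rsid, float(r.beta), float(r.pval))
    return best


def naive_r2(panel, rsid_a, rsid_b):
    if rsid_a == rsid_b:
        return 1.0
    a = panel.haplotypes[panel.index_of(rsid_a)].astype(float)
    b = panel.haplotypes[panel.index_of(rsid_b)].astype(float)
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def naive_classify(tables, panel, threshold=0.8):
    """Re-derive the status of every (gene, tissue pair) analysis table.

    Returns {(gene, tissue_x, tissue_y): status} for sorted tissue pairs.
    """
    tables = list(tables)
    beta_of = {}
    for table in tables:
        for r in table.df.itertuples(index=False):
            beta_of[(table.tissue, r.gene_id, r.rsid)] = float(r.beta)
    top = naive_top_snps(tables)
    genes = sorted({g for g, _ in top})
    tissues = sorted(t.tissue for t in tables)
    out = {}
    for gene in genes:
        for tx, ty in itertools.combinations(tissues, 2):
            if (gene, tx) not in top or (gene, ty) not in top:
                out[(gene, tx, ty)] = "ineligible"
                continue
            snp_x, bxx, _ = top[(gene, tx)]
            snp_y, byy, _ = top[(gene, ty)]
            if snp_x == snp_y:
                bxy, byx = byy, bxx
            else:
                bxy = beta_of.get((ty, gene, snp_x), 0.0)
                byx = beta_of.get((tx, gene, snp_y), 0.0)
            if not (snp_x == snp_y or bxy != 0.0 or byx != 0.0):
                out[(gene, tx, ty)] = "excluded"
                continue
            opposite = bxx * bxy <= 0.0 and byx * byy <= 0.0
            rr = naive_r2(panel, snp_x, snp_y)
            strong = rr is not None and rr > threshold
            out[(gene, tx, ty)] = {
                (True, True): "1a", (True, False): "1b",
                (False, True): "2a", (False, False): "2b",
            }[(opposite, strong)]
    return out


def naive_designations(statuses, top):
    """Aggregate naive statuses into (multi_genes, opp_genes, multi_snps,
    opp_snps) using the per-(gene, tissue) top map from naive_top_snps."""
    multi_genes, opp_genes = set(), set()
    multi_snps, opp_snps = set(), set()
    for (gene, tx, ty), status in statuses.items():
        if status not in ("1a", "2a"):
            continue
        multi_genes.add(gene)
        snps = {top[(gene, tx)][0], top[(gene, ty)][0]}
        multi_snps |= snps
        if status == "1a":
            opp_genes.add(gene)
            opp_snps |= snps
    return multi_genes, opp_genes, multi_snps, opp_snps


def hypergeom_fisher_p(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric point masses ≤ observed."""
    from math import comb
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    p_obs = comb(r1, a) * comb(n - r1, c1 - a) / denom
    total = 0.0
    for k in range(lo, hi + 1):
        pk = comb(r1, k) * comb(n - r1, c1 - k) / denom
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)
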