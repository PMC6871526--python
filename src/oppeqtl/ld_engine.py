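"""Pairwise linkage disequilibrium (r²) from a phased reference haplotype panel.

r² is computed by direct haplotype-frequency counting, the behaviour of
standard LD tools on phased panels: with alt-allele frequencies p_A, p_B and
joint alt-alt haplotype frequency p_AB over the panel,

    r² = (p_AB − p_A·p_B)² / (p_A (1 − p_A) · p_B (1 − p_B))

which equals the squared Pearson correlation of the two 0/1 haplotype
vectors.  A pair involving a monomorphic site has undefined r²; every caller
in this package treats undefined as "not in LD".  A SNP queried against
itself has r² = 1 by definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

DEFAULT_R2_THRESHOLD = 0.8
#: maximum distance scanned for LD partners; cis analysis never needs more.
LD_SEARCH_WINDOW_BP = 1_000_000


@dataclass
class HaplotypePanel:
    """Phased biallelic reference panel (variant × haplotype 0/1 matrix)."""

    variant_keys: list[str]
    rsids: list[str]
    chroms: np.ndarray          # str per variant
    positions: np.ndarray       # int bp, 1-based
    haplotypes: np.ndarray      # shape (n_variants, n_haplotypes), int8 in {0,1}
    population_label: str = "EUR"
    _by_rsid: dict[str, int] = field(init=False, repr=False)
    _by_key: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        H = np.asarray(self.haplotypes, dtype=np.int8)
        if H.ndim != 2 or H.shape[0] != len(self.variant_keys):
            raise ValueError("haplotype matrix shape does not match variants")
        if H.shape[1] < 2:
            raise ValueError("panel needs at least 2 haplotypes")
        if not np.isin(H, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        if len(set(self.variant_keys)) != len(self.variant_keys):
            raise ValueError("variant keys not unique")
        self.haplotypes = H
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chroms = np.asarray(self.chroms, dtype=object)
        self._by_rsid = {r: i for i, r in enumerate(self.rsids)}
        self._by_key = {k: i for i, k in enumerate(self.variant_keys)}

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    def keys(self) -> set[str]:
        return set(self.variant_keys)

    def has_rsid(self, rsid: str) -> bool:
        return rsid in self._by_rsid

    def index_of(self, rsid: str) -> int:
        try:
            return self._by_rsid[rsid]
        except KeyError:
            raise KeyError(f"rsID {rsid!r} not in panel") from None

    def alt_freq(self, rsid: str) -> float:
        return float(self.haplotypes[self.index_of(rsid)].mean())

    # --- I/O ---------------------------------------------------------------

    @classmethod
    def from_vcf(cls, path, population_label: str = "EUR") -> "HaplotypePanel":
        """Load a phased biallelic VCF (all GTs must be phased diploid)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        keys, rsids, chroms, positions, rows = [], [], [], [], []
        for v in vcf:
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                continue  # biallelic SNPs only
            gts = np.array(v.genotypes, dtype=object)
            if not all(g[2] for g in v.genotypes):
                raise ValueError(f"unphased genotype at {v.CHROM}:{v.POS}")
            hap = np.array([[g[0], g[1]] for g in v.genotypes],
                           dtype=np.int8).reshape(-1)
            keys.append(f"{v.CHROM}_{v.POS}_{v.REF}_{v.ALT[0]}_b37")
            rsids.append(v.ID or ".")
            chroms.append(v.CHROM)
            positions.append(v.POS)
            rows.append(hap)
        vcf.close()
        return cls(keys, rsids, np.array(chroms, dtype=object),
                   np.array(positions), np.array(rows, dtype=np.int8),
                   population_label)

    def to_vcf(self, path) -> None:
        """Write the panel as an uncompressed phased VCF (deterministic)."""
        n_samples = self.n_haplotypes // 2
        if self.n_haplotypes % 2:
            raise ValueError("odd haplotype count cannot be written as diploid VCF")
        samples = [f"HG{i:04d}" for i in range(n_samples)]
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(f"##source=oppeqtl synthetic panel ({self.population_label})\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples) + "\n")
            for i, key in enumerate(self.variant_keys):
                chrom, pos, ref, alt, _ = key.split("_")
                row = self.haplotypes[i]
                gts = "\t".join(
                    f"{row[2 * s]}|{row[2 * s + 1]}" for s in range(n_samples))
                fh.write(f"{chrom}\t{pos}\t{self.rsids[i]}\t{ref}\t{alt}"
                         f"\t.\tPASS\t.\tGT\t{gts}\n")


@dataclass(frozen=True)
class LdResult:
    snp_a: str
    snp_b: str
    r2: float | None  # None = undefined (monomorphic site involved)

    @property
    def defined(self) -> bool:
        return self.r2 is not None


def _r2_vectors(a: np.ndarray, b: np.ndarray) -> float | None:
    pa = a.mean()
    pb = b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return None
    pab = float((a & b).mean())
    d = pab - pa * pb
    return float(d * d / (pa * (1.0 - pa) * pb * (1.0 - pb)))


def r2(snp_a: str, snp_b: str, panel: HaplotypePanel) -> LdResult:
    """r² between two panel SNPs; exactly 1.0 when the rsIDs are identical."""
    if snp_a == snp_b:
        panel.index_of(snp_a)  # absence is still an error
        return LdResult(snp_a, snp_b, 1.0)
    ia, ib = panel.index_of(snp_a), panel.index_of(snp_b)
    return LdResult(snp_a, snp_b,
                    _r2_vectors(panel.haplotypes[ia], panel.haplotypes[ib]))


def in_ld(snp_a: str, snp_b: str, panel: HaplotypePanel,
          threshold: float = DEFAULT_R2_THRESHOLD) -> bool:
    """True iff r² is defined and strictly exceeds ``threshold``."""
    res = r2(snp_a, snp_b, panel)
    return res.defined and res.r2 > threshold


@dataclass
class LdOverlap:
    """Result of scanning a query SNP set against a target SNP set."""

    hits: dict[str, bool]       # per query rsid
    n_queries: int
    n_hits: int
    n_unresolved: int           # queries absent from the panel

    @property
    def proportion(self) -> float:
        return self.n_hits / self.n_queries if self.n_queries else float("nan")


def ld_hits_against_set(queries: Iterable[str], targets: Iterable[str],
                        panel: HaplotypePanel,
                        threshold: float = DEFAULT_R2_THRESHOLD,
                        window_bp: int = LD_SEARCH_WINDOW_BP) -> LdOverlap:
    """Count queries in LD (r² > threshold) with at least one target.

    A query that is itself a target is a hit (self r² = 1).  Queries or
    targets absent from the panel cannot contribute through LD and are
    skipped with a warning; such queries can still hit via identity.
    Target scanning is restricted to the same chromosome within
    ``window_bp`` of the query position.
    """
    queries = sorted(set(queries))
    target_set = set(targets)
    resolved_targets = [t for t in target_set if panel.has_rsid(t)]
    n_missing_targets = len(target_set) - len(resolved_targets)
    if n_missing_targets:
        warnings.warn(f"{n_missing_targets} target rsIDs not in panel; "
                      "they can only match by identity")
    t_idx = np.array([panel.index_of(t) for t in resolved_targets], dtype=int)

    hits: dict[str, bool] = {}
    n_unresolved = 0
    H = panel.haplotypes
    for q in queries:
        if q in target_set:
            hits[q] = True
            continue
        if not panel.has_rsid(q):
            n_unresolved += 1
            warnings.warn(f"query rsID {q!r} not in panel; skipped")
            hits[q] = False
            continue
        qi = panel.index_of(q)
        if len(t_idx) == 0:
            hits[q] = False
            continue
        near = t_idx[(panel.chroms[t_idx] == panel.chroms[qi])
                     & (np.abs(panel.positions[t_idx] - panel.positions[qi])
                        <= window_bp)]
        hit = False
        a = H[qi]
        pa = a.mean()
        if 0.0 < pa < 1.0 and len(near):
            B = H[near]
            pb = B.mean(axis=1)
            pab = (B & a).mean(axis=1)
            poly = (pb > 0.0) & (pb < 1.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                rr = (pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb))
            hit = bool(np.any(poly & (rr > threshold)))
        hits[q] = hit
    return LdOverlap(hits=hits, n_queries=len(queries),
                     n_hits=int(sum(hits.values())), n_unresolved=n_unresolved)
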