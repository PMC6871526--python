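"""LD overlap of eQTL SNP classes with genome-wide-significant GWAS SNPs.

A class SNP "overlaps" the GWAS catalog when its r² with at least one
trait-associated SNP (reported p < 5 × 10⁻⁸, any trait) strictly exceeds
the LD threshold over the reference panel; a SNP that is itself a GWAS SNP
counts via self-LD.  Class-vs-class enrichment uses a two-sided Fisher
exact test (sample odds ratio reported); the TSS-matched comparison uses
the same matched-resampling machinery as the annotation enrichment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from . import ld_engine
from .epi_enrichment import tss_window_matched_subsample
from .tss_enrichment import DistanceSample, EnrichmentPValue, replicate_rngs

GWAS_P_THRESHOLD = 5e-8
_RSID_RE = re.compile(r"^rs\d+$")


@dataclass
class GwasSnpSet:
    """Genome-wide-significant GWAS-catalog SNPs (min reported p per rsID)."""

    source_pvalues: dict[str, float]
    n_skipped: int = 0

    @property
    def rsids(self) -> set[str]:
        return set(self.source_pvalues)

    def __len__(self) -> int:
        return len(self.source_pvalues)


def load_gwas_catalog(path, p_threshold: float = GWAS_P_THRESHOLD) -> GwasSnpSet:
    """Read a GWAS-catalog association TSV and keep SNPs with p < threshold.

    Dialect: header row with columns ``SNPS`` (one rsID) and ``P-VALUE``.
    Multi-trait duplicates collapse to one entry keeping the minimum p;
    malformed p-values or rsIDs are skipped and counted; the threshold is a
    strict less-than.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("SNPS", "P-VALUE"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    pvals = pd.to_numeric(df["P-VALUE"], errors="coerce")
    rsids = df["SNPS"].fillna("").str.strip()
    ok = pvals.notna() & (pvals >= 0) & rsids.map(lambda s: bool(_RSID_RE.match(s)))
    n_skipped = int((~ok).sum())
    kept = pd.DataFrame({"rsid": rsids[ok], "p": pvals[ok]})
    kept = kept[kept["p"] < p_threshold]
    best = kept.groupby("rsid")["p"].min()
    return GwasSnpSet(source_pvalues=best.to_dict(), n_skipped=n_skipped)


@dataclass
class ClassOverlap:
    label: str
    n_total: int
    n_hits: int

    @property
    def proportion(self) -> float:
        return self.n_hits / self.n_total if self.n_total else float("nan")


def class_ld_overlap(snp_class: Iterable[str], gwas: GwasSnpSet,
                     panel: ld_engine.HaplotypePanel,
                     threshold: float = ld_engine.DEFAULT_R2_THRESHOLD,
                     label: str = "") -> ClassOverlap:
    """Count/proportion of class SNPs in LD (r² > threshold) with any GWAS SNP."""
    snps = set(snp_class)
    res = ld_engine.ld_hits_against_set(snps, gwas.rsids, panel, threshold)
    return ClassOverlap(label=label, n_total=len(snps), n_hits=res.n_hits)


@dataclass
class FisherResult:
    odds_ratio: float | None  # sample OR; None when a margin is zero
    p: float


def fisher_enrichment(hits_a: int, n_a: int, hits_b: int, n_b: int) -> FisherResult:
    """Two-sided Fisher exact test of the 2×2 hit table of two SNP classes.

    Table: [[hits_a, n_a − hits_a], [hits_b, n_b − hits_b]].  The reported
    odds ratio is the sample (unconditional) OR; a zero-margin table gives
    p = 1 and an undefined OR.
    """
    if not (0 <= hits_a <= n_a and 0 <= hits_b <= n_b):
        raise ValueError("hits must be within 0..n")
    table = np.array([[hits_a, n_a - hits_a], [hits_b, n_b - hits_b]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return FisherResult(odds_ratio=None, p=1.0)
    res = stats.fisher_exact(table, alternative="two-sided")
    orat = float(res.statistic)
    return FisherResult(odds_ratio=None if not np.isfinite(orat) else orat,
                        p=float(res.pvalue))


@dataclass
class ResamplingOverlap:
    observed_proportion: float
    adjusted_mean: float
    ci_low: float
    ci_high: float
    pvalue: EnrichmentPValue


def resampling_enrichment(opp: DistanceSample, multi: DistanceSample,
                          gwas: GwasSnpSet, panel: ld_engine.HaplotypePanel,
                          n_rep: int = 10_000, seed: int = 0,
                          threshold: float = ld_engine.DEFAULT_R2_THRESHOLD,
                          ) -> ResamplingOverlap:
    """GWAS-LD overlap of opp SNPs vs the TSS-matched multi null.

    Each replicate regenerates the TSS-window-matched multi subsample and
    recomputes its overlap proportion.  Hit status per SNP is resolved once
    against the panel (LD is a property of the SNP, not the subsample), so
    replicates only re-average precomputed hit flags.
    """
    universe = set(multi.pairs["rsid"]) | set(opp.pairs["rsid"])
    hit_map = ld_engine.ld_hits_against_set(universe, gwas.rsids, panel,
                                            threshold).hits
    opp_snps = sorted(set(opp.pairs["rsid"]))
    observed = float(np.mean([hit_map[s] for s in opp_snps]))
    reps = np.empty(n_rep)
    for i, rng in enumerate(replicate_rngs(seed, n_rep)):
        sub = tss_window_matched_subsample(multi, opp, rng)
        snps = sorted(set(sub.pairs["rsid"]))
        reps[i] = np.mean([hit_map[s] for s in snps]) if snps else np.nan
    lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    pv = EnrichmentPValue(observed=observed, n_rep=n_rep,
                          exceedances=int(np.nansum(reps >= observed)),
                          replicate_mean=float(np.nanmean(reps)),
                          replicate_sd=float(np.nanstd(reps, ddof=1)))
    return ResamplingOverlap(observed, float(np.nanmean(reps)),
                             float(lo), float(hi), pv)


def overlap_table(classes: dict[str, set[str]], gwas: GwasSnpSet,
                  panel: ld_engine.HaplotypePanel,
                  threshold: float = ld_engine.DEFAULT_R2_THRESHOLD,
                  ) -> pd.DataFrame:
    """Counts and proportions of SNPs in LD with GWAS SNPs, per class."""
    rows = []
    for label, snps in classes.items():
        ov = class_ld_overlap(snps, gwas, panel, threshold, label=label)
        rows.append({"class": label, "total": ov.n_total, "hits": ov.n_hits,
                     "proportion_pct": 100.0 * ov.proportion})
    return pd.DataFrame(rows)
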