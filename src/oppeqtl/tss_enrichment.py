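"""TSS-proximity enrichment of opposite-effect eQTL SNPs.

The peakedness of the signed TSS-distance distribution is summarized by the
Pearson (non-excess) sample kurtosis m₄/m₂² of the raw distances.  The
enrichment null matches the confounder "number of sharing tissues": each
replicate draws, without replacement, a subsample of multi-eQTL (gene, SNP)
pairs whose sharing-count histogram equals that of the opp set, and the
one-sided p-value is the fraction of replicate kurtoses at or above the
observed opp kurtosis.  A zero exceedance count is reported as the strict
bound p < 1/n_rep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .eqtl_io import TissueTable, TopEqtlMap
from .pair_classifier import DesignationSets

PAIR_COLUMNS = ("gene_id", "rsid", "tss_distance", "sharing")


@dataclass
class DistanceSample:
    """A labelled set of (gene, SNP) pairs with TSS distances and sharing counts."""

    label: str
    pairs: pd.DataFrame  # columns: gene_id, rsid, tss_distance, sharing

    def __post_init__(self) -> None:
        missing = set(PAIR_COLUMNS) - set(self.pairs.columns)
        if missing:
            raise ValueError(f"distance sample missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def distances(self) -> np.ndarray:
        return self.pairs["tss_distance"].to_numpy(dtype=float)

    def sharing_histogram(self) -> dict[int, int]:
        return self.pairs["sharing"].value_counts().to_dict()


def distance_samples(tables: Iterable[TissueTable], top: TopEqtlMap,
                     designations: DesignationSets) -> dict[str, DistanceSample]:
    """Build the per-class distance samples: any, top, multi, opp.

    A (gene, SNP) pair appearing in several tissues enters once; its sharing
    count is the number of tissues where it is significant.
    """
    frames = [t.df[["gene_id", "rsid", "tss_distance"]] for t in tables]
    allp = pd.concat(frames, ignore_index=True)
    sharing = (allp.groupby(["gene_id", "rsid"], sort=True)
               .agg(tss_distance=("tss_distance", "first"),
                    sharing=("tss_distance", "size"))
               .reset_index())

    def subset(label: str, keep: pd.Series) -> DistanceSample:
        return DistanceSample(label, sharing.loc[keep].reset_index(drop=True))

    key = pd.Series(list(zip(sharing["gene_id"], sharing["rsid"])),
                    index=sharing.index)
    top_pairs = {(g, e.rsid) for g, per in top.entries.items()
                 for e in per.values()}
    return {
        "any": subset("any", pd.Series(True, index=sharing.index)),
        "top": subset("top", key.isin(top_pairs)),
        "multi": subset("multi", key.isin(designations.multi_pairs)),
        "opp": subset("opp", key.isin(designations.opp_pairs)),
    }


def sharing_matched_subsample(multi: DistanceSample, opp: DistanceSample,
                              rng: np.random.Generator) -> DistanceSample:
    """Subsample multi pairs to match opp's sharing-count histogram.

    Per sharing-count stratum k, draws without replacement from multi's
    stratum the number of opp pairs with count k, capped at availability
    (deficits recorded on the returned sample as ``deficits``).
    """
    want = opp.sharing_histogram()
    groups = {int(k): idx.to_numpy()
              for k, idx in multi.pairs.groupby("sharing").groups.items()}
    take: list[np.ndarray] = []
    deficits: dict[int, int] = {}
    for k in sorted(want):
        avail = groups.get(k, np.empty(0, dtype=int))
        n = min(want[k], len(avail))
        if n < want[k]:
            deficits[k] = want[k] - n
        if n:
            take.append(rng.choice(avail, size=n, replace=False))
    idx = np.sort(np.concatenate(take)) if take else np.empty(0, dtype=int)
    sub = DistanceSample("multi-sharing-adjusted",
                         multi.pairs.loc[idx].reset_index(drop=True))
    sub.deficits = deficits  # type: ignore[attr-defined]
    return sub


def kurtosis(distances) -> float:
    """Pearson (non-excess) sample kurtosis m₄/m₂² of the raw values.

    Requires ≥4 values with nonzero variance; 3 for a normal sample, 1 for a
    symmetric two-point sample (the minimum).
    """
    x = np.asarray(distances, dtype=float)
    if x.size < 4:
        raise ValueError("kurtosis needs at least 4 values")
    c = x - x.mean()
    m2 = np.mean(c ** 2)
    if m2 == 0.0:
        raise ValueError("kurtosis undefined for zero variance")
    return float(np.mean(c ** 4) / m2 ** 2)


@dataclass
class EnrichmentPValue:
    """One-sided resampling p-value with bound reporting.

    ``p`` is exceedances/n_rep; when no replicate reaches the observed
    statistic, ``is_bound`` is True and ``bound`` = 1/n_rep (read "p < bound").
    """

    observed: float
    n_rep: int
    exceedances: int
    replicate_mean: float
    replicate_sd: float

    @property
    def p(self) -> float:
        return self.exceedances / self.n_rep

    @property
    def is_bound(self) -> bool:
        return self.exceedances == 0

    @property
    def bound(self) -> float:
        return 1.0 / self.n_rep

    def __str__(self) -> str:
        return (f"p < {self.bound:g}" if self.is_bound
                else f"p = {self.p:g}") + f" ({self.n_rep} replicates)"


def replicate_rngs(seed: int, n_rep: int) -> list[np.random.Generator]:
    """Independent, order-independent per-replicate generators from one seed."""
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n_rep)]


def tss_enrichment_pvalue(opp: DistanceSample, multi: DistanceSample,
                          n_rep: int = 10_000, seed: int = 0,
                          ) -> EnrichmentPValue:
    """Sharing-matched resampling test for TSS-proximity (kurtosis) enrichment.

    One-sided: higher kurtosis = more TSS-peaked.  Each replicate draws a
    fresh sharing-matched subsample of multi and recomputes the kurtosis.
    """
    observed = kurtosis(opp.distances)
    reps = np.empty(n_rep)
    for i, rng in enumerate(replicate_rngs(seed, n_rep)):
        sub = sharing_matched_subsample(multi, opp, rng)
        reps[i] = kurtosis(sub.distances)
    exceed = int((reps >= observed).sum())
    return EnrichmentPValue(observed=observed, n_rep=n_rep,
                            exceedances=exceed,
                            replicate_mean=float(reps.mean()),
                            replicate_sd=float(reps.std(ddof=1)))


@dataclass
class DensityRatio:
    ratio: float
    bandwidth_a: float
    bandwidth_b: float


def density_ratio_at_tss(sample_a: DistanceSample, sample_b: DistanceSample,
                         ) -> DensityRatio:
    """Ratio of Gaussian KDE densities of the two samples evaluated at 0 bp.

    Bandwidths follow Silverman's rule and are recorded in the result.
    Returns density_b(0) / density_a(0).
    """
    ka = gaussian_kde(sample_a.distances, bw_method="silverman")
    kb = gaussian_kde(sample_b.distances, bw_method="silverman")
    return DensityRatio(
        ratio=float(kb(0.0)[0] / ka(0.0)[0]),
        bandwidth_a=float(ka.factor * np.std(sample_a.distances)),
        bandwidth_b=float(kb.factor * np.std(sample_b.distances)),
    )
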