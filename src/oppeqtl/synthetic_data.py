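"""Synthetic multi-tissue cis-eQTL cohort generator with planted ground truth.

Every input the pipeline consumes is emulated here with controllable truth:

* a phased haplotype reference panel with block-diagonal LD (within a block,
  haplotypes descend from a complementary ancestral pair with a per-site
  flip rate tuned to a target pairwise r²; blocks are independent and placed
  >1 Mbp apart so LD never leaks across blocks);
* per-tissue significant-pair tables: each gene gets one causal block/SNP,
  a set of active tissues, a signed effect per tissue (opposite genes carry
  a sign flip in one designated tissue), LD-partner records attenuated by
  the signed haplotype correlation r, deterministic p-values monotone
  decreasing in |β|, and TSS distances drawn from a mixture of a sharp
  Laplace peak at the TSS and a broad uniform background over the cis
  window — opposite genes get a higher peak weight, which raises both the
  density at the TSS and the kurtosis of the distance distribution (a pure
  scale change would not: kurtosis is scale-invariant);
* an epigenetic annotation matrix (background Bernoulli rate, boosted for
  SNPs of opposite genes);
* a GWAS-catalog table (verified r² > 0.8 LD partners for a fraction ρ of
  opposite causal SNPs, plus background associations and sub-threshold rows
  to exercise the significance filter).

All randomness flows from one mandatory seed through four named
sub-streams (panel / eqtl / annotations / gwas), so every emitted file is
byte-identical across runs with the same config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import ld_engine
from .epi_enrichment import MARKS, AnnotationMatrix
from .eqtl_io import TissueTable

CIS_WINDOW_BP = 1_000_000
_BLOCK_SPACING_BP = 2_000_000  # > LD search window: no cross-block hits
_SNP_SPACING_BP = 500


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a desk-scale cohort: 200 genes over 6 tissues with a
    200-haplotype panel of 40 eight-SNP LD blocks (within-block r² target
    0.9), a planted opposite-gene fraction of 0.1, log-normal effect sizes
    around |β| ≈ 0.6, truncated-geometric tissue sharing, logistic
    |β|-dependent detection of LD-partner records, TSS distances from a
    25 kb Laplace peak over a uniform cis background (peak weight 0.6;
    0.85 for opposite genes), a 0.2 background annotation rate with +0.2
    boost on opposite-gene SNPs, and GWAS partner rate ρ = 0.3.
    """

    seed: int
    n_tissues: int = 6
    n_genes: int = 200
    n_haplotypes: int = 200
    n_blocks: int = 40
    snps_per_block: int = 8
    block_r2_target: float = 0.9
    theta_opp: float = 0.1
    beta_log_mu: float = float(np.log(0.6))
    beta_log_sigma: float = 0.35
    beta_tissue_jitter: float = 0.10
    sharing_geom_p: float = 0.35     # truncated geometric on active-tissue count
    secondary_rate: float = 0.2      # genes with an independent second LD block
    detect_slope: float = 12.0       # logistic censoring of partner records
    detect_mid: float = 0.25
    tissue_scale_range: tuple[float, float] = (0.7, 1.3)  # "sample size" proxy
    tss_peak_scale_bp: float = 25_000.0
    tss_peak_weight: float = 0.6      # mass of the Laplace TSS peak
    opp_tss_peak_weight: float = 0.85  # enrichment knob for opposite genes
    n_cells: int = 20                # cell lines for annotations (up to 127)
    annot_background: float = 0.2
    annot_boost: float = 0.2
    annot_availability: float = 0.8
    gwas_rho: float = 0.3
    n_gwas_background: int = 6
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("theta_opp", "annot_background", "annot_boost",
                     "annot_availability", "gwas_rho", "sharing_geom_p",
                     "tss_peak_weight", "opp_tss_peak_weight",
                     "secondary_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.block_r2_target <= 1.0:
            raise ValueError("block_r2_target must be in (0, 1]")
        if self.annot_background + self.annot_boost > 1.0:
            raise ValueError("annotation rate + boost exceeds 1")

    @property
    def tissues(self) -> list[str]:
        return [f"TIS{i:02d}" for i in range(1, self.n_tissues + 1)]

    def organ_system(self, tissue: str) -> str:
        i = self.tissues.index(tissue)
        return f"SYS{i % 4}"

    def streams(self) -> dict[str, np.random.Generator]:
        kids = np.random.SeedSequence(self.seed).spawn(4)
        names = ("panel", "eqtl", "annotations", "gwas")
        return {n: np.random.default_rng(k) for n, k in zip(names, kids)}

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "tissue_scale_range" in raw:
            raw["tissue_scale_range"] = tuple(raw["tissue_scale_range"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted labels: what the pipeline should recover."""

    gene_labels: dict[str, str]              # opposite / concordant / single_tissue
    causal: dict[str, tuple[int, str]]       # gene -> (block, causal rsid)
    planted_pairs: dict[str, list[tuple[str, str]]]  # gene -> (flip, other) tissues
    annotation_flagged: set[str]             # rsids with boosted annotation rate
    gwas_partner_flagged: set[str]           # opp causal rsids given a GWAS partner
    secondary_blocks: dict[str, int] = field(default_factory=dict)  # gene -> block

    def opposite_genes(self) -> set[str]:
        return {g for g, l in self.gene_labels.items() if l == "opposite"}

    def concordant_genes(self) -> set[str]:
        return {g for g, l in self.gene_labels.items() if l == "concordant"}

    def to_json(self, path) -> None:
        payload = {
            "gene_labels": dict(sorted(self.gene_labels.items())),
            "causal": {g: list(v) for g, v in sorted(self.causal.items())},
            "planted_pairs": {g: [list(p) for p in v]
                              for g, v in sorted(self.planted_pairs.items())},
            "annotation_flagged": sorted(self.annotation_flagged),
            "gwas_partner_flagged": sorted(self.gwas_partner_flagged),
            "secondary_blocks": dict(sorted(self.secondary_blocks.items())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            gene_labels=raw["gene_labels"],
            causal={g: (int(b), r) for g, (b, r) in raw["causal"].items()},
            planted_pairs={g: [tuple(p) for p in v]
                           for g, v in raw["planted_pairs"].items()},
            annotation_flagged=set(raw["annotation_flagged"]),
            gwas_partner_flagged=set(raw["gwas_partner_flagged"]),
            secondary_blocks={g: int(b)
                              for g, b in raw.get("secondary_blocks", {}).items()},
        )


# --- panel -----------------------------------------------------------------

def mutation_rate_for_r2(target: float) -> float:
    """Per-site flip rate giving expected pairwise within-block r² = target.

    Two sites sharing the complementary ancestral pair have allele
    correlation (1−2μ)² after independent flips at rate μ, hence
    r² = (1−2μ)⁴ and μ = (1 − target^{1/4}) / 2.
    """
    if not 0.0 < target <= 1.0:
        raise ValueError(f"infeasible within-block r² target {target}")
    return 0.5 * (1.0 - target ** 0.25)


def simulate_panel(config: SimConfig,
                   rng: np.random.Generator | None = None) -> ld_engine.HaplotypePanel:
    """Build the phased reference panel with block-diagonal LD."""
    rng = rng if rng is not None else config.streams()["panel"]
    mu = mutation_rate_for_r2(config.block_r2_target)
    n_hap = config.n_haplotypes
    n_snps = config.n_blocks * config.snps_per_block

    # shuffled rs numbers give realistic, varied-length IDs for the
    # lexicographic tie-break
    rs_numbers = rng.permutation(np.arange(1, 20 * n_snps + 1))[:n_snps]

    keys, rsids, chroms, positions, rows = [], [], [], [], []
    i = 0
    for b in range(config.n_blocks):
        # ancestral membership: z=1 haplotypes carry the alt-rich ancestor
        z = rng.integers(0, 2, size=n_hap).astype(np.int8)
        while not 0.05 <= z.mean() <= 0.95:
            z = rng.integers(0, 2, size=n_hap).astype(np.int8)
        start = 1 + b * _BLOCK_SPACING_BP
        for s in range(config.snps_per_block):
            flips = (rng.random(n_hap) < mu).astype(np.int8)
            hap = z ^ flips
            if hap.min() == hap.max():  # monomorphic guard
                hap[s % n_hap] ^= 1
            pos = start + s * _SNP_SPACING_BP
            keys.append(f"{config.chrom}_{pos}_A_G_b37")
            rsids.append(f"rs{rs_numbers[i]}")
            chroms.append(config.chrom)
            positions.append(pos)
            rows.append(hap)
            i += 1
    return ld_engine.HaplotypePanel(
        keys, rsids, np.array(chroms, dtype=object), np.array(positions),
        np.array(rows, dtype=np.int8), population_label="EUR")


# --- eQTL tables -----------------------------------------------------------

def _truncated_geometric(rng: np.random.Generator, p: float,
                         lo: int, hi: int) -> int:
    ks = np.arange(lo, hi + 1)
    w = (1.0 - p) ** (ks - 1)
    return int(rng.choice(ks, p=w / w.sum()))


def simulate_eqtl_tables(config: SimConfig, panel: ld_engine.HaplotypePanel,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Generate per-tissue significant-pair tables (input dialect) + truth.

    Returns {tissue: DataFrame with the significant-pair TSV columns}.
    Causal SNPs are always emitted in their active tissues; LD-partner
    records pass a logistic |β|-dependent detection filter.  p-values are a
    deterministic monotone map of |β| and a per-tissue scale, so top-SNP
    extraction is ground-truth-aware.
    """
    rng = rng if rng is not None else config.streams()["eqtl"]
    tissues = config.tissues
    scale = {t: rng.uniform(*config.tissue_scale_range) for t in tissues}
    gain = {t: 12.0 * scale[t] for t in tissues}

    block_rows = {
        b: np.arange(b * config.snps_per_block, (b + 1) * config.snps_per_block)
        for b in range(config.n_blocks)}

    gene_labels: dict[str, str] = {}
    causal: dict[str, tuple[int, str]] = {}
    planted_pairs: dict[str, list[tuple[str, str]]] = {}
    annotation_flagged: set[str] = set()
    truth_secondary: dict[str, int] = {}
    per_tissue: dict[str, list[tuple]] = {t: [] for t in tissues}

    H = panel.haplotypes.astype(float)
    for gi in range(config.n_genes):
        gene = f"SGENE{gi + 1:05d}"
        opposite = rng.random() < config.theta_opp
        k = _truncated_geometric(rng, config.sharing_geom_p,
                                 2 if opposite else 1, config.n_tissues)
        active = sorted(rng.choice(tissues, size=k, replace=False))
        if k == 1:
            label = "single_tissue"
        else:
            label = "opposite" if opposite else "concordant"
        gene_labels[gene] = label

        block = int(rng.integers(config.n_blocks))
        rows = block_rows[block]
        causal_row = int(rng.choice(rows))
        causal[gene] = (block, panel.rsids[causal_row])

        flip_tissue = None
        if label == "opposite":
            flip_tissue = active[int(rng.integers(len(active)))]
            planted_pairs[gene] = [(flip_tissue, t) for t in active
                                   if t != flip_tissue]
            annotation_flagged.update(panel.rsids[r] for r in rows)

        # signals: (block rows, causal row, base sign, magnitude, carriers).
        # A fraction of genes carries an independent secondary signal in a
        # second LD block — the sign does not flip across tissues, but in
        # tissues where it outgrows the primary it becomes the top signal
        # (the low-r² discordance the LD threshold is there to filter).
        mag = rng.lognormal(config.beta_log_mu, config.beta_log_sigma)
        base_sign = 1.0 if rng.random() < 0.5 else -1.0
        signals = [(rows, causal_row, base_sign, mag, list(active))]
        if len(active) >= 2 and rng.random() < config.secondary_rate:
            block2 = int(rng.integers(config.n_blocks))
            while block2 == block:
                block2 = int(rng.integers(config.n_blocks))
            rows2 = block_rows[block2]
            causal2 = int(rng.choice(rows2))
            sign2 = 1.0 if rng.random() < 0.5 else -1.0
            mag2 = mag * rng.lognormal(-0.3, 0.4)
            carriers2 = [t for t in active if rng.random() < 0.6]
            if carriers2:
                signals.append((rows2, causal2, sign2, mag2, carriers2))
                truth_secondary[gene] = block2

        # TSS distance is a property of the (gene, SNP) pair: drawn once per
        # signal from a Laplace-peak + uniform-background mixture
        w_peak = (config.opp_tss_peak_weight if label == "opposite"
                  else config.tss_peak_weight)
        for sig_rows, sig_causal, sig_sign, sig_mag, carriers in signals:
            hc = H[sig_causal]
            r_signed = {}
            for r in sig_rows:
                with np.errstate(invalid="ignore"):
                    r_signed[r] = float(np.corrcoef(hc, H[r])[0, 1])
            if rng.random() < w_peak:
                d0_raw = rng.laplace(0.0, config.tss_peak_scale_bp)
            else:
                d0_raw = rng.uniform(-CIS_WINDOW_BP, CIS_WINDOW_BP)
            d0 = int(np.clip(round(d0_raw), -CIS_WINDOW_BP, CIS_WINDOW_BP))
            tss_of = {
                r: int(np.clip(d0 + panel.positions[r] - panel.positions[sig_causal],
                               -CIS_WINDOW_BP, CIS_WINDOW_BP))
                for r in sig_rows}
            for t in carriers:
                # the planted reversal flips the gene's regulation in the
                # flip tissue as a whole, so every signal flips with it
                sign_t = sig_sign * (-1.0 if t == flip_tissue else 1.0)
                beta_t = sig_mag * float(
                    np.exp(rng.normal(0.0, config.beta_tissue_jitter)))
                for r in sig_rows:
                    rr = r_signed[r]
                    if not np.isfinite(rr):
                        continue
                    beta = sign_t * beta_t * (1.0 if r == sig_causal else rr)
                    if abs(beta) < 1e-6:
                        continue
                    if r != sig_causal:
                        p_detect = expit(config.detect_slope
                                         * (scale[t] * abs(beta)
                                            - config.detect_mid))
                        if rng.random() >= p_detect:
                            continue
                    exponent = min(1.30103 + gain[t] * abs(beta), 290.0)
                    pval = 10.0 ** (-exponent)
                    per_tissue[t].append((gene, panel.variant_keys[r],
                                          panel.rsids[r], tss_of[r], beta, pval))

    frames = {}
    for t in tissues:
        frames[t] = pd.DataFrame(
            per_tissue[t],
            columns=["gene_id", "variant_id", "rs_id_dbSNP", "tss_distance",
                     "slope", "pval_nominal"])
    truth = GroundTruth(gene_labels, causal, planted_pairs,
                        annotation_flagged, set(), truth_secondary)
    return frames, truth


# --- annotations -----------------------------------------------------------

def simulate_annotations(config: SimConfig, panel: ld_engine.HaplotypePanel,
                         truth: GroundTruth,
                         rng: np.random.Generator | None = None,
                         ) -> AnnotationMatrix:
    """Bernoulli annotation flags, boosted for SNPs of opposite genes.

    Availability is drawn per (cell, mark); the first cell line always has
    data for every mark so no mark is left without a denominator.
    """
    rng = rng if rng is not None else config.streams()["annotations"]
    cells = [f"CELL{i:03d}" for i in range(1, config.n_cells + 1)]
    flagged = np.array([r in truth.annotation_flagged for r in panel.rsids])
    rate = np.where(flagged, config.annot_background + config.annot_boost,
                    config.annot_background)
    cols = {}
    for cell in cells:
        for mark in MARKS:
            available = (cell == cells[0]
                         or rng.random() < config.annot_availability)
            draw = rng.random(panel.n_variants) < rate  # consume stream always
            if available:
                cols[(cell, mark)] = draw
    presence = pd.DataFrame(cols, index=pd.Index(panel.rsids, name="rsid"))
    presence.columns = pd.MultiIndex.from_tuples(presence.columns)
    return AnnotationMatrix(presence)


# --- GWAS catalog ----------------------------------------------------------

def simulate_gwas_catalog(config: SimConfig, panel: ld_engine.HaplotypePanel,
                          truth: GroundTruth,
                          rng: np.random.Generator | None = None,
                          ) -> pd.DataFrame:
    """Emit a GWAS-catalog TSV emulating trait associations.

    For each opposite gene's causal SNP, with probability ρ a same-block LD
    partner (verified r² > 0.8, falling back to the causal SNP itself) is
    reported with p < 5 × 10⁻⁸ and the causal SNP is flagged in the ground
    truth.  Background associations land in random blocks, and a handful of
    sub-threshold rows (p ≥ 5 × 10⁻⁸) exercise the loader's filter.
    """
    rng = rng if rng is not None else config.streams()["gwas"]
    spb = config.snps_per_block
    rows_of = lambda b: list(range(b * spb, (b + 1) * spb))
    records: list[tuple[str, str, float]] = []

    for gene in sorted(truth.opposite_genes()):
        block, causal_rsid = truth.causal[gene]
        if rng.random() >= config.gwas_rho:
            continue
        candidates = []
        for r in rows_of(block):
            rs = panel.rsids[r]
            if rs == causal_rsid:
                continue
            res = ld_engine.r2(causal_rsid, rs, panel)
            if res.defined and res.r2 > 0.8:
                candidates.append(rs)
        partner = (str(rng.choice(sorted(candidates))) if candidates
                   else causal_rsid)
        pval = 10.0 ** (-rng.uniform(8.5, 30.0))
        records.append((partner, f"trait_{gene}", pval))
        truth.gwas_partner_flagged.add(causal_rsid)

    for i in range(config.n_gwas_background):
        rs = panel.rsids[int(rng.integers(panel.n_variants))]
        records.append((rs, f"bg_trait_{i}", 10.0 ** (-rng.uniform(8.5, 30.0))))

    for i in range(max(3, config.n_gwas_background // 5)):
        rs = panel.rsids[int(rng.integers(panel.n_variants))]
        records.append((rs, f"weak_trait_{i}", 10.0 ** (-rng.uniform(3.0, 7.3))))

    return pd.DataFrame(records, columns=["SNPS", "DISEASE/TRAIT", "P-VALUE"])


# --- whole-cohort convenience ---------------------------------------------

@dataclass
class Cohort:
    config: SimConfig
    panel: ld_engine.HaplotypePanel
    tables: dict[str, TissueTable]
    frames: dict[str, pd.DataFrame]  # tables in the input TSV dialect
    truth: GroundTruth
    annotations: AnnotationMatrix
    gwas_frame: pd.DataFrame


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate everything in memory (panel, tables, annotations, GWAS)."""
    streams = config.streams()
    panel = simulate_panel(config, streams["panel"])
    frames, truth = simulate_eqtl_tables(config, panel, streams["eqtl"])
    annotations = simulate_annotations(config, panel, truth,
                                       streams["annotations"])
    gwas_frame = simulate_gwas_catalog(config, panel, truth, streams["gwas"])
    tables = {}
    for t, df in frames.items():
        tables[t] = TissueTable(
            tissue=t,
            df=pd.DataFrame({
                "gene_id": df["gene_id"],
                "variant_key": df["variant_id"],
                "rsid": df["rs_id_dbSNP"],
                "beta": df["slope"].astype(float),
                "pval": df["pval_nominal"].astype(float),
                "tss_distance": df["tss_distance"].astype(int),
            }),
            organ_system=config.organ_system(t))
    return Cohort(config, panel, tables, frames, truth, annotations, gwas_frame)


def write_cohort(config: SimConfig, outdir) -> Cohort:
    """Generate the cohort and write every input file the pipeline reads.

    Files: ``panel.vcf``, ``<TISSUE>.signif.tsv`` per tissue,
    ``annotations.tsv``, ``gwas_catalog.tsv``, ``ground_truth.json``.
    Byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    cohort.panel.to_vcf(outdir / "panel.vcf")
    for t, df in cohort.frames.items():
        df.to_csv(outdir / f"{t}.signif.tsv", sep="\t", index=False)
    cohort.annotations.to_tsv(outdir / "annotations.tsv")
    cohort.gwas_frame.to_csv(outdir / "gwas_catalog.tsv", sep="\t", index=False)
    cohort.truth.to_json(outdir / "ground_truth.json")
    return cohort
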