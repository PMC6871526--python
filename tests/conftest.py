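"""Shared fixtures: synthetic cohorts and derived pipeline products.

Session-scoped because cohort generation and classification are pure
functions of the config; tests must not mutate fixture objects.
"""

import numpy as np
import pytest

from oppeqtl import eqtl_io, ld_engine, pair_classifier, synthetic_data, tss_enrichment


@pytest.fixture(scope="session")
def default_cohort():
    """The default desk-scale study cohort: 200 genes x 6 tissues."""
    return synthetic_data.simulate_cohort(synthetic_data.SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_pipeline(default_cohort):
    """Classified analysis tables, designations and distance samples."""
    cohort = default_cohort
    top = eqtl_io.extract_top_eqtl(cohort.tables.values())
    analysis = pair_classifier.classify_tables(top, cohort.tables.values(),
                                               cohort.panel)
    desig = pair_classifier.aggregate_designations(analysis, top)
    samples = tss_enrichment.distance_samples(cohort.tables.values(), top, desig)
    return {"top": top, "analysis": analysis, "designations": desig,
            "samples": samples}


@pytest.fixture(scope="session")
def planted_cohort():
    """Strong-knob planted-enrichment cohort: one block per ~1.3 genes so
    per-SNP flags do not leak across genes, high TSS peak contrast, strong
    annotation boost and GWAS partner rate."""
    cfg = synthetic_data.SimConfig(
        seed=5, n_genes=400, n_blocks=300, theta_opp=0.15,
        tss_peak_weight=0.4, opp_tss_peak_weight=0.9,
        annot_background=0.15, annot_boost=0.5,
        gwas_rho=0.9, n_gwas_background=2)
    return synthetic_data.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_pipeline(planted_cohort):
    cohort = planted_cohort
    top = eqtl_io.extract_top_eqtl(cohort.tables.values())
    analysis = pair_classifier.classify_tables(top, cohort.tables.values(),
                                               cohort.panel)
    desig = pair_classifier.aggregate_designations(analysis, top)
    samples = tss_enrichment.distance_samples(cohort.tables.values(), top, desig)
    return {"top": top, "analysis": analysis, "designations": desig,
            "samples": samples}


def make_panel(hap_rows, positions=None, rsids=None, chrom="1"):
    """Small hand-built haplotype panel for LD unit tests."""
    H = np.asarray(hap_rows, dtype=np.int8)
    n = H.shape[0]
    positions = positions if positions is not None else [100 + 10 * i
                                                         for i in range(n)]
    rsids = rsids if rsids is not None else [f"rs{i + 1}" for i in range(n)]
    keys = [f"{chrom}_{p}_A_G_b37" for p in positions]
    return ld_engine.HaplotypePanel(
        keys, rsids, np.array([chrom] * n, dtype=object),
        np.array(positions), H)


@pytest.fixture
def tiny_panel():
    """Four SNPs over 8 haplotypes with known pairwise structure."""
    return make_panel([
        [1, 1, 1, 1, 0, 0, 0, 0],   # rs1
        [1, 1, 1, 1, 0, 0, 0, 0],   # rs2: perfect coupling with rs1
        [1, 1, 1, 1, 1, 0, 0, 0],   # rs3: partial LD with rs1
        [1, 1, 1, 1, 1, 1, 1, 1],   # rs4: monomorphic
    ])
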