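"""The 2x2 direction/LD classifier and the nested designation sets."""

import itertools
import math

import pandas as pd
import pytest

from oppeqtl import eqtl_io, pair_classifier as pc


def table_from_rows(tissue, rows):
    df = pd.DataFrame(rows, columns=["gene_id", "variant_key", "rsid", "beta",
                                     "pval", "tss_distance"])
    return eqtl_io.TissueTable(tissue, df)


def fixture_tables():
    """4 genes x 3 tissues with hand-placed signals."""
    return [
        table_from_rows("A", [
            ("G1", "1_1_A_G_b37", "rs1", 0.5, 1e-10, 0),
            ("G2", "1_2_A_G_b37", "rs2", -0.4, 1e-8, 10),
            ("G3", "1_3_A_G_b37", "rs3", 0.3, 1e-6, 20),
        ]),
        table_from_rows("B", [
            ("G1", "1_1_A_G_b37", "rs1", -0.2, 1e-9, 0),
            ("G2", "1_2_A_G_b37", "rs2", -0.6, 1e-7, 10),
            ("G4", "1_4_A_G_b37", "rs4", 0.9, 1e-12, 30),
        ]),
        table_from_rows("C", [
            ("G2", "1_5_A_G_b37", "rs5", 0.1, 1e-5, 40),
        ]),
    ]


class TestBuildTable:
    def test_gene_significant_in_one_tissue_is_ineligible(self):
        tables = fixture_tables()
        top = eqtl_io.extract_top_eqtl(tables)
        sig = eqtl_io.SignificanceIndex(tables)
        t = pc.build_analysis_table("G3", "A", "B", top, sig)
        assert t.status == pc.INELIGIBLE

    def test_identical_top_snp_copies_cross_cells(self):
        tables = fixture_tables()
        top = eqtl_io.extract_top_eqtl(tables)
        sig = eqtl_io.SignificanceIndex(tables)
        t = pc.build_analysis_table("G1", "A", "B", top, sig)
        assert t.snp_x == t.snp_y == "rs1"
        assert t.beta_xy == t.beta_yy and t.beta_yx == t.beta_xx
        assert t.r2 == 1.0

    def test_all_cells_match_direct_dictionary_lookups(self):
        tables = fixture_tables()
        top = eqtl_io.extract_top_eqtl(tables)
        sig = eqtl_io.SignificanceIndex(tables)
        lookup = {(tab.tissue, r.gene_id, r.rsid): r.beta
                  for tab in tables for r in tab.df.itertuples(index=False)}
        for gene in ("G1", "G2", "G3", "G4"):
            for tx, ty in itertools.combinations("ABC", 2):
                t = pc.build_analysis_table(gene, tx, ty, top, sig)
                if t.status == pc.INELIGIBLE:
                    continue
                assert t.beta_xx == lookup[(tx, gene, t.snp_x)]
                assert t.beta_yy == lookup[(ty, gene, t.snp_y)]
                assert t.beta_xy == lookup.get((ty, gene, t.snp_x), 0.0)
                assert t.beta_yx == lookup.get((tx, gene, t.snp_y), 0.0)


class TestEligibility:
    def make(self, snp_x, snp_y, bxy, byx):
        return pc.AnalysisTable("G", "A", "B", snp_x, snp_y,
                                beta_xx=0.5, beta_xy=bxy, beta_yx=byx,
                                beta_yy=0.3, status="pending")

    def test_identical_snps_always_eligible(self):
        assert pc.eligibility(self.make("rs1", "rs1", 0.3, 0.5))

    def test_distinct_snps_need_one_cross_signal(self):
        assert not pc.eligibility(self.make("rs1", "rs2", 0.0, 0.0))
        assert pc.eligibility(self.make("rs1", "rs2", -0.1, 0.0))
        assert pc.eligibility(self.make("rs1", "rs2", 0.0, 0.2))


class TestDirection:
    def make(self, bxx, bxy, byx, byy):
        return pc.AnalysisTable("G", "A", "B", "rs1", "rs2",
                                bxx, bxy, byx, byy, status="pending")

    def test_identical_snp_sign_flip_is_opposite(self):
        t = self.make(0.5, -0.3, 0.5, -0.3)
        assert pc.classify_direction(t) == pc.OPPOSITE

    def test_identical_snp_same_sign_is_same(self):
        t = self.make(0.5, 0.3, 0.5, 0.3)
        assert pc.classify_direction(t) == pc.SAME

    def test_all_cross_sign_patterns_match_rule_enumeration(self):
        # exhaustive 3x3 sign patterns of (beta_xy, beta_yx); zero counts
        # as "<= 0" on its side of the product rule
        for sx in (-0.2, 0.0, 0.2):
            for sy in (-0.3, 0.0, 0.3):
                t = self.make(0.4, sx, sy, 0.6)
                expected = (0.4 * sx <= 0) and (sy * 0.6 <= 0)
                got = pc.classify_direction(t) == pc.OPPOSITE
                assert got == expected, (sx, sy)


class TestGrouping:
    @pytest.mark.parametrize("direction, r2, expected", [
        (pc.OPPOSITE, 1.0, "1a"),
        (pc.OPPOSITE, 0.5, "1b"),
        (pc.OPPOSITE, 0.8, "1b"),   # strict threshold
        (pc.SAME, 0.95, "2a"),
        (pc.SAME, 0.8, "2b"),
        (pc.OPPOSITE, None, "1b"),  # undefined r2 = not in LD
    ])
    def test_group_assignment(self, direction, r2, expected):
        assert pc.assign_group(direction, r2) == expected

    def test_every_eligible_table_gets_exactly_one_group(self, default_pipeline):
        for t in default_pipeline["analysis"]:
            if t.status in (pc.INELIGIBLE, pc.EXCLUDED):
                continue
            assert t.status in pc.GROUPS

    def test_tissue_swap_preserves_direction_and_group(self, default_cohort,
                                                       default_pipeline):
        tables = list(default_cohort.tables.values())
        top = default_pipeline["top"]
        sig = eqtl_io.SignificanceIndex(tables)
        checked = 0
        for t in default_pipeline["analysis"]:
            if t.status not in pc.GROUPS or checked >= 200:
                continue
            s = pc.build_analysis_table(t.gene_id, t.tissue_y, t.tissue_x,
                                        top, sig)
            assert (s.snp_x, s.snp_y) == (t.snp_y, t.snp_x)
            assert pc.classify_direction(s) == pc.classify_direction(t)
            assert pc.assign_group(pc.classify_direction(s), t.r2) == t.status
            checked += 1
        assert checked > 50


class TestDesignations:
    def test_subset_chain_holds(self, default_pipeline):
        d = default_pipeline["designations"]
        assert d.opp_genes <= d.multi_genes <= d.eqtl_genes
        assert d.opp_snps <= d.multi_snps <= d.top_eqtl_snps

    def test_lowering_threshold_never_shrinks_sets(self, default_cohort,
                                                   default_pipeline):
        top = default_pipeline["top"]
        tables = default_cohort.tables.values()
        prev = None
        for thr in (0.95, 0.8, 0.5, 0.0):
            analysis = pc.classify_tables(top, tables, default_cohort.panel,
                                          threshold=thr)
            d = pc.aggregate_designations(analysis, top)
            if prev is not None:
                assert prev.multi_genes <= d.multi_genes
                assert prev.opp_genes <= d.opp_genes
                assert prev.multi_snps <= d.multi_snps
                assert prev.opp_snps <= d.opp_snps
            prev = d

    def test_null_cohort_recovers_no_opposites(self):
        from oppeqtl import synthetic_data
        cfg = synthetic_data.SimConfig(seed=21, n_genes=60, theta_opp=0.0)
        cohort = synthetic_data.simulate_cohort(cfg)
        top = eqtl_io.extract_top_eqtl(cohort.tables.values())
        analysis = pc.classify_tables(top, cohort.tables.values(), cohort.panel)
        d = pc.aggregate_designations(analysis, top)
        assert d.opp_genes == set()

    def test_single_planted_pair_yields_one_evidence_entry(self):
        # one gene opposite between exactly one pair of tissues
        tables = [
            table_from_rows("A", [("G1", "1_1_A_G_b37", "rs1", 0.5, 1e-9, 0)]),
            table_from_rows("B", [("G1", "1_1_A_G_b37", "rs1", -0.5, 1e-9, 0)]),
            table_from_rows("C", [("G2", "1_2_A_G_b37", "rs2", 0.1, 1e-6, 0)]),
        ]
        top = eqtl_io.extract_top_eqtl(tables)
        sig = eqtl_io.SignificanceIndex(tables)
        t = pc.build_analysis_table("G1", "A", "B", top, sig)
        t.status = pc.assign_group(pc.classify_direction(t), t.r2)
        d = pc.aggregate_designations([t], top)
        assert d.opp_genes == {"G1"}
        assert d.gene_evidence["G1"] == [("A", "B", "1a")]


class TestCountIdentity:
    def test_tables_per_cohort_formula(self):
        assert math.comb(48, 2) == 1128
        assert pc.count_analysis_tables(31_212, 48) == 35_207_136

    def test_one_table_per_gene_and_tissue_pair(self, default_cohort,
                                                default_pipeline):
        top = default_pipeline["top"]
        n_tissues = default_cohort.config.n_tissues
        assert len(default_pipeline["analysis"]) == \
            pc.count_analysis_tables(len(top.genes()), n_tissues)
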