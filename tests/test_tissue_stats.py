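"""Per-tissue summaries, opposite-fraction matrix, clustering, p-value maps."""

import numpy as np
import pandas as pd
import pytest

from oppeqtl import eqtl_io, pair_classifier as pc, tissue_stats as ts


def table_from_rows(tissue, rows):
    df = pd.DataFrame(rows, columns=["gene_id", "variant_key", "rsid", "beta",
                                     "pval", "tss_distance"])
    return eqtl_io.TissueTable(tissue, df)


class TestPerTissueCounts:
    def test_single_tissue_cohort_has_no_multi_or_opp(self):
        tables = [table_from_rows("A", [("G1", "1_1_A_G_b37", "rs1",
                                         0.5, 1e-9, 0)])]
        top = eqtl_io.extract_top_eqtl(tables)
        d = pc.aggregate_designations([], top)
        summary = ts.per_tissue_counts(d)
        assert summary.table.loc["A", "n_multi_genes"] == 0
        assert summary.table.loc["A", "n_opp_genes"] == 0

    def test_counts_match_naive_recount_from_evidence(self, default_pipeline):
        d = default_pipeline["designations"]
        summary = ts.per_tissue_counts(d)
        for tissue in summary.table.index:
            multi = {g for g, evs in d.gene_evidence.items()
                     if any(tissue in (tx, ty) for tx, ty, _ in evs)}
            opp = {g for g, evs in d.gene_evidence.items()
                   if any(tissue in (tx, ty) and grp == "1a"
                          for tx, ty, grp in evs)}
            assert summary.table.loc[tissue, "n_multi_genes"] == len(multi)
            assert summary.table.loc[tissue, "n_opp_genes"] == len(opp)
            assert summary.table.loc[tissue, "n_eqtl_genes"] == len(
                d.per_tissue_eqtl_genes[tissue])

    def test_identical_counts_give_zero_cv(self):
        top = eqtl_io.TopEqtlMap({
            f"G{i}": {t: eqtl_io.TopEntry("rs1", "1_1_A_G_b37", 0.5, 1e-9, 0)
                      for t in ("A", "B", "C")}
            for i in range(4)})
        d = pc.aggregate_designations([], top)
        summary = ts.per_tissue_counts(d)
        assert summary.cv["n_eqtl_genes"] == pytest.approx(0.0)

    def test_ratios_bounded_and_ordered(self, default_pipeline):
        t = ts.per_tissue_counts(default_pipeline["designations"]).table
        assert ((t["opp_over_eqtl"].dropna() >= 0)
                & (t["opp_over_eqtl"].dropna() <= 1)).all()
        assert (t["n_opp_genes"] <= t["n_multi_genes"]).all()
        assert (t["n_multi_genes"] <= t["n_eqtl_genes"]).all()


class TestOppositeFractionMatrix:
    def test_identical_beta_tables_give_zero(self):
        rows = [("G1", "1_1_A_G_b37", "rs1", 0.5, 1e-9, 0),
                ("G2", "1_2_A_G_b37", "rs2", -0.3, 1e-8, 5)]
        m = ts.opposite_fraction_matrix([table_from_rows("A", rows),
                                         table_from_rows("B", rows)])
        assert m.fraction.loc["A", "B"] == 0.0
        assert m.n_shared.loc["A", "B"] == 2

    def test_fully_negated_tables_give_one(self):
        rows = [("G1", "1_1_A_G_b37", "rs1", 0.5, 1e-9, 0),
                ("G2", "1_2_A_G_b37", "rs2", -0.3, 1e-8, 5)]
        neg = [(g, v, r, -b, p, d) for g, v, r, b, p, d in rows]
        m = ts.opposite_fraction_matrix([table_from_rows("A", rows),
                                         table_from_rows("B", neg)])
        assert m.fraction.loc["A", "B"] == 1.0

    def test_matches_bruteforce_pairwise_comparison(self, default_cohort):
        tables = list(default_cohort.tables.values())[:3]
        m = ts.opposite_fraction_matrix(tables)
        for i, ta in enumerate(tables):
            for tb in tables[i + 1:]:
                a = {(r.gene_id, r.variant_key): r.beta
                     for r in ta.df.itertuples(index=False)}
                b = {(r.gene_id, r.variant_key): r.beta
                     for r in tb.df.itertuples(index=False)}
                shared = set(a) & set(b)
                opp = sum(1 for k in shared if a[k] * b[k] < 0)
                assert m.n_shared.loc[ta.tissue, tb.tissue] == len(shared)
                if shared:
                    assert m.fraction.loc[ta.tissue, tb.tissue] == \
                        pytest.approx(opp / len(shared))
                    # fraction * n_shared is the opposite count (an integer)
                    prod = m.fraction.loc[ta.tissue, tb.tissue] * len(shared)
                    assert prod == pytest.approx(round(prod))

    def test_invariant_to_tissue_input_order(self, default_cohort):
        tables = list(default_cohort.tables.values())
        m1 = ts.opposite_fraction_matrix(tables)
        m2 = ts.opposite_fraction_matrix(tables[::-1])
        pd.testing.assert_frame_equal(m1.fraction, m2.fraction)

    def test_no_shared_records_flagged_undefined(self):
        m = ts.opposite_fraction_matrix([
            table_from_rows("A", [("G1", "1_1_A_G_b37", "rs1", 0.5, 1e-9, 0)]),
            table_from_rows("B", [("G2", "1_2_A_G_b37", "rs2", 0.5, 1e-9, 0)]),
        ])
        assert np.isnan(m.fraction.loc["A", "B"])
        assert m.undefined_pairs() == [("A", "B")]


class TestClustering:
    def matrix(self, frac, tissues):
        df = pd.DataFrame(frac, index=tissues, columns=tissues, dtype=float)
        n = pd.DataFrame(10, index=tissues, columns=tissues)
        return ts.OppositeFractionMatrix(tissues, df, n)

    def test_identical_rows_merge_first_at_height_zero(self):
        m = self.matrix([[0, .1, .5], [.1, 0, .5], [.5, .5, 0]],
                        ["A", "B", "C"])
        # rows A and C of the fraction matrix are NOT identical; A vs B are
        # symmetric twins -> distance sqrt(2)*0.1; make true duplicates:
        m.fraction.loc["B"] = m.fraction.loc["A"].values
        res = ts.cluster_tissues(m)
        first = res.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0)

    def test_three_tissue_heights_match_hand_computed_distances(self):
        m = self.matrix([[0, .2, .6], [.2, 0, .4], [.6, .4, 0]],
                        ["A", "B", "C"])
        res = ts.cluster_tissues(m)
        X = m.fraction.to_numpy()
        d = lambda i, j: float(np.sqrt(((X[i] - X[j]) ** 2).sum()))
        dists = sorted([d(0, 1), d(0, 2), d(1, 2)])
        assert res.linkage[0, 2] == pytest.approx(dists[0])
        # complete linkage: the final merge height is the max pairwise distance
        assert res.linkage[1, 2] == pytest.approx(dists[-1])

    def test_block_structured_matrix_separates_planted_groups(self):
        rng = np.random.default_rng(0)
        tissues = [f"T{i}" for i in range(6)]
        base = np.full((6, 6), 0.05)
        base[:3, 3:] = base[3:, :3] = 0.4        # high discordance across groups
        base += rng.uniform(0, 0.01, (6, 6))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 0.0)
        res = ts.cluster_tissues(self.matrix(base, tissues))
        order = res.leaf_order
        first3 = {t for t in order[:3]}
        assert first3 in ({"T0", "T1", "T2"}, {"T3", "T4", "T5"})
        assert res.newick.endswith(";") and all(t in res.newick for t in tissues)

    def test_fewer_than_two_tissues_is_error(self):
        m = self.matrix([[0.0]], ["A"])
        with pytest.raises(ValueError):
            ts.cluster_tissues(m)

    def test_deterministic_across_runs(self, default_cohort):
        tables = list(default_cohort.tables.values())
        m = ts.opposite_fraction_matrix(tables)
        r1 = ts.cluster_tissues(m)
        r2 = ts.cluster_tissues(ts.opposite_fraction_matrix(tables))
        assert r1.leaf_order == r2.leaf_order
        assert r1.newick == r2.newick


class TestPvalueDeviation:
    def test_histograms_normalized_and_difference_sums_to_zero(
            self, default_pipeline):
        dens = ts.pvalue_deviation_density(default_pipeline["analysis"])
        assert dens.hist_multi.sum() == pytest.approx(1.0)
        assert dens.hist_opp.sum() == pytest.approx(1.0)
        assert dens.difference.sum() == pytest.approx(0.0, abs=1e-12)

    def test_equal_pvalues_land_on_the_diagonal(self):
        t = pc.AnalysisTable("G", "A", "B", "rs1", "rs1", 0.5, 0.5, 0.5, 0.5,
                             pval_x=1e-4, pval_y=1e-4, r2=1.0, status="1a")
        dens = ts.pvalue_deviation_density([t])
        ij = np.argwhere(dens.hist_opp > 0)
        assert len(ij) == 1 and ij[0][0] == ij[0][1]   # 4.0 -> bin 16

    def test_all_mass_where_first_axis_dominates(self, default_pipeline):
        dens = ts.pvalue_deviation_density(default_pipeline["analysis"])
        # p-value_1 <= p-value_2 so -log10 p1 >= -log10 p2: upper triangle empty
        above = np.triu(dens.hist_multi, k=1).sum()
        assert above == pytest.approx(0.0)
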