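"""Family counts, dominant coding and contingency tables against the
published margins and a brute-force chi-square."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import famepi as fp
from famepi.aggregation import trend_test

SNP1, SNP2 = "rs4242382", "rs10486567"

# the published carrier-by-case-count cells, frozen
TABLE1 = {
    (SNP1, "all"): [[198, 103], [228, 90], [79, 80], [80, 89]],
    (SNP2, "all"): [[174, 127], [193, 123], [82, 76], [85, 83]],
    (SNP1, "aggressive"): [[265, 173], [209, 94], [97, 84], [14, 11]],
    (SNP2, "aggressive"): [[257, 179], [163, 139], [99, 81], [15, 10]],
}
TABLE1_PCT = {
    (SNP1, "all"): [34.2, 28.3, 50.3, 52.7],
    (SNP2, "all"): [42.2, 38.9, 48.1, 49.4],
    (SNP1, "aggressive"): [39.5, 31.0, 46.4, 44.0],
    (SNP2, "aggressive"): [41.1, 46.0, 45.0, 40.0],
}


class TestFamilyCounts:
    def test_counts_per_family(self, tiny_cohort):
        fc = fp.family_case_counts(tiny_cohort).set_index("family_id")
        assert fc.loc["f1", "n_members"] == 2
        assert fc.loc["f1", "n_affected"] == 2
        assert fc.loc["f1", "n_aggressive"] == 1
        assert fc.loc["f2", "n_affected"] == 1
        assert fc.loc["f2", "n_aggressive"] == 0

    def test_fixture_totals_match_study(self, table1_cohort):
        fc = fp.family_case_counts(table1_cohort)
        assert len(fc) == 76
        assert fc["n_affected"].sum() == 228
        assert fc["n_aggressive"].sum() == 57
        # per-family affected distribution: 30x2, 26x3, 12x4, 6x5, 2x6
        dist = fc["n_affected"].value_counts().sort_index()
        assert dist.to_dict() == {2: 30, 3: 26, 4: 12, 5: 6, 6: 2}

    def test_invariant_aggressive_le_affected_le_members(self, table1_cohort):
        fc = fp.family_case_counts(table1_cohort)
        assert ((fc["n_aggressive"] <= fc["n_affected"])
                & (fc["n_affected"] <= fc["n_members"])).all()

    def test_nonaggressive_outcome_is_difference(self, tiny_cohort):
        non = fp.family_outcome(tiny_cohort, "nonaggressive")
        assert non["f1"] == 1 and non["f2"] == 1

    def test_aggressive_endpoint_without_flags_errors(self, tiny_cohort):
        data = tiny_cohort.data.copy()
        data["aggressive"] = pd.array([pd.NA] * 4, dtype="boolean")
        bare = fp.Cohort(data=data, snps=tiny_cohort.snps)
        with pytest.raises(fp.CohortValidationError, match="aggressive"):
            fp.family_outcome(bare, "aggressive")


class TestDominantCode:
    @pytest.mark.parametrize(
        "genotype,expected", [("AG", 1), ("AA", 1), ("GG", 0), (None, None)]
    )
    def test_carrier_iff_risk_allele_present(self, genotype, expected):
        assert fp.dominant_code(genotype, "A") == expected

    def test_risk_allele_must_be_single(self):
        with pytest.raises(ValueError):
            fp.dominant_code("AG", "AG")

    def test_vectorised_codes_propagate_missing(self, tiny_cohort):
        codes = fp.dominant_codes(tiny_cohort, "rs1")
        assert codes[0] == 1 and codes[1] == 0 and codes[2] == 1
        assert np.isnan(codes[3])


class TestCarrierCountTable:
    @pytest.mark.parametrize("snp,endpoint", list(TABLE1))
    def test_fixture_reproduces_published_cells(self, table1_cohort, snp, endpoint):
        tab = fp.carrier_count_table(table1_cohort, snp, endpoint=endpoint)
        assert tab.cells.tolist() == TABLE1[(snp, endpoint)]
        np.testing.assert_allclose(
            np.round(tab.row_percentages[:, 1], 1), TABLE1_PCT[(snp, endpoint)]
        )

    def test_column_sums_equal_genotyped_subjects(self, table1_cohort):
        t1 = fp.carrier_count_table(table1_cohort, SNP1)
        t2 = fp.carrier_count_table(table1_cohort, SNP2)
        assert t1.totals.tolist() == [585, 362]
        assert t2.totals.tolist() == [534, 409]  # 4 subjects ungenotyped

    def test_row_percentages_sum_to_100(self, table1_cohort):
        tab = fp.carrier_count_table(table1_cohort, SNP1)
        np.testing.assert_allclose(tab.row_percentages.sum(axis=1), 100.0)

    def test_single_family_cohort_single_bin(self, tiny_cohort):
        one = fp.Cohort(
            data=tiny_cohort.data[tiny_cohort.data.family_id == "f1"].reset_index(
                drop=True
            ),
            snps=tiny_cohort.snps,
        )
        tab = fp.carrier_count_table(one, "rs1", bins=[2])
        assert tab.cells.tolist() == [[1, 1]]
        np.testing.assert_allclose(tab.row_percentages, [[50.0, 50.0]])

    def test_empty_bin_reported_with_zero_counts(self, tiny_cohort):
        tab = fp.carrier_count_table(tiny_cohort, "rs1", bins=[1, 2, 3])
        assert tab.cells[2].tolist() == [0, 0]

    def test_count_outside_bins_is_an_error(self, tiny_cohort):
        with pytest.raises(ValueError, match="outside bins"):
            fp.carrier_count_table(tiny_cohort, "rs1", bins=[5, "6+"])


class TestChisq:
    def test_homogeneous_table_gives_zero(self):
        tab = fp.ContingencyTable(
            "x", "all", (0, 1), np.array([[10, 10], [10, 10]]), np.full((2, 2), 50.0)
        )
        stat, df, p = fp.contingency_chisq(tab)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # rows 30/30, cols 30/30 -> E = 15 everywhere, sum (O-E)^2/E = 4*25/15
        tab = fp.ContingencyTable(
            "x", "all", (0, 1), np.array([[20, 10], [10, 20]]), np.zeros((2, 2))
        )
        stat, df, p = fp.contingency_chisq(tab)
        assert stat == pytest.approx(100 / 15, rel=1e-12)
        assert df == 1

    @given(
        st.lists(
            st.tuples(st.integers(1, 40), st.integers(1, 40)),
            min_size=2,
            max_size=6,
        )
    )
    def test_matches_bruteforce_pearson_formula(self, rows):
        cells = np.array(rows, dtype=float)
        if (cells.sum(axis=0) == 0).any():
            return
        tab = fp.ContingencyTable("x", "all", tuple(range(len(rows))), cells.astype(int),
                                  np.zeros_like(cells))
        stat, df, _ = fp.contingency_chisq(tab)
        expected = np.outer(cells.sum(1), cells.sum(0)) / cells.sum()
        brute = ((cells - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(brute, abs=1e-10)
        assert df == len(rows) - 1

    def test_fixture_association_is_overwhelming(self, table1_cohort):
        tab = fp.carrier_count_table(table1_cohort, SNP1)
        _, _, p = fp.contingency_chisq(tab)
        assert p < 1e-4

    def test_zero_bin_advises_merge(self):
        tab = fp.ContingencyTable(
            "x", "all", (0, 1), np.array([[10, 5], [0, 0]]), np.zeros((2, 2))
        )
        with pytest.raises(ValueError, match="merge"):
            fp.contingency_chisq(tab)

    def test_trend_test_detects_increasing_carrier_share(self, table1_cohort):
        tab = fp.carrier_count_table(table1_cohort, SNP1)
        z, p = trend_test(tab)
        assert z > 0 and p < 1e-4
        flipped = fp.ContingencyTable(
            tab.snp, tab.endpoint, tab.bins, tab.cells[:, ::-1].copy(),
            tab.row_percentages,
        )
        z2, _ = trend_test(flipped)
        assert z2 == pytest.approx(-z)
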