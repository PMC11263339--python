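"""Contingency tables, Pearson X^2, G-test and printed proportions."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, chi2_contingency

from intersexpr.phenotype import (
    ContingencyTable,
    PhenotypeRecord,
    build_contingency,
    g_test,
    pearson_chi2,
    proportion,
    read_records,
    write_records,
)
from intersexpr.records import (
    intersex_by_pupa_table,
    mag_by_pupa_table,
    rrm_backcross_records,
    uum_backcross_records,
)


def _table(values, rows=None, cols=None) -> ContingencyTable:
    arr = np.asarray(values, dtype=int)
    rows = rows or [f"r{i}" for i in range(arr.shape[0])]
    cols = cols or [f"c{i}" for i in range(arr.shape[1])]
    return ContingencyTable(pd.DataFrame(arr, index=rows, columns=cols))


class TestBuildContingency:
    def test_no_records_is_an_error(self):
        with pytest.raises(ValueError, match="no records"):
            build_contingency([], "pupa_type", "adult_class")

    def test_known_counts_are_exact(self):
        recs = [
            PhenotypeRecord("a", "I", adult_class=1),
            PhenotypeRecord("b", "I", adult_class=3),
            PhenotypeRecord("c", "II", adult_class=3),
            PhenotypeRecord("d", "II", adult_class=None),  # died: dropped
        ]
        t = build_contingency(recs, "pupa_type", "adult_class")
        assert t.observed.loc["I", 1] == 1
        assert t.observed.loc["I", 3] == 1
        assert t.observed.loc["II", 3] == 1
        assert t.n == 3

    def test_collapse_applied_before_counting(self):
        recs = [PhenotypeRecord(f"x{i}", "III", adult_class=c) for i, c in
                enumerate([3, 4, 5, 1])]
        t = build_contingency(
            recs, "pupa_type", "adult_class",
            col_collapse={3: "ix", 4: "ix", 5: "ix"},
        )
        assert t.observed.loc["III", "ix"] == 3
        assert t.observed.loc["III", 1] == 1

    def test_uum_row_totals_match_printed_counts(self):
        t = intersex_by_pupa_table(uum_backcross_records())
        assert t.observed.sum(axis=1).tolist() == [21, 23, 16]


class TestPearsonChi2:
    def test_observed_equals_expected_gives_zero(self):
        stat, df, p = pearson_chi2(_table([[10, 10], [10, 10]]))
        assert stat == 0.0
        assert df == 1
        assert p == 1.0

    def test_hand_computed_statistic(self):
        """X^2 from direct O/E arithmetic on a fixed 3x2 table."""
        o = np.array([[5, 16], [18, 5], [15, 1]], dtype=float)
        e = np.outer(o.sum(1), o.sum(0)) / o.sum()
        want = ((o - e) ** 2 / e).sum()
        stat, df, p = pearson_chi2(_table(o.astype(int)))
        assert stat == pytest.approx(want, rel=1e-12)
        assert df == 2
        assert p == pytest.approx(float(chi2.sf(want, 2)), abs=1e-12)

    def test_doubling_cells_doubles_statistic(self):
        t1 = _table([[5, 16], [18, 5], [15, 1]])
        t2 = _table([[10, 32], [36, 10], [30, 2]])
        assert pearson_chi2(t2)[0] == pytest.approx(2 * pearson_chi2(t1)[0], rel=1e-12)

    def test_agrees_with_independent_implementation(self):
        o = np.array([[12, 7, 3], [5, 9, 14]])
        stat, df, p = pearson_chi2(_table(o))
        ref = chi2_contingency(o, correction=False)
        assert stat == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            pearson_chi2(_table([[3, 4, 5]]))

    def test_permutation_invariance(self):
        o = [[5, 16], [18, 5], [15, 1]]
        t1 = _table(o)
        t2 = _table([r[::-1] for r in o[::-1]])
        assert pearson_chi2(t1)[0] == pytest.approx(pearson_chi2(t2)[0], rel=1e-12)
        assert g_test(t1)[0] == pytest.approx(g_test(t2)[0], rel=1e-12)


class TestGTest:
    def test_observed_equals_expected_gives_zero(self):
        stat, df, p = g_test(_table([[7, 7], [7, 7]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        o = np.array([[5, 16], [18, 5], [15, 1]], dtype=float)
        e = np.outer(o.sum(1), o.sum(0)) / o.sum()
        want = 2 * (o * np.log(o / e)).sum()
        stat, df, _ = g_test(_table(o.astype(int)))
        assert stat == pytest.approx(want, rel=1e-12)

    def test_zero_observed_cells_contribute_nothing(self):
        stat, _, _ = g_test(_table([[0, 20], [10, 10]]))
        assert np.isfinite(stat) and stat > 0

    def test_agrees_with_independent_implementation(self):
        o = np.array([[12, 7, 3], [5, 9, 14]])
        stat, df, p = g_test(_table(o))
        ref = chi2_contingency(o, correction=False, lambda_="log-likelihood")
        assert stat == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_asymptotic_agreement_with_chi2(self, rng):
        """On large-count simulated tables G and X^2 agree within 5%."""
        for _ in range(10):
            # independent margins: the asymptotic equivalence holds under H0
            probs = np.outer(rng.dirichlet([5, 5]), rng.dirichlet([5, 5]))
            o = rng.multinomial(20_000, probs.ravel()).reshape(2, 2)
            t = _table(o)
            g = g_test(t)[0]
            x2 = pearson_chi2(t)[0]
            if x2 > 1.0:  # ratio is uninformative at ~0
                assert g == pytest.approx(x2, rel=0.05)


class TestProportions:
    def test_printed_uum_percentages(self):
        t = intersex_by_pupa_table(uum_backcross_records())
        assert proportion(t, "I", ["intersex"]) == 23.81
        assert proportion(t, "II", ["intersex"]) == 78.26
        assert proportion(t, "III", ["intersex"]) == 93.75

    def test_printed_rrm_percentages(self):
        t = intersex_by_pupa_table(rrm_backcross_records())
        assert proportion(t, "I", ["intersex"]) == 41.18
        assert proportion(t, "II", ["intersex"]) == 76.92
        assert proportion(t, "III", ["intersex"]) == 85.29

    def test_printed_mag_percentage(self):
        t = mag_by_pupa_table(uum_backcross_records())
        assert proportion(t, "I", [2]) == 76.19

    def test_zero_selection_is_zero_percent(self):
        t = _table([[5, 0], [1, 1]])
        assert proportion(t, "r0", ["c1"]) == 0.0

    def test_zero_row_total_is_an_error(self):
        t = _table([[5, 3], [0, 0], [1, 1]])
        with pytest.raises(ValueError, match="zero"):
            proportion(t, "r1", ["c0"])


class TestRecordIO:
    def test_round_trip(self, tmp_path):
        recs = uum_backcross_records()[:10] + [PhenotypeRecord("dead", "II")]
        path = tmp_path / "r.csv"
        write_records(recs, path)
        assert read_records(path) == recs

    def test_adult_fields_require_eclosion(self):
        with pytest.raises(ValueError, match="adult"):
            PhenotypeRecord("x", "I", adult_class=None, mag_count=2)
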