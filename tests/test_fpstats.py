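"""False-positive enrichment: expected counts, chi-squared tests, consistency."""

import numpy as np
import pandas as pd
import pytest

from nbstiming.fpstats import (
    DiseaseMarkerSpec,
    FPCountTable,
    category_test,
    classify_consistency,
    count_fp,
    enrichment,
    expected_counts,
    gof_test,
    load_published_fp_counts,
    load_published_neg_sizes,
    published_count_table,
    share_pct,
    significance_stars,
    table_report,
)

NEG = (90060, 305674, 19135)


def chi2_oracle(obs, exp):
    """Longhand Pearson statistic."""
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp))


class TestExpectedCounts:
    def test_conservation(self):
        exact, _ = expected_counts((44, 381, 46), NEG)
        assert exact.sum() == pytest.approx(471, abs=1e-9)

    def test_published_carnitine_row(self):
        exact, display = expected_counts((44, 381, 46), NEG)
        assert np.allclose(exact, (102.24, 347.03, 21.72), atol=0.01)
        assert list(display) == [102, 347, 22]

    def test_symmetry_under_equal_sizes(self):
        exact, display = expected_counts((10, 12, 8), (5, 5, 5))
        assert np.allclose(exact, 10.0)
        assert list(display) == [10, 10, 10]

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero observed total"):
            expected_counts((0, 0, 0), NEG)

    def test_rounding_half_away_from_zero(self):
        # 4.52 -> 5 and 0.55 -> 1 (PA and HCY late cells)
        _, pa = expected_counts((29, 65, 4), NEG)
        _, hcy = expected_counts((3, 9, 0), NEG)
        assert pa[2] == 5 and hcy[2] == 1


class TestGofTest:
    def test_exact_agreement_gives_p_one(self):
        res = gof_test((217, 737, 46), (217, 737, 46))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 2

    def test_strong_departure_is_significant(self):
        res = gof_test((44, 381, 46), NEG)
        assert res.p_value < 0.001

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(100):
            neg = rng.integers(50, 10_000, size=3)
            obs = rng.integers(0, 200, size=3)
            if obs.sum() == 0:
                continue
            exp = obs.sum() * neg / neg.sum()
            res = gof_test(obs, neg)
            assert res.statistic == pytest.approx(chi2_oracle(obs, exp), abs=1e-10)

    def test_small_expected_warns(self):
        with pytest.warns(UserWarning, match="below 5"):
            gof_test((3, 9, 0), NEG)


class TestCategoryTest:
    def test_exact_share_gives_p_one(self):
        res = category_test((217, 737, 46), (2170, 7370, 460), "early")
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_early_excess_detected(self):
        assert category_test((66, 97, 27), NEG, "early").p_value < 0.001  # MMA
        assert category_test((51, 112, 0), NEG, "early").p_value < 0.05  # PKU

    def test_matches_two_cell_oracle(self, rng):
        for _ in range(100):
            neg = rng.integers(100, 10_000, size=3)
            obs = rng.integers(1, 100, size=3)
            pi = neg[0] / neg.sum()
            total = obs.sum()
            exp = [total * pi, total * (1 - pi)]
            res = category_test(obs, neg, "early")
            assert res.statistic == pytest.approx(
                chi2_oracle([obs[0], total - obs[0]], exp), abs=1e-10
            )

    def test_degenerate_share_rejected(self):
        with pytest.raises(ValueError, match="between 0 and 1"):
            category_test((5, 5, 0), (10, 0, 0), "early")


class TestCountFP:
    def test_window_tallies_and_percentages(self):
        cases = pd.DataFrame({
            "disease": ["D"] * 10,
            "aabc": [30] * 10,
        })
        table = count_fp(cases, neg_sizes=NEG)
        assert table.counts.loc["D"].tolist() == [0, 10, 0]
        assert table.percentages().loc["D"].tolist() == [0.0, 100.0, 0.0]

    def test_published_percentages(self):
        pct = published_count_table().percentages()
        assert pct.loc["CTD"].tolist() == [9.3, 80.9, 9.8]
        assert pct.loc["MMA"].tolist() == [34.7, 51.1, 14.2]

    def test_out_of_window_cases_excluded(self):
        cases = pd.DataFrame({"disease": ["D"] * 4, "aabc": [10, 30, 30, 180]})
        table = count_fp(cases, neg_sizes=NEG)
        assert int(table.totals["D"]) == 2

    def test_reference_restriction_applied(self):
        cases = pd.DataFrame({
            "disease": ["D", "D", "D"],
            "aabc": [30, 30, 30],
            "ga": [39, 36, 39],
            "bw": [3000, 3000, 2000],
            "tpn": ["no", "no", "no"],
        })
        table = count_fp(cases, neg_sizes=NEG)
        assert int(table.totals["D"]) == 1

    def test_empty_case_list_has_nan_percentages(self):
        cases = pd.DataFrame({
            "disease": pd.Series(["D"], dtype=str), "aabc": [30]})
        table = count_fp(cases, neg_sizes=NEG)
        empty = FPCountTable(
            counts=pd.DataFrame({"early": [0], "standard": [0], "late": [0]},
                                index=pd.Index(["E"], name="disease")),
            neg_sizes=NEG,
        )
        assert empty.percentages().isna().all().all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            FPCountTable(
                counts=pd.DataFrame({"early": [-1], "standard": [0], "late": [0]},
                                    index=pd.Index(["D"], name="disease")),
                neg_sizes=NEG,
            )


@pytest.fixture(scope="module")
def published_calls():
    with pytest.warns(UserWarning, match="below 5"):
        report = table_report(published_count_table(),
                              marker_info=load_published_fp_counts())
    return report


class TestConsistency:
    def _call(self, disease, category, d, direction):
        table = published_count_table()
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                enr = enrichment(table, disease)
        spec = DiseaseMarkerSpec(disease, "X", direction)
        return classify_consistency(d, spec, enr, category)

    def test_elevated_marker_with_early_excess_is_consistent(self):
        call = self._call("PKU", "early", 0.55, "elevated")
        assert call.call == "consistent"

    def test_decreased_marker_with_early_deficit_is_consistent(self):
        call = self._call("CTD", "early", 0.23, "decreased")
        assert call.call == "consistent"

    def test_excess_against_prediction_is_inconsistent(self):
        call = self._call("VLCADD", "late", -0.26, "elevated")
        assert call.call == "inconsistent"

    def test_small_effect_is_indeterminate(self):
        call = self._call("CTD", "late", -0.015, "decreased")
        assert call.call == "indeterminate"

    def test_predicted_direction_without_significance_is_indeterminate(self):
        # HCY early: d = 0.50 but only 3 false positives
        call = self._call("HCY", "early", 0.50, "elevated")
        assert call.call == "indeterminate"
        assert "not significant" in call.rationale["reason"]

    def test_full_published_calls(self, published_calls):
        calls = published_calls
        assert calls.loc["PKU", "call_early"] == "consistent"
        assert calls.loc["MMA", "call_early"] == "consistent"
        assert calls.loc["IVA", "call_early"] == "consistent"
        assert calls.loc["CTD", "call_early"] == "consistent"
        assert calls.loc["OTCD", "call_late"] == "consistent"
        assert calls.loc["PKU", "call_late"] == "consistent"
        assert calls.loc["VLCADD", "call_late"] == "inconsistent"
        assert calls.loc["CITR", "call_late"] == "inconsistent"
        assert calls.loc["IVA", "call_late"] == "inconsistent"
        assert calls.loc["PA", "call_early"] == "indeterminate"
        assert calls.loc["HCY", "call_early"] == "indeterminate"
        assert calls.loc["HCY", "call_late"] == "indeterminate"


class TestReport:
    def test_every_published_expected_cell_reproduced(self, published_calls):
        printed = {
            "CTD": (102, 347, 22), "PA": (21, 72, 5), "MMA": (41, 140, 9),
            "IVA": (6, 21, 1), "VLCADD": (29, 97, 6), "CITR": (21, 71, 4),
            "OTCD": (53, 181, 11), "HCY": (3, 9, 1), "PKU": (35, 120, 7),
        }
        for disease, cells in printed.items():
            got = tuple(
                published_calls.loc[disease, f"exp_{c}"] for c in ("early", "standard", "late")
            )
            assert got == cells, disease

    def test_stars_tiering(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.02) == "*"
        assert significance_stars(0.2) == ""

    def test_share_pct(self):
        assert share_pct(414_869, 500_539) == 82.9
        assert share_pct(90_060, 414_869) == 21.7

    def test_packaged_fixture_integrity(self):
        df = load_published_fp_counts()
        assert len(df) == 9
        assert set(df["direction"]) == {"elevated", "decreased"}
        assert load_published_neg_sizes() == NEG
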