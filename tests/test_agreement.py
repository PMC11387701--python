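"""ICC (against brute-force ANOVA and pingouin), Bland-Altman, percent
agreement, rating scales, report tables, and the reliability sample-size
formula."""

import math

import numpy as np
import pandas as pd
import pytest

from hipmorph import (
    AgreementError,
    HipSpec,
    bland_altman,
    generate_hip,
    icc,
    icc_sample_size,
    measure_pair,
    measurements_frame,
    percent_agreement,
    rate_icc,
    rate_percent,
    reliability_report,
)
from hipmorph.landmarks import default_schema

OFFSET_MATRIX = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0]])


def anova_oracle(values: np.ndarray):
    """Independent mean-squares computation by direct elementwise summation."""
    n, k = values.shape
    grand = sum(values[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(values[i]) / k for i in range(n)]
    col = [sum(values[:, j]) / n for j in range(k)]
    msr = k * sum((r - grand) ** 2 for r in row) / (n - 1)
    msc = n * sum((c - grand) ** 2 for c in col) / (k - 1)
    sse = sum(
        (values[i][j] - row[i] - col[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def oracle_icc(values: np.ndarray, icc_type: str) -> float:
    msr, msc, mse = anova_oracle(values)
    n, k = values.shape
    if icc_type == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identical_columns_absolute_agreement_is_one(self):
        col = np.array([1.0, 5.0, 2.0, 8.0])
        res = icc(np.column_stack([col, col]))
        assert res.estimate == pytest.approx(1.0)
        assert res.ci95 == (1.0, 1.0)

    def test_offset_matrix_consistency_is_one(self):
        res = icc(OFFSET_MATRIX, icc_type="consistency")
        assert res.estimate == pytest.approx(1.0, abs=1e-12)

    def test_offset_matrix_absolute_agreement_is_ten_thirteenths(self):
        res = icc(OFFSET_MATRIX, icc_type="absolute-agreement")
        assert res.estimate == pytest.approx(10.0 / 13.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            mat = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1))
            for icc_type in ("absolute-agreement", "consistency"):
                est = icc(mat, icc_type=icc_type).estimate
                assert est == pytest.approx(oracle_icc(mat, icc_type), abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "y": mat.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="y")
        ref = ref.set_index("Type")
        ours_a = icc(mat, icc_type="absolute-agreement")
        ours_c = icc(mat, icc_type="consistency")
        assert ours_a.estimate == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-10)
        assert ours_c.estimate == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-10)
        # pingouin rounds its reported CI to 2 decimals
        np.testing.assert_allclose(ours_a.ci95, ref.loc["ICC(A,1)", "CI95"], atol=6e-3)
        np.testing.assert_allclose(ours_c.ci95, ref.loc["ICC(C,1)", "CI95"], atol=6e-3)

    def test_absolute_below_consistency_under_rater_offsets(self):
        # The ordering holds whenever the between-rater mean square exceeds
        # the error mean square, here guaranteed by systematic rater offsets.
        rng = np.random.default_rng(9)
        for _ in range(50):
            mat = (
                0.5 * rng.normal(size=(8, 3))
                + 2.0 * rng.normal(size=(8, 1))
                + np.array([0.0, 2.0, 4.0])
            )
            a = icc(mat, icc_type="absolute-agreement").estimate
            c = icc(mat, icc_type="consistency").estimate
            assert a < c

    def test_column_offset_lowers_absolute_not_consistency(self):
        rng = np.random.default_rng(3)
        mat = 0.5 * rng.normal(size=(10, 2)) + 3.0 * rng.normal(size=(10, 1))
        shifted = mat.copy()
        shifted[:, 1] += 5.0
        assert icc(shifted, icc_type="consistency").estimate == pytest.approx(
            icc(mat, icc_type="consistency").estimate, abs=1e-12
        )
        assert (
            icc(shifted, icc_type="absolute-agreement").estimate
            < icc(mat, icc_type="absolute-agreement").estimate
        )

    def test_listwise_deletion_reported(self):
        mat = np.array([[1.0, 2.0], [np.nan, 3.0], [3.0, 4.0], [4.0, 5.0], [2.0, 2.5]])
        res = icc(mat)
        assert res.n_used == 4 and res.n_dropped == 1

    def test_zero_variance_is_missing_with_reason(self):
        res = icc(np.full((5, 2), 3.0))
        assert res.estimate is None
        assert "zero total variance" in res.reason

    def test_too_small_matrix_rejected(self):
        with pytest.raises(AgreementError, match="after listwise deletion"):
            icc(np.array([[1.0, 2.0]]))

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            mat = rng.normal(size=(10, 2)) + 2 * rng.normal(size=(10, 1))
            res = icc(mat)
            assert res.ci95[0] <= res.estimate <= res.ci95[1]
            assert -1.0 <= res.estimate <= 1.0


class TestRatings:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.49, "poor"), (0.50, "moderate"), (0.75, "moderate"),
         (0.755, "good"), (0.90, "good"), (0.91, "excellent")],
    )
    def test_icc_bands(self, value, expected):
        assert rate_icc(value) == expected

    @pytest.mark.parametrize(
        "value,expected",
        [(49.9, "poor"), (50.0, "moderate"), (70.0, "moderate"),
         (70.5, "good"), (90.0, "good"), (90.1, "excellent")],
    )
    def test_percent_bands(self, value, expected):
        assert rate_percent(value) == expected


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(x, x, "angle")
        assert res.bias == 0.0
        assert res.loa == (0.0, 0.0)
        assert not res.systematic_error

    def test_worked_differences(self):
        y = np.array([10.0, 20.0, 30.0, 40.0])
        x = y + np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(x, y, "angle")
        assert res.bias == pytest.approx(2.5)
        assert res.sd_diff == pytest.approx(math.sqrt(5.0 / 3.0))
        assert res.loa[0] == pytest.approx(2.5 - 1.96 * math.sqrt(5.0 / 3.0))
        assert res.loa[1] == pytest.approx(2.5 + 1.96 * math.sqrt(5.0 / 3.0))

    @pytest.mark.parametrize("bias,expected", [(2.6, True), (2.4, False)])
    def test_angle_systematic_error_rule(self, bias, expected):
        y = np.array([100.0, 110.0, 120.0, 130.0])
        res = bland_altman(y + bias, y, "angle")
        assert res.systematic_error is expected

    def test_ratio_systematic_error_rule(self):
        y = np.full(5, 300.0)
        assert bland_altman(y + 4.0, y, "ratio").systematic_error is True
        assert bland_altman(y + 2.0, y, "ratio").systematic_error is False

    def test_antisymmetric_bias(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert bland_altman(x, y, "angle").bias == pytest.approx(
            -bland_altman(y, x, "angle").bias
        )

    def test_incomplete_pairs_dropped_and_minimum_enforced(self):
        x = np.array([1.0, np.nan, 3.0, 4.0])
        y = np.array([1.0, 2.0, np.nan, 4.0])
        with pytest.raises(AgreementError, match=">= 3 complete pairs"):
            bland_altman(x, y, "angle")


class TestPercentAgreement:
    def test_identical(self):
        pct, rating = percent_agreement(["a"] * 5, ["a"] * 5)
        assert pct == 100.0 and rating == "excellent"

    def test_half_matching(self):
        a = [True] * 30
        b = [True] * 15 + [False] * 15
        pct, rating = percent_agreement(a, b)
        assert pct == pytest.approx(50.0) and rating == "moderate"

    def test_none_matching(self):
        pct, rating = percent_agreement([1, 2, 3], [4, 5, 6])
        assert pct == 0.0 and rating == "poor"

    def test_zero_comparable_pairs(self):
        with pytest.raises(AgreementError, match="zero comparable"):
            percent_agreement([None, None], [None, True])


def test_bland_altman_plot_renders():
    import matplotlib

    matplotlib.use("Agg")
    from hipmorph.agreement import bland_altman_plot

    rng = np.random.default_rng(8)
    y = rng.normal(120, 5, 20)
    res = bland_altman(y + rng.normal(0, 1, 20), y, "angle")
    ax = bland_altman_plot(res, title="nsa")
    assert len(ax.collections) == 1 and len(ax.lines) == 3


class TestSampleSize:
    def test_reference_scenario_magnitude(self):
        # Independent evaluation of the closed form for the reference design:
        # rho0=0.75, rho1=0.90, k=2, one-sided alpha 0.05, beta 0.20.
        from scipy.stats import norm

        z = norm.ppf(0.95) + norm.ppf(0.80)
        c0 = (1 + 2 * 3.0) / (1 + 2 * 9.0)
        expected = math.ceil(1 + 2 * 2 * z**2 / (1 * math.log(c0) ** 2))
        n = icc_sample_size(0.75, 0.90, k=2)
        assert n == expected
        assert 20 <= n <= 30  # same magnitude as typical published designs

    def test_monotone_in_alternative(self):
        assert icc_sample_size(0.75, 0.95) < icc_sample_size(0.75, 0.85)

    def test_monotone_in_power(self):
        assert icc_sample_size(0.75, 0.9, beta=0.1) > icc_sample_size(0.75, 0.9, beta=0.2)

    def test_invalid_ordering(self):
        with pytest.raises(AgreementError):
            icc_sample_size(0.9, 0.8)


@pytest.fixture(scope="module")
def batch():
    schema = default_schema()
    sets = []
    for i, alpha in enumerate(np.linspace(44, 75, 8)):
        pair, _ = generate_hip(
            HipSpec(
                target_alpha_deg=float(alpha),
                target_adr=250.0 + 10 * i,
                target_lcea_deg=22.0 + 2.5 * i,
                target_wcea_deg=18.0 + 2.5 * i,
                target_mai_deg=1.0 + 1.5 * i,
                target_nsa_deg=118.0 + 3.0 * i,
            ),
            image_id=f"h{i}",
        )
        sets.append(measure_pair(pair, schema)["left"])
    return measurements_frame(sets)

    def test_identical_sources(self, batch):
        report = reliability_report({"a": batch, "b": batch.copy()})
        assert np.allclose(report["icc"]["icc"], 1.0)
        assert np.allclose(report["bland_altman"]["bias"], 0.0)
        assert (report["diagnosis"]["percent_agreement"].dropna() == 100.0).all()

    def test_misaligned_hips_listed(self, batch):
        other = batch.copy()
        other.index = [f"x{i}" for i in range(len(other))]
        with pytest.raises(AgreementError, match="unmatched ids"):
            reliability_report({"a": batch, "b": other})

    def test_missing_nsa_reduces_n(self, batch):
        other = batch.copy()
        other.loc[other.index[:2], "nsa_deg"] = np.nan
        report = reliability_report({"a": batch, "b": other})
        nsa = report["icc"].loc["nsa_deg"]
        assert nsa["n_used"] == len(batch) - 2
        assert nsa["note"] == "n reduced"
        assert report["icc"].loc["lcea_deg", "n_used"] == len(batch)
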