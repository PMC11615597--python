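import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aortamotion.motion import MotionCurves
from aortamotion.stats import (
    agreement_stats,
    diameter_from_area,
    group_median_iqr,
    max_variability,
)


def curves_from_array(arr: np.ndarray) -> MotionCurves:
    """Wrap a per-phase value vector into a MotionCurves with that value everywhere."""
    n = len(arr)
    return MotionCurves(
        pd.DataFrame(
            {
                "phase": np.arange(n),
                "mean_displacement_mm": arr,
                "max_displacement_mm": arr,
                "mean_diameter_mm": arr,
                "mean_diameter_change_mm": arr,
                "mean_diameter_change_pct": arr,
            }
        )
    )


class TestGroupMedianIqr:
    def test_identical_curves_zero_iqr(self):
        curves = [curves_from_array(np.arange(5.0))] * 4
        out = group_median_iqr(curves)
        assert np.allclose(out["iqr"], 0.0)

    def test_hand_quantiles(self):
        curves = [curves_from_array(np.array([float(v)])) for v in [1, 2, 3, 4, 5]]
        out = group_median_iqr(curves)
        row = out[out.metric == "mean_displacement_mm"].iloc[0]
        assert row["median"] == 3.0
        assert row["iqr"] == 2.0  # Q1=2, Q3=4 with linear interpolation

    def test_matches_independent_quantile_oracle(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(9, 6))  # 9 subjects, 6 phases
        curves = [curves_from_array(row) for row in data]
        out = group_median_iqr(curves)
        sub = out[out.metric == "mean_diameter_mm"].sort_values("phase")
        # oracle: explicit linear-interpolation quantile formula
        for t in range(6):
            srt = np.sort(data[:, t])
            for q, col in [(0.25, "q1"), (0.5, "median"), (0.75, "q3")]:
                h = (len(srt) - 1) * q
                lo = int(math.floor(h))
                expected = srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])
                assert sub.iloc[t][col] == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(6, 4))
        curves = [curves_from_array(row) for row in data]
        a = group_median_iqr(curves)
        b = group_median_iqr(curves[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_mixed_phase_counts_rejected(self):
        with pytest.raises(ValueError):
            group_median_iqr([curves_from_array(np.zeros(3)),
                              curves_from_array(np.zeros(4))])


class TestAgreementStats:
    def test_identical_measurements(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = agreement_stats(a, a)
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0
        assert res.pearson_r == pytest.approx(1.0)

    def test_constant_offset_bias_sign(self):
        a = np.array([1.0, 2.0, 3.0, 5.0])
        res = agreement_stats(a, a + 1.0)
        assert res.bias == pytest.approx(-1.0)  # diff = a - b

    def test_matches_brute_force_formulas(self):
        rng = np.random.default_rng(11)
        from scipy.stats import shapiro

        for _ in range(100):
            n = int(rng.integers(5, 40))
            a = rng.normal(size=n)
            b = a + rng.normal(scale=0.3, size=n)
            res = agreement_stats(a, b)
            d = a - b
            bias = d.sum() / n
            sd = math.sqrt(((d - bias) ** 2).sum() / (n - 1))
            am, bm = a.mean(), b.mean()
            r = ((a - am) * (b - bm)).sum() / math.sqrt(
                ((a - am) ** 2).sum() * ((b - bm) ** 2).sum()
            )
            assert res.bias == pytest.approx(bias, abs=1e-12)
            assert res.loa_low == pytest.approx(bias - 1.96 * sd, abs=1e-12)
            assert res.loa_high == pytest.approx(bias + 1.96 * sd, abs=1e-12)
            assert res.pearson_r == pytest.approx(r, abs=1e-12)
            assert res.shapiro_p == pytest.approx(shapiro(d).pvalue, abs=1e-12)

    def test_antisymmetric_bias(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert agreement_stats(a, b).bias == -agreement_stats(b, a).bias

    def test_errors(self):
        with pytest.raises(ValueError):
            agreement_stats([1.0, 2.0], [1.0, 2.0])  # too few
        with pytest.raises(ValueError):
            agreement_stats([1.0, 2.0, 3.0], [1.0, 2.0])  # length mismatch
        with pytest.raises(ValueError, match="variance"):
            agreement_stats([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_nonnormal_differences_warn(self):
        rng = np.random.default_rng(0)
        a = np.arange(30.0)
        b = a - rng.exponential(scale=4.0, size=30) ** 3
        with pytest.warns(UserWarning, match="Shapiro"):
            res = agreement_stats(a, b)
        assert res.normality_warning


class TestMaxVariability:
    def test_identical_scans_zero(self):
        c = curves_from_array(np.array([1.0, 2.0, 3.0]))
        assert max_variability([c, c, c], "mean_diameter_mm").max_variability == 0.0

    def test_hand_example(self):
        cs = [curves_from_array(np.array(v, float))
              for v in ([1, 2, 3], [1, 2, 3], [1, 2, 6])]
        res = max_variability(cs, "mean_displacement_mm")
        assert np.allclose(res.per_phase_range, [0, 0, 3])
        assert res.max_variability == 3.0

    def test_order_invariant(self):
        rng = np.random.default_rng(2)
        cs = [curves_from_array(rng.normal(size=5)) for _ in range(3)]
        base = max_variability(cs, "mean_diameter_mm").max_variability
        assert max_variability(cs[::-1], "mean_diameter_mm").max_variability == base

    def test_requires_three_scans(self):
        c = curves_from_array(np.zeros(3))
        with pytest.raises(ValueError):
            max_variability([c, c], "mean_diameter_mm")


class TestDiameterFromArea:
    def test_known_values(self):
        assert diameter_from_area(math.pi).da_mm == pytest.approx(2.0)
        assert diameter_from_area(0.0).da_mm == 0.0
        assert diameter_from_area(526.85).da_mm == pytest.approx(25.9, abs=0.05)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            diameter_from_area(-1.0)

    @given(st.floats(min_value=0.1, max_value=60.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_inverts_circle_area(self, d):
        area = math.pi * (d / 2) ** 2
        assert diameter_from_area(area).da_mm == pytest.approx(d, rel=1e-12)
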