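"""Ratio extraction, regression, detection limits, and QC evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qmsi
from qmsi.calibration import RatioObservation
from qmsi.errors import CalibrationError, UndefinedRatioError

from conftest import make_tiny_grid

LADDER = qmsi.DEFAULT_LADDER


def cal_obs(levels, ratio_fn, n_rep=3):
    """Exact calibration observations: ratio = ratio_fn(conc) per replicate."""
    return [
        RatioObservation(f"C{i}", "calibration", c, ratio_fn(c), rep, 100)
        for i, c in enumerate(levels, 1)
        for rep in range(1, n_rep + 1)
    ]


class TestSummedRatio:
    def test_ratio_of_sums_not_mean_of_ratios(self):
        grid = make_tiny_grid(
            {"drug": [[10.0, 20.0, 30.0]], "lipid": [[100.0, 100.0, 100.0]]}
        )
        roi = qmsi.RoiMask.from_rect("w", 0, 0, 3, 1)
        assert qmsi.summed_ratio(grid, roi, "drug", "lipid") == pytest.approx(0.2)

    def test_zero_analyte_gives_zero(self):
        grid = make_tiny_grid({"drug": [[0.0, 0.0]], "lipid": [[5.0, 7.0]]})
        roi = qmsi.RoiMask.from_rect("w", 0, 0, 2, 1)
        assert qmsi.summed_ratio(grid, roi, "drug", "lipid") == 0.0

    def test_invariant_under_pixel_value_permutation(self):
        vals = np.array([[3.0, 1.0, 4.0, 1.5]])
        lipid = np.array([[10.0, 20.0, 5.0, 8.0]])
        g1 = make_tiny_grid({"drug": vals, "lipid": lipid})
        perm = [2, 0, 3, 1]
        g2 = make_tiny_grid({"drug": vals[:, perm], "lipid": lipid[:, perm]})
        roi = qmsi.RoiMask.from_rect("w", 0, 0, 4, 1)
        assert qmsi.summed_ratio(g1, roi, "drug", "lipid") == pytest.approx(
            qmsi.summed_ratio(g2, roi, "drug", "lipid")
        )

    def test_zero_reference_sum_raises_naming_roi(self):
        grid = make_tiny_grid({"drug": [[1.0]], "lipid": [[0.0]]})
        roi = qmsi.RoiMask.from_rect("lesion_r1", 0, 0, 1, 1)
        with pytest.raises(UndefinedRatioError, match="lesion_r1"):
            qmsi.summed_ratio(grid, roi, "drug", "lipid")


class TestFitLine:
    def test_perfect_line_recovered(self):
        slope, intercept, r2 = qmsi.fit_line(cal_obs(LADDER, lambda c: 0.001 * c))
        assert slope == pytest.approx(0.001, abs=1e-15)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_constant_response_is_flat_with_zero_r2(self):
        slope, intercept, r2 = qmsi.fit_line(cal_obs(LADDER, lambda c: 0.42))
        assert slope == 0.0
        assert intercept == pytest.approx(0.42)
        assert r2 == 0.0

    def test_fewer_than_three_levels_rejected(self):
        with pytest.raises(CalibrationError, match="3 distinct"):
            qmsi.fit_line(cal_obs((25.0, 250.0), lambda c: 0.001 * c))

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_normal_equations_oracle(self, seed):
        """OLS on per-level means equals the closed-form normal equations."""
        rng = np.random.default_rng(seed)
        n_levels = int(rng.integers(3, 9))
        x = np.sort(rng.uniform(1.0, 2500.0, size=n_levels))
        while np.ptp(x) == 0 or len(set(x)) < 3:  # pragma: no cover - vanishing odds
            x = np.sort(rng.uniform(1.0, 2500.0, size=n_levels))
        y = 0.001 * x + rng.normal(0, 0.05, size=n_levels)
        y = np.abs(y)
        obs = [
            RatioObservation(f"C{i}", "calibration", xi, yi, 1, 10)
            for i, (xi, yi) in enumerate(zip(x, y), 1)
        ]
        slope, intercept, r2 = qmsi.fit_line(obs)
        # independent oracle: solve the 2x2 normal equations directly
        n = len(x)
        sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
        det = n * sxx - sx * sx
        slope_o = (n * sxy - sx * sy) / det
        intercept_o = (sy * sxx - sx * sxy) / det
        ss_res = float(np.sum((y - slope_o * x - intercept_o) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        assert slope == pytest.approx(slope_o, abs=1e-10, rel=1e-10)
        assert intercept == pytest.approx(intercept_o, abs=1e-10, rel=1e-10)
        if ss_tot > 0:
            assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)


class TestDetectionLimits:
    def test_formula_arithmetic(self):
        assert qmsi.compute_lod(0.006, 0.002) == pytest.approx(9.0)
        assert qmsi.compute_lloq(0.006, 0.002) == pytest.approx(15.0)

    def test_zero_blank_sd_gives_zero_lod(self):
        assert qmsi.compute_lod(0.0, 0.01) == 0.0

    def test_blank_replicates_through_sample_sd(self):
        # sample SD (n-1) of (0.001, 0.002, 0.003) is exactly 0.001
        sd = float(np.std([0.001, 0.002, 0.003], ddof=1))
        assert sd == pytest.approx(0.001)
        assert qmsi.compute_lod(sd, 0.001) == pytest.approx(3.0)

    @pytest.mark.parametrize("slope", [0.0, -0.5])
    def test_nonpositive_slope_rejected(self, slope):
        with pytest.raises(CalibrationError):
            qmsi.compute_lod(0.01, slope)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.floats(min_value=1e-9, max_value=1e3),
        st.floats(min_value=1e-9, max_value=10.0),
    )
    def test_lloq_to_lod_ratio_is_exactly_five_thirds(self, sd_blank, slope):
        lod = qmsi.compute_lod(sd_blank, slope)
        lloq = qmsi.compute_lloq(sd_blank, slope)
        assert lloq == pytest.approx(lod * 5.0 / 3.0, rel=1e-12)


class TestBuildCalibration:
    def test_clean_data_no_exclusions_single_fit(self):
        curve = qmsi.build_calibration(
            cal_obs(LADDER, lambda c: 0.001 * c), [0.0, 0.0, 0.0]
        )
        assert curve.excluded_levels == ()
        assert curve.n_refits == 1
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.uloq == 2500.0
        assert curve.lloq == pytest.approx(curve.lod * 5 / 3)

    def test_inflated_blanks_exclude_low_levels(self):
        # sd_blank = 0.01 with slope 0.001 puts the LOD at 30 ug/g: the 12.5
        # and 25 ug/g standards fall below it and must leave the line.
        curve = qmsi.build_calibration(
            cal_obs(LADDER, lambda c: 0.001 * c), [0.0, 0.01, 0.02]
        )
        assert curve.excluded_levels == (12.5, 25.0)
        assert curve.included_levels == (50.0, 125.0, 250.0, 500.0, 1250.0, 2500.0)
        assert curve.lod == pytest.approx(30.0)
        assert curve.n_refits == 2
        assert curve.uloq == 2500.0

    def test_refit_is_idempotent_on_included_levels(self):
        blanks = [0.0, 0.01, 0.02]
        first = qmsi.build_calibration(cal_obs(LADDER, lambda c: 0.001 * c), blanks)
        again = qmsi.build_calibration(
            cal_obs(first.included_levels, lambda c: 0.001 * c), blanks
        )
        assert again.excluded_levels == ()
        assert again.slope == pytest.approx(first.slope)
        assert again.intercept == pytest.approx(first.intercept)
        assert again.lod == pytest.approx(first.lod)

    def test_exclusion_below_three_levels_fails_reporting_lod(self):
        with pytest.raises(CalibrationError, match="LOD"):
            qmsi.build_calibration(
                cal_obs(LADDER, lambda c: 0.001 * c), [0.0, 0.7, 1.4]
            )

    def test_too_few_blanks_rejected(self):
        with pytest.raises(CalibrationError, match="blank"):
            qmsi.build_calibration(cal_obs(LADDER, lambda c: 0.001 * c), [0.0])


class TestBackCalculate:
    @pytest.fixture()
    def curve(self):
        return qmsi.build_calibration(
            cal_obs(LADDER, lambda c: 0.001 * c), [0.0, 0.005, 0.01]
        )

    def test_inverts_the_line(self, curve):
        conc, flag = qmsi.back_calculate(curve, 0.25)
        assert conc == pytest.approx(250.0)
        assert flag == "ok"

    def test_above_uloq_flagged(self, curve):
        ratio = curve.slope * curve.uloq + curve.intercept
        assert qmsi.back_calculate(curve, ratio * 1.2).flag == "above_uloq"

    def test_ratio_at_intercept_is_zero_below_lod(self, curve):
        conc, flag = qmsi.back_calculate(curve, curve.intercept)
        assert conc == 0.0
        assert flag == "below_lod"

    def test_between_lod_and_lloq_flagged(self, curve):
        mid = (curve.lod + curve.lloq) / 2
        assert qmsi.back_calculate(curve, curve.slope * mid + curve.intercept).flag == (
            "below_lloq"
        )


class TestEvaluateQc:
    def test_tight_replicates_pass(self):
        res = qmsi.evaluate_qc([24.0, 25.0, 26.0], 25.0, lloq=5.0)
        assert res.precision_rsd == pytest.approx(4.0)
        assert res.accuracy_pct == pytest.approx(100.0)
        assert res.passes_precision and res.passes_accuracy
        assert not res.below_lloq

    def test_biased_replicates_fail_accuracy_only(self):
        res = qmsi.evaluate_qc([30.0, 30.0, 30.0], 25.0, lloq=5.0)
        assert res.precision_rsd == 0.0
        assert res.accuracy_pct == pytest.approx(120.0)
        assert res.passes_precision and not res.passes_accuracy

    @pytest.mark.parametrize("lloq,expected", [(25.0, True), (10.0, False)])
    def test_widened_precision_limit_applies_only_at_lloq(self, lloq, expected):
        # sample SD of (20, 25, 30) is exactly 5 -> RSD 20.0%
        res = qmsi.evaluate_qc([20.0, 25.0, 30.0], 25.0, lloq=lloq)
        assert res.precision_rsd == pytest.approx(20.0)
        assert res.passes_precision is expected

    def test_single_replicate_rejected(self):
        with pytest.raises(CalibrationError, match="n >= 2"):
            qmsi.evaluate_qc([25.0], 25.0, lloq=5.0)


class TestScaleEquivariance:
    """Global analyte rescaling must not move any concentration-scale result."""

    @pytest.mark.parametrize("k", [0.25, 3.7, 1000.0])
    def test_lod_concentrations_and_qc_invariant(self, k, layout, noisy_params):
        grid, _ = qmsi.generate_mimetic_array(layout, noisy_params)
        scaled = qmsi.ChannelGrid(
            pixel_size_um=grid.pixel_size_um,
            channels=list(grid.channels),
            intensities={
                name: (arr * k if name != "lipid_782" else arr.copy())
                for name, arr in grid.intensities.items()
            },
        )
        curves, qcs = [], []
        for g in (grid, scaled):
            obs = qmsi.observe_array(g, layout, "compound_A", "lipid_782")
            cal = [o for o in obs if o.role == "calibration"]
            blanks = [o for o in obs if o.role == "blank"]
            curve = qmsi.build_calibration(cal, blanks)
            curves.append(curve)
            qcs.append(
                {
                    nom: [qmsi.back_calculate(curve, r).conc for r in ratios]
                    for nom, ratios in qmsi.qc_replicate_ratios(obs).items()
                }
            )
        base, scl = curves
        assert scl.slope == pytest.approx(base.slope * k, rel=1e-9)
        assert scl.sd_blank == pytest.approx(base.sd_blank * k, rel=1e-9)
        assert scl.lod == pytest.approx(base.lod, rel=1e-9)
        assert scl.lloq == pytest.approx(base.lloq, rel=1e-9)
        assert scl.r_squared == pytest.approx(base.r_squared, rel=1e-12)
        for nom in qcs[0]:
            assert qcs[1][nom] == pytest.approx(qcs[0][nom], rel=1e-9)
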