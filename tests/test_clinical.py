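import numpy as np
import pandas as pd
import pytest

from drugcombo.clinical import (
    TrialDesign,
    classify_trial,
    comboscore_matrix,
    dose_grid_scan,
    hazard_ratio,
    idacomboscore,
    logrank_power,
    read_trial_table,
    viability_to_hazard,
)
from drugcombo.combo import bliss_combo, ida_combo
from drugcombo.dose_response import fit_ll4, ll4
from drugcombo.errors import (
    ConsistencyError,
    InputError,
    RangeError,
    UndefinedHazardRatioError,
)
from drugcombo.io import ConcentrationMap
from drugcombo.panel import Treatment

from conftest import make_panel


class TestViabilityToHazard:
    @pytest.mark.parametrize("v,h", [(1.0, 1.0), (0.0, 0.0), (0.5, 0.5)])
    def test_identity_anchors(self, v, h):
        assert viability_to_hazard(v) == h

    def test_negative_viability_floors_to_zero(self):
        assert viability_to_hazard(-0.3) == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(InputError):
            viability_to_hazard(float("nan"))


class TestHazardRatio:
    def _preds(self, a_vals, b_vals):
        panel = make_panel({("A", 1.0): a_vals, ("B", 1.0): b_vals})
        n = len(a_vals)
        return (
            ida_combo(panel, Treatment((("A", 1.0),)), min_lines=n),
            ida_combo(panel, Treatment((("B", 1.0),)), min_lines=n),
        )

    def test_ratio_of_mean_viabilities(self):
        test, control = self._preds([0.2, 0.2], [0.4, 0.4])
        assert hazard_ratio(test, control).hr == pytest.approx(0.5)

    def test_identical_treatments_give_unit_hr(self):
        test, control = self._preds([0.3, 0.5], [0.3, 0.5])
        assert hazard_ratio(test, control).hr == pytest.approx(1.0)

    def test_zero_control_hazard_is_undefined(self):
        test, control = self._preds([0.2, 0.2], [0.0, 0.0])
        with pytest.raises(UndefinedHazardRatioError):
            hazard_ratio(test, control)

    def test_mismatched_line_sets_rejected(self):
        p1 = make_panel({("A", 1.0): [0.2, 0.3], ("B", 1.0): [0.4, 0.5]})
        p2 = make_panel({("A", 1.0): [0.2, 0.3, 0.4], ("B", 1.0): [0.4, 0.5, 0.6]})
        t1 = ida_combo(p1, Treatment((("A", 1.0),)), min_lines=2)
        c2 = ida_combo(p2, Treatment((("B", 1.0),)), min_lines=3)
        with pytest.raises(ConsistencyError):
            hazard_ratio(t1, c2)

    def test_reciprocal_identity(self):
        test, control = self._preds([0.25, 0.35], [0.5, 0.6])
        forward = hazard_ratio(test, control).hr
        backward = hazard_ratio(control, test).hr
        assert forward * backward == pytest.approx(1.0, abs=1e-12)


class TestLogrankPower:
    def test_no_effect_limit_is_half_alpha(self):
        for m, k in [(10, 1.0), (500, 2.0)]:
            est = logrank_power(1.0, TrialDesign(m, k, alpha=0.05))
            assert est.power == pytest.approx(0.025, abs=1e-12)

    def test_closed_form_example(self):
        est = logrank_power(0.5, TrialDesign(100, 1.0, 0.05))
        assert est.power == pytest.approx(0.915, abs=5e-4)

    def test_strictly_decreasing_in_hr_below_one(self):
        design = TrialDesign(100)
        hrs = np.linspace(0.1, 0.99, 40)
        powers = [logrank_power(h, design).power for h in hrs]
        assert np.all(np.diff(powers) < 0)

    def test_strictly_increasing_in_events(self):
        powers = [logrank_power(0.7, TrialDesign(m)).power for m in [50, 100, 400, 1600]]
        assert np.all(np.diff(powers) > 0)

    def test_power_tends_to_one_with_many_events(self):
        assert logrank_power(0.8, TrialDesign(10 ** 6)).power > 1 - 1e-9

    def test_invalid_hr_rejected(self):
        with pytest.raises(InputError):
            logrank_power(float("inf"), TrialDesign(100))


class TestClassifyTrial:
    @pytest.mark.parametrize("power,expected", [(0.85, True), (0.80, True), (0.10, False)])
    def test_threshold_convention(self, power, expected):
        from drugcombo.clinical import PowerEstimate

        est = PowerEstimate(power=power)
        assert classify_trial(est, 0.80) is expected
        assert est.predicted_success is expected


class TestIDAcomboscore:
    def test_hand_computed_example(self):
        # combo mean 0.3 against best mono 0.6: delta 0.3, HR 0.5, score 0.15
        panel = make_panel({("A", 1.0): [0.3, 0.9], ("B", 1.0): [0.9, 0.3]})
        res = idacomboscore(panel, Treatment((("A", 1.0), ("B", 1.0))), min_lines=2)
        assert res.delta_via == pytest.approx(0.3)
        assert res.hr_c_mbest == pytest.approx(0.5)
        assert res.score == pytest.approx(0.15)

    def test_zero_score_when_combo_equals_best_reference(self):
        panel = make_panel({("A", 1.0): [0.6, 0.4], ("B", 1.0): [0.9, 0.9]})
        res = idacomboscore(panel, Treatment((("A", 1.0), ("B", 1.0))), min_lines=2)
        assert res.score == 0.0

    def test_algebraic_identity_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            panel = make_panel(
                {("A", 1.0): rng.uniform(0.05, 1, 6), ("B", 1.0): rng.uniform(0.05, 1, 6)}
            )
            res = idacomboscore(panel, Treatment((("A", 1.0), ("B", 1.0))), min_lines=6)
            assert res.score == pytest.approx(
                res.delta_via * (1 - res.hr_c_mbest), abs=1e-12
            )
            assert (res.score > 0) == (res.delta_via > 0)

    def test_backbone_reference_treated_as_monotherapy(self):
        panel = make_panel(
            {("A", 1.0): [0.7, 0.5], ("B", 1.0): [0.6, 0.8], ("C", 1.0): [0.4, 0.9]}
        )
        backbone = Treatment((("A", 1.0), ("B", 1.0)), label="backbone")
        combo = Treatment((("A", 1.0), ("B", 1.0), ("C", 1.0)))
        res = idacomboscore(panel, combo, references=[backbone], min_lines=2)
        backbone_mean = ida_combo(panel, backbone, min_lines=2).mean
        combo_mean = ida_combo(panel, combo, min_lines=2).mean
        assert res.best_reference == "backbone"
        assert res.delta_via == pytest.approx(backbone_mean - combo_mean)


class TestComboscoreMatrix:
    def _setup(self):
        rng = np.random.default_rng(5)
        panel = make_panel(
            {("A", 1.0): rng.uniform(0.2, 0.9, 6),
             ("B", 2.0): rng.uniform(0.2, 0.9, 6),
             ("C", 0.5): rng.uniform(0.2, 0.9, 6)}
        )
        cmap = ConcentrationMap(
            csustained={"A": 1.0, "B": 2.0, "C": 0.5},
            max_tested={"A": 10.0, "B": 10.0, "C": 10.0},
        )
        return panel, cmap

    def test_three_drugs_three_pairs_symmetric(self):
        panel, cmap = self._setup()
        mat = comboscore_matrix(panel, ["A", "B", "C"], cmap, min_lines=3)
        off_diag = mat.notna().to_numpy().sum()
        assert off_diag == 6  # 3 pairs, mirrored
        pd.testing.assert_frame_equal(mat, mat.T)

    def test_drug_order_invariance(self):
        panel, cmap = self._setup()
        m1 = comboscore_matrix(panel, ["A", "B", "C"], cmap, min_lines=3)
        m2 = comboscore_matrix(panel, ["C", "A", "B"], cmap, min_lines=3)
        pd.testing.assert_frame_equal(m1, m2)

    def test_insufficient_pairs_missing(self):
        panel, cmap = self._setup()
        mat = comboscore_matrix(panel, ["A", "B", "C"], cmap, min_lines=50)
        assert mat.isna().all().all()


class TestDoseGridScan:
    def _fits(self):
        doses = np.geomspace(0.01, 10, 8)
        fits = {}
        rng = np.random.default_rng(3)
        for line in ["L0", "L1", "L2"]:
            for drug in ["A", "B"]:
                b, c, e = rng.uniform(1, 2), rng.uniform(0, 0.3), rng.uniform(0.3, 3)
                fits[(line, drug)] = fit_ll4(doses, ll4(doses, b, c, 1.0, e))
        return fits

    def test_zero_zero_point_is_mean_min_upper_asymptote(self):
        fits = self._fits()
        surface = dose_grid_scan(fits, ("A", "B"), ([0.0, 1.0], [0.0, 1.0]))
        origin = surface[(surface.conc_a_uM == 0) & (surface.conc_b_uM == 0)]
        expected = np.mean(
            [min(fits[(l, "A")].d, fits[(l, "B")].d) for l in ["L0", "L1", "L2"]]
        )
        assert origin["mean_viability"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_degenerate_axis_equals_monotherapy(self):
        fits = self._fits()
        surface = dose_grid_scan(fits, ("A", "B"), ([0.0, 2.0], [0.0]))
        at_a = surface[(surface.conc_a_uM == 2.0) & (surface.conc_b_uM == 0.0)]
        mono = np.mean([min(fits[(l, "A")](2.0), fits[(l, "B")].d) for l in ["L0", "L1", "L2"]])
        assert at_a["mean_viability"].iloc[0] == pytest.approx(mono, abs=1e-9)

    def test_surface_non_increasing_along_axes(self):
        fits = self._fits()
        grid = [0.0, 0.1, 0.5, 1.0, 5.0]
        surface = dose_grid_scan(fits, ("A", "B"), (grid, grid))
        wide = surface.pivot(index="conc_a_uM", columns="conc_b_uM", values="mean_viability")
        assert (wide.diff(axis=0).dropna() <= 1e-9).all().all()
        assert (wide.diff(axis=1).dropna(axis=1) <= 1e-9).all().all()

    def test_grid_beyond_limit_rejected(self):
        with pytest.raises(RangeError):
            dose_grid_scan(self._fits(), ("A", "B"), ([0.0, 100.0], [0.0]))


class TestTrialTable:
    def test_parse_with_defaults(self, tmp_path):
        path = tmp_path / "trials.csv"
        pd.DataFrame(
            {"trial_id": ["t1"], "endpoint": ["OS"], "events": [150],
             "control": ["A@1"], "test": ["A@1+B@2"]}
        ).to_csv(path, index=False)
        (trial,) = read_trial_table(path)
        assert trial.design.total_events == 150
        assert trial.design.allocation_ratio == 1.0
        assert trial.design.alpha == 0.05
        assert trial.test.components == (("A", 1.0), ("B", 2.0))
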