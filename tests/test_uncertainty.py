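import numpy as np
import pytest

from drugcombo.errors import BootstrapFailureError, InputError
from drugcombo.panel import Treatment
from drugcombo.uncertainty import (
    BootstrapConfig,
    bh_fdr,
    bootstrap_combo_mean,
    bootstrap_comboscore,
    bootstrap_hazard_ratio,
    bootstrap_statistic,
    draw_coupled_panel,
    empirical_null_probability,
    format_null_probability,
    resample_lines,
    subsample_stability,
)

from conftest import make_panel


def textbook_bh(p):
    """Independent step-up oracle: p_(i) * m / i with right-to-left min accumulation."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted_sorted = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        adjusted_sorted[i] = min(adjusted_sorted[i], adjusted_sorted[i + 1])
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


class TestDrawCoupledPanel:
    def test_zero_se_reproduces_panel(self, two_drug_panel):
        zeroed = make_panel({("A", 1.0): [0.5, 0.8, 0.2], ("B", 1.0): [0.6, 0.3, 0.9]}, ses=0.0)
        sim = draw_coupled_panel(zeroed, np.random.default_rng(0))
        assert (sim.means.to_numpy() == zeroed.means.to_numpy()).all()

    def test_shared_component_draws_identical_across_treatments(self, two_drug_panel):
        # one column per (drug, conc): any two therapies referencing drug A
        # at 1 uM read the same simulated values by construction
        sim = draw_coupled_panel(two_drug_panel, np.random.default_rng(1))
        col = sim.column("A", 1.0)
        assert (col == sim.means[("A", 1.0)]).all()

    def test_simulated_mean_approaches_point_estimate(self, two_drug_panel):
        draws = [
            draw_coupled_panel(two_drug_panel, np.random.default_rng(i)).means.iloc[0, 0]
            for i in range(10_000)
        ]
        v_hat = two_drug_panel.means.iloc[0, 0]
        se = two_drug_panel.ses.iloc[0, 0]
        assert abs(np.mean(draws) - v_hat) < 3 * se / 100


class TestResampleLines:
    def test_single_line_forced(self):
        out = resample_lines(["L0"], np.random.default_rng(0))
        assert list(out) == ["L0"]

    def test_size_conserved(self):
        lines = [f"L{i}" for i in range(17)]
        out = resample_lines(lines, np.random.default_rng(1))
        assert len(out) == 17
        assert set(out) <= set(lines)

    def test_expected_distinct_fraction(self):
        n = 20
        lines = [f"L{i}" for i in range(n)]
        fractions = [
            len(set(resample_lines(lines, np.random.default_rng(i)))) / n
            for i in range(2000)
        ]
        expected = 1 - (1 - 1 / n) ** n
        assert np.mean(fractions) == pytest.approx(expected, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            resample_lines([], np.random.default_rng(0))


class TestBootstrapStatistic:
    def test_constant_statistic_has_zero_se(self, two_drug_panel):
        res = bootstrap_statistic(
            lambda values, idx: 1.23, two_drug_panel, BootstrapConfig(n_sims=100, seed=0)
        )
        assert res.se == 0.0
        assert res.ci == (1.23, 1.23)

    def test_same_seed_bit_identical(self, two_drug_panel, treatment_ab):
        cfg = BootstrapConfig(n_sims=200, seed=42)
        r1 = bootstrap_combo_mean(two_drug_panel, treatment_ab, cfg, min_lines=3)
        r2 = bootstrap_combo_mean(two_drug_panel, treatment_ab, cfg, min_lines=3)
        assert r1.point == r2.point
        assert r1.se == r2.se
        assert (r1.simulated == r2.simulated).all()

    def test_zero_measurement_error_matches_resampling_se(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0.2, 0.9, 25)
        panel = make_panel({("A", 1.0): vals}, ses=0.0)
        res = bootstrap_combo_mean(
            panel, Treatment((("A", 1.0),)),
            BootstrapConfig(n_sims=10_000, seed=0), min_lines=25,
        )
        analytic = np.std(vals, ddof=0) / np.sqrt(vals.size)
        assert res.se == pytest.approx(analytic, rel=0.15)

    def test_majority_failure_raises(self, two_drug_panel):
        def bad(values, idx):
            raise ValueError("boom")

        with pytest.raises(BootstrapFailureError):
            bootstrap_statistic(bad, two_drug_panel, BootstrapConfig(n_sims=20, seed=0))

    def test_percentile_ci_option(self, two_drug_panel, treatment_ab):
        cfg = BootstrapConfig(n_sims=500, seed=1, ci_method="percentile")
        res = bootstrap_combo_mean(two_drug_panel, treatment_ab, cfg, min_lines=3)
        lo, hi = np.quantile(res.simulated, [0.025, 0.975])
        assert res.ci == (pytest.approx(lo), pytest.approx(hi))


class TestCoupledHazardRatio:
    def test_identical_treatments_hr_exactly_one_se_zero(self, two_drug_panel, treatment_ab):
        out = bootstrap_hazard_ratio(
            two_drug_panel, treatment_ab, treatment_ab,
            BootstrapConfig(n_sims=500, seed=0), min_lines=3,
        )
        assert out["hr"].point == 1.0
        assert (out["hr"].simulated == 1.0).all()
        assert out["hr"].se == 0.0

    def test_uncoupled_identical_treatments_vary(self, two_drug_panel, treatment_ab):
        panel = make_panel(
            {("A", 1.0): [0.5, 0.8, 0.2], ("B", 1.0): [0.6, 0.3, 0.9]}, ses=0.05
        )
        out = bootstrap_hazard_ratio(
            panel, treatment_ab, treatment_ab,
            BootstrapConfig(n_sims=300, seed=0, couple_shared_drugs=False), min_lines=3,
        )
        assert out["hr"].se > 0


class TestNullProbability:
    def test_counting(self):
        assert empirical_null_probability([0.1, 0.2, -0.05, 0.3]) == 0.25

    def test_all_positive_reports_bound(self):
        raw = empirical_null_probability(np.full(1000, 0.5))
        assert raw == 0.0
        assert format_null_probability(raw, 1000) == "<0.001"

    def test_all_non_positive(self):
        assert empirical_null_probability([-1.0, 0.0]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            empirical_null_probability([])


class TestBHFDR:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-15
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_reapplication_preserves_order_and_never_decreases(self):
        # BH is a step-up envelope: re-adjusting adjusted values can only
        # push them up, and never reorders them
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        once = bh_fdr(p)
        twice = bh_fdr(once)
        assert (twice >= once - 1e-15).all()
        order = np.argsort(once, kind="mergesort")
        assert (np.diff(twice[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_fdr([0.5, 1.5])

    def test_matches_independent_step_up_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), textbook_bh(p), atol=1e-15)


class TestSubsampleStability:
    def _panel(self, n=30):
        rng = np.random.default_rng(4)
        return make_panel(
            {("A", 1.0): rng.uniform(0.2, 0.9, n), ("B", 1.0): rng.uniform(0.2, 0.9, n)}
        )

    def test_full_size_has_zero_dispersion(self, treatment_ab):
        panel = self._panel()
        out = subsample_stability(panel, treatment_ab, sizes=[30], reps=20, seed=0)
        assert out["dispersion"].iloc[0] == 0.0

    def test_dispersion_decreases_with_size(self, treatment_ab):
        panel = self._panel()
        out = subsample_stability(panel, treatment_ab, sizes=[5, 15, 29], reps=200, seed=0)
        disp = out["dispersion"].to_numpy()
        assert disp[0] > disp[1] > disp[2]

    def test_oversized_subset_rejected(self, treatment_ab):
        with pytest.raises(InputError):
            subsample_stability(self._panel(), treatment_ab, sizes=[31], reps=5, seed=0)

    def test_reproducible(self, treatment_ab):
        panel = self._panel()
        a = subsample_stability(panel, treatment_ab, sizes=[10], reps=50, seed=7)
        b = subsample_stability(panel, treatment_ab, sizes=[10], reps=50, seed=7)
        assert a.equals(b)


class TestBootstrapComboscore:
    def test_null_probability_reflects_simulated_sign(self):
        rng = np.random.default_rng(6)
        panel = make_panel(
            {("A", 1.0): rng.uniform(0.4, 0.9, 10), ("B", 1.0): rng.uniform(0.4, 0.9, 10)},
            ses=0.02,
        )
        res = bootstrap_comboscore(
            panel, Treatment((("A", 1.0), ("B", 1.0))),
            BootstrapConfig(n_sims=500, seed=0), min_lines=10,
        )
        assert res.null_p == empirical_null_probability(res.simulated)
        assert 0.0 <= res.null_p <= 1.0
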