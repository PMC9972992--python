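"""Gradients, release/benefit conditions, thresholds, and parameter sweeps."""

import numpy as np
import pytest

import comres as cr
from conftest import sample_coexistence_params


class TestGradientDf:
    @pytest.mark.parametrize(
        ("alpha_pc", "alpha_cp", "expected"),
        [
            (0.8, 0.8, 0.4444),    # competition
            (0.8, -0.8, 0.0976),   # commensal exploits pathogen
            (-0.8, 0.8, -0.0976),  # pathogen exploits commensal
            (-0.8, -0.8, -0.4444),  # mutualism
        ],
    )
    def test_four_interaction_scenarios(self, fig3a, alpha_pc, alpha_cp, expected):
        """dP*/df at full exposure across the four canonical interaction signs."""
        p = fig3a.replace(alpha_pc=alpha_pc, alpha_cp=alpha_cp, A=1.0)
        assert round(cr.dPstar_df(p), 4) == expected

    def test_zero_without_antibiotic(self, fig3a):
        assert cr.dPstar_df(fig3a.replace(A=0.0)) == 0.0

    def test_not_applicable_outside_coexistence(self, fig3a):
        with pytest.raises(cr.NotApplicableError):
            cr.dPstar_df(fig3a.replace(A=1.0, f=2.0))


class TestGradientDA:
    def test_sign_flips_across_release_threshold(self, fig3a):
        """f* = 1.25 for the competition scenario: release above, suppression below."""
        assert cr.dPstar_dA(fig3a.replace(f=2.0, A=0.5)) > 0
        assert cr.dPstar_dA(fig3a.replace(f=0.5, A=0.5)) < 0

    @pytest.mark.parametrize("f", [0.0, 0.5, 1.0, 2.0])
    def test_facilitating_commensal_never_releases(self, fig3a, f):
        """alpha_pc < 0: antibiotic always suppresses the pathogen."""
        p = fig3a.replace(alpha_pc=-0.8, f=f, A=0.3)
        assert cr.dPstar_dA(p) < 0

    def test_gradients_match_finite_differences(self):
        """Closed forms vs central differences of the interior P*, step 1e-6."""
        rng = np.random.default_rng(3)
        h = 1e-6
        for _ in range(25):
            p = sample_coexistence_params(rng, fd_step=h)
            fd_A = (
                cr.coexistence_point(p.replace(A=p.A + h))[0]
                - cr.coexistence_point(p.replace(A=p.A - h))[0]
            ) / (2 * h)
            fd_f = (
                cr.coexistence_point(p.replace(f=p.f + h))[0]
                - cr.coexistence_point(p.replace(f=p.f - h))[0]
            ) / (2 * h)
            assert fd_A == pytest.approx(cr.dPstar_dA(p), rel=1e-6)
            assert fd_f == pytest.approx(cr.dPstar_df(p), rel=1e-6)


class TestReleaseThreshold:
    def test_fast_pathogen_scenario(self):
        """r_p=0.75, r_c=0.25, alpha_pc=0.8: release above f* = 0.417."""
        p = cr.ModelParams(r_p=0.75, r_c=0.25, alpha_pc=0.8, alpha_cp=0.8, x=0.1)
        assert round(cr.release_threshold_f(p), 3) == 0.417

    def test_competition_baseline(self, fig3a):
        assert cr.release_threshold_f(fig3a) == pytest.approx(1.25)

    def test_symmetric_limit_approaches_one(self, fig3a):
        assert cr.release_threshold_f(fig3a.replace(alpha_pc=0.999)) == pytest.approx(
            1.0, rel=2e-3
        )

    def test_undefined_for_facilitating_commensal(self, fig3a):
        with pytest.raises(cr.ThresholdUndefinedError):
            cr.release_threshold_f(fig3a.replace(alpha_pc=-0.8))

    def test_threshold_is_exact_sign_change(self, fig3a):
        """Bisection of the dP*/dA sign change in f lands on the closed-form f*."""
        fstar = cr.release_threshold_f(fig3a)
        lo, hi = 0.5, 2.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if cr.dPstar_dA(fig3a.replace(f=mid, A=0.3)) > 0:
                hi = mid
            else:
                lo = mid
        assert 0.5 * (lo + hi) == pytest.approx(fstar, abs=1e-12)


class TestBeneficialResistance:
    @pytest.mark.parametrize(
        ("alpha_pc", "alpha_cp", "expected"),
        [(0.8, 0.8, True), (0.8, -0.8, True), (-0.8, 0.8, False), (-0.8, -0.8, False)],
    )
    def test_depends_only_on_commensal_inhibition_sign(
        self, fig3a, alpha_pc, alpha_cp, expected
    ):
        p = fig3a.replace(alpha_pc=alpha_pc, alpha_cp=alpha_cp, A=1.0)
        assert cr.beneficial_resistance_condition(p) is expected
        # consistency with the gradient it summarizes
        assert (cr.dPstar_df(p) > 0) is expected

    def test_boundary_and_no_exposure_are_false(self, fig3a):
        assert not cr.beneficial_resistance_condition(fig3a.replace(alpha_pc=0.0, A=1.0))
        assert not cr.beneficial_resistance_condition(fig3a.replace(A=0.0))


@pytest.fixture(scope="module")
def af_grid():
    return cr.scan_Af(cr.ModelParams(), np.linspace(0, 1, 41), np.linspace(0, 2, 41))


@pytest.fixture(scope="module")
def alpha_grid():
    base = cr.ModelParams(alpha_pc=0.0, alpha_cp=0.0, A=1.0)
    vals = np.linspace(-0.8, 0.8, 17)  # step 0.1, includes +-0.8 and 0
    return cr.scan_alpha(base, vals, vals)


class TestScanAf:
    def test_shape_and_outcome_classes(self, af_grid):
        assert af_grid.P_star.shape == (41, 41)
        assert set(np.unique(af_grid.outcome)) <= {o.value for o in cr.Outcome}

    def test_dominance_confined_to_high_exposure_high_susceptibility(self, af_grid):
        A, F = np.meshgrid(af_grid.axis1_values, af_grid.axis2_values, indexing="ij")
        dom = af_grid.outcome == "pathogen_dominance"
        assert dom.any()
        assert A[dom].min() > 0.8 and F[dom].min() > 1.75

    def test_coexistence_cells_match_closed_form(self, af_grid):
        co = af_grid.outcome == "coexistence"
        for i, j in zip(*np.where(co)):
            p = af_grid.base_params.replace(
                A=float(af_grid.axis1_values[i]), f=float(af_grid.axis2_values[j])
            )
            P, _ = cr.coexistence_point(p)
            assert abs(af_grid.P_star[i, j] - P) < 1e-12

    def test_no_antibiotic_row_is_flat_in_f(self, af_grid):
        row = af_grid.P_star[0, :]  # A = 0
        assert np.ptp(row) < 1e-12

    def test_monotonicity_along_exposure_columns(self, af_grid):
        """P* non-increasing in A below f*, non-decreasing above, within coexistence."""
        fstar = cr.release_threshold_f(af_grid.base_params)
        co = af_grid.outcome == "coexistence"
        for j, f in enumerate(af_grid.axis2_values):
            col = af_grid.P_star[co[:, j], j]
            diffs = np.diff(col)
            if f < fstar - 1e-9:
                assert np.all(diffs <= 1e-12)
            elif f > fstar + 1e-9:
                assert np.all(diffs >= -1e-12)

    def test_higher_capacity_commensal_excludes_pathogen_everywhere(self):
        """k_c > k_p scenario: commensal dominance across the whole plane."""
        base = cr.ModelParams(k_p=0.5, k_c=1.5)
        af_grid = cr.scan_Af(base, np.linspace(0, 1, 21), np.linspace(0, 2, 21))
        assert np.all(af_grid.outcome == "commensal_dominance")
        assert np.all(np.isnan(af_grid.dP_dA))  # no coexistence, hence no release anywhere


class TestScanAlpha:
    def test_marked_interaction_points(self, alpha_grid):
        assert round(alpha_grid.value_at(0.8, 0.8), 4) == 0.4444
        assert round(alpha_grid.value_at(0.8, -0.8), 4) == 0.0976
        assert round(alpha_grid.value_at(-0.8, 0.8), 4) == -0.0976
        assert round(alpha_grid.value_at(-0.8, -0.8), 4) == -0.4444

    def test_zero_commensal_effect_row_is_zero(self, alpha_grid):
        i = int(np.argmin(np.abs(alpha_grid.axis1_values)))  # alpha_pc = 0
        row = alpha_grid.dP_df[i, :]
        assert np.all(np.abs(row[~np.isnan(row)]) < 1e-15)

    def test_sign_equals_commensal_inhibition_sign(self, alpha_grid):
        """Under exposure the benefit sign map is sign(alpha_pc) everywhere."""
        a = alpha_grid.axis1_values[:, None] * np.ones_like(alpha_grid.axis2_values)[None, :]
        ok = ~np.isnan(alpha_grid.dP_df)
        assert np.all(np.sign(alpha_grid.dP_df[ok]) == np.sign(a[ok]))

    def test_antisymmetry_relation(self, alpha_grid):
        """g(a, b) = -g(-a, b) (1 + ab) / (1 - ab), from the closed form."""
        rng = np.random.default_rng(5)
        vals = alpha_grid.axis1_values
        for _ in range(20):
            a = float(rng.choice(vals[vals > 0]))
            b = float(rng.choice(vals))
            g_pos = alpha_grid.value_at(a, b)
            g_neg = alpha_grid.value_at(-a, b)
            if np.isnan(g_pos) or np.isnan(g_neg):
                continue
            assert g_pos == pytest.approx(-g_neg * (1 + a * b) / (1 - a * b), rel=1e-9)

    def test_axis_bounds_validated(self):
        with pytest.raises(cr.NotApplicableError):
            cr.scan_alpha(cr.ModelParams(A=1.0), np.array([0.5, 1.0]), np.array([0.0]))


def test_scan_csv_roundtrip(tmp_path, fig3a):
    grid = cr.scan_Af(fig3a, np.linspace(0, 1, 5), np.linspace(0, 2, 5))
    path = tmp_path / "scan.csv"
    grid.to_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert list(df.columns) == ["A", "f", "P_star", "C_star", "outcome", "dP_dA", "dP_df"]
    assert len(df) == 25
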