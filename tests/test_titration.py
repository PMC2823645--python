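"""Titration fits, equivalence interpolation and bootstrap inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rcqge.preprocess import preprocess
from rcqge.simulate import ExpressionScenario, LadderDesign, simulate_expression
from rcqge.titration import (
    FitError,
    bootstrap_inference,
    fit_titration,
    format_qge_table,
    interpolate_equivalence,
    log_fold_change,
    run_panel,
)


def _points(xy, group="high", sample="s1", assay="G"):
    x, y = zip(*xy)
    return pd.DataFrame(
        {
            "sample_id": sample, "group": group, "assay": assay,
            "point_index": range(len(x)),
            "competitor_conc_M": 10.0 ** np.asarray(x, float),
            "log10_conc": np.asarray(x, float),
            "logit": np.asarray(y, float),
            "frequency": 1 / (1 + 10.0 ** (-np.asarray(y, float))),
        }
    )


class TestFit:
    def test_exact_line(self):
        df = _points([(-17, 1), (-16, 0), (-15, -1)])
        fit = fit_titration(df)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.intercepts["high"] == pytest.approx(-16.0, abs=1e-10)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_points_same_coefficients(self):
        df = _points([(-17, 1.2), (-16, 0.1), (-15, -0.9), (-14, -2.2)])
        fit1 = fit_titration(df)
        fit2 = fit_titration(pd.concat([df, df], ignore_index=True))
        assert fit2.slope == pytest.approx(fit1.slope, abs=1e-12)
        assert fit2.intercepts["high"] == pytest.approx(fit1.intercepts["high"], abs=1e-10)

    def test_noiseless_simulated_gene_zero_residual(self, noiseless_table):
        clean, _ = preprocess(noiseless_table)
        fit = fit_titration(clean[clean["assay"] == "GENE"])
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)
        assert fit.slope == pytest.approx(-1.0, abs=1e-10)

    def test_singular_design_raises(self):
        df = _points([(-16, 0.1), (-16, -0.1), (-16, 0.0)])
        with pytest.raises(FitError, match="G"):
            fit_titration(df)


class TestEquivalence:
    def test_closed_form_root(self):
        fit = fit_titration(_points([(-17, 1), (-16, 0), (-15, -1)]))
        eq = interpolate_equivalence(fit, "high")
        assert eq.x0 == pytest.approx(-16.0, abs=1e-10)
        assert eq.ec50 == pytest.approx(1e-16, rel=1e-9)

    def test_intercept_shift_moves_root_one_decade(self):
        base = _points([(-17, 1), (-16, 0), (-15, -1)])
        shifted = base.assign(logit=base["logit"] + 1.0)
        eq = interpolate_equivalence(fit_titration(shifted), "high")
        assert eq.x0 == pytest.approx(-15.0, abs=1e-10)

    def test_recovers_generator_baseline(self, default_design):
        scen = ExpressionScenario(
            true_log10_fc={"G": 0.0, "HK": 0.0},
            baseline_log10_conc={"G": -14.2, "HK": -16.0},
            housekeeping="HK", n_per_group=3, noise_sd=0.0,
        )
        clean, _ = preprocess(simulate_expression(scen, default_design, seed=1))
        fit = fit_titration(clean[clean["assay"] == "G"])
        for g in ("high", "low"):
            assert interpolate_equivalence(fit, g).x0 == pytest.approx(-14.2, abs=1e-9)

    def test_agrees_with_grid_search(self):
        """Closed-form root matches a brute-force scan of |y(x)|."""
        fit = fit_titration(_points([(-17.3, 1.4), (-16.1, 0.2), (-15.2, -0.7), (-14.0, -1.9)]))
        eq = interpolate_equivalence(fit, "high")
        grid = np.arange(-18.0, -13.0, 1e-6)
        yhat = fit.intercepts["high"] + fit.slope * grid
        brute = grid[np.argmin(np.abs(yhat))]
        assert eq.x0 == pytest.approx(brute, abs=1e-5)

    def test_degree_two_root_inside_range(self):
        x = np.linspace(-18, -13, 12)
        y = -0.02 * (x + 16) ** 2 - (x + 16)  # root at x = -16
        fit = fit_titration(_points(list(zip(x, y))), degree=2)
        eq = interpolate_equivalence(fit, "high")
        assert eq.x0 == pytest.approx(-16.0, abs=1e-6)
        assert not eq.extrapolated


class TestLogFoldChange:
    def test_null(self):
        lfc, fc, norm = log_fold_change(-16.0, -16.0, -15.0, -15.0)
        assert lfc == 0.0 and fc == 1.0 and norm

    def test_star_like_pair(self):
        """A normalized log10FC of 1.13 corresponds to a 13.5-fold change."""
        lfc, fc, _ = log_fold_change(-14.87, -16.0, -15.0, -15.0)
        assert lfc == pytest.approx(1.13)
        assert round(fc, 1) == 13.5

    def test_missing_housekeeping_flagged(self):
        with pytest.warns(UserWarning, match="unnormalized"):
            lfc, fc, norm = log_fold_change(-15.0, -16.0)
        assert not norm and lfc == pytest.approx(1.0)

    @given(st.floats(-18, -12), st.floats(-18, -12), st.floats(-18, -12), st.floats(-18, -12))
    def test_swap_inverts_fold_change(self, a, b, c, d):
        lfc, fc, _ = log_fold_change(a, b, c, d)
        lfc_sw, fc_sw, _ = log_fold_change(b, a, d, c)
        assert lfc_sw == pytest.approx(-lfc, abs=1e-12)
        assert fc * fc_sw == pytest.approx(1.0, rel=1e-9)

    @given(st.floats(-3, 3))
    def test_fc_is_power_of_lfc(self, lfc):
        _, fc, _ = log_fold_change(lfc, 0.0, 0.0, 0.0)
        assert fc == 10.0**lfc


@pytest.fixture(scope="module")
def clean_pair(noiseless_table):
    clean, _ = preprocess(noiseless_table)
    return clean[clean["assay"] == "GENE"], clean[clean["assay"] == "HPRT"]


class TestBootstrap:
    def test_seeded_determinism(self, clean_pair):
        g, hk = clean_pair
        a = bootstrap_inference(g, hk, B=200, seed=3)
        b = bootstrap_inference(g, hk, B=200, seed=3)
        assert a == b

    def test_noiseless_degenerate(self, clean_pair):
        g, hk = clean_pair
        res = bootstrap_inference(g, hk, B=200, seed=3)
        assert res.log10_fold_change == pytest.approx(np.log10(2.0), abs=1e-9)
        assert res.bias == pytest.approx(0.0, abs=1e-9)
        assert res.std_error == pytest.approx(0.0, abs=1e-9)

    def test_animal_unit_also_degenerate(self, clean_pair):
        g, hk = clean_pair
        res = bootstrap_inference(g, hk, B=200, seed=3, resample_unit="animal")
        assert res.std_error == pytest.approx(0.0, abs=1e-9)

    def test_self_normalization_is_null(self, clean_pair):
        g, _ = clean_pair
        res = bootstrap_inference(g, g, B=200, seed=1)
        assert res.log10_fold_change == pytest.approx(0.0, abs=1e-12)
        assert res.fold_change == pytest.approx(1.0, abs=1e-12)

    def test_fc_matches_log_fc_exactly(self, clean_pair):
        g, hk = clean_pair
        res = bootstrap_inference(g, hk, B=200, seed=3)
        assert res.fold_change == 10.0**res.log10_fold_change

    def test_p_floor(self, clean_pair):
        g, hk = clean_pair
        res = bootstrap_inference(g, hk, B=200, seed=3)
        assert 1.0 / 200 <= res.p_value <= 2.0 / 201 + 1e-12


class TestRunPanel:
    def test_schema_and_row_count(self, default_design):
        scen = ExpressionScenario(
            true_log10_fc={f"G{i}": 0.1 * i for i in range(1, 5)} | {"HPRT": 0.0},
            baseline_log10_conc={f"G{i}": -15.0 for i in range(1, 5)} | {"HPRT": -16.0},
            housekeeping="HPRT", n_per_group=4, noise_sd=0.0,
        )
        clean, _ = preprocess(simulate_expression(scen, default_design, seed=2))
        res = run_panel(clean, "HPRT", B=150, seed=0)
        assert len(res) == 5  # one row per assay, housekeeping included unnormalized
        hk_row = res[res["assay"] == "HPRT"].iloc[0]
        assert not hk_row["normalized"]
        assert set(res.columns) >= {
            "assay", "breed", "fold_change", "log10_fold_change", "bias",
            "std_error", "p_value", "n_high", "n_low",
        }

    def test_swapped_groups_invert_fold_changes(self, default_design):
        scen = ExpressionScenario(
            true_log10_fc={"G": 0.42, "HPRT": 0.0},
            baseline_log10_conc={"G": -15.0, "HPRT": -16.0},
            housekeeping="HPRT", n_per_group=5, noise_sd=0.1,
        )
        clean, _ = preprocess(simulate_expression(scen, default_design, seed=8))
        res = run_panel(clean, "HPRT", B=150, seed=1)
        res_sw = run_panel(clean, "HPRT", B=150, seed=1, groups=("low", "high"))
        g = res[res["assay"] == "G"].iloc[0]
        g_sw = res_sw[res_sw["assay"] == "G"].iloc[0]
        assert g_sw["log10_fold_change"] == pytest.approx(-g["log10_fold_change"], abs=1e-12)
        assert g_sw["fold_change"] * g["fold_change"] == pytest.approx(1.0, rel=1e-9)

    def test_empty_input(self):
        with pytest.warns(UserWarning, match="empty"):
            res = run_panel(pd.DataFrame(columns=["assay"]), "HPRT")
        assert res.empty

    def test_unknown_housekeeping(self, noiseless_table):
        clean, _ = preprocess(noiseless_table)
        with pytest.raises(ValueError, match="housekeeping"):
            run_panel(clean, "NOPE", B=150)


class TestFormatting:
    def test_published_rounding_convention(self):
        df = pd.DataFrame(
            {
                "assay": ["A"], "breed": ["L"], "fold_change": [10**1.13],
                "log10_fold_change": [1.13], "bias": [0.00321],
                "std_error": [0.136], "p_value": [0.000049],
            }
        )
        out = format_qge_table(df)
        assert out["fold_change"].iloc[0] == 13.5
        assert out["bias"].iloc[0] == 0.0032
        assert out["std_error"].iloc[0] == 0.14
        assert out["p_value"].iloc[0] == 0.0000


class TestOptions:
    def test_bh_adjustment_column(self, default_design):
        scen = ExpressionScenario(
            true_log10_fc={"G1": 0.5, "G2": 0.0, "HPRT": 0.0},
            baseline_log10_conc={"G1": -15.0, "G2": -14.5, "HPRT": -16.0},
            housekeeping="HPRT", n_per_group=5, noise_sd=0.1,
        )
        clean, _ = preprocess(simulate_expression(scen, default_design, seed=21))
        res = run_panel(clean, "HPRT", B=150, seed=2, adjust="bh")
        assert "p_adjusted" in res.columns
        sub = res[res["assay"] != "HPRT"]
        assert (sub["p_adjusted"] >= sub["p_value"] - 1e-12).all()

    def test_degree_two_bootstrap_matches_line_estimate(self, clean_pair):
        g, hk = clean_pair
        res1 = bootstrap_inference(g, hk, B=150, seed=5, degree=1)
        res2 = bootstrap_inference(g, hk, B=150, seed=5, degree=2)
        assert res2.log10_fold_change == pytest.approx(res1.log10_fold_change, abs=1e-6)

    def test_animal_resampling_available_in_panel(self, noiseless_table):
        clean, _ = preprocess(noiseless_table)
        res = run_panel(clean, "HPRT", B=150, seed=0, resample_unit="animal")
        gene = res[res["assay"] == "GENE"].iloc[0]
        assert gene["log10_fold_change"] == pytest.approx(np.log10(2.0), abs=1e-9)
        assert gene["std_error"] == pytest.approx(0.0, abs=1e-9)
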