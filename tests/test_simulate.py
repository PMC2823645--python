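"""The generator must honour its closed-form measurement model exactly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rcqge.simulate import (
    ASEScenario,
    AVOGADRO,
    ExpressionScenario,
    LadderDesign,
    PhenotypeScenario,
    inv_logit10,
    logit10,
    make_ladder,
    molecules_at,
    simulate_ase,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotypes,
)


class TestLadder:
    @pytest.mark.parametrize(
        "design, expected",
        [
            (dict(start_conc=1e-12, dilution_factor=10, n_points=1), [1e-12]),
            (dict(start_conc=1e-12, dilution_factor=2, n_points=4),
             [1e-12, 5e-13, 2.5e-13, 1.25e-13]),
        ],
    )
    def test_exact_geometric_points(self, design, expected):
        np.testing.assert_allclose(make_ladder(LadderDesign(**design)), expected, rtol=0)

    def test_default_fine_scan_endpoint(self):
        """Ten 7-fold dilutions from 4.04e-11 M end at 1.43e-19 M (3 s.f.)."""
        conc = make_ladder(LadderDesign())
        assert len(conc) == 11
        assert conc[0] == 4.04e-11
        assert float(f"{conc[-1]:.3g}") == 1.43e-19

    @given(
        start=st.floats(1e-20, 1e-6), factor=st.floats(1.01, 100),
        n=st.integers(3, 30),
    )
    def test_strictly_decreasing_geometric(self, start, factor, n):
        conc = make_ladder(LadderDesign(start_conc=start, dilution_factor=factor, n_points=n))
        assert np.all(np.diff(conc) < 0)
        np.testing.assert_allclose(conc[1:] * factor, conc[:-1], rtol=1e-12)

    @pytest.mark.parametrize(
        "kwargs", [dict(start_conc=0.0), dict(start_conc=-1e-12),
                   dict(dilution_factor=1.0), dict(dilution_factor=0.5)],
    )
    def test_invalid_design_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LadderDesign(**kwargs)


class TestMolecules:
    def test_three_molecules_at_attomolar(self):
        """1e-18 M in a 5 µL reaction is about 3 competitor molecules."""
        expected, nearest = molecules_at(1.00e-18, 5e-6)
        assert nearest == 3
        assert expected == pytest.approx(3.011, abs=0.001)

    def test_zero_concentration(self):
        assert molecules_at(0.0, 5e-6) == (0.0, 0)

    def test_unit_construction(self):
        expected, nearest = molecules_at(1.0, 1.0 / AVOGADRO)
        assert nearest == 1
        assert expected == pytest.approx(1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            molecules_at(-1e-18, 5e-6)
        with pytest.raises(ValueError):
            molecules_at(1e-18, 0.0)


class TestExpressionSimulator:
    def test_equivalence_point_frequency_is_half(self):
        """Noiseless frequency is exactly 0.5 where cDNA equals competitor."""
        design = LadderDesign(start_conc=1e-12, dilution_factor=10, n_points=9)
        scen = ExpressionScenario(
            true_log10_fc={"G": 0.0, "HK": 0.0},
            baseline_log10_conc={"G": -16.0, "HK": -16.0},
            housekeeping="HK", n_per_group=2, noise_sd=0.0,
        )
        df = simulate_expression(scen, design, seed=0)
        at_eq = df[df["point_index"] == 4]  # 1e-12 / 10**4 = 1e-16 M
        assert np.allclose(at_eq["competitor_conc_M"], 1e-16, rtol=1e-12)
        assert np.allclose(at_eq["frequency"], 0.5, atol=1e-15)

    def test_twofold_gene_gives_two_thirds_at_equivalence(self):
        """log10FC=0.301 puts the high group at f = R/(R+1) = 2/3 (R=2)."""
        design = LadderDesign(start_conc=1e-12, dilution_factor=10, n_points=9)
        scen = ExpressionScenario(
            true_log10_fc={"G": 0.301, "HK": 0.0},
            baseline_log10_conc={"G": -16.0, "HK": -16.0},
            housekeeping="HK", n_per_group=2, noise_sd=0.0,
        )
        df = simulate_expression(scen, design, seed=0)
        high = df[(df["assay"] == "G") & (df["group"] == "high")
                  & (df["point_index"] == 4)]
        assert np.allclose(high["frequency"], 10**0.301 / (10**0.301 + 1), atol=1e-12)
        assert np.allclose(high["frequency"], 2.0 / 3.0, atol=1e-3)

    def test_same_seed_identical_output(self, default_design):
        scen = ExpressionScenario(
            true_log10_fc={"G": 0.2, "HK": 0.0},
            baseline_log10_conc={"G": -15.0, "HK": -16.0},
            housekeeping="HK", n_per_group=3, noise_sd=0.2,
        )
        a = simulate_expression(scen, default_design, seed=42)
        b = simulate_expression(scen, default_design, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_expression(scen, default_design, seed=43)
        assert not a["frequency"].equals(c["frequency"])

    def test_frequencies_in_unit_interval(self, default_design):
        scen = ExpressionScenario(
            true_log10_fc={"G": 0.5, "HK": 0.0},
            baseline_log10_conc={"G": -15.0, "HK": -16.0},
            housekeeping="HK", n_per_group=10, noise_sd=0.8,
        )
        df = simulate_expression(scen, default_design, seed=5)
        f = df["frequency"].dropna()
        assert ((f > 0) & (f < 1)).all()

    def test_dropout_rate_matches_binomial(self, default_design):
        rate = 0.2
        scen = ExpressionScenario(
            true_log10_fc={"G": 0.0, "HK": 0.0},
            baseline_log10_conc={"G": -15.0, "HK": -16.0},
            housekeeping="HK", n_per_group=50, noise_sd=0.1,
            replicate_count=5, dropout_rate=rate,
        )
        df = simulate_expression(scen, default_design, seed=11)
        n = len(df)
        assert n >= 10_000
        observed = df["frequency"].isna().mean()
        tol = 4 * np.sqrt(rate * (1 - rate) / n)
        assert abs(observed - rate) < tol

    def test_housekeeping_must_be_null(self):
        with pytest.raises(ValueError, match="housekeeping"):
            ExpressionScenario(
                true_log10_fc={"G": 0.1, "HK": 0.2},
                baseline_log10_conc={"G": -15.0, "HK": -16.0},
                housekeeping="HK", noise_sd=0.0,
            )


class TestASESimulator:
    def test_frequencies_sum_to_one(self, default_design):
        scen = ASEScenario(allele1_fraction={"high": 0.7, "low": 0.6}, n_per_group=4)
        df = simulate_ase(scen, default_design, seed=2)
        sums = df.groupby(["sample_id", "point_index", "replicate"])["frequency"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_balanced_alleles_equal_frequencies(self, default_design):
        scen = ASEScenario(
            allele1_fraction={"high": 0.5, "low": 0.5},
            noise_sd=0.0, ratio_noise_sd=0.0, n_per_group=2,
        )
        df = simulate_ase(scen, default_design, seed=3)
        w = df.pivot_table(index=["sample_id", "point_index", "replicate"],
                           columns="allele", values="frequency")
        assert np.allclose(w["allele1"], w["allele2"], atol=1e-15)

    def test_skewed_partition_at_equivalence(self):
        """80:20 alleles at 1:1 cDNA:competitor give (0.4, 0.1, 0.5)."""
        design = LadderDesign(start_conc=1e-12, dilution_factor=10, n_points=9)
        scen = ASEScenario(
            allele1_fraction={"high": 0.8, "low": 0.8},
            baseline_log10_conc=-16.0, noise_sd=0.0, ratio_noise_sd=0.0,
            n_per_group=1,
        )
        df = simulate_ase(scen, design, seed=4)
        at_eq = df[df["point_index"] == 4]  # 1e-16 M
        w = at_eq.pivot_table(index=["sample_id", "replicate"], columns="allele",
                              values="frequency")
        assert np.allclose(w["allele1"], 0.4, atol=1e-12)
        assert np.allclose(w["allele2"], 0.1, atol=1e-12)
        assert np.allclose(w["competitor"], 0.5, atol=1e-12)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ASEScenario(allele1_fraction={"high": 1.0, "low": 0.5})


class TestPhenotypes:
    def test_genotypes_follow_hwe(self):
        geno = simulate_genotypes(20_000, {"s": ("A", "G")}, {"s": 0.3}, seed=1)
        counts = geno["genotype"].value_counts()
        n = len(geno)
        # expected HWE proportions for p=0.3
        assert counts.get("AA", 0) / n == pytest.approx(0.09, abs=0.01)
        assert counts.get("AG", 0) / n == pytest.approx(0.42, abs=0.01)
        assert counts.get("GG", 0) / n == pytest.approx(0.49, abs=0.01)

    def test_all_effects_zero_gives_constant_level(self):
        scen = PhenotypeScenario(scale=0.0, sire_sd=0.0, hys_sd=0.0)
        ph = simulate_phenotypes(scen, 20, seed=9)
        assert np.allclose(ph["androstenone"], 1.17, atol=1e-12)

    def test_extreme_selection_fractions(self):
        scen = PhenotypeScenario(extreme_fraction=0.06)
        ph = simulate_phenotypes(scen, 1000, seed=10)
        assert (ph["extreme_group"] == "high").sum() == 60
        assert (ph["extreme_group"] == "low").sum() == 60
        highs = ph.loc[ph["extreme_group"] == "high", "androstenone"]
        lows = ph.loc[ph["extreme_group"] == "low", "androstenone"]
        mid = ph.loc[ph["extreme_group"] == "", "androstenone"]
        assert highs.min() >= mid.max() - 1e-12
        assert lows.max() <= mid.min() + 1e-12

    def test_extreme_fraction_validated(self):
        with pytest.raises(ValueError):
            PhenotypeScenario(extreme_fraction=0.5)


class TestLogitHelpers:
    @given(st.floats(1e-6, 1 - 1e-6))
    def test_round_trip(self, f):
        assert inv_logit10(logit10(f)) == pytest.approx(f, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            logit10(0.0)
        with pytest.raises(ValueError):
            logit10(1.0)
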