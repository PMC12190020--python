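"""Scheffé mixture modelling: transformation, fitting, optimization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cuprackit as ck
from cuprackit.mixture import (
    MixtureDesignTable,
    MixtureObservation,
    ScheffeCoefficients,
    SolventComposition,
)
from cuprackit.simulate import DESIGN_POINTS

from _oracles import closed_form_scheffe

PRINTED_COEFFS = ScheffeCoefficients(0.046, 0.038, 0.015, 0.063, 0.112, 0.066)
PRINTED_SIGMA = {"pure": 0.039, "binary": 0.046, "ternary": 0.060}


class TestComposition:
    @pytest.mark.parametrize(
        "z, expected",
        [
            ((1, 0, 0), "pure"),
            ((0.64, 0, 0.36), "binary"),
            ((0.33, 0.33, 0.33), "ternary"),
            ((0, 0, 1), "pure"),
        ],
    )
    def test_classification(self, z, expected):
        assert ck.classify_composition(SolventComposition(*z)) == expected

    def test_normalisation_within_tolerance(self):
        z = SolventComposition(0.33, 0.33, 0.33)
        assert z.z1 + z.z2 + z.z3 == pytest.approx(1.0, abs=1e-15)
        assert z.z1 == pytest.approx(1 / 3)

    def test_sum_outside_tolerance_rejected(self):
        with pytest.raises(ck.DataValidationError, match="sum"):
            SolventComposition(0.5, 0.2, 0.2)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ck.DataValidationError):
            SolventComposition(-0.2, 0.6, 0.6)


class TestTransform:
    def test_hand_computed_products(self):
        table = MixtureDesignTable(
            observations=[
                MixtureObservation(SolventComposition(1, 0, 0), 1.147),
                MixtureObservation(SolventComposition(1 / 3, 1 / 3, 1 / 3), 0.933),
                MixtureObservation(SolventComposition(0.5, 0, 0.5), 0.0),
            ]
        )
        out = ck.transform_signals(table, PRINTED_SIGMA)
        phis = [phi for _, phi in out]
        assert phis[0] == pytest.approx(1.147 * 0.039)   # 0.044733
        assert phis[1] == pytest.approx(0.933 * 0.060)   # 0.05598
        assert phis[2] == 0.0

    def test_missing_class_sigma_raises(self):
        table = MixtureDesignTable(
            observations=[MixtureObservation(SolventComposition(1, 0, 0), 1.0)]
        )
        with pytest.raises(ck.ConfigurationError, match="pure"):
            ck.transform_signals(table, {"binary": 0.05})

    def test_back_transform_inverts_transform(self, screen_table):
        sigma = ck.compute_sigma_by_class(screen_table)
        for z, phi in ck.transform_signals(screen_table, sigma):
            psi = ck.back_transform(phi, z, sigma)
            assert psi == pytest.approx(phi / sigma[z.mixture_class], rel=1e-14)

    def test_back_transform_hand_value(self):
        psi = ck.back_transform(0.046, SolventComposition(1, 0, 0), PRINTED_SIGMA)
        assert psi == pytest.approx(0.046 / 0.039, rel=1e-12)  # ~1.179
        assert ck.back_transform(0.0, SolventComposition(1, 0, 0), PRINTED_SIGMA) == 0.0

    def test_back_transform_zero_sigma_raises(self):
        with pytest.raises(ZeroDivisionError):
            ck.back_transform(0.1, SolventComposition(1, 0, 0), {"pure": 0.0})


class TestSigmaByClass:
    def test_reference_screen_matches_reported_class_sigmas(self, screen_table):
        sigma = ck.compute_sigma_by_class(screen_table)
        assert sigma["pure"] == pytest.approx(0.039, abs=5e-4)
        assert sigma["binary"] == pytest.approx(0.046, abs=5e-4)
        assert sigma["ternary"] == pytest.approx(0.060, abs=6e-4)

    def test_singleton_composition_listed(self):
        table = MixtureDesignTable(
            observations=[
                MixtureObservation(SolventComposition(1, 0, 0), 1.0, 1),
                MixtureObservation(SolventComposition(1, 0, 0), 1.1, 2),
                MixtureObservation(SolventComposition(0, 1, 0), 0.9, 1),
            ]
        )
        with pytest.raises(ck.DataValidationError, match="single replicate"):
            ck.compute_sigma_by_class(table)

    def test_identical_replicates_flagged_degenerate(self):
        table = MixtureDesignTable(
            observations=[
                MixtureObservation(SolventComposition(1, 0, 0), 1.0, r) for r in (1, 2)
            ]
        )
        sigma = ck.compute_sigma_by_class(table)
        assert sigma["pure"] == 0.0
        assert "pure" in table.metadata["degenerate_sigma_classes"]


class TestFit:
    def test_reference_screen_recovers_reported_polynomial(self, screen_table):
        res = ck.ScheffeMixtureModel(screen_table).fit()
        # printed coefficients reflect unrounded raw signals; agreement is
        # to the third decimal on each term
        np.testing.assert_allclose(
            res.params, PRINTED_COEFFS.as_array(), atol=1.1e-3
        )

    def test_saturated_design_interpolates_exactly(self):
        rng = np.random.default_rng(7)
        obs = [
            MixtureObservation(z, float(rng.uniform(0.5, 1.5)))
            for z in DESIGN_POINTS[:6]  # vertices + midpoints, no centroid
        ]
        table = MixtureDesignTable(observations=obs)
        transformed = [(o.composition, o.psi) for o in obs]
        coeffs, resid, _ = ck.fit_scheffe(transformed)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)
        # vertex identity: fitted k_i equals the signal at vertex i
        assert coeffs.k1 == pytest.approx(obs[0].psi, abs=1e-12)
        assert coeffs.k2 == pytest.approx(obs[1].psi, abs=1e-12)
        assert coeffs.k3 == pytest.approx(obs[2].psi, abs=1e-12)

    def test_noiseless_recovery_to_machine_precision(self):
        truth = PRINTED_COEFFS
        transformed = [
            (z, ck.predict_phi(truth, z)) for z in DESIGN_POINTS for _ in range(3)
        ]
        coeffs, _, _ = ck.fit_scheffe(transformed)
        np.testing.assert_allclose(coeffs.as_array(), truth.as_array(), atol=1e-12)

    def test_closed_form_oracle_on_replicated_design(self, rng):
        """LS coefficients equal the closed-form vertex/edge estimates on a
        vertices + edge-midpoints design (replicated, with noise)."""
        transformed = []
        for z in DESIGN_POINTS[:6]:
            for _ in range(3):
                transformed.append(
                    (z, ck.predict_phi(PRINTED_COEFFS, z) + rng.normal(0, 0.005))
                )
        coeffs, _, _ = ck.fit_scheffe(transformed)
        np.testing.assert_allclose(
            coeffs.as_array(), closed_form_scheffe(transformed), atol=1e-10
        )

    def test_rank_deficient_design_names_missing_support(self):
        transformed = [(z, 1.0) for z in DESIGN_POINTS[:3]]  # vertices only
        with pytest.raises(ck.SingularDesignError, match="0.5"):
            ck.fit_scheffe(transformed)


class TestPredict:
    def test_vertex_identity(self):
        assert ck.predict_phi(PRINTED_COEFFS, SolventComposition(1, 0, 0)) == 0.046

    def test_centroid_closed_form(self):
        k = PRINTED_COEFFS
        expected = (k.k1 + k.k2 + k.k3) / 3 + (k.k12 + k.k13 + k.k23) / 9
        z = SolventComposition(1 / 3, 1 / 3, 1 / 3)
        assert ck.predict_phi(k, z) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(0.0598, abs=1e-4)

    def test_edge_midpoint_closed_form(self):
        k = PRINTED_COEFFS
        z = SolventComposition(0.5, 0, 0.5)
        expected = (k.k1 + k.k3) / 2 + k.k13 / 4  # = 0.0585
        assert ck.predict_phi(k, z) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(0.0585, abs=1e-4)


class TestOptimize:
    def test_reference_model_optimum_is_methanol_water_64_36(self, screen_table):
        res = ck.ScheffeMixtureModel(screen_table).fit()
        opt = res.optimize(grid_step=0.005)
        assert opt.as_ratio() == (0.64, 0.0, 0.36)
        # predicted maximum on the absorbance scale
        assert opt.psi_pred == pytest.approx(1.332, rel=0.015)

    def test_linear_model_optimum_at_best_vertex(self):
        k = ScheffeCoefficients(0.05, 0.04, 0.03, 0, 0, 0)
        sigma = {"pure": 0.04, "binary": 0.04, "ternary": 0.04}
        opt = ck.optimize_composition(k, sigma, grid_step=0.05)
        assert opt.composition.as_array() == pytest.approx([1, 0, 0])

    def test_symmetric_tie_broken_toward_methanol(self):
        k = ScheffeCoefficients(0.05, 0.05, 0.05, 0, 0, 0)
        sigma = {"pure": 0.04, "binary": 0.04, "ternary": 0.04}
        opt = ck.optimize_composition(k, sigma, grid_step=0.25)
        assert opt.composition.z1 == 1.0

    def test_optimum_dominates_exhaustive_grid(self, screen_table):
        """The returned psi is >= psi at every lattice point of pitch 0.01
        and at every closed-form stationary point."""
        res = ck.ScheffeMixtureModel(screen_table).fit()
        opt = res.optimize(grid_step=0.01)
        sigma = res.model.sigma_by_class
        n = 100
        for i in range(n + 1):
            for j in range(n - i + 1):
                z = SolventComposition(i / n, j / n, (n - i - j) / n)
                psi = ck.back_transform(res.predict_phi(z), z, sigma)
                assert opt.psi_pred >= psi - 1e-12

    def test_bad_grid_step_rejected(self, screen_table):
        res = ck.ScheffeMixtureModel(screen_table).fit()
        with pytest.raises(ck.ConfigurationError, match="grid_step"):
            res.optimize(grid_step=0.3)


class TestSignalRatios:
    def test_reference_ratios_vs_pure_water(self, screen_table):
        water = SolventComposition(0, 0, 1)
        ratios = ck.signal_ratios(screen_table, water)
        expected = {
            (1.0, 0.0, 0.0): 3.07,   # methanol
            (0.0, 1.0, 0.0): 2.54,   # ethanol
            (0.5, 0.5, 0.0): 3.26,   # methanol/ethanol
            (0.5, 0.0, 0.5): 3.29,   # methanol/water
            (0.0, 0.5, 0.5): 2.41,   # ethanol/water
        }
        for key, val in expected.items():
            assert ratios[key] == val
        centroid = SolventComposition(1 / 3, 1 / 3, 1 / 3).key()
        assert ratios[centroid] == 2.56

    def test_reference_to_itself_is_one(self, screen_table):
        water = SolventComposition(0, 0, 1)
        ratios = ck.signal_ratios(screen_table, water, ndigits=None)
        full = dict(screen_table.mean_psi())
        assert full[water.key()] / full[water.key()] == 1.0

    def test_absent_reference_raises(self, screen_table):
        with pytest.raises(ck.DataValidationError, match="reference"):
            ck.signal_ratios(screen_table, SolventComposition(0.25, 0.25, 0.5))


@settings(max_examples=30, deadline=None)
@given(
    k=st.lists(st.floats(-0.1, 0.2, allow_nan=False), min_size=6, max_size=6),
)
def test_vertex_identity_property(k):
    """Predicted Phi at vertex i equals k_i for any coefficient vector."""
    coeffs = ScheffeCoefficients.from_array(k)
    assert ck.predict_phi(coeffs, SolventComposition(1, 0, 0)) == pytest.approx(k[0], abs=1e-15)
    assert ck.predict_phi(coeffs, SolventComposition(0, 1, 0)) == pytest.approx(k[1], abs=1e-15)
    assert ck.predict_phi(coeffs, SolventComposition(0, 0, 1)) == pytest.approx(k[2], abs=1e-15)


def test_parameter_recovery_within_three_se():
    """Simulated screens at the reference noise level recover the true
    coefficients within 3 estimated SEs in >= 95% of 200 seeds."""
    truth = PRINTED_COEFFS
    hits = 0
    n_sim = 200
    for seed in range(n_sim):
        cfg = ck.GeneratorConfig(seed=seed)
        table = ck.gen_mixture_table(cfg)
        transformed = ck.transform_signals(table, PRINTED_SIGMA)
        coeffs, _, bse = ck.fit_scheffe(transformed)
        if np.all(np.abs(coeffs.as_array() - truth.as_array()) <= 3 * bse):
            hits += 1
    assert hits / n_sim >= 0.95
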