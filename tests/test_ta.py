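import math

import numpy as np
import pytest
from scipy import integrate, optimize

from lovspec import synth
from lovspec.errors import ValidationError
from lovspec.io import SpeciesBasis, Spectrum
from lovspec.ta import (
    convolved_exponential,
    decompose_spectrum,
    gaussian_irf_kernel,
    global_lifetime_analysis,
    intermediate_detection_limit,
    intermediate_peak_fraction,
    intermediate_profile,
    reconstruct,
    subtract_reference,
    svd_denoise,
    t0_spectrum,
)


class TestConvolvedExponential:
    def test_pure_exponential_limit(self):
        val = convolved_exponential(1.0, 0.0, 1e-9, np.array([1.0]))[0]
        assert abs(val - math.exp(-1.0)) < 1e-9

    def test_step_midpoint_for_nondecaying(self):
        assert convolved_exponential(0.0, 0.0, 0.4, np.array([0.0]))[0] == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "k,sigma", [(0.5, 0.3), (2.0, 0.1), (0.0, 0.5), (10.0, 1.0), (0.03, 2.0)]
    )
    def test_matches_numerical_quadrature(self, k, sigma):
        """Closed form vs direct quadrature of ∫₀^∞ e^{-ks} g(t−t0−s) ds."""
        t0 = 1.3
        for t in (-0.5, 0.0, 1.0, 1.5, 3.0, 8.0):
            def integrand(s):
                return math.exp(-k * s) * math.exp(
                    -0.5 * ((t - t0 - s) / sigma) ** 2
                ) / (sigma * math.sqrt(2 * math.pi))

            # finite range covering the Gaussian peak (marked as a breakpoint
            # so the quadrature cannot step over a narrow IRF)
            peak = max(t - t0, 0.0)
            upper = peak + 30.0 * sigma
            expected, _ = integrate.quad(
                integrand, 0.0, upper, limit=400, points=[peak]
            )
            got = convolved_exponential(k, t0, sigma, np.array([t]))[0]
            assert abs(got - expected) < 1e-8

    def test_large_k_sigma_is_finite(self):
        out = convolved_exponential(1e3, 0.0, 1.0, np.linspace(-5, 5, 11))
        assert np.all(np.isfinite(out))

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValidationError):
            convolved_exponential(1.0, 0.0, -0.1, np.array([0.0]))


class TestGlobalLifetimeAnalysis:
    def test_noiseless_two_component_recovery(self, ta_scene):
        """Decaying 28.0 µs + non-decaying DADS recovered to 1e-6 relative."""
        s = ta_scene
        m = synth.simulate_ta_matrix(
            s["dads"], s["lifetimes"], s["times"], t0=s["t0"], irf_sigma=s["irf_sigma"]
        )
        res = global_lifetime_analysis(
            m, 2, nondecaying=True, t0=s["t0"], irf_sigma=s["irf_sigma"]
        )
        assert abs(res.lifetimes[0] - 28.0) / 28.0 < 1e-6
        assert math.isinf(res.lifetimes[1])
        for got, want in zip(res.dads, s["dads"]):
            scale = np.max(np.abs(want.values))
            np.testing.assert_allclose(got.values, want.values, atol=1e-6 * scale)

    def test_single_nondecaying_component(self, flavin_basis):
        spec = flavin_basis["FMNHrad"]
        t = np.linspace(0.0, 100.0, 128)
        m = synth.simulate_ta_matrix([spec], [np.inf], t, t0=1.0, irf_sigma=0.3)
        res = global_lifetime_analysis(m, 1, nondecaying=True, t0=1.0, irf_sigma=0.3)
        assert res.lifetimes == [math.inf]
        np.testing.assert_allclose(res.dads[0].values, spec.values, rtol=1e-9)

    def test_variable_projection_equals_joint_fit(self):
        """On a small instance the variable-projection optimum coincides with a
        full joint nonlinear optimisation of lifetimes and amplitudes."""
        grid = np.linspace(400.0, 600.0, 5)
        basis = synth.make_flavin_basis(grid)
        dads = [basis["FMNox"], basis["FMNHrad"]]
        t = np.linspace(0.0, 50.0, 50)
        t0, sigma, tau_true = 1.0, 0.3, 7.0
        m = synth.simulate_ta_matrix(dads, [tau_true, np.inf], t, t0=t0, irf_sigma=sigma)

        varpro = global_lifetime_analysis(m, 2, nondecaying=True, t0=t0, irf_sigma=sigma)

        # joint fit: one log-lifetime plus all 2×5 amplitudes simultaneously
        def joint_residual(params):
            tau = math.exp(params[0])
            amps = params[1:].reshape(2, grid.size)
            c1 = convolved_exponential(1 / tau, t0, sigma, t)
            c2 = convolved_exponential(0.0, t0, sigma, t)
            model = np.outer(amps[0], c1) + np.outer(amps[1], c2)
            return (model - m.values).ravel()

        p0 = np.concatenate(
            [[math.log(5.0)], dads[0].values * 0.9, dads[1].values * 1.1]
        )
        joint = optimize.least_squares(joint_residual, p0, xtol=1e-15, ftol=1e-15)
        tau_joint = math.exp(joint.x[0])
        assert abs(varpro.lifetimes[0] - tau_joint) / tau_joint < 1e-6

    def test_forward_model_reconstruction(self, ta_scene):
        s = ta_scene
        m = synth.simulate_ta_matrix(
            s["dads"], s["lifetimes"], s["times"], t0=s["t0"], irf_sigma=s["irf_sigma"]
        )
        res = global_lifetime_analysis(
            m, 2, nondecaying=True, t0=s["t0"], irf_sigma=s["irf_sigma"]
        )
        model = reconstruct(res, m)
        assert np.max(np.abs(model.values - m.values)) < 1e-6

    def test_artifact_spectrum_recovered(self, flavin_basis):
        grid = np.linspace(360.0, 660.0, 40)
        basis = synth.make_flavin_basis(grid)
        d0 = basis["FMNox"].with_values(0.2 * basis["FMNox"].values, label="D0")
        dads = [basis["Triplet"]]
        t = np.linspace(0.0, 80.0, 256)
        m = synth.simulate_ta_matrix(
            dads, [12.0], t, t0=2.0, irf_sigma=0.4, d0=d0
        )
        res = global_lifetime_analysis(
            m, 1, fit_artifact=True, t0=2.0, irf_sigma=0.4
        )
        assert abs(res.lifetimes[0] - 12.0) / 12.0 < 1e-6
        np.testing.assert_allclose(
            res.d0.values, d0.values, atol=1e-6 * np.max(np.abs(d0.values))
        )

    def test_too_few_time_points_rejected(self, flavin_basis):
        m = synth.simulate_ta_matrix(
            [flavin_basis["FMNox"]], [5.0], np.linspace(0, 10, 5)
        )
        with pytest.raises(ValidationError):
            global_lifetime_analysis(m, 2)


class TestT0Spectrum:
    def test_cancellation_of_opposite_dads(self, ta_scene):
        from lovspec.ta import GLAResult

        d = ta_scene["dads"][0]
        res = GLAResult(
            [5.0, math.inf], [d, d.with_values(-d.values)], None, 0.0, 0.4,
            np.zeros((1, 1)), 0.0,
        )
        np.testing.assert_allclose(t0_spectrum(res).values, 0.0, atol=1e-15)

    def test_triplet_decay_scenario_gives_pure_triplet_spectrum(self, ta_scene):
        """DADS1 = triplet − ground (decaying), DADS2 = radical − ground
        (persistent): their sum is the spectrum immediately after excitation,
        here triplet + radical − 2·ground by construction."""
        s = ta_scene
        m = synth.simulate_ta_matrix(
            s["dads"], s["lifetimes"], s["times"], t0=s["t0"], irf_sigma=s["irf_sigma"]
        )
        res = global_lifetime_analysis(
            m, 2, nondecaying=True, t0=s["t0"], irf_sigma=s["irf_sigma"]
        )
        expected = s["dads"][0].values + s["dads"][1].values
        np.testing.assert_allclose(
            t0_spectrum(res).values, expected, atol=1e-6 * np.max(np.abs(expected))
        )


class TestDecomposeSpectrum:
    def test_construction_coefficients_recovered(self, flavin_basis):
        diff = flavin_basis["FMNHrad"].values - flavin_basis["FMNox"].values
        basis = SpeciesBasis(
            {
                "FMNH-FMNox": Spectrum(flavin_basis.grid, diff),
                "TrpRad": flavin_basis["TrpRad"],
            }
        )
        target = Spectrum(flavin_basis.grid, 1.0 * diff + 0.3 * flavin_basis["TrpRad"].values)
        result = decompose_spectrum(target, basis)
        assert abs(result["FMNH-FMNox"] - 1.0) < 1e-9
        assert abs(result["TrpRad"] - 0.3) < 1e-9
        assert result.rms < 1e-12

    def test_single_reference_identity(self, flavin_basis):
        basis = flavin_basis.subset(["FMNox", "TyrORad"])
        result = decompose_spectrum(flavin_basis["FMNox"], basis)
        assert abs(result["FMNox"] - 1.0) < 1e-9
        assert abs(result["TyrORad"]) < 1e-9

    def test_orthogonal_target_gives_zero_coefficients(self):
        grid = np.arange(350.0, 650.0, 1.0)
        ref = Spectrum(grid, np.where(grid < 500.0, 1.0, 0.0))
        target = Spectrum(grid, np.where(grid >= 500.0, 0.7, 0.0))
        result = decompose_spectrum(target, SpeciesBasis({"ref": ref}))
        assert abs(result["ref"]) < 1e-12
        np.testing.assert_allclose(result.residual.values, target.values)

    def test_collinear_basis_names_the_pair(self, flavin_basis):
        basis = SpeciesBasis(
            {
                "FMNox": flavin_basis["FMNox"],
                "FMNox_x2": flavin_basis["FMNox"].with_values(
                    2.0 * flavin_basis["FMNox"].values
                ),
                "TrpRad": flavin_basis["TrpRad"],
            }
        )
        with pytest.raises(ValidationError, match="FMNox"):
            decompose_spectrum(flavin_basis["TrpRad"], basis)

    def test_nonnegative_constraint(self, flavin_basis):
        basis = flavin_basis.subset(["FMNox", "TrpRad"])
        target = Spectrum(
            flavin_basis.grid,
            -0.5 * flavin_basis["FMNox"].values + 0.2 * flavin_basis["TrpRad"].values,
        )
        result = decompose_spectrum(target, basis, nonnegative=True)
        assert result["FMNox"] == 0.0
        assert result["TrpRad"] >= 0.0

    def test_adding_a_present_reference_never_raises_rms(self, flavin_basis):
        target = Spectrum(
            flavin_basis.grid,
            0.8 * flavin_basis["FMNHrad"].values + 0.4 * flavin_basis["TyrORad"].values,
        )
        small = flavin_basis.subset(["FMNHrad"])
        large = flavin_basis.subset(["FMNHrad", "TyrORad"])
        assert (
            decompose_spectrum(target, large).rms
            <= decompose_spectrum(target, small).rms + 1e-15
        )


class TestSubtractReference:
    def test_zero_scale_is_identity(self, flavin_basis):
        target = flavin_basis["FMNHrad"]
        out = subtract_reference(target, flavin_basis["FMNox"], 0.0)
        np.testing.assert_array_equal(out.values, target.values)

    def test_construction_recovery(self, flavin_basis):
        a = flavin_basis["TyrORad"].values
        b = flavin_basis["FMNox"].values
        target = Spectrum(flavin_basis.grid, a + 0.7 * b)
        out = subtract_reference(target, flavin_basis["FMNox"], 0.7)
        np.testing.assert_allclose(out.values, a, atol=1e-12)

    def test_tyrosyl_band_isolated_from_synthetic_dads2(self, flavin_basis):
        """Subtracting the flavin difference spectrum from a radical-pair DADS
        leaves the narrow 400 nm tyrosyl band with its 380 nm shoulder."""
        grid = flavin_basis.grid
        diff = flavin_basis["FMNHrad"].values - flavin_basis["FMNox"].values
        dads2 = Spectrum(grid, diff + 0.4 * flavin_basis["TyrORad"].values)
        out = subtract_reference(dads2, Spectrum(grid, diff), 1.0)
        peak = grid[np.argmax(out.values)]
        assert abs(peak - 400.0) <= 1.0
        shoulder_region = (grid >= 375.0) & (grid <= 385.0)
        assert out.values[shoulder_region].max() > 0.3 * out.values.max()


class TestSvdDenoise:
    def test_full_rank_is_identity(self, flavin_basis):
        m = synth.simulate_photoreduction_series(
            flavin_basis, 25.7, np.arange(0.0, 51.0, 5.0), noise_sigma=0.01, seed=1
        )
        out = svd_denoise(m, min(m.shape))
        np.testing.assert_allclose(out.values, m.values, atol=1e-9)

    def test_rank_one_matrix_reconstructed_exactly(self, flavin_basis):
        t = np.arange(0.0, 50.0, 5.0)
        vals = np.outer(flavin_basis["TrpRad"].values, np.exp(-t / 20.0))
        from lovspec.io import SpectralMatrix

        m = SpectralMatrix(flavin_basis.grid, t, vals, "s")
        np.testing.assert_allclose(svd_denoise(m, 1).values, vals, atol=1e-12)

    def test_denoising_beats_raw_noise(self, flavin_basis):
        t = np.arange(0.0, 151.0, 5.0)
        clean = synth.simulate_photoreduction_series(flavin_basis, 25.7, t)
        noisy = synth.simulate_photoreduction_series(
            flavin_basis, 25.7, t, noise_sigma=0.005, seed=9
        )
        denoised = svd_denoise(noisy, 2)
        err_raw = np.sqrt(np.mean((noisy.values - clean.values) ** 2))
        err_den = np.sqrt(np.mean((denoised.values - clean.values) ** 2))
        assert err_den < err_raw

    def test_rank_out_of_bounds_rejected(self, flavin_basis):
        m = synth.simulate_photoreduction_series(
            flavin_basis, 25.7, np.arange(0.0, 51.0, 5.0)
        )
        with pytest.raises(ValidationError):
            svd_denoise(m, 0)


class TestDetectionLimit:
    def test_ten_percent_threshold_gives_ratio_point_14(self):
        """A 10% peak-concentration detection threshold corresponds to a
        formation/decay rate-constant ratio of ca. 0.14."""
        lim = intermediate_detection_limit(28.0, 0.10)
        assert round(lim.ratio, 2) == 0.14
        assert abs(lim.ratio - 0.137) < 5e-4

    def test_lifetime_bound_for_28us_formation(self):
        lim = intermediate_detection_limit(28.0, 0.10)
        assert round(lim.lifetime_bound, 1) == 3.8

    def test_root_verified_by_numerical_peak_maximisation(self):
        """Independent check: maximise the analytic B(t) profile numerically
        and compare its peak to the threshold."""
        lim = intermediate_detection_limit(28.0, 0.10)
        t = np.linspace(0.0, 300.0, 200001)
        peak = intermediate_profile(t, lim.tau_form, lim.ratio).max()
        assert abs(peak - 0.10) < 1e-8

    def test_peak_fraction_closed_form(self):
        for x in (0.05, 0.137, 0.5, 0.9):
            t = np.linspace(0.0, 500.0, 400001)
            peak = intermediate_profile(t, 10.0, x).max()
            assert abs(peak - intermediate_peak_fraction(x)) < 1e-7

    def test_threshold_toward_one_drives_ratio_to_one(self):
        lim = intermediate_detection_limit(10.0, 0.999)
        assert lim.ratio > 0.999
        assert lim.lifetime_bound == pytest.approx(10.0, rel=1e-3)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValidationError):
            intermediate_detection_limit(10.0, 1.5)
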