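"""Population profiles and constrained channel-bank fits."""

import itertools

import numpy as np
import pytest
import sympy

from expectprofile.channels import (BASELINE_CENTERS, MAIN_CENTERS,
                                    PopulationProfile, build_population_profile,
                                    channel_sum, fit_sharpening, fit_shift,
                                    fit_combined, rmsd, channel_changes,
                                    mean_shift, SIGMA_BOUNDS)

ORIENTS = np.arange(20.0, 71.0, 10.0)


def bank_profile(condition, amps, centers, widths):
    lo, hi = {"B20": (15, 75), "B70": (15, 75),
              "E20": (15, 65), "E70": (25, 75)}[condition]
    grid = np.arange(lo, hi + 0.5, 1.0)
    return PopulationProfile(grid, channel_sum(grid, amps, centers, widths),
                             "baseline" if condition[0] == "B" else "main",
                             condition)


class TestPopulationProfile:
    def test_constant_thresholds_give_constant_negated_profile(self):
        prof = build_population_profile(ORIENTS, np.full(6, 2.5), "B20")
        assert np.allclose(prof.values, -2.5)

    def test_grid_lengths_61_baseline_51_main(self):
        assert build_population_profile(ORIENTS, np.ones(6), "B20").n_points == 61
        main = build_population_profile(ORIENTS[:-1], np.ones(5), "E20")
        assert main.n_points == 51
        assert build_population_profile(ORIENTS[1:], np.ones(5), "E70").n_points == 51

    def test_linear_thresholds_interpolate_exactly(self):
        dts = 2.0 + 0.01 * ORIENTS
        prof = build_population_profile(ORIENTS, dts, "B20")
        assert np.allclose(prof.values, -(2.0 + 0.01 * prof.grid))

    def test_nearest_extension_flat_margins(self):
        dts = 2.0 + 0.01 * ORIENTS
        prof = build_population_profile(ORIENTS, dts, "B20",
                                        extension="nearest")
        assert np.allclose(prof.values[:5], -(2.0 + 0.01 * 20.0))

    def test_too_few_orientations_rejected(self):
        with pytest.raises(ValueError):
            build_population_profile([20.0], [1.0], "B20")


class TestRMSD:
    def test_limiting_values(self):
        assert rmsd(0.0, 51, 7) == 0.0
        assert rmsd(44.0, 51, 7) == pytest.approx(1.0)

    @pytest.mark.parametrize("sse,n,k", [(3.7, 61, 7), (0.02, 51, 11), (12.5, 21, 5)])
    def test_matches_arbitrary_precision(self, sse, n, k):
        exact = float(sympy.sqrt(sympy.Float(sse, 30) / (n - k)))
        assert rmsd(sse, n, k) == pytest.approx(exact, abs=1e-12)

    def test_undefined_for_saturated_model(self):
        with pytest.raises(ValueError):
            rmsd(1.0, 5, 5)


class TestSharpeningFit:
    def test_recovers_equal_energy_bank(self):
        sig = np.full(6, 10.0)
        energy = -30.0
        amps = energy / (sig * np.sqrt(np.pi))
        prof = bank_profile("B20", amps, BASELINE_CENTERS, sig)
        fit = fit_sharpening(prof)
        assert fit.sse == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(fit.widths, 10.0, atol=0.05)
        assert fit.energy == pytest.approx(energy, rel=1e-3)

    def test_equal_energy_constraint_exact(self):
        prof = bank_profile("E20", np.full(5, -1.0), MAIN_CENTERS["E20"],
                            np.full(5, 12.0))
        fit = fit_sharpening(prof)
        dev = np.abs(fit.amplitudes * fit.widths * np.sqrt(np.pi) - fit.energy)
        assert dev.max() < 1e-9

    def test_channel_counts_six_baseline_five_main(self):
        base = bank_profile("B70", np.full(6, -1.0), BASELINE_CENTERS,
                            np.full(6, 10.0))
        main = bank_profile("E70", np.full(5, -1.0), MAIN_CENTERS["E70"],
                            np.full(5, 10.0))
        assert fit_sharpening(base).n_channels == 6
        assert fit_sharpening(main).n_channels == 5

    def test_widths_stay_in_bounds_on_noisy_data(self, rng):
        prof = bank_profile("B20", np.full(6, -1.0), BASELINE_CENTERS,
                            np.full(6, 10.0))
        prof.values = prof.values + 0.3 * rng.standard_normal(len(prof.grid))
        fit = fit_sharpening(prof)
        assert np.all(fit.widths >= SIGMA_BOUNDS[0])
        assert np.all(fit.widths <= SIGMA_BOUNDS[1])


class TestShiftFit:
    def test_lattice_identity_configuration(self):
        prof = bank_profile("B20", np.full(6, -1.0), BASELINE_CENTERS,
                            np.full(6, 12.0))
        fit = fit_shift(prof)
        assert fit.sse == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(fit.centers, BASELINE_CENTERS, atol=0.05)

    def test_recovers_uniform_displacement(self):
        prof = bank_profile("B70", np.full(6, -1.0), BASELINE_CENTERS + 2.0,
                            np.full(6, 12.0))
        fit = fit_shift(prof)
        assert np.allclose(fit.centers - BASELINE_CENTERS, 2.0, atol=0.1)

    def test_bounds_respected_for_main_conditions(self, rng):
        prof = bank_profile("E20", np.full(5, -1.0), MAIN_CENTERS["E20"],
                            np.full(5, 12.0))
        prof.values = prof.values + 0.3 * rng.standard_normal(len(prof.grid))
        fit = fit_shift(prof)
        assert np.all(fit.centers >= 15.0) and np.all(fit.centers <= 65.0)


class TestCombinedFit:
    def base_bank(self):
        sig = np.full(6, 10.0)
        energy = -30.0
        return bank_profile("B20", energy / (sig * np.sqrt(np.pi)),
                            BASELINE_CENTERS, sig)

    def test_recovers_sharpening_plus_shift_truth(self):
        base = self.base_bank()
        sig_m = np.array([7.0, 12.0, 12.0, 12.0, 12.0])
        amps_m = np.array([-30.0 / (7.0 * np.sqrt(np.pi)), -1, -1, -1, -1])
        cen_m = np.array([20.0, 32.0, 42.0, 52.0, 62.0])
        main = bank_profile("E20", amps_m, cen_m, sig_m)
        fit = fit_combined(base, main)
        assert fit.sse == pytest.approx(0.0, abs=1e-8)
        i0 = int(np.argmin(np.abs(fit.centers - 20.0)))
        assert fit.widths[i0] == pytest.approx(7.0, abs=0.1)
        others = np.delete(fit.centers, i0)
        assert np.allclose(others, [32.0, 42.0, 52.0, 62.0], atol=0.1)

    def test_null_truth_gives_zero_deltas(self):
        base = self.base_bank()
        sig = np.full(5, 10.0)
        main = bank_profile("E20", -30.0 / (sig * np.sqrt(np.pi)),
                            MAIN_CENTERS["E20"], sig)
        fit = fit_combined(base, main)
        i0 = int(np.argmin(np.abs(fit.centers - 20.0)))
        assert fit.widths[i0] == pytest.approx(10.0, abs=0.2)
        assert np.allclose(np.delete(fit.centers, i0), [30, 40, 50, 60],
                           atol=0.2)

    def test_combined_nests_both_pure_models(self, rng):
        base = self.base_bank()
        sig = np.full(5, 11.0)
        main = bank_profile("E20", -28.0 / (sig * np.sqrt(np.pi)),
                            MAIN_CENTERS["E20"] + 1.0, sig)
        main.values = main.values + 0.1 * rng.standard_normal(len(main.grid))
        sse_combined = fit_combined(base, main).sse
        sse_sharp = fit_sharpening(main).sse
        sse_shift = fit_shift(main).sse
        assert sse_combined <= min(sse_sharp, sse_shift) * 1.01 + 1e-9


class TestGridSearchOracle:
    def test_two_channel_sharpening_matches_exhaustive_search(self):
        """On an 11-point grid with two channels, the multi-start optimizer
        attains the SSE of an exhaustive width grid search (energy profiled
        in closed form) within 1% relative."""
        grid = np.arange(0.0, 10.5, 1.0)
        truth_s = np.array([2.3, 4.1])
        centers = np.array([3.0, 7.0])
        energy = -5.0
        y = channel_sum(grid, energy / (truth_s * np.sqrt(np.pi)), centers,
                        truth_s) + 0.05 * np.sin(grid)

        def sse_at(s1, s2):
            s = np.array([s1, s2])
            b = (np.exp(-((grid[:, None] - centers[None, :]) ** 2) / s ** 2)
                 / (s * np.sqrt(np.pi))).sum(axis=1)
            e = float(b @ y) / float(b @ b)
            return float(np.sum((e * b - y) ** 2))

        widths = np.arange(0.25, 12.01, 0.25)
        best_grid = min(sse_at(a, b) for a, b in
                        itertools.product(widths, widths))

        prof = PopulationProfile(grid, y, "baseline", "B20")
        fit = fit_sharpening(prof, n_starts=12, seed=0, centers=centers)
        assert fit.sse <= best_grid * 1.01


class TestGenerativeTruthProperties:
    def _noisy(self, y, rng):
        return y + 0.05 * rng.standard_normal(len(y))

    def test_sharpening_truth_cohort_shows_sign_pattern(self):
        """Profiles generated from a sharpened expected channel (sigma 10 ->
        6 under equal energy) yield, across a simulated cohort, amplitude
        change > 0 and width change < 0 at the expected channel."""
        rng = np.random.default_rng(0)
        gb, gm = np.arange(15.0, 76.0), np.arange(15.0, 66.0)
        d_amp, d_wid = [], []
        for _ in range(8):
            sig_b = np.full(6, 10.0)
            yb = self._noisy(channel_sum(gb, -30.0 / (sig_b * np.sqrt(np.pi)),
                                         BASELINE_CENTERS, sig_b), rng)
            fb = fit_sharpening(PopulationProfile(gb, yb, "baseline", "B20"))
            sig_m = np.array([6.0, 10.0, 10.0, 10.0, 10.0])
            ym = self._noisy(channel_sum(gm, -30.0 / (sig_m * np.sqrt(np.pi)),
                                         MAIN_CENTERS["E20"], sig_m), rng)
            fm = fit_sharpening(PopulationProfile(gm, ym, "main", "E20"))
            chg = channel_changes(fb, fm)
            d_amp.append(chg.delta_amplitude)
            d_wid.append(chg.delta_width)
        assert np.mean(d_amp) > 0
        assert np.mean(d_wid) < 0

    def test_models_prefer_their_own_generative_truth(self):
        """Sharpening-truth profiles are better fit (lower RMSD) by the
        sharpening model and shift-truth profiles by the shift model, on
        average over simulated cohorts."""
        rng = np.random.default_rng(1)
        gm = np.arange(15.0, 66.0)
        adv_sharp, adv_shift = [], []
        for _ in range(6):
            sig = np.array([6.0, 10.0, 10.0, 10.0, 10.0])
            y = self._noisy(channel_sum(gm, -30.0 / (sig * np.sqrt(np.pi)),
                                        MAIN_CENTERS["E20"], sig), rng)
            prof = PopulationProfile(gm, y, "main", "E20")
            adv_sharp.append(fit_shift(prof).rmsd - fit_sharpening(prof).rmsd)
            cen = MAIN_CENTERS["E20"].astype(float).copy()
            cen[1:] -= 2.5
            y2 = self._noisy(channel_sum(gm, np.full(5, -1.7), cen,
                                         np.full(5, 10.0)), rng)
            prof2 = PopulationProfile(gm, y2, "main", "E20")
            adv_shift.append(fit_sharpening(prof2).rmsd - fit_shift(prof2).rmsd)
        assert np.mean(adv_sharp) > 0
        assert np.mean(adv_shift) > 0


class TestChannelChanges:
    def mk_fit(self, kind, condition, centers, widths, amps):
        from expectprofile.channels import ChannelFit
        return ChannelFit(kind, condition, np.asarray(centers, float),
                          np.asarray(widths, float), np.asarray(amps, float),
                          None, 0.0, 0.0, 1.0)

    def test_identical_banks_give_zero_deltas(self):
        b = self.mk_fit("shift", "B20", BASELINE_CENTERS, np.full(6, 10.0),
                        np.full(6, -1.0))
        e = self.mk_fit("shift", "E20", MAIN_CENTERS["E20"], np.full(5, 10.0),
                        np.full(5, -1.0))
        chg = channel_changes(b, e)
        assert chg.delta_amplitude == 0.0
        assert chg.delta_width == 0.0
        assert np.allclose(chg.delta_location, 0.0)

    def test_attraction_toward_expected_is_positive(self):
        b = self.mk_fit("shift", "B20", BASELINE_CENTERS, np.full(6, 10.0),
                        np.full(6, -1.0))
        shifted = MAIN_CENTERS["E20"].astype(float).copy()
        shifted[1:] -= 1.5  # unexpected channels move toward 20 deg
        e = self.mk_fit("shift", "E20", shifted, np.full(5, 10.0),
                        np.full(5, -1.0))
        chg = channel_changes(b, e)
        assert chg.expectward_shift == pytest.approx(1.5)

    def test_mean_shift_formula(self):
        assert mean_shift(1.0, -0.5) == pytest.approx(0.75)
        assert mean_shift(0.0, 0.0) == 0.0

    def test_mismatched_phases_rejected(self):
        b = self.mk_fit("shift", "B20", BASELINE_CENTERS, np.full(6, 10.0),
                        np.full(6, -1.0))
        with pytest.raises(ValueError):
            channel_changes(b, b)
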