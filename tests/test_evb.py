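"""EVB engine: sampler, FEP estimator, profiles, Marcus oracles, calibration."""

import math

import numpy as np
import pytest
from scipy import stats

from coldkin import evb
from coldkin.thermokinetics import R_KCAL, fit_arrhenius


def _sem(values):
    a = np.asarray(values, float)
    return a.std(ddof=1) / math.sqrt(a.size)


class TestGroundState:
    def test_uncoupled_limit_is_min(self):
        assert evb.ground_state_energy(3.0, 7.0, 0.0) == 3.0
        assert evb.ground_state_energy(7.0, 3.0, 0.0) == 3.0

    def test_resonance_point(self):
        assert evb.ground_state_energy(5.0, 5.0, 2.5) == pytest.approx(2.5)

    def test_hand_arithmetic_example(self):
        # 5 - sqrt(136)/2
        assert evb.ground_state_energy(0.0, 10.0, 3.0) == pytest.approx(
            5.0 - 0.5 * math.sqrt(136.0), abs=1e-10
        )


class TestSampler:
    def test_equipartition_in_a_harmonic_well(self):
        well = evb.EVBSystem(
            evb.HarmonicSurface(50.0, 0.3), evb.HarmonicSurface(50.0, 0.3), 0.0
        )
        proto = evb.MappingProtocol(steps_per_window=100_000, equilibration_steps=2000)
        w = evb.sample_window(well, 0.5, 300.0, proto, seed=11)
        RT = R_KCAL * 300.0
        var = w.x.var()
        # sem of the variance of n effective samples; thin for correlation
        n_eff = w.x.size / 20
        assert var == pytest.approx(RT / 50.0, abs=3 * (RT / 50.0) * math.sqrt(2 / n_eff))
        assert 0.2 < w.acceptance < 0.6

    def test_endpoint_window_matches_state1_distribution(self):
        sys_ = evb.EVBSystem(
            evb.HarmonicSurface(50.0, 0.0), evb.HarmonicSurface(50.0, 1.0), 0.0
        )
        proto = evb.MappingProtocol(steps_per_window=100_000, equilibration_steps=2000)
        w = evb.sample_window(sys_, 0.0, 298.15, proto, seed=5)
        sd = math.sqrt(R_KCAL * 298.15 / 50.0)
        thin = w.x[::20]
        p = stats.kstest(thin, "norm", args=(0.0, sd)).pvalue
        assert p > 0.01

    def test_midpoint_window_sits_midway_between_equal_wells(self):
        sys_ = evb.EVBSystem(
            evb.HarmonicSurface(50.0, 0.0), evb.HarmonicSurface(50.0, 1.0), 0.0
        )
        proto = evb.MappingProtocol(steps_per_window=50_000, equilibration_steps=2000)
        w = evb.sample_window(sys_, 0.5, 298.15, proto, seed=6)
        sd = math.sqrt(R_KCAL * 298.15 / 50.0)
        assert w.x.mean() == pytest.approx(0.5, abs=3 * sd / math.sqrt(w.x.size / 20))

    def test_invalid_inputs_rejected(self):
        sys_ = evb.EVBSystem(
            evb.HarmonicSurface(50.0, 0.0), evb.HarmonicSurface(50.0, 1.0), 0.0
        )
        proto = evb.MappingProtocol(steps_per_window=10, equilibration_steps=10)
        with pytest.raises(ValueError):
            evb.sample_window(sys_, 1.5, 300.0, proto, 0)
        with pytest.raises(ValueError):
            evb.sample_window(sys_, 0.5, -10.0, proto, 0)


class TestFEP:
    def test_identical_surfaces_give_zero_increments(self):
        sys_ = evb.EVBSystem(
            evb.HarmonicSurface(30.0, 0.0), evb.HarmonicSurface(30.0, 0.0), 0.0
        )
        proto = evb.MappingProtocol(
            n_windows=5, steps_per_window=2000, equilibration_steps=200
        )
        fep = evb.run_fep(sys_, 300.0, proto, 3)
        assert np.allclose(fep.G_lambda, 0.0, atol=1e-12)

    def test_constant_shift_recovered_exactly(self):
        # V2 = V1 + c: the perturbation is deterministic, so EXP is exact
        c = 2.75
        sys_ = evb.EVBSystem(
            evb.HarmonicSurface(30.0, 0.0), evb.HarmonicSurface(30.0, 0.0, c), 0.0
        )
        proto = evb.MappingProtocol(
            n_windows=2, steps_per_window=2000, equilibration_steps=200
        )
        fep = evb.run_fep(sys_, 300.0, proto, 4)
        assert fep.G_lambda[-1] - fep.G_lambda[0] == pytest.approx(c, abs=1e-10)

    def test_total_free_energy_converged_in_window_count(self, marcus_system):
        totals = {}
        for n_win in (11, 51):
            vals = []
            for seed in range(3):
                proto = evb.MappingProtocol(
                    n_windows=n_win, steps_per_window=3000, equilibration_steps=400
                )
                fep = evb.run_fep(marcus_system, 298.15, proto, 100 + seed)
                vals.append(fep.G_lambda[-1] - fep.G_lambda[0])
            totals[n_win] = vals
        diff = abs(np.mean(totals[11]) - np.mean(totals[51]))
        comb = math.hypot(_sem(totals[11]), _sem(totals[51]))
        assert diff < 3 * comb


class TestMarcusSuite:
    LAMBDA = 0.5 * 40.0 * 1.0**2  # half k d^2 = 20 kcal/mol

    def test_quadrature_matches_closed_forms(self, marcus_system):
        prof, dia = evb.quadrature_profiles(marcus_system, 298.15, bin_width=0.5)
        assert dia.lambda_R == pytest.approx(self.LAMBDA, rel=0.01)
        assert dia.lambda_I == pytest.approx(self.LAMBDA, rel=0.01)
        assert prof.dG0 == pytest.approx(0.0, abs=0.02)
        # Marcus barrier on the diabatic surface at the crossing (gap = 0)
        assert dia.height_at(0.0, "R") == pytest.approx(self.LAMBDA / 4, abs=0.05)

    def test_sampled_reorganization_energy(self, marcus_replicates):
        lam = [d.lambda_R for _, _, d in marcus_replicates]
        assert abs(np.mean(lam) - self.LAMBDA) < 3 * _sem(lam)

    def test_sampled_marcus_barrier(self, marcus_replicates):
        # dG0 ~ 0 so the diabatic crossing height is lambda/4
        heights = [d.height_at(0.0, "R") for _, _, d in marcus_replicates]
        assert abs(np.mean(heights) - self.LAMBDA / 4) < 3 * _sem(heights)
        dg0 = [p.dG0 for _, p, _ in marcus_replicates]
        assert abs(np.mean(dg0)) < 3 * _sem(dg0)

    def test_diabatic_profiles_are_parabolas(self, marcus_system):
        _, dia = evb.quadrature_profiles(marcus_system, 298.15, bin_width=0.5)
        ok = np.isfinite(dia.dG_R) & (dia.dG_R - np.nanmin(dia.dG_R) < 30.0)
        coeff = np.polyfit(dia.centers[ok], dia.dG_R[ok], 2)
        # curvature of (de + lambda)^2 / (4 lambda)
        assert coeff[0] == pytest.approx(1.0 / (4 * self.LAMBDA), rel=0.05)

    def test_reactant_minimum_moves_inward_as_lambda_shrinks(self):
        # smaller reorganization -> reactant gap minimum closer to zero
        positions = []
        for k in (60.0, 30.0):
            sys_ = evb.EVBSystem(
                evb.HarmonicSurface(k, 0.0), evb.HarmonicSurface(k, 1.0), 0.0
            )
            prof, _ = evb.quadrature_profiles(sys_, 298.15, bin_width=0.5)
            positions.append(abs(prof.reactant_pos))
        assert positions[1] < positions[0]

    def test_coupling_depresses_the_crossing_by_h12(self, coupled_system):
        prof, dia = evb.quadrature_profiles(coupled_system, 298.15, bin_width=0.5)
        # adiabatic barrier ~ diabatic crossing minus H12 (cusp-binning tolerance)
        assert prof.barrier == pytest.approx(
            dia.height_at(0.0, "R") - coupled_system.H12, abs=0.4
        )


class TestProfiles:
    def test_sampling_agrees_with_quadrature(self, marcus_replicates, marcus_system):
        quad, _ = evb.quadrature_profiles(marcus_system, 298.15, bin_width=0.5)
        barriers = [p.barrier for _, p, _ in marcus_replicates]
        assert abs(np.mean(barriers) - quad.barrier) < 3 * _sem(barriers)

    def test_invariance_to_bin_halving(self, marcus_replicates):
        coarse, fine = [], []
        for fep, _, _ in marcus_replicates[:4]:
            p1, _ = evb.build_profiles(
                fep.windows, 298.15, bin_width=0.5, G_lambda=fep.G_lambda
            )
            p2, _ = evb.build_profiles(
                fep.windows, 298.15, bin_width=0.25, G_lambda=fep.G_lambda
            )
            coarse.append(p1.barrier)
            fine.append(p2.barrier)
        diff = abs(np.mean(coarse) - np.mean(fine))
        assert diff < 3 * math.hypot(_sem(coarse), _sem(fine)) + 0.05

    def test_merge_modes_agree_within_noise(self, marcus_replicates):
        fep, prof, _ = marcus_replicates[0]
        pw, _ = evb.build_profiles(
            fep.windows, 298.15, bin_width=0.5, G_lambda=fep.G_lambda, merge="weighted"
        )
        assert pw.barrier == pytest.approx(prof.barrier, abs=0.15)

    def test_endpoint_consistency(self, marcus_replicates):
        # dG0 from the profile equals the FEP endpoint difference for
        # symmetric wells (equal binning entropy on both sides)
        diffs = []
        for fep, prof, _ in marcus_replicates:
            diffs.append(prof.dG0 - (fep.G_lambda[-1] - fep.G_lambda[0]))
        assert abs(np.mean(diffs)) < 3 * _sem(diffs) + 0.1

    def test_missing_well_raises(self):
        well = evb.EVBSystem(
            evb.HarmonicSurface(50.0, 0.0), evb.HarmonicSurface(50.0, 0.0, 30.0), 0.0
        )
        with pytest.raises(evb.ProfileError):
            evb.quadrature_profiles(well, 298.15, bin_width=0.5)


class TestCalibration:
    def test_quadrature_calibration_hits_targets_exactly(self):
        ref = evb.toy_reference_system()
        cal = evb.calibrate(ref, *evb.WATER_REFERENCE_TARGETS, tol=1e-4)
        assert cal.converged
        assert cal.barrier == pytest.approx(23.9, abs=1e-3)
        assert cal.dG0 == pytest.approx(-1.1, abs=1e-3)

    def test_already_matching_system_is_a_fixed_point(self):
        ref = evb.toy_reference_system()
        cal = evb.calibrate(ref, *evb.WATER_REFERENCE_TARGETS, tol=1e-4)
        again = evb.calibrate(cal.system, *evb.WATER_REFERENCE_TARGETS, tol=1e-4)
        assert again.alpha == pytest.approx(cal.alpha, abs=1e-3)
        assert again.H12 == pytest.approx(cal.H12, abs=1e-3)
        assert again.n_iter == 1

    def test_infeasible_targets_rejected(self):
        ref = evb.toy_reference_system()
        with pytest.raises(ValueError):
            evb.calibrate(ref, -5.0, -1.0)


class TestTemperatureScan:
    def test_default_ladder_is_eight_temperatures(self):
        temps = evb.DEFAULT_SCAN_TEMPS
        assert len(temps) == 8
        assert temps[0] == 278.0 and temps[-1] == 313.0
        assert np.allclose(np.diff(temps), 5.0)

    def test_temperature_independent_system_has_zero_entropy(self, fast_protocol):
        sys_ = evb.EVBSystem(
            evb.HarmonicSurface(40.0, 0.0), evb.HarmonicSurface(40.0, 1.0), 1.0
        )
        scan = evb.temperature_scan(
            sys_, temps=[278.0, 288.0, 298.0, 308.0], protocol=fast_protocol, seed=7
        )
        fit = fit_arrhenius(scan.series)
        assert abs(fit.params.dS) < 2 * fit.dS_se + 1e-4

    def test_sem_scales_with_replicate_count(self, fast_protocol):
        sys_ = evb.EVBSystem(
            evb.HarmonicSurface(40.0, 0.0), evb.HarmonicSurface(40.0, 1.0), 1.0
        )
        s_small = evb.temperature_scan(
            sys_, temps=[288.0, 298.0], protocol=fast_protocol, n_replicas=10, seed=3
        )
        s_large = evb.temperature_scan(
            sys_, temps=[288.0, 298.0], protocol=fast_protocol, n_replicas=40, seed=4
        )
        pooled = lambda s: math.sqrt(np.mean(np.asarray(s.series.sem) ** 2))
        ratio = pooled(s_small) / pooled(s_large)
        assert 1.2 < ratio < 3.3  # expected 2, wide band for sem-of-sem noise
        for T, arr in s_small.replicate_barriers.items():
            i = int(np.flatnonzero(s_small.series.T == T)[0])
            assert s_small.series.sem[i] == pytest.approx(
                arr.std(ddof=1) / math.sqrt(arr.size)
            )

    def test_too_few_replicas_rejected(self, fast_protocol):
        sys_ = evb.EVBSystem(
            evb.HarmonicSurface(40.0, 0.0), evb.HarmonicSurface(40.0, 1.0), 1.0
        )
        with pytest.raises(ValueError):
            evb.temperature_scan(sys_, temps=[288.0, 298.0], protocol=fast_protocol, n_replicas=1)
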