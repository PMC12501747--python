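"""RADISH pipeline: smoothing, maxima, case enumeration, selection, refinement."""

import math

import numpy as np
import pytest

from radish import (
    Candidate,
    MaximaSet,
    RadishOptions,
    WasabiParams,
    ZSpectrum,
    b1_to_peak_distance,
    build_template,
    enumerate_candidates,
    find_local_maxima,
    fit_volume,
    fit_voxel,
    refine_b1,
    select_best,
    smooth_spectrum,
    wasabi_forward,
)
from radish.core import _score_candidate

from conftest import make_spectrum


def independent_l1_derivative_score(y, template):
    """Brute-force oracle for the objective: explicit central/one-sided
    differences written without np.gradient."""
    y = np.asarray(y, float)
    t = np.asarray(template, float)

    def deriv(v):
        d = np.empty_like(v)
        d[0] = v[1] - v[0]
        d[-1] = v[-1] - v[-2]
        d[1:-1] = (v[2:] - v[:-2]) / 2.0
        return d

    return float(np.abs(deriv(y) - deriv(t)).sum())


class TestSmoothing:
    def test_noiseless_samples_reproduced_within_tolerance(self, ctx7t, offsets49):
        y = make_spectrum(ctx7t, offsets49)
        curve = smooth_spectrum(y, epsilon=3e-4)
        assert np.max(np.abs(curve(y.offsets) - y.values)) <= math.sqrt(3e-4)

    def test_constant_spectrum_yields_constant_curve_and_no_maxima(self, offsets49):
        y = ZSpectrum(offsets=offsets49, values=np.full(49, 0.8))
        curve = smooth_spectrum(y)
        np.testing.assert_allclose(curve(offsets49), 0.8, atol=1e-9)
        assert len(find_local_maxima(curve, (-1.5, 1.5))) == 0

    def test_non_finite_input_rejected(self, offsets49):
        vals = np.ones(49)
        vals[3] = np.nan
        with pytest.raises(ValueError):
            smooth_spectrum(ZSpectrum(offsets=offsets49, values=vals))

    def test_noisy_maxima_stay_near_noiseless_maxima(self, ctx7t, offsets49):
        clean = make_spectrum(ctx7t, offsets49)
        reference = find_local_maxima(smooth_spectrum(clean), (-1.5, 1.5)).locations
        flanking = reference[-2:]  # the pair flanking the water shift
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            noisy = ZSpectrum(
                offsets=offsets49,
                values=np.abs(clean.values + rng.normal(0, 0.02, 49)),
            )
            locs = find_local_maxima(smooth_spectrum(noisy), (-1.5, 1.5)).locations
            if locs.size and all(np.min(np.abs(locs - m)) < 0.05 for m in flanking):
                hits += 1
        assert hits >= 95


class TestMaximaDetection:
    def test_fig1_flanking_pair_matches_analytic_distance(self, ctx7t, fig1_spectrum):
        locs = find_local_maxima(smooth_spectrum(fig1_spectrum), (-1.5, 1.5)).locations
        expected_x = b1_to_peak_distance(3.7, ctx7t).x
        flank_left = locs[np.argmin(np.abs(locs - (0.3 - expected_x / 2)))]
        flank_right = locs[np.argmin(np.abs(locs - (0.3 + expected_x / 2)))]
        assert flank_right - flank_left == pytest.approx(expected_x, abs=2e-3)
        assert (flank_left + flank_right) / 2 == pytest.approx(0.3, abs=5e-3)

    def test_monotone_curve_has_no_maxima(self):
        assert len(find_local_maxima(lambda x: np.asarray(x) * 0.1, (-1.5, 1.5))) == 0

    def test_plateau_reports_single_leftmost_maximum(self):
        def plateau(x):
            x = np.asarray(x, float)
            return np.where(np.abs(x) <= 0.5, 1.0, 1.0 - (np.abs(x) - 0.5) ** 2)

        locs = find_local_maxima(plateau, (-1.5, 1.5), grid_resolution=1e-3).locations
        assert locs.size == 1
        assert locs[0] == pytest.approx(-0.5, abs=2e-3)

    def test_boundary_points_are_never_maxima(self):
        locs = find_local_maxima(lambda x: -np.asarray(x) ** 2, (-1.5, 1.5)).locations
        assert np.all(np.abs(locs) < 1.4)


class TestCaseEnumeration:
    def test_two_maxima_give_at_most_one_candidate(self, ctx7t):
        maxima = MaximaSet(locations=np.array([-0.4, 0.4]))
        cands = enumerate_candidates(maxima, ctx7t)
        assert len(cands) <= 1 and all(c.case_id == 1 for c in cands)

    def test_seven_maxima_bounded_by_three_m_minus_seven(self, ctx7t):
        # wide bounds so only geometry limits the count: 3m-7 = 14 for m=7
        opts = RadishOptions(b1_range=(0.0, 1e4), dw_range=(-10.0, 10.0))
        ctx = type(ctx7t)(omega0=ctx7t.omega0, tp=1e-4, b1_nominal=3.7)
        maxima = MaximaSet(locations=np.linspace(-0.6, 0.6, 7))
        assert len(enumerate_candidates(maxima, ctx, opts)) == 14

    def test_fig1_contains_true_case1_candidate(self, ctx7t, fig1_spectrum):
        locs = find_local_maxima(smooth_spectrum(fig1_spectrum), (-1.5, 1.5))
        cands = enumerate_candidates(locs, ctx7t)
        best = min(
            cands, key=lambda c: abs(c.delta_omega - 0.3) + abs(c.b1 - 3.7)
        )
        assert best.case_id == 1
        assert best.delta_omega == pytest.approx(0.3, abs=0.01)
        assert best.b1 == pytest.approx(3.7, abs=0.1)

    def test_out_of_bounds_candidates_dropped(self, ctx7t):
        maxima = MaximaSet(locations=np.array([0.5, 1.4]))  # midpoint 0.95 > 0.6
        assert enumerate_candidates(maxima, ctx7t) == []


class TestSelection:
    def test_single_candidate_returned(self, ctx7t, fig1_spectrum):
        cand = Candidate(case_id=1, delta_omega=0.3, x=0.827, d=1.0, b1=3.7, anchor_index=0)
        est = select_best(fig1_spectrum, [cand], ctx7t)
        assert est.valid and est.delta_omega == 0.3

    def test_empty_candidates_flagged(self, ctx7t, fig1_spectrum):
        est = select_best(fig1_spectrum, [], ctx7t)
        assert not est.valid and est.failure_reason == "no-candidate-in-bounds"

    def test_true_case_beats_distractor(self, ctx7t, fig1_spectrum):
        good = Candidate(case_id=1, delta_omega=0.3, x=0.827, d=1.0, b1=3.7, anchor_index=1)
        bad = Candidate(case_id=2, delta_omega=-0.1, x=1.0, d=1.5, b1=3.17, anchor_index=0)
        est = select_best(fig1_spectrum, [good, bad], ctx7t)
        assert est.case_id == 1 and est.delta_omega == 0.3

    def test_exact_tie_broken_by_lower_case_id(self, ctx7t, fig1_spectrum):
        a = Candidate(case_id=2, delta_omega=0.3, x=0.827, d=1.0, b1=3.7, anchor_index=0)
        b = Candidate(case_id=1, delta_omega=0.3, x=0.827, d=1.0, b1=3.7, anchor_index=1)
        assert select_best(fig1_spectrum, [a, b], ctx7t).case_id == 1

    def test_matches_bruteforce_argmin_on_noisy_spectra(self, ctx7t, offsets49):
        rng = np.random.default_rng(11)
        checked = 0
        for seed in range(100):
            dw = rng.uniform(-0.4, 0.4)
            b1 = rng.uniform(1.5, 4.4)
            y = make_spectrum(ctx7t, offsets49, dw, b1, noise_sigma=0.02, seed=seed)
            locs = find_local_maxima(smooth_spectrum(y), (-1.5, 1.5))
            cands = enumerate_candidates(locs, ctx7t)
            if not cands:
                continue
            scores = [
                independent_l1_derivative_score(
                    y.values,
                    build_template(
                        WasabiParams(c=1, d=c.d, delta_omega=c.delta_omega, b1=c.b1),
                        y.offsets,
                        ctx7t,
                    ),
                )
                for c in cands
            ]
            brute = cands[int(np.argmin(scores))]
            est = select_best(y, cands, ctx7t)
            assert est.delta_omega == brute.delta_omega and est.b1 == brute.b1
            checked += 1
        assert checked >= 90


class TestRefinement:
    def test_recovers_power_beyond_coarse_sampling(self, ctx7t, offsets49):
        y = make_spectrum(ctx7t, offsets49, delta_omega=0.0, b1=2.0)
        est = fit_voxel(y, ctx7t)
        assert est.refined
        assert est.b1 == pytest.approx(2.0, abs=0.02)

    def test_exact_template_is_fixed_point(self, ctx7t, fig1_spectrum):
        cands = enumerate_candidates(
            find_local_maxima(smooth_spectrum(fig1_spectrum), (-1.5, 1.5)), ctx7t
        )
        est = select_best(fig1_spectrum, cands, ctx7t)
        refined = refine_b1(fig1_spectrum, est, est.peak_distance, ctx7t)
        assert refined.objective_score <= est.objective_score

    def test_degenerate_interval_returns_unchanged(self, ctx7t, fig1_spectrum):
        opts = RadishOptions(b1_range=(0.0, 0.2))
        cand = Candidate(case_id=1, delta_omega=0.3, x=0.827, d=1.0, b1=0.1, anchor_index=0)
        est = select_best(fig1_spectrum, [cand], ctx7t)
        refined = refine_b1(fig1_spectrum, est, cand.x, ctx7t, opts)
        assert not refined.refined
        assert refined.b1 == est.b1

    def test_small_distance_clips_interval_without_error(self, ctx7t, offsets25):
        # x - l2*step < 0 for a tight pair on a coarse grid
        y = make_spectrum(ctx7t, offsets25, delta_omega=0.0, b1=4.6)
        est = fit_voxel(y, ctx7t)
        assert est.valid

    def test_never_worsens_objective(self, ctx7t, offsets49):
        rng = np.random.default_rng(5)
        for seed in range(20):
            y = make_spectrum(
                ctx7t,
                offsets49,
                rng.uniform(-0.4, 0.4),
                rng.uniform(1.5, 4.4),
                noise_sigma=0.02,
                seed=seed,
            )
            locs = find_local_maxima(smooth_spectrum(y), (-1.5, 1.5))
            cands = enumerate_candidates(locs, ctx7t)
            if not cands:
                continue
            est = select_best(y, cands, ctx7t)
            refined = refine_b1(y, est, est.peak_distance, ctx7t)
            assert refined.objective_score <= est.objective_score


class TestVoxelFit:
    def test_worked_example_recovery(self, ctx7t, fig1_spectrum):
        est = fit_voxel(fig1_spectrum, ctx7t)
        assert est.valid
        assert est.delta_omega == pytest.approx(0.3, abs=0.01)
        assert est.b1 == pytest.approx(3.7, abs=0.05)

    def test_all_zero_spectrum_invalid(self, ctx7t, offsets49):
        est = fit_voxel(ZSpectrum(offsets=offsets49, values=np.zeros(49)), ctx7t)
        assert not est.valid
        assert math.isnan(est.delta_omega) and math.isnan(est.b1)

    def test_downsampled_recovery_holds(self, ctx7t, offsets25):
        est = fit_voxel(make_spectrum(ctx7t, offsets25), ctx7t)
        assert est.valid
        assert est.delta_omega == pytest.approx(0.3, abs=0.02)
        assert est.b1 == pytest.approx(3.7, abs=0.1)

    def test_non_finite_input_flagged(self, ctx7t, offsets49):
        vals = np.ones(49)
        vals[0] = np.inf
        est = fit_voxel(ZSpectrum(offsets=offsets49, values=vals), ctx7t)
        assert not est.valid and est.failure_reason == "non-finite-input"


class TestVolumeFit:
    def _tiny_volume(self, ctx, offsets, shape=(3, 3, 2)):
        rng = np.random.default_rng(9)
        dw = rng.uniform(-0.3, 0.3, shape)
        b1 = rng.uniform(2.0, 4.4, shape)
        m0 = np.full(shape, 500.0)
        vol = np.empty(shape + (offsets.size,))
        for idx in np.ndindex(shape):
            theta = WasabiParams(c=1, d=1, delta_omega=dw[idx], b1=b1[idx])
            vol[idx] = np.abs(wasabi_forward(offsets, theta, ctx)) * m0[idx]
        return vol, m0, dw, b1

    def test_noiseless_recovery_against_truth(self, ctx7t, offsets49):
        vol, m0, dw, b1 = self._tiny_volume(ctx7t, offsets49)
        maps = fit_volume(vol, m0, offsets49, ctx7t)
        assert maps.valid_mask.all()
        assert np.nanmax(np.abs(maps.delta_omega_map - dw)) <= 0.02
        assert np.nanmax(np.abs(maps.b1_map - b1) / b1) <= 0.02
        np.testing.assert_allclose(maps.rb1_map, maps.b1_map / ctx7t.b1_nominal)

    def test_empty_mask_processes_nothing(self, ctx7t, offsets49):
        vol, m0, *_ = self._tiny_volume(ctx7t, offsets49)
        maps = fit_volume(vol, m0, offsets49, ctx7t, mask=np.zeros(m0.shape, bool))
        assert not maps.valid_mask.any()
        assert np.isnan(maps.delta_omega_map).all()

    def test_volume_equals_independent_voxel_fits(self, ctx7t, offsets49):
        # order independence: each voxel's result must equal a standalone fit
        vol, m0, *_ = self._tiny_volume(ctx7t, offsets49)
        maps = fit_volume(vol, m0, offsets49, ctx7t)
        for idx in [(0, 0, 0), (2, 1, 1), (1, 2, 0)]:
            y = ZSpectrum(offsets=offsets49, values=vol[idx] / m0[idx])
            est = fit_voxel(y, ctx7t)
            assert maps.delta_omega_map[idx] == est.delta_omega
            assert maps.b1_map[idx] == est.b1

    def test_shape_mismatch_rejected(self, ctx7t, offsets49):
        vol, m0, *_ = self._tiny_volume(ctx7t, offsets49)
        with pytest.raises(ValueError):
            fit_volume(vol[..., :-1], m0, offsets49, ctx7t)
        with pytest.raises(ValueError):
            fit_volume(vol, m0[:-1], offsets49, ctx7t)

    def test_nonpositive_m0_marked_invalid(self, ctx7t, offsets49):
        vol, m0, *_ = self._tiny_volume(ctx7t, offsets49)
        m0 = m0.copy()
        m0[0, 0, 0] = 0.0
        maps = fit_volume(vol, m0, offsets49, ctx7t, mask=np.ones(m0.shape, bool))
        assert not maps.valid_mask[0, 0, 0]
        assert maps.failure_counts.get("non-positive-m0") == 1
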