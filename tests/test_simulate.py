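"""Generator contracts: ground-truth exactness, determinism, degenerate specs."""

import numpy as np
import pytest

from synaptoquant.em import edge_distance
from synaptoquant.simulate import (
    CohortSpec,
    ReleaseModelSpec,
    StedLayoutSpec,
    generate_axon_profiles,
    generate_frap_trace,
    generate_profile_set,
    generate_sted_fixture,
    simulate_depression_train,
)
from synaptoquant.simulate.trains import pool_fixed_point
from synaptoquant.condensate import line_dispersion
from synaptoquant.geometry import signed_polygon_distance


class TestProfileGenerator:
    def test_degenerate_spec_zero_vesicles(self):
        spec = CohortSpec(n_profiles_per_group=5, mean_docked=0, mean_zone=0, mean_bulk=0, seed=1)
        pset = generate_profile_set(spec)
        assert all(len(p.vesicles) == 0 for p in pset.profiles)

    def test_invalid_spec_names_field(self):
        with pytest.raises(ValueError, match="mean_docked"):
            CohortSpec(mean_docked=-1)
        with pytest.raises(ValueError, match="zone_scale_by_group"):
            CohortSpec(zone_scale_by_group={"KO": 0.0})
        with pytest.raises(ValueError, match="active_zone_length"):
            CohortSpec(active_zone_length=2000.0, membrane_length=1000.0)

    def test_docked_mean_within_three_se(self):
        pset = generate_profile_set(
            CohortSpec(n_profiles_per_group=300, groups=(("WT", "no stim"),), seed=42)
        )
        docked = np.array([r["counts"]["docked"] for r in pset.truth])
        assert abs(docked.mean() - 2.0) < 3 * np.sqrt(2.0 / 300)

    def test_truth_distances_are_exact(self, small_cohort):
        """Sidecar distance equals the measured geometric distance."""
        for p, rec in zip(small_cohort.profiles[:10], small_cohort.truth[:10]):
            az = p.active_zone_polyline()
            for v, vrec in zip(p.vesicles, rec["vesicles"]):
                assert edge_distance(v, az) == pytest.approx(
                    vrec["edge_distance_nm"], abs=1e-6)

    def test_distance_classes_respect_bands(self, small_cohort):
        for rec in small_cohort.truth:
            for v in rec["vesicles"]:
                d = v["edge_distance_nm"]
                if v["class"] == "docked":
                    assert d == 0.0
                elif v["class"] == "replacement":
                    assert 0 < d <= 20
                else:
                    assert 20 < d <= 200

    def test_no_overlapping_vesicles(self, small_cohort):
        for p in small_cohort.profiles:
            c = np.array([v.center for v in p.vesicles])
            if len(c) < 2:
                continue
            d = np.hypot(c[:, None, 0] - c[None, :, 0], c[:, None, 1] - c[None, :, 1])
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 2 * p.vesicles[0].radius - 1e-9

    def test_membrane_is_simple_and_gently_curved(self, small_cohort):
        for p in small_cohort.profiles[:20]:
            p.validate()  # raises on self-intersection
            seg = np.diff(p.membrane, axis=0)
            ang = np.arctan2(seg[:, 1], seg[:, 0])
            assert np.all(np.abs(np.diff(ang)) <= np.deg2rad(10) + 1e-9)

    def test_fixed_seed_reproducible(self):
        a = generate_profile_set(CohortSpec(n_profiles_per_group=5, seed=9))
        b = generate_profile_set(CohortSpec(n_profiles_per_group=5, seed=9))
        for pa, pb in zip(a.profiles, b.profiles):
            np.testing.assert_array_equal(pa.membrane, pb.membrane)
            assert [v.center for v in pa.vesicles] == [v.center for v in pb.vesicles]
        assert a.metadata["rng"] == "numpy PCG64"


class TestStedFixture:
    def test_no_puncta_gives_noise_around_baseline(self):
        fx = generate_sted_fixture(StedLayoutSpec(seed=0, puncta_signed_distances=()))
        assert abs(fx.target.mean() - 2.0) < 0.5  # baseline 2, Poisson noise

    def test_zero_distance_punctum_on_contour(self):
        fx = generate_sted_fixture(StedLayoutSpec(seed=1, puncta_signed_distances=(0.0,)))
        d = signed_polygon_distance(fx.puncta_xy[0], fx.halfmax_contour)
        assert abs(d) < 0.5  # px

    def test_realized_distances_match_requested(self):
        req = (-150.0, -40.0, 80.0, 240.0)
        fx = generate_sted_fixture(StedLayoutSpec(seed=2, puncta_signed_distances=req))
        np.testing.assert_allclose(fx.puncta_signed_distances, req, atol=0.5 * fx.pixel_size)

    def test_disc_halfmax_radius_matches_radial_oracle(self):
        """Contour radius of the blurred disc matches 1-D radial brute force."""
        spec = StedLayoutSpec(seed=0, boundary_shape=("disc", 20.0), psf_sigma=2.0,
                              boundary_peak=200.0, roi_size=64)
        fx = generate_sted_fixture(spec)
        contour = fx.halfmax_contour
        centroid = contour[:-1].mean(axis=0)
        r_measured = np.hypot(*(contour - centroid).T).mean()
        # oracle: dense 2-D grid convolution of the disc with the Gaussian,
        # radial profile -> half-max crossing
        n = 1024
        scale = 8  # subpixel resolution
        ax = (np.arange(n) - n / 2) / scale
        xx, yy = np.meshgrid(ax, ax)
        disc = (xx**2 + yy**2 <= 20.0**2).astype(float)
        from scipy.ndimage import gaussian_filter

        blurred = gaussian_filter(disc, 2.0 * scale)
        prof = blurred[n // 2, n // 2:]
        r_ax = ax[n // 2:]
        half = prof.max() / 2
        i = np.argmax(prof < half)
        # linear interpolation of the crossing
        r_oracle = r_ax[i - 1] + (prof[i - 1] - half) / (prof[i - 1] - prof[i]) * (r_ax[i] - r_ax[i - 1])
        assert abs(r_measured - r_oracle) < 0.5

    def test_out_of_roi_placement_errors(self):
        with pytest.raises(ValueError):
            generate_sted_fixture(StedLayoutSpec(seed=0, puncta_signed_distances=(5000.0,)))

    def test_roi_size_invariant(self):
        with pytest.raises(ValueError, match="roi_size"):
            StedLayoutSpec(roi_size=20)


class TestFrapGenerator:
    def test_closed_form_at_tau(self):
        tr = generate_frap_trace(tau=2.0, plateau=0.8, noise_sd=0.0, frame_interval=0.5,
                                 n_frames=50, bleach_frame=3)
        i_tau = 3 + 4  # t = 2.0 s after bleach
        assert tr.intensities[i_tau] == pytest.approx(0.8 * (1 - np.exp(-1)))

    def test_asymptote_reaches_plateau(self):
        tr = generate_frap_trace(tau=0.5, plateau=0.7, noise_sd=0.0, n_frames=200)
        assert tr.intensities[-1] == pytest.approx(0.7, abs=1e-6)

    def test_prebleach_at_one(self):
        tr = generate_frap_trace(tau=1.0, plateau=0.5, noise_sd=0.0, bleach_frame=3)
        np.testing.assert_array_equal(tr.intensities[:3], 1.0)
        assert tr.intensities[3] == 0.0

    def test_noise_sd_calibrated(self):
        """Per-frame sample SD across replicates within 10% of the requested SD."""
        traces = np.array([
            generate_frap_trace(2.0, 0.8, noise_sd=0.05, n_frames=30, seed=s).intensities
            for s in range(1000)
        ])
        sd = traces.std(axis=0, ddof=1)
        assert np.all(np.abs(sd - 0.05) < 0.005)

    def test_bleach_frame_validation(self):
        with pytest.raises(ValueError, match="bleach_frame"):
            generate_frap_trace(1.0, 0.5, bleach_frame=100, n_frames=100)


class TestAxonProfiles:
    def test_diffuse_zero_noise_constant(self):
        prof = generate_axon_profiles("diffuse", 1, seed=0)[0]
        assert np.ptp(prof.intensities) == 0

    def test_empty_set(self):
        assert generate_axon_profiles("punctate", 0, seed=0) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matched_intensity_and_dispersion_order(self, seed):
        """Total intensity matched within 1%; punctate strictly more dispersed."""
        punc = generate_axon_profiles("punctate", 3, seed=seed, noise_sd=1.0)
        diff = generate_axon_profiles("diffuse", 3, seed=seed, noise_sd=1.0)
        for p, d in zip(punc, diff):
            assert abs(p.intensities.sum() - d.intensities.sum()) / p.intensities.sum() < 0.01
            assert line_dispersion(p) > line_dispersion(d)


class TestDepressionTrain:
    def test_full_depletion(self):
        rec = simulate_depression_train(ReleaseModelSpec(N=50, q=2, p=1.0, k_rep=0.0, n_pulses=5))
        assert rec.amplitudes[0] == pytest.approx(100.0)
        np.testing.assert_allclose(rec.amplitudes[1:], 0.0, atol=1e-12)

    def test_geometric_closed_form(self):
        rec = simulate_depression_train(ReleaseModelSpec(N=100, q=1, p=0.5, k_rep=0.0, n_pulses=10))
        i = np.arange(10)
        np.testing.assert_allclose(rec.amplitudes, 100 * 0.5 * 0.5**i, rtol=1e-12)

    def test_converges_to_fixed_point(self):
        """Long-train amplitudes converge to the update map's fixed point."""
        spec = ReleaseModelSpec(N=100, q=1, p=0.3, k_rep=5.0, n_pulses=500, frequency=20.0)
        rec = simulate_depression_train(spec)
        # independent oracle: iterate the recurrence 10^4 steps
        r = 1 - np.exp(-spec.k_rep / spec.frequency)
        P = spec.N
        for _ in range(10_000):
            s = P * (1 - spec.p)
            P = s + (spec.N - s) * r
        assert rec.amplitudes[-1] == pytest.approx(spec.q * spec.p * P, rel=1e-9)
        assert pool_fixed_point(spec) == pytest.approx(P, rel=1e-9)

    def test_invalid_spec(self):
        with pytest.raises(ValueError, match="p must be"):
            ReleaseModelSpec(p=0.0)
        with pytest.raises(ValueError, match="k_rep"):
            ReleaseModelSpec(k_rep=-1.0)
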