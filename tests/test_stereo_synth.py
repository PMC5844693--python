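import numpy as np
import pytest
from scipy import optimize, special

from tilt3d import image_cues, stereo_synth, surface_truth
from tilt3d.circstats import circ_error, circ_mean_var
from tilt3d.stereo_synth import (
    SamplingConstraints,
    SceneSpec,
    SyntheticObserverSpec,
    UnknownTextureError,
    ViewingGeometry,
    make_texture,
    perturb_surface,
    render_stereo,
    sample_stimuli,
    sample_tilt_prior,
    simulate_cue_samples,
    synthetic_observer,
)

from conftest import center_tilt_slant

PPD = 1920.0 / 36.0


def radial_amplitude_profile(tex, ppd):
    """Radially averaged amplitude spectrum; returns (freq cpd, amplitude)."""
    n = tex.shape[0]
    amp = np.abs(np.fft.fftshift(np.fft.fft2(tex)))
    f = np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / ppd))
    fx, fy = np.meshgrid(f, f)
    radial = np.hypot(fx, fy)
    step = ppd / n
    bins = (radial / step).astype(int)
    prof = np.bincount(bins.ravel(), weights=amp.ravel()) / np.maximum(
        np.bincount(bins.ravel()), 1
    )
    freqs = np.arange(prof.size) * step
    return freqs, prof


class TestMakeTexture:
    def test_seed_determinism(self):
        t1 = make_texture("plaid_3.5cpd", 128, PPD, seed=11)
        t2 = make_texture("plaid_3.5cpd", 128, PPD, seed=11)
        assert np.array_equal(t1, t2)

    def test_unknown_kind_rejected(self):
        with pytest.raises(UnknownTextureError):
            make_texture("checkerboard", 64, PPD, seed=0)

    def test_zero_mean_unit_rms(self):
        for kind in stereo_synth.TEXTURE_KINDS:
            t = make_texture(kind, 128, PPD, seed=3)
            assert abs(t.mean()) < 1e-9
            assert t.std() == pytest.approx(1.0, abs=1e-9)

    def test_onef_spectrum_slope(self):
        # oracle: direct FFT, radially averaged, log-log fit over mid band
        tex = make_texture("onef_noise", 512, PPD, seed=7)
        freqs, prof = radial_amplitude_profile(tex, PPD)
        sel = (freqs > 0.5) & (freqs < 15.0)
        slope = np.polyfit(np.log(freqs[sel]), np.log(prof[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    @pytest.mark.parametrize("kind,cpd", [("plaid_3.5cpd", 3.5), ("plaid_5.25cpd", 5.25)])
    def test_plaid_peak_frequency(self, kind, cpd):
        tex = make_texture(kind, 256, PPD, seed=5)
        freqs, prof = radial_amplitude_profile(tex, PPD)
        prof[freqs < 1.0] = 0.0
        peak = freqs[np.argmax(prof)]
        assert abs(peak - cpd) <= PPD / 256.0 + 1e-9  # within one frequency bin


class TestRenderStereo:
    def test_frontoparallel_constant_range(self, fronto_patch):
        r = fronto_patch.range_map
        assert np.allclose(r, 10.0, rtol=2e-4)
        assert r.min() >= 10.0 - 1e-6  # center is the nearest point

    def test_ground_plane_range_increases_with_elevation(self, ground_patch):
        r = ground_patch.range_map
        assert r[10, 32] > r[54, 32]  # row 10 is higher elevation than row 54
        tilt_hat, _ = center_tilt_slant(ground_patch)
        assert abs(circ_error(tilt_hat, 90.0, 360.0)) < 1.0

    def test_determinism_bit_identical(self, geom):
        spec = SceneSpec(tilt=200.0, slant=55.0, distance=7.0, seed=123, bump_amplitude=0.02)
        p1 = render_stereo(spec, geom)
        p2 = render_stereo(spec, geom)
        assert np.array_equal(p1.left_image, p2.left_image)
        assert np.array_equal(p1.right_image, p2.right_image)
        assert np.array_equal(p1.range_map, p2.range_map)

    def test_invalid_specs_rejected(self, geom):
        with pytest.raises(ValueError):
            SceneSpec(slant=95.0)
        with pytest.raises(ValueError):
            SceneSpec(distance=-3.0)

    def test_planar_limit_tilt_matches_spec(self, geom):
        for tilt in (30.0, 145.0, 260.0):
            spec = SceneSpec(tilt=tilt, slant=50.0, distance=12.0, seed=4)
            tilt_hat, _ = center_tilt_slant(render_stereo(spec, geom))
            assert abs(circ_error(tilt_hat, tilt, 360.0)) < 1.0

    def test_disparity_consistency_frontoparallel(self, geom, cue_cfg):
        # parallel axes: uniform shift = b/d radians within 0.5 px
        g = ViewingGeometry(image_size=128)
        spec = SceneSpec(tilt=0.0, slant=0.0, distance=10.0, texture_kind="onef_noise", seed=6)
        p = render_stereo(spec, g, convergence_distance=None)
        analytic = g.interocular_distance / 10.0 * g.focal_px
        disp, valid = image_cues.disparity_map(
            p.left_image, p.right_image, cue_cfg, search_range_px=int(analytic) + 8
        )
        inner = (slice(40, 88), slice(45, 83))
        assert valid[inner].all()
        assert np.abs(disp[inner] - analytic).max() < 0.5

    def test_converged_rendering_zero_center_disparity(self, geom, cue_cfg):
        spec = SceneSpec(tilt=0.0, slant=0.0, distance=8.0, texture_kind="onef_noise", seed=8)
        p = render_stereo(spec, geom)  # converged at 8 m
        disp, valid = image_cues.disparity_map(p.left_image, p.right_image, cue_cfg)
        assert valid[32, 32]
        assert abs(disp[32, 32]) < 0.5


class TestPerturbSurface:
    def test_zero_amplitude_reproduces_planar_render(self, geom):
        a = render_stereo(SceneSpec(tilt=45, slant=40, distance=9, seed=3, bump_amplitude=0.0), geom)
        h, _ = perturb_surface(SceneSpec(tilt=45, slant=40, distance=9, seed=3), geom)
        assert h is None
        dx, dy = surface_truth.range_gradient(a.range_map)
        tv = surface_truth.tilt_variance(
            surface_truth.groundtruth_tilt(dx, dy),
            surface_truth.TruthConfig(pixels_per_degree=geom.pixels_per_degree),
        )
        assert tv < 1e-4

    def test_amplitude_monotone_tilt_variance(self, geom, truth_cfg):
        # median central tilt variance strictly increases with bump amplitude
        amps = [0.0, 0.01, 0.03, 0.08]
        medians = []
        for amp in amps:
            tvs = []
            for seed in range(50):
                spec = SceneSpec(
                    tilt=120.0, slant=45.0, distance=10.0, seed=seed,
                    bump_amplitude=amp, bump_corr_length=0.3, texture_kind="onef_noise",
                )
                patch = render_stereo(spec, geom)
                dx, dy = surface_truth.range_gradient(patch.range_map, truth_cfg)
                tvs.append(surface_truth.tilt_variance(surface_truth.groundtruth_tilt(dx, dy), truth_cfg))
            medians.append(np.median(tvs))
        assert all(m2 > m1 for m1, m2 in zip(medians, medians[1:]))

    def test_long_correlation_length_locally_planar(self, geom, truth_cfg):
        spec = SceneSpec(
            tilt=120.0, slant=45.0, distance=10.0, seed=5,
            bump_amplitude=0.3, bump_corr_length=30.0, texture_kind="onef_noise",
        )
        patch = render_stereo(spec, geom)
        dx, dy = surface_truth.range_gradient(patch.range_map, truth_cfg)
        tv = surface_truth.tilt_variance(surface_truth.groundtruth_tilt(dx, dy), truth_cfg)
        assert tv < 0.01

    def test_realized_rms_matches_amplitude(self, geom):
        spec = SceneSpec(bump_amplitude=0.05, bump_corr_length=0.3, distance=10.0, seed=4)
        h, _ = perturb_surface(spec, geom)
        assert h.std() == pytest.approx(0.05, rel=0.35)


class TestSampleStimuli:
    def test_counts_and_constraints(self, geom):
        cons = SamplingConstraints(n_tilt_bins=4, n_per_bin=3)
        patches = sample_stimuli(cons, geom, seed=1)
        assert len(patches) == 12
        assert len({p.stimulus_id for p in patches}) == 12
        bin_width = 360.0 / cons.n_tilt_bins
        for i, p in enumerate(patches):
            tilt_hat, slant_hat = center_tilt_slant(p)
            assert (i // cons.n_per_bin) * bin_width <= tilt_hat < (i // cons.n_per_bin + 1) * bin_width
            assert slant_hat > cons.min_slant
            assert cons.distance_range[0] <= p.spec.distance <= cons.distance_range[1]
            c = image_cues.local_contrast(
                p.left_image, image_cues.CueConfig(pixels_per_degree=geom.pixels_per_degree)
            )
            assert cons.contrast_range[0] <= c <= cons.contrast_range[1]

    def test_n_per_bin_validation(self, geom):
        with pytest.raises(ValueError):
            sample_stimuli(SamplingConstraints(n_per_bin=0), geom, seed=0)

    def test_seed_determinism(self, geom):
        cons = SamplingConstraints(n_tilt_bins=2, n_per_bin=2)
        a = sample_stimuli(cons, geom, seed=5)
        b = sample_stimuli(cons, geom, seed=5)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.left_image, pb.left_image)


class TestTiltPrior:
    def test_cardinal_heavy(self):
        tilts = sample_tilt_prior(20_000, seed=0)
        near_card = (np.abs(circ_error(tilts, 0.0, 180.0)) <= 10.0) | (
            np.abs(circ_error(tilts, 90.0, 180.0)) <= 10.0
        )
        assert near_card.mean() > 0.5  # far above the uniform fraction (2/9)
        assert np.all((tilts >= 0) & (tilts < 180))


class TestSimulateCueSamples:
    def test_noiseless(self):
        tilts = np.array([10.0, 100.0, 170.0])
        cues = simulate_cue_samples(tilts, kappas=np.inf, seed=0)
        assert np.allclose(cues, tilts[:, None])

    def test_noise_concentration(self):
        tilts = np.full(5000, 60.0)
        cues = simulate_cue_samples(tilts, kappas=8.0, seed=1)
        for j in range(3):
            v = circ_mean_var(cues[:, j], period=180.0)
            assert abs(circ_error(v.mean, 60.0, 180.0)) < 2.0
            assert 0.01 < v.variance < 0.2


def fit_axial_kappa(angles_deg):
    """ML von-Mises concentration of axial data (oracle for observer noise)."""
    doubled = np.deg2rad(2.0 * np.asarray(angles_deg))
    rbar = abs(np.exp(1j * doubled).mean())
    return optimize.brentq(lambda k: special.i1(k) / special.i0(k) - rbar, 1e-6, 500.0)


class TestSyntheticObserver:
    def test_noiseless_limit(self):
        est = np.array([10.0, 75.0, 160.0])
        obs = SyntheticObserverSpec(noise_concentration=np.inf, lapse_rate=0.0)
        assert np.allclose(synthetic_observer(est, obs, seed=0), est)

    def test_kappa_zero_uniform(self):
        est = np.full(20_000, 45.0)
        obs = SyntheticObserverSpec(noise_concentration=0.0)
        resp = synthetic_observer(est, obs, seed=1)
        assert circ_mean_var(resp, period=180.0).variance > 0.97

    def test_kappa_recovery(self):
        est = np.full(10_000, 90.0)
        obs = SyntheticObserverSpec(noise_concentration=5.0)
        resp = synthetic_observer(est, obs, seed=2)
        errors = circ_error(resp, 90.0, 180.0)
        assert fit_axial_kappa(errors) == pytest.approx(5.0, rel=0.10)

    def test_lapses(self):
        est = np.full(20_000, 90.0)
        obs = SyntheticObserverSpec(noise_concentration=np.inf, lapse_rate=0.3)
        resp = synthetic_observer(est, obs, seed=3)
        assert np.mean(resp != 90.0) == pytest.approx(0.3, abs=0.02)

    def test_bias_applied(self):
        est = np.full(10, 50.0)
        obs = SyntheticObserverSpec(noise_concentration=np.inf, bias_fn=lambda t: 10.0 * np.ones_like(t))
        assert np.allclose(synthetic_observer(est, obs, seed=4), 60.0)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SyntheticObserverSpec(noise_concentration=-1.0)
        with pytest.raises(ValueError):
            SyntheticObserverSpec(lapse_rate=1.5)
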