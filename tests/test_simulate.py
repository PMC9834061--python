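"""Synthetic tomogram generator: subunits, filaments, wedge, noise."""

import numpy as np
import pytest
import scipy.signal

from helicta import (
    AcquisitionGeometry,
    FilamentTrace,
    HelicalParams,
    PlacementError,
    Volume,
    add_noise,
    apply_missing_wedge,
    lokiactin_subunit,
    make_subunit_model,
    missing_wedge_fraction,
    missing_wedge_mask,
    render_filament,
    ribosome_model,
    scatter_particles,
)
from helicta._geom import rot_x, rot_z, rotate_data

from conftest import VOX, straight_filament


class TestSubunitModels:
    def test_gaussian_blob_fwhm(self):
        sub = make_subunit_model("gaussian_blob", 50.0, VOX)
        c = sub.shape[0] // 2
        prof = sub.data[c, c, :]
        x = (np.arange(len(prof)) - c) * VOX
        above = x[prof >= 0.5]
        fwhm = above.max() - above.min() + VOX
        assert fwhm == pytest.approx(50.0, rel=0.10)

    def test_sphere_shell_peaks_on_shell(self):
        sub = make_subunit_model("sphere_shell", 60.0, VOX)
        c = sub.shape[0] // 2
        prof = sub.data[c, c, c:]
        r_peak = np.argmax(prof) * VOX
        assert r_peak == pytest.approx(30.0, abs=VOX)
        assert sub.data[c, c, c] < 0.1  # ~0 at the center

    def test_normalized_and_centered(self):
        for kind in ("gaussian_blob", "two_lobe", "sphere_shell"):
            sub = make_subunit_model(kind, 40.0, VOX)
            assert sub.data.max() == pytest.approx(1.0)

    def test_oversized_diameter_rejected(self):
        with pytest.raises(ValueError):
            make_subunit_model("gaussian_blob", 200.0, VOX, box=9)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_subunit_model("banana", 40.0, VOX)


class TestRenderFilament:
    def test_subunit_count_and_azimuths(self):
        # straight axial trace of length 279 A at rise 27.9 -> 11 per strand
        trace = FilamentTrace(0, np.array([[160.0, 160.0, 20.0], [160.0, 160.0, 299.0]]))
        params = HelicalParams(27.9, -167.7)
        vol, gt = render_filament(
            trace, params, lokiactin_subunit(VOX), (64, 60, 60), VOX
        )
        strand0 = gt.subunits.query("strand == 0")
        assert len(strand0) == 11
        assert len(gt.subunits) == 22  # two strands
        expected = (np.arange(11) * -167.7) % 360.0
        np.testing.assert_allclose(strand0["azimuth"].to_numpy(), expected, atol=1e-6)

    def test_axial_autocorrelation_peak_at_rise(self):
        # brute-force oracle: first off-origin autocorrelation peak of the
        # z-profile of a noise-free filament sits at the rise, +- one voxel
        trace = FilamentTrace(0, np.array([[160.0, 160.0, 20.0], [160.0, 160.0, 299.0]]))
        sub = make_subunit_model("gaussian_blob", 20.0, VOX)
        vol, _ = render_filament(
            trace, HelicalParams(27.9, -167.7), sub, (64, 60, 60), VOX,
            two_strands=False, strand_radius=12.0,
        )
        prof = vol.data.sum(axis=(1, 2))
        prof = prof - prof.mean()
        ac = np.correlate(prof, prof, "full")[len(prof) - 1:]
        peaks, _ = scipy.signal.find_peaks(ac)
        assert abs(peaks[0] * VOX - 27.9) <= VOX

    def test_short_trace_warns_and_renders_nothing(self):
        trace = FilamentTrace(0, np.array([[100.0, 100.0, 100.0], [100.0, 100.0, 110.0]]))
        with pytest.warns(UserWarning, match="shorter than one rise"):
            vol, gt = render_filament(
                trace, HelicalParams(27.9, -167.7), lokiactin_subunit(VOX),
                (40, 40, 40), VOX,
            )
        assert len(gt.subunits) == 0
        assert vol.data.max() == 0.0

    def test_negative_polarity_is_the_flipped_filament(self):
        """A polarity -1 filament must equal the in-plane 180-deg flip of the
        +1 filament up to a helical-symmetry rotation and axial shift."""
        volP, _ = straight_filament(48, azimuth0=0.0, polarity=1)
        volM, _ = straight_filament(48, azimuth0=0.0, polarity=-1)
        flipP = rotate_data(volP.data, rot_x(180.0))
        box = 48
        zz, yy, xx = np.meshgrid(*(np.arange(box),) * 3, indexing="ij")
        mask = (np.sqrt((xx - 24) ** 2 + (yy - 24) ** 2) <= 10) & (np.abs(zz - 24) <= 15)
        a = flipP[mask] - flipP[mask].mean()
        best = -1.0
        for az in np.arange(0, 360, 3.0):
            for dz in np.arange(-3, 3.1, 0.5):
                v = rotate_data(volM.data, rot_z(az), shift_xyz=np.array([0, 0, dz]))[mask]
                v = v - v.mean()
                best = max(best, float(a @ v / (np.linalg.norm(a) * np.linalg.norm(v))))
        assert best > 0.98

    def test_ground_truth_poses_recoverable_by_template_matching(self):
        """Oracle: cross-correlating a crop at each ground-truth subunit
        center against the subunit model over a coarse azimuth grid recovers
        the recorded azimuth progression (up to one fixed frame offset)."""
        from helicta._geom import sample_at_points

        trace = FilamentTrace(0, np.array([[134.0, 134.0, 30.0], [134.0, 134.0, 240.0]]))
        sub = lokiactin_subunit(VOX)
        vol, gt = render_filament(
            trace, HelicalParams(27.9, -167.7), sub, (50, 50, 50), VOX,
            two_strands=False,
        )
        grid = np.arange(0.0, 360.0, 15.0)
        c = sub.shape[0] // 2
        models = []
        for az in grid:
            posed = rotate_data(sub.data, rot_z(az))
            m = posed[c - 5:c + 6, c - 5:c + 6, c - 5:c + 6].ravel()
            models.append((m - m.mean()) / np.linalg.norm(m - m.mean()))
        offsets = []
        for _, row in gt.subunits.iterrows():
            center = np.array([row.x, row.y, row.z]) / VOX
            if np.any(center < 6) or np.any(center > 43):
                continue
            offs = np.arange(-5, 6)
            oz, oy, ox = np.meshgrid(offs, offs, offs, indexing="ij")
            pts = np.stack([ox + center[0], oy + center[1], oz + center[2]], axis=-1)
            crop = sample_at_points(vol.data, pts.reshape(-1, 3))
            a = crop - crop.mean()
            a /= np.linalg.norm(a)
            best = int(np.argmax([a @ m for m in models]))
            offsets.append((grid[best] - row.azimuth) % 360.0)
        assert len(offsets) >= 4
        # all recovered azimuths share one frame offset, within one grid step
        devs = np.array(offsets) - offsets[0]
        devs = (devs + 180.0) % 360.0 - 180.0
        assert np.abs(devs).max() <= 15.0 + 1e-6


class TestScatterParticles:
    def test_empty_field(self):
        vol, gt = scatter_particles((32, 32, 32), 9.0, 0, {"a": ribosome_model(9.0)}, 0.0, seed=1)
        assert vol.data.max() == 0.0
        assert len(gt.particles) == 0

    def test_deterministic_under_seed(self):
        models = {"a": make_subunit_model("gaussian_blob", 40.0, 9.0)}
        _, gt1 = scatter_particles((48, 64, 64), 9.0, 10, models, 60.0, seed=7)
        _, gt2 = scatter_particles((48, 64, 64), 9.0, 10, models, 60.0, seed=7)
        assert gt1.particles.equals(gt2.particles)

    def test_min_distance_respected(self):
        models = {"a": make_subunit_model("gaussian_blob", 40.0, 9.0)}
        _, gt = scatter_particles((48, 64, 64), 9.0, 12, models, 80.0, seed=3)
        xyz = gt.particles[["x", "y", "z"]].to_numpy()
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 80.0

    def test_impossible_packing_raises(self):
        models = {"a": make_subunit_model("gaussian_blob", 30.0, 9.0)}
        with pytest.raises(PlacementError, match="placed only"):
            scatter_particles((24, 24, 24), 9.0, 50, models, 100.0, seed=1,
                              max_retries=10)


class TestMissingWedge:
    def test_full_tilt_range_is_identity(self):
        rng = np.random.default_rng(0)
        v = Volume(rng.normal(size=(16, 16, 16)), 5.0)
        g = AcquisitionGeometry(tilt_min=-90, tilt_max=90)
        np.testing.assert_allclose(apply_missing_wedge(v, g).data, v.data, atol=1e-9)

    def test_pm60_zeroes_one_third(self):
        frac = missing_wedge_fraction((64, 64, 64), AcquisitionGeometry())
        assert frac == pytest.approx(1.0 / 3.0, abs=0.02)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        v = Volume(rng.normal(size=(24, 24, 24)), 5.0)
        g = AcquisitionGeometry()
        once = apply_missing_wedge(v, g)
        twice = apply_missing_wedge(once, g)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-9)

    def test_commutes_with_density_scaling(self):
        rng = np.random.default_rng(2)
        v = Volume(rng.normal(size=(16, 16, 16)), 5.0)
        g = AcquisitionGeometry()
        a = apply_missing_wedge(v.with_data(3.5 * v.data), g).data
        b = 3.5 * apply_missing_wedge(v, g).data
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_tilt_axis_choice_rotates_the_wedge(self):
        gy = AcquisitionGeometry(tilt_axis="y")
        gx = AcquisitionGeometry(tilt_axis="x")
        my = missing_wedge_mask((32, 32, 32), gy)
        mx = missing_wedge_mask((32, 32, 32), gx)
        assert not np.array_equal(my, mx)
        # the x-axis mask is the y-axis mask with kx and ky swapped
        np.testing.assert_array_equal(mx, my.transpose(0, 2, 1))


class TestCTF:
    def test_first_zero_at_the_analytic_frequency(self):
        # pure phase contrast, no spherical aberration: chi = pi lam df k^2
        # crosses pi (first zero) at k = sqrt(1 / (lam * df))
        from helicta import ctf_2d

        df = 30000.0  # 3 um underfocus
        ctf = ctf_2d((512, 512), 2.0, df, cs_mm=0.0, amplitude_contrast=0.0)
        prof = ctf[0, :256]  # along one axis from DC
        k = np.fft.fftfreq(512, d=2.0)[:256]
        lam = 12.2639 / np.sqrt(300e3 * (1.0 + 0.97845e-6 * 300e3))
        k_zero = np.sqrt(1.0 / (lam * df))
        # first sign change of the oscillatory part after the initial rise
        crossings = np.where(np.diff(np.sign(prof[1:])))[0]
        assert abs(k[crossings[0] + 1] - k_zero) < 2 * (k[1] - k[0])

    def test_application_preserves_realness_and_is_off_by_default(self):
        from helicta import apply_ctf

        rng = np.random.default_rng(0)
        img = rng.normal(size=(64, 64))
        out = apply_ctf(img, 4.51, 80000.0)
        assert out.shape == img.shape
        assert np.isrealobj(out)
        assert not np.allclose(out, img)


from hypothesis import given, settings, strategies as st


class TestWedgeProperties:
    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(tilt=st.floats(20.0, 88.0))
    def test_missing_fraction_matches_solid_angle(self, tilt):
        g = AcquisitionGeometry(tilt_min=-tilt, tilt_max=tilt)
        frac = missing_wedge_fraction((48, 48, 48), g)
        expected = (90.0 - tilt) / 90.0  # solid-angle fraction of the wedge
        assert frac == pytest.approx(expected, abs=0.03)

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(tilt=st.floats(30.0, 85.0), seed=st.integers(0, 100))
    def test_wedge_application_idempotent_for_any_range(self, tilt, seed):
        rng = np.random.default_rng(seed)
        v = Volume(rng.normal(size=(16, 16, 16)), 4.0)
        g = AcquisitionGeometry(tilt_min=-tilt, tilt_max=tilt)
        once = apply_missing_wedge(v, g)
        twice = apply_missing_wedge(once, g)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-9)


class TestNoise:
    def test_snr_one_measured_ratio(self):
        vol, _ = straight_filament(64)
        noisy = add_noise(vol, 1.0, seed=0)
        mask = np.abs(vol.data) > 0.1 * np.abs(vol.data).max()
        noise_var = (noisy.data - vol.data)[mask].var()
        assert vol.data[mask].var() / noise_var == pytest.approx(1.0, rel=0.10)

    def test_high_snr_limit(self):
        vol, _ = straight_filament(32)
        out = add_noise(vol, 1e9, seed=0)
        assert np.abs(out.data - vol.data).max() < 1e-3 * np.abs(vol.data).max()

    def test_seeds_change_noise_not_signal(self):
        vol, _ = straight_filament(32)
        a = add_noise(vol, 1.0, seed=1)
        b = add_noise(vol, 1.0, seed=2)
        assert not np.allclose(a.data, b.data)
        # noise is zero-mean additive: averaging many realizations -> signal
        mean40 = np.mean([add_noise(vol, 1.0, seed=s).data for s in range(40)], axis=0)
        rms = np.sqrt(((mean40 - vol.data) ** 2).mean())
        assert rms < 0.1 * vol.data.max()

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError, match="SNR"):
            add_noise(Volume(np.zeros((8, 8, 8)), 1.0), 1.0, seed=0)
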