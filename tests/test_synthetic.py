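"""Synthetic scene generator: spectra, rendering physics and dataset plumbing."""

import numpy as np
import pytest

from msiaudit.radiometry import ChannelSpec, ConfigurationError, ValidationError, channel_index
from msiaudit.synthetic import (
    NO_FILTER_ILLUMINANTS,
    TISSUE_CLASSES,
    channel_mean_counts,
    dataset_manifest,
    generate_dataset,
    make_illuminants,
    make_sensor,
    render_cube,
    sample_reflectance_library,
)


class TestIlluminants:
    def test_blue445_peaks_at_nominal_wavelength(self, lights):
        c = lights["blue445"]
        assert c.wavelengths_nm[np.argmax(c.values)] == pytest.approx(445, abs=2)

    def test_zero_power_gives_all_zero_curve(self):
        lights = make_illuminants({"red638": {"peak_power": 0.0}})
        assert np.all(lights["red638"].values == 0)

    def test_gaussian_fwhm_half_max(self):
        lights = make_illuminants({"green525": {"fwhm_nm": 20.0}})
        c = lights["green525"]
        peak = c.values.max()
        at_half = np.interp(525 + 10.0, c.wavelengths_nm, c.values)
        assert at_half == pytest.approx(0.5 * peak, rel=0.01)

    def test_unknown_roster_entry_rejected(self):
        with pytest.raises(ConfigurationError):
            make_illuminants({"magenta999": {"peak_power": 1.0}})


class TestSensor:
    def test_visible_lobe_ordering(self, sensor):
        grid = sensor.qe["R"].wavelengths_nm
        vis = grid < 740  # restrict to the visible lobes, below the NIR shoulder
        argmax = {s: grid[vis][np.argmax(sensor.qe[s].values[vis])] for s in "RGB"}
        assert argmax["B"] < argmax["G"] < argmax["R"]

    def test_blocker_cuts_ir_signal_by_95_percent(self, lights, sensor, channel_spec):
        qe_open = sensor.qe["R"]
        grid = qe_open.wavelengths_nm
        blocked = sensor.effective_qe("R", illuminant="arri_white")  # engaged
        from msiaudit.radiometry import channel_signal
        s_open = channel_signal(lights["ir808"], qe_open, channel_spec)
        s_blocked = channel_signal(lights["ir808"], blocked, channel_spec)
        assert s_blocked <= 0.05 * s_open

    def test_blocker_removed_for_ir_acquisition(self, sensor):
        q_ir = sensor.effective_qe("R", illuminant="ir808")
        np.testing.assert_allclose(q_ir.values, sensor.qe["R"].resample(
            q_ir.wavelengths_nm))

    def test_unit_transmission_blocker_changes_nothing(self, lights, channel_spec):
        s = make_sensor({"blocker_leak": 1.0})
        grid = s.qe["G"].wavelengths_nm
        np.testing.assert_allclose(
            s.effective_qe("G", illuminant="arri_white").values,
            s.qe["G"].resample(grid), atol=1e-12)

    def test_uv_effectively_undetectable_when_engaged(self, sensor):
        for ch in "RGB":
            eff = sensor.effective_qe(ch, illuminant="uv405")
            at_405 = np.interp(405, eff.wavelengths_nm, eff.values)
            assert at_405 < 0.01 * sensor.qe[ch].values.max()

    def test_excessive_qe_rejected(self):
        with pytest.raises(ValidationError):
            make_sensor({"G": {"peak_qe": 0.95, "nir_peak_qe": 0.3, "uv_peak_qe": 0.3,
                               "pedestal_qe": 0.2}})


class TestReflectanceLibrary:
    def test_zero_separability_identical_means(self):
        lib = sample_reflectance_library(n_classes=5, separability=0.0, seed=3)
        assert np.all(lib.curves == lib.curves[0])

    def test_seed_determinism(self):
        a = sample_reflectance_library(n_classes=4, separability=0.05, seed=11)
        b = sample_reflectance_library(n_classes=4, separability=0.05, seed=11)
        np.testing.assert_array_equal(a.curves, b.curves)

    def test_default_class_roster(self):
        lib = sample_reflectance_library(seed=0)
        assert lib.class_names == TISSUE_CLASSES

    def test_band_limited_info_reaches_only_ir_channels(self, lights, sensor,
                                                        channel_spec):
        # classes differing only in 780-830 nm produce different counts only
        # in IR-illuminated channels (oracle: direct channel integration)
        lib = sample_reflectance_library(n_classes=2, separability=0.1,
                                         band_nm=(780.0, 830.0), seed=5)
        mu0 = channel_mean_counts(lib.curves[0], lights, sensor, channel_spec)
        mu1 = channel_mean_counts(lib.curves[1], lights, sensor, channel_spec)
        rel = np.abs(mu1 - mu0) / np.maximum(mu0, 1e-9)
        ir = [channel_index("ir808", s) for s in "RGB"]
        other = [i for i in range(21) if i not in ir]
        assert rel[ir].min() > 0.05
        assert rel[other].max() < 1e-3

    def test_reflectance_bounds(self):
        lib = sample_reflectance_library(n_classes=8, separability=0.5, seed=2)
        assert lib.curves.min() >= 0.0 and lib.curves.max() <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            sample_reflectance_library(n_classes=1)


class TestRenderCube:
    def test_deterministic_mode_reproducible(self, small_library, lights, sensor,
                                             channel_spec):
        kw = dict(height=96, width=96, poisson=False, seed=42)
        c1, m1 = render_cube("artery", small_library, lights, sensor, channel_spec, **kw)
        c2, m2 = render_cube("artery", small_library, lights, sensor, channel_spec, **kw)
        np.testing.assert_array_equal(c1.pixels, c2.pixels)
        np.testing.assert_array_equal(m1.mask, m2.mask)

    def test_zero_reflectance_zero_foreground_counts(self, lights, sensor,
                                                     channel_spec):
        lib = sample_reflectance_library(n_classes=2, separability=0.0, seed=1,
                                         scale_jitter_sd=0.0, perturb_amplitude=0.0)
        lib.curves[:] = 0.0
        cube, mask = render_cube("artery", lib, lights, sensor, channel_spec,
                                 seed=3, height=96, width=96, poisson=False,
                                 texture_sd=0.0, background_reflectance=0.0)
        assert np.all(cube.pixels == 0)

    def test_poisson_variance_to_mean_ratio(self, lights, sensor, channel_spec):
        # flat texture: per-channel foreground variance/mean ratio ~ 1
        lib = sample_reflectance_library(n_classes=2, separability=0.0, seed=1,
                                         scale_jitter_sd=0.0, perturb_amplitude=0.0)
        cube, mask = render_cube("artery", lib, lights, sensor, channel_spec,
                                 seed=9, height=160, width=160, poisson=True,
                                 texture_sd=0.0, coverage_range=(0.7, 0.8))
        fg = mask.mask
        assert fg.sum() >= 10_000
        counts = cube.pixels[fg].astype(float)
        mu = counts.mean(axis=0)
        ratio = counts.var(axis=0) / np.maximum(mu, 1e-12)
        sel = mu >= 50
        assert sel.sum() >= 10
        assert np.all(ratio[sel] > 0.9) and np.all(ratio[sel] < 1.1)

    def test_empirical_snr_matches_shot_noise_formula(self, lights, sensor,
                                                      channel_spec):
        from msiaudit.radiometry import snr_db
        lib = sample_reflectance_library(n_classes=2, separability=0.0, seed=1,
                                         scale_jitter_sd=0.0, perturb_amplitude=0.0)
        cube, mask = render_cube("artery", lib, lights, sensor, channel_spec,
                                 seed=10, height=160, width=160, poisson=True,
                                 texture_sd=0.0, coverage_range=(0.7, 0.8))
        counts = cube.pixels[mask.mask].astype(float)
        mu = counts.mean(axis=0)
        for c in np.nonzero(mu >= 100)[0]:
            emp_db = 20 * np.log10(counts[:, c].mean() / counts[:, c].std())
            assert abs(emp_db - snr_db(mu[c])) < 0.5

    def test_composite_scene_two_regions(self, small_library, lights, sensor,
                                         channel_spec):
        class_map = np.full((96, 96), -1)
        class_map[20:60, 10:45] = 0
        class_map[20:60, 50:90] = 1
        cube, mask = render_cube(class_map, small_library, lights, sensor,
                                 channel_spec, seed=4, height=96, width=96,
                                 poisson=False, texture_sd=0.0)
        assert cube.class_label == "artery+bone"
        # the two regions carry different spectra in at least one channel
        a = cube.pixels[30, 20]
        b = cube.pixels[30, 70]
        assert np.any(np.abs(a.astype(float) - b.astype(float)) > 0)

    def test_all_background_rejected(self, small_library, lights, sensor,
                                     channel_spec):
        class_map = np.full((64, 64), -1)
        with pytest.raises(ValidationError):
            render_cube(class_map, small_library, lights, sensor, channel_spec,
                        seed=1, height=64, width=64)

    def test_mask_coverage_within_requested_range(self, small_library, lights,
                                                  sensor, channel_spec):
        for seed in range(4):
            _, mask = render_cube("artery", small_library, lights, sensor,
                                  channel_spec, seed=seed, height=128, width=128,
                                  coverage_range=(0.3, 0.8))
            cov = mask.mask.mean()
            assert 0.1 < cov < 0.95  # wobble makes the bound approximate


class TestGenerateDataset:
    def test_default_scene_and_specimen_counts(self, small_library, lights, sensor,
                                               channel_spec):
        recs = list(generate_dataset(small_library, lights, sensor, channel_spec,
                                     seed=5, height=64, width=64))
        # 9 specimens x 3 classes x 1 scene
        assert len(recs) == 27
        assert len({r.specimen_id for r in recs}) == 9

    def test_manifest_deterministic_under_seed(self, small_library, lights, sensor,
                                               channel_spec):
        kw = dict(seed=6, height=64, width=64)
        m1 = dataset_manifest(generate_dataset(small_library, lights, sensor,
                                               channel_spec, **kw))
        m2 = dataset_manifest(generate_dataset(small_library, lights, sensor,
                                               channel_spec, **kw))
        assert m1.equals(m2)

    def test_split_specimens_pairwise_disjoint(self, small_library, lights, sensor,
                                               channel_spec):
        recs = list(generate_dataset(small_library, lights, sensor, channel_spec,
                                     seed=7, height=64, width=64))
        by_split = {}
        for r in recs:
            by_split.setdefault(r.split, set()).add(r.specimen_id)
        splits = list(by_split)
        for i in range(len(splits)):
            for j in range(i + 1, len(splits)):
                assert not (by_split[splits[i]] & by_split[splits[j]])

    def test_empty_split_rejected(self, small_library, lights, sensor, channel_spec):
        with pytest.raises(ConfigurationError):
            next(generate_dataset(small_library, lights, sensor, channel_spec,
                                  seed=1, n_specimens=(6, 0, 1)))
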