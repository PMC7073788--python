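"""Simulator: wavelength axis, shot/sample generation, dataset structure."""

import numpy as np
import pytest

import libseed as ls
from libseed import synth

from conftest import small_config


class TestAxis:
    def test_geometric_step(self):
        ax = ls.build_axis(400.0, 410.0, 1000.0)
        assert ax.values[0] == pytest.approx(400.0)
        assert ax.values[1] == pytest.approx(400.0 * (1 + 1 / 1000.0))
        ratios = ax.values[1:] / ax.values[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_spacing_increases_with_wavelength(self):
        ax = ls.build_axis(230.0, 880.0, 5000.0)
        assert np.all(np.diff(np.diff(ax.values)) > -1e-9)

    def test_large_r_limit_is_uniform(self):
        # on a short range the geometric grid tends to uniform spacing
        # (residual non-uniformity ~ span / lambda)
        ax = ls.build_axis(500.0, 500.01, 1e8)
        d = np.diff(ax.values)
        assert np.ptp(d) / d.mean() < 5e-5

    def test_invalid_arguments(self):
        for args in [(-1, 10, 100), (10, 5, 100), (10, 20, 0)]:
            with pytest.raises(ValueError):
                ls.build_axis(*args)

    def test_trimmed_band_holds_13435_points(self):
        ax = synth.default_axis()
        inside = (ax.values >= 380.01) & (ax.values <= 860.04)
        assert int(inside.sum()) == 13435


class TestShot:
    def setup_method(self):
        self.axis = ls.build_axis(400.0, 430.0, 3000.0)

    def _profile(self, lines):
        return ls.CultivarProfile(cultivar=1, lines=tuple(lines))

    def test_single_line_peaks_at_nearest_grid_point(self):
        line = ls.EmissionLine(416.70, 0.2, "CN", 1.0)
        cfg = ls.SimConfig(baseline_coeffs=(0.0,)).noiseless()
        fine = ls.build_axis(410.0, 425.0, 1e5)  # resolves the 0.2 nm line
        s = ls.simulate_shot(self._profile([line]), fine, cfg,
                             np.random.default_rng(0))
        assert fine.values[np.argmax(s)] == pytest.approx(416.70, abs=0.01)
        # unit-height Lorentzian, fully resolved
        assert s.max() == pytest.approx(1.0, rel=1e-3)

    def test_superposition_of_nonoverlapping_lines(self):
        cfg = ls.SimConfig(baseline_coeffs=(0.0,)).noiseless()
        rng = np.random.default_rng(0)
        la = ls.EmissionLine(405.0, 0.1, "A", 2.0)
        lb = ls.EmissionLine(425.0, 0.1, "B", 3.0)
        both = ls.simulate_shot(self._profile([la, lb]), self.axis, cfg, rng)
        sa = ls.simulate_shot(self._profile([la]), self.axis, cfg, rng)
        sb = ls.simulate_shot(self._profile([lb]), self.axis, cfg, rng)
        assert np.allclose(both, sa + sb)

    def test_seeded_determinism(self):
        cfg = ls.SimConfig()
        prof = ls.CultivarProfile(1, cfg.lines)
        a = ls.simulate_shot(prof, self.axis, cfg, np.random.default_rng(42))
        b = ls.simulate_shot(prof, self.axis, cfg, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            ls.WavelengthAxis(values=np.array([1.0]), resolving_power=10)


class TestSample:
    def test_zero_noise_sample_equals_single_shot(self):
        cfg = small_config().noiseless()
        axis = synth.default_axis(cfg)
        prof = ls.CultivarProfile(2, cfg.lines)
        sample = ls.simulate_sample(prof, axis, cfg, np.random.default_rng(0))
        shot = ls.simulate_shot(prof, axis, cfg, np.random.default_rng(1))
        assert np.allclose(sample, shot)

    def test_averaging_reduces_noise_variance_80x(self):
        # additive-noise-only config: residual variance of the averaged
        # spectrum should be noise_sd^2 / (16*5), +-10%
        cfg = small_config(noise_sd=10.0, shot_jitter_sigma=0.0,
                           sample_jitter_sigma=0.0, sample_scale_sigma=0.0)
        axis = synth.default_axis(cfg)
        prof = ls.CultivarProfile(1, cfg.lines)
        clean = ls.simulate_sample(prof, axis, cfg.noiseless(),
                                   np.random.default_rng(0))
        resid = []
        for seed in range(5):
            noisy = ls.simulate_sample(prof, axis, cfg,
                                       np.random.default_rng(seed))
            resid.append(noisy - clean)
        var = np.var(np.concatenate(resid))
        assert var == pytest.approx(10.0**2 / 80.0, rel=0.10)

    def test_shot_count_is_craters_times_accumulations(self):
        cfg = ls.SimConfig()
        assert cfg.n_shots == 16 * 5 == 80


class TestDataset:
    def test_shape_labels_and_order(self, small_dataset):
        cfg = small_config()
        assert small_dataset.intensities.shape[0] == 3 * cfg.n_samples_per_cultivar
        assert np.array_equal(np.unique(small_dataset.labels), [1, 2, 3])
        # per-cultivar acquisition order: blocks of equal labels
        lab = small_dataset.labels
        assert np.all(np.diff(lab) >= 0)
        assert small_dataset.sample_ids[0] == "C1-01"

    def test_same_seed_bitwise_identical(self):
        a = ls.generate_dataset(small_config(n_samples_per_cultivar=2), seed=7)
        b = ls.generate_dataset(small_config(n_samples_per_cultivar=2), seed=7)
        assert np.array_equal(a.intensities, b.intensities)

    def test_class_mean_ratio_tracks_multipliers(self, small_dataset):
        # CN 416.70 nm multipliers are (0.70, 1.00, 1.25); class means of
        # the simulated line amplitude must reproduce those ratios
        wl = small_dataset.wavelengths
        j = np.argmin(np.abs(wl - 416.70))
        base = np.polynomial.polynomial.polyval(
            (wl[j] - 230.0) / 650.0, np.asarray((25.0, -70.0, 50.0)))
        means = [small_dataset.intensities[small_dataset.labels == c, j].mean()
                 - base for c in (1, 2, 3)]
        assert means[2] / means[1] == pytest.approx(1.25, rel=0.12)
        assert means[0] / means[1] == pytest.approx(0.70, rel=0.12)

    def test_roundtrip_io(self, tmp_path, small_dataset):
        path = tmp_path / "d.csv"
        ls.write_dataset(small_dataset, path, manifest={"seed": 101})
        back = ls.read_dataset(path)
        assert np.allclose(back.wavelengths, small_dataset.wavelengths)
        assert np.allclose(back.intensities, small_dataset.intensities,
                           atol=1e-4, rtol=1e-4)
        assert np.array_equal(back.labels, small_dataset.labels)
        assert back.meta["seed"] == 101

    def test_equal_multipliers_give_chance_accuracy(self):
        # strip the class signal: every classifier should fall to ~1/3
        lines = tuple(
            ls.EmissionLine(l.center_nm, l.fwhm_nm, l.species,
                            l.base_intensity, (1.0, 1.0, 1.0))
            for l in ls.default_line_table())
        cfg = small_config(n_samples_per_cultivar=18, lines=lines)
        accs = []
        for seed in (0, 1, 2):
            ds = ls.generate_dataset(cfg, seed=seed)
            pre = ls.preprocess_pipeline(ds)
            split = ls.split_cal_pred(18, 3)
            est = ls.ELMClassifier(random_state=seed).fit(
                pre.intensities[split.calibration],
                pre.labels[split.calibration])
            accs.append((est.predict(pre.intensities[split.prediction])
                         == pre.labels[split.prediction]).mean())
        assert abs(float(np.median(accs)) - 1 / 3) <= 0.20


def test_resolving_power_solver_is_deterministic_and_exact():
    r1 = synth.solve_resolving_power()
    r2 = synth.solve_resolving_power()
    assert r1 == r2
    assert synth._count_in_band(r1, 230.0, 380.01, 860.04) == 13435
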