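import numpy as np
import pytest

from lignomap import synth
from lignomap.spectra_io import COMPONENTS, WavenumberGrid
from lignomap.preprocess import common_grid


class TestGenDesign:
    def test_factorial_size_180(self):
        meta, Y = synth.gen_design(synth.DesignSpec(seed=0))
        assert len(meta) == 180 and Y.shape == (180, 3)
        # full factorial: every (site, age, part) cell has 3 replicates
        cells = {(m.site, m.age, m.part) for m in meta}
        assert len(cells) == 3 * 5 * 4

    def test_seed_determinism(self):
        _, a = synth.gen_design(synth.DesignSpec(seed=5))
        _, b = synth.gen_design(synth.DesignSpec(seed=5))
        np.testing.assert_array_equal(a, b)

    def test_hemicellulose_mean_matches_cohort_statistics(self):
        # CLT bound on the grand mean over 10 independent seeds
        means = [synth.gen_design(synth.DesignSpec(seed=s))[1][:, 1].mean()
                 for s in range(10)]
        bound = 3 * 0.025 / np.sqrt(180)
        assert abs(np.mean(means) - 0.237) < bound

    def test_mass_fraction_constraints(self):
        _, Y = synth.gen_design(synth.DesignSpec(seed=7))
        assert np.all(Y > 0) and np.all(Y < 1)
        assert np.all(Y.sum(axis=1) < 0.95)

    def test_effect_signs_follow_field_observations(self):
        # pool several seeds so effects dominate sampling noise
        rows = []
        for s in range(6):
            meta, Y = synth.gen_design(synth.DesignSpec(seed=40 + s))
            rows.append((meta, Y))
        def mean_where(pred, col):
            vals = [y[col] for meta, Y in rows
                    for m, y in zip(meta, Y) if pred(m)]
            return np.mean(vals)
        # 1-year culms: more cellulose, less hemicellulose/lignin
        assert mean_where(lambda m: m.age == 1, 0) > mean_where(lambda m: m.age > 1, 0)
        assert mean_where(lambda m: m.age == 1, 1) < mean_where(lambda m: m.age > 1, 1)
        # nodes: less cellulose, more hemicellulose and lignin
        assert mean_where(lambda m: m.part == "node", 0) < mean_where(lambda m: m.part != "node", 0)
        assert mean_where(lambda m: m.part == "node", 2) > mean_where(lambda m: m.part != "node", 2)
        # sites: cellulose DSH > MY, hemicellulose lowest at DSH
        assert mean_where(lambda m: m.site == "DSH", 0) > mean_where(lambda m: m.site == "MY", 0)
        assert mean_where(lambda m: m.site == "DSH", 1) < mean_where(lambda m: m.site == "BT", 1)


class TestPureSpectra:
    def test_lignin_peaks_at_1504(self):
        grid = common_grid()
        pure = synth.gen_pure_spectra(synth.DEFAULT_COMPONENT_SPECS, grid)
        lignin = pure[2]
        i = grid.nearest_index(1504.0)
        lo, hi = max(0, i - 6), i + 7
        assert np.argmax(lignin[lo:hi]) + lo == i

    def test_zero_peaks_zero_spectrum(self):
        grid = common_grid()
        out = synth.gen_pure_spectra(
            [synth.ComponentSpectrumSpec("empty", ())], grid)
        assert np.all(out == 0)

    def test_gaussian_area_matches_closed_form(self):
        # oracle: analytic area of a Gaussian = h * sigma * sqrt(2 pi)
        grid = WavenumberGrid(np.linspace(900.0, 2100.0, 6000))
        h, w = 0.7, 12.0
        spec = synth.ComponentSpectrumSpec("x", ((1500.0, h, w),))
        y = synth.gen_pure_spectra([spec], grid)[0]
        area = np.trapezoid(y, grid.values)
        sigma = w / (2 * np.sqrt(2 * np.log(2)))
        assert area == pytest.approx(h * sigma * np.sqrt(2 * np.pi), rel=0.01)

    def test_peak_outside_grid_rejected(self):
        grid = WavenumberGrid(np.linspace(900.0, 1800.0, 100))
        with pytest.raises(synth.SpecError):
            synth.gen_pure_spectra(synth.DEFAULT_COMPONENT_SPECS, grid)


class TestMacroSpectra:
    def test_noise_free_limit_reproduces_mixture(self, fingerprint_grid,
                                                 fingerprint_pure):
        Y = np.array([[0.45, 0.24, 0.20], [0.40, 0.28, 0.18]])
        residue = np.ones(len(fingerprint_grid)) * 0.1
        ds = synth.gen_macro_spectra(Y, fingerprint_pure, fingerprint_grid,
                                     snr=np.inf, baseline=(0.0, 0.0),
                                     residue=residue, gain_jitter_sd=0.0,
                                     offset_jitter_sd=0.0, ref_noise_sd=0.0)
        expected = Y @ fingerprint_pure + np.outer(1 - Y.sum(1), residue)
        np.testing.assert_allclose(ds.X, expected, atol=1e-12)

    def test_mixture_linearity_in_concentrations(self, fingerprint_grid,
                                                 fingerprint_pure):
        residue = np.zeros(len(fingerprint_grid))
        base = dict(snr=np.inf, baseline=(0.0, 0.0), residue=residue,
                    gain_jitter_sd=0.0, offset_jitter_sd=0.0, ref_noise_sd=0.0)
        Y1 = np.array([[0.2, 0.1, 0.1]])
        a = synth.gen_macro_spectra(Y1, fingerprint_pure, fingerprint_grid, **base)
        b = synth.gen_macro_spectra(2 * Y1, fingerprint_pure, fingerprint_grid, **base)
        np.testing.assert_allclose(b.X, 2 * a.X, atol=1e-12)

    def test_empirical_snr_within_ten_percent(self, fingerprint_grid,
                                              fingerprint_pure):
        Y = np.tile([0.45, 0.24, 0.20], (40, 1))
        residue = np.zeros(len(fingerprint_grid))
        kw = dict(baseline=(0.0, 0.0), residue=residue,
                  gain_jitter_sd=0.0, offset_jitter_sd=0.0, ref_noise_sd=0.0)
        clean = synth.gen_macro_spectra(Y, fingerprint_pure, fingerprint_grid,
                                        snr=np.inf, **kw)
        noisy = synth.gen_macro_spectra(Y, fingerprint_pure, fingerprint_grid,
                                        snr=200.0, seed=3, **kw)
        measured = clean.X.mean() / (noisy.X - clean.X).std()
        assert measured == pytest.approx(200.0, rel=0.10)


class TestSlaveResponse:
    def test_identity_spec_is_noop(self, fingerprint_grid):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.1, 1.0, size=(3, len(fingerprint_grid)))
        resp = synth.SlaveResponseSpec(broadening_fwhm=4.0, shift=0.0,
                                       gain=1.0, offset=0.0, noise_sd=0.0)
        assert resp.is_identity
        np.testing.assert_allclose(
            synth.gen_slave(X, fingerprint_grid, resp), X, atol=1e-12)

    def test_broadening_preserves_interior_peak_area(self):
        grid = WavenumberGrid(np.linspace(900.0, 1800.0, 1200))
        y = np.exp(-0.5 * ((grid.values - 1350.0) / 8.0) ** 2)
        resp = synth.SlaveResponseSpec(shift=0.0, gain=1.0, offset=0.0,
                                       noise_sd=0.0)
        out = synth.gen_slave(y[None, :], grid, resp)[0]
        a0 = np.trapezoid(y, grid.values)
        a1 = np.trapezoid(out, grid.values)
        assert a1 == pytest.approx(a0, rel=0.01)

    def test_default_distortion_changes_spectra(self, fingerprint_grid,
                                                fingerprint_pure):
        X = fingerprint_pure
        out = synth.gen_slave(X, fingerprint_grid,
                              synth.SlaveResponseSpec(), seed=1)
        rmse = np.sqrt(np.mean((out - X) ** 2))
        assert rmse > 0.01

    def test_invalid_specs_rejected(self, fingerprint_grid):
        with pytest.raises(synth.SpecError):
            synth.SlaveResponseSpec(broadening_fwhm=2.0)  # below master res
        with pytest.raises(synth.SpecError):
            synth.SlaveResponseSpec(gain=0.0)
        with pytest.raises(synth.SpecError):
            synth.gen_slave(np.zeros((1, len(fingerprint_grid))),
                            fingerprint_grid,
                            synth.SlaveResponseSpec(shift=2000.0))


class TestHypercube:
    def test_default_geometry_441_pixels(self):
        cube, truth = synth.gen_hypercube(seed=0)
        assert cube.n_pixels == 441
        assert cube.shape == (21, 21, 2800)
        assert truth["cellulose"].shape == (21, 21)

    def test_strand_ordering_in_ground_truth(self):
        cube, truth = synth.gen_hypercube(seed=1)
        m = truth["strand_mask"]
        assert truth["cellulose"][m].mean() > truth["cellulose"][~m].mean()
        assert truth["lignin"][m].mean() > truth["lignin"][~m].mean()

    def test_hemicellulose_contrast_below_third_of_cellulose(self):
        # recomputed from the emitted truth maps, not the design constants
        cube, truth = synth.gen_hypercube(seed=2)
        m = truth["strand_mask"]
        d = {c: abs(truth[c][m].mean() - truth[c][~m].mean())
             for c in COMPONENTS}
        assert d["hemicellulose"] < d["cellulose"] / 3.0

    def test_site_mean_pinning(self):
        target = np.array([0.43, 0.25, 0.21])
        cube, truth = synth.gen_hypercube(site_mean=target, seed=3,
                                          pixel_noise_sd=0.0)
        got = np.array([truth[c].mean() for c in COMPONENTS])
        np.testing.assert_allclose(got, target, atol=1e-6)

    def test_determinism_and_mask_shape_validation(self):
        a, _ = synth.gen_hypercube(seed=4)
        b, _ = synth.gen_hypercube(seed=4)
        np.testing.assert_array_equal(a.data, b.data)
        with pytest.raises(synth.SpecError):
            synth.gen_hypercube(rows=5, cols=5,
                                region_mask=np.zeros((4, 4)), seed=0)
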