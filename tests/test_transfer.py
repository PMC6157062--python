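import numpy as np
import pytest

from conftest import small_design

from lignomap import plsr, sampling, synth, transfer
from lignomap.spectra_io import GridMismatchError, Hypercube, Spectrum, WavenumberGrid


@pytest.fixture()
def site_setup(fingerprint_grid, fingerprint_pure):
    """Small macro dataset + one tiny cube per site on the fingerprint grid."""
    meta, Y = synth.gen_design(small_design(seed=11))
    residue = synth.gen_pure_spectra(
        synth.restrict_specs([synth.RESIDUE_SPEC], 900.0, 1800.0),
        fingerprint_grid)[0]
    ds = synth.gen_macro_spectra(Y, fingerprint_pure, fingerprint_grid,
                                 snr=500.0, seed=12, residue=residue, meta=meta)
    resp = synth.SlaveResponseSpec()
    cubes = {}
    truths = {}
    for i, site in enumerate(synth.SITES):
        rows = [j for j, m in enumerate(ds.meta) if m.site == site]
        cube, truth = synth.gen_hypercube(
            rows=9, cols=9, site=site, grid=fingerprint_grid, resp=resp,
            site_mean=ds.Y[rows].mean(axis=0), seed=13 + i)
        cubes[site] = cube
        truths[site] = truth
    return ds, cubes, truths


class TestMakeRepresentatives:
    def test_three_sites_three_pairs(self, site_setup):
        ds, cubes, _ = site_setup
        reps = transfer.make_representatives(ds, cubes)
        assert reps.master_reps.shape[0] == 3
        assert reps.labels == sorted(cubes)

    def test_master_rep_is_group_mean(self, site_setup):
        ds, cubes, _ = site_setup
        reps = transfer.make_representatives(ds, cubes)
        i = reps.labels.index("MY")
        rows = [j for j, m in enumerate(ds.meta) if m.site == "MY"]
        np.testing.assert_allclose(reps.master_reps[i], ds.X[rows].mean(axis=0),
                                   atol=1e-12)

    def test_cube_rep_equals_brute_force_pixel_loop(self, site_setup):
        ds, cubes, _ = site_setup
        reps = transfer.make_representatives(ds, cubes)
        i = reps.labels.index("BT")
        cube = cubes["BT"]
        acc = np.zeros(len(cube.grid))
        for r in range(cube.data.shape[0]):
            for c in range(cube.data.shape[1]):
                acc += cube.data[r, c]
        np.testing.assert_allclose(reps.slave_reps[i], acc / cube.n_pixels,
                                   atol=1e-10)

    def test_identical_spectra_group_rep_equals_member(self, fingerprint_grid):
        from lignomap.spectra_io import SampleMeta, SpectralDataset
        x = np.linspace(0.1, 0.2, len(fingerprint_grid))
        ds = SpectralDataset(
            X=np.tile(x, (4, 1)), Y=np.full((4, 3), 0.2),
            meta=[SampleMeta("MY", 1, "middle", i + 1) for i in range(4)],
            grid=fingerprint_grid)
        cube = Hypercube(np.tile(x, (2, 2, 1)), fingerprint_grid, pixel_size=10)
        reps = transfer.make_representatives(ds, {"MY": cube})
        np.testing.assert_allclose(reps.master_reps[0], x, atol=1e-12)
        np.testing.assert_allclose(reps.slave_reps[0], x, atol=1e-12)

    def test_missing_group_rejected(self, site_setup):
        ds, cubes, _ = site_setup
        cubes = dict(cubes)
        cubes["NOWHERE"] = cubes["MY"]
        with pytest.raises(transfer.MissingGroupError):
            transfer.make_representatives(ds, cubes)


class TestDSFit:
    def test_self_transfer_is_identity_on_reps(self, site_setup):
        ds, cubes, _ = site_setup
        reps = transfer.make_representatives(ds, cubes)
        same = transfer.RepresentativeSet(reps.master_reps, reps.master_reps,
                                          reps.labels, reps.grid)
        tm = transfer.ds_fit(same)
        out = transfer.ds_apply(reps.master_reps, tm)
        assert np.abs(out - reps.master_reps).max() < 1e-10

    def test_gain_offset_distortion_recovered(self, site_setup):
        ds, cubes, _ = site_setup
        reps = transfer.make_representatives(ds, cubes)
        slave = 0.8 * reps.master_reps + 0.05
        pair = transfer.RepresentativeSet(reps.master_reps, slave,
                                          reps.labels, reps.grid)
        tm = transfer.ds_fit(pair)
        out = transfer.ds_apply(slave, tm)
        assert np.abs(out - reps.master_reps).max() < 1e-8

    def test_underdetermined_system_interpolates_standards(self, site_setup):
        # r=3 pairs, p=600: minimal-norm solution reproduces the standards
        ds, cubes, _ = site_setup
        reps = transfer.make_representatives(ds, cubes)
        tm = transfer.ds_fit(reps)
        out = transfer.ds_apply(reps.slave_reps, tm)
        assert np.abs(out - reps.master_reps).max() < 1e-8

    def test_nonfinite_rejected(self, fingerprint_grid):
        bad = np.full((2, len(fingerprint_grid)), np.nan)
        reps = transfer.RepresentativeSet(bad, bad, ["a", "b"], fingerprint_grid)
        with pytest.raises(ValueError):
            transfer.ds_fit(reps)


class TestDSApply:
    def test_identity_transfer_leaves_spectra_unchanged(self, fingerprint_grid):
        p = len(fingerprint_grid)
        tm = transfer.TransferModel(E=np.eye(p), B=np.zeros(p),
                                    grid=fingerprint_grid, n_reps=0, svd_tol=0)
        s = Spectrum(fingerprint_grid, np.linspace(0, 1, p))
        out = transfer.ds_apply(s, tm)
        np.testing.assert_allclose(out.intensity, s.intensity, atol=1e-12)

    def test_hypercube_shape_preserved(self, site_setup):
        ds, cubes, _ = site_setup
        tm = transfer.ds_fit(transfer.make_representatives(ds, cubes))
        out = transfer.ds_apply(cubes["MY"], tm)
        assert out.shape == cubes["MY"].shape
        assert out.pixel_size == cubes["MY"].pixel_size

    def test_grid_mismatch_rejected(self, site_setup, fingerprint_grid):
        ds, cubes, _ = site_setup
        tm = transfer.ds_fit(transfer.make_representatives(ds, cubes))
        other = WavenumberGrid(np.linspace(900, 1800, 50))
        with pytest.raises(GridMismatchError):
            transfer.ds_apply(Spectrum(other, np.zeros(50)), tm)

    def test_transfer_reduces_spectral_rmse_of_distorted_slaves(self, site_setup):
        # held-out slave spectra: distorted copies of master site means
        ds, cubes, _ = site_setup
        reps = transfer.make_representatives(ds, cubes)
        tm = transfer.ds_fit(reps)
        master = reps.master_reps
        slave = synth.gen_slave(master, ds.grid, synth.SlaveResponseSpec(),
                                seed=21)
        before = np.sqrt(np.mean((slave - master) ** 2))
        after = np.sqrt(np.mean((transfer.ds_apply(slave, tm) - master) ** 2))
        assert after < before


class TestTransferWithPrediction:
    def test_transferred_pixels_predict_better_than_raw(self, site_setup):
        ds, cubes, truths = site_setup
        y = ds.y("cellulose")
        split = sampling.allocate(y)
        model = plsr.fit(ds.X[split.calibration_idx], y[split.calibration_idx],
                         n_lv=6)
        tm = transfer.ds_fit(transfer.make_representatives(ds, cubes))
        err_t, err_r = [], []
        for site, cube in cubes.items():
            truth = truths[site]["cellulose"].ravel()
            P = cube.pixel_matrix()
            err_t.append(model.predict(transfer.ds_apply(P, tm)) - truth)
            err_r.append(model.predict(P) - truth)
        rmse_t = np.sqrt(np.mean(np.concatenate(err_t) ** 2))
        rmse_r = np.sqrt(np.mean(np.concatenate(err_r) ** 2))
        assert rmse_t < rmse_r

    def test_persistence_round_trip(self, site_setup, tmp_path):
        ds, cubes, _ = site_setup
        tm = transfer.ds_fit(transfer.make_representatives(ds, cubes))
        transfer.save_transfer(tm, str(tmp_path / "tm.npz"))
        back = transfer.load_transfer(str(tmp_path / "tm.npz"))
        np.testing.assert_array_equal(back.E, tm.E)
        np.testing.assert_array_equal(back.B, tm.B)
        assert back.grid == tm.grid and back.n_reps == tm.n_reps
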