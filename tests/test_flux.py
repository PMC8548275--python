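import numpy as np
import pandas as pd
import pytest
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter, map_coordinates

from gonad.flux import (
    PivParams,
    SignalQualityError,
    cell_volume_flux,
    fl_per_min_to_um3_per_s,
    flux_from_field,
    infer_J,
    infer_S,
    piv_displacement,
    um3_per_s_to_fl_per_min,
    zero_crossing_x,
)
from gonad.synthetic import generate_cell_table, generate_image_pair, generate_velocity_field, ground_truth_profiles
from gonad.types import GeometryError, VelocityField


def _speckle(shape=(64, 128), seed=0, sigma=1.0):
    return gaussian_filter(np.random.default_rng(seed).uniform(size=shape), sigma)


def _warp(frame, dc, dr=0.0):
    rows, cols = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]].astype(float)
    return map_coordinates(frame, [rows - dr, cols - dc], order=1, mode="nearest")


PIV = PivParams(template_px=16, overlap_px=8, frame_interval=1.0, pixel_size=1.0)


class TestPiv:
    def test_identical_frames_zero_displacement(self):
        # zero to within sub-pixel refinement accuracy (~0.05 px bias)
        a = _speckle()
        field = piv_displacement(a, a, PIV)
        assert np.abs(field.u).max() < 0.1
        assert np.abs(field.v).max() < 0.1
        assert np.abs(field.u).mean() < 0.02

    def test_uniform_two_pixel_shift(self):
        a = _speckle()
        field = piv_displacement(a, _warp(a, 2.0), PIV)
        inner = field.u[1:-1, 1:-1]
        assert np.abs(inner - 2.0).max() < 0.2

    def test_subpixel_half_shift(self):
        a = _speckle(seed=3)
        field = piv_displacement(a, _warp(a, 3.5), PIV)
        inner = field.u[1:-1, 2:-2]
        assert np.abs(inner - 3.5).max() < 0.3

    def test_rotated_geometry_gives_transverse(self):
        a = _speckle(shape=(128, 64), seed=4)
        field = piv_displacement(a, _warp(a, 0.0, dr=2.0), PIV)
        inner_v = field.v[1:-1, 1:-1]
        inner_u = field.u[1:-1, 1:-1]
        assert np.abs(inner_v - 2.0).max() < 0.2
        assert np.abs(inner_u).max() < 0.2

    def test_velocity_scaling(self):
        a = _speckle(seed=5)
        params = PivParams(template_px=16, overlap_px=8, frame_interval=4.0, pixel_size=0.5)
        field = piv_displacement(a, _warp(a, 2.0), params)
        # 2 px * 0.5 um / 4 s = 0.25 um/s
        assert field.u[2, 3] == pytest.approx(0.25, abs=0.05)

    def test_all_invalid_raises(self):
        flat = np.zeros((64, 64))
        with pytest.raises(SignalQualityError):
            piv_displacement(flat, flat, PIV)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            piv_displacement(_speckle(), _speckle(shape=(32, 32)), PIV)

    def test_invalid_vectors_filled_and_counted(self):
        a = _speckle(seed=6)
        b = _warp(a, 1.0)
        a[:20, :20] = 0.0  # featureless corner -> invalid blocks
        b[:20, :20] = 0.0
        field = piv_displacement(a, b, PIV)
        assert field.n_filled > 0
        assert np.isfinite(field.u).all()

    def test_known_shift_through_generator_images(self, small_cfg):
        import dataclasses

        # boost the flux so displacements are a resolvable 2-3 px per frame
        cfg = dataclasses.replace(small_cfg, rachis_flux_peak=400.0)
        truth = ground_truth_profiles(cfg)
        field = generate_velocity_field(cfg, truth)
        frame_a, frame_b = generate_image_pair(field, cfg)
        params = PivParams(
            template_px=16, overlap_px=8,
            frame_interval=cfg.frame_interval, pixel_size=cfg.pixel_size,
        )
        est = piv_displacement(frame_a, frame_b, params, mask=field.mask)
        # compare estimated speeds with the generator's field at block centres
        step = params.step_px
        true_blocks = field.u[8::step, 8::step][: est.u.shape[0], : est.u.shape[1]]
        sel = np.abs(true_blocks) > 0.3 * np.abs(field.u).max()
        err = np.abs(est.u[: true_blocks.shape[0], : true_blocks.shape[1]][sel] - true_blocks[sel])
        # 0.2 px accuracy in velocity units
        assert np.median(err) < 0.2 * params.pixel_size / params.frame_interval


class TestFluxFromField:
    def _plug(self, v0=2.0, n=40):
        return VelocityField(
            u=np.full((n, n), v0),
            v=np.zeros((n, n)),
            mask=np.ones((n, n), bool),
            centreline=np.column_stack([np.arange(n) + 0.5, np.full(n, n / 2.0)]),
            pixel_size=1.0,
        )

    def test_plug_flow_closed_form(self):
        a = 5.0
        q = flux_from_field(self._plug(2.0), a, 40.0)
        expected = um3_per_s_to_fl_per_min(np.pi * a**2 * 2.0)
        assert q["Qr"].iloc[20] == pytest.approx(expected, rel=1e-6)

    def test_poiseuille_closed_form(self):
        n, a, vmax = 80, 15.0, 3.0
        r = np.abs(np.arange(n) + 0.5 - n / 2.0)
        u = np.where(r < a, vmax * (1 - (r / a) ** 2), 0.0)[:, None] * np.ones((1, n))
        field = VelocityField(
            u=u, v=np.zeros_like(u), mask=u > 0,
            centreline=np.column_stack([np.arange(n) + 0.5, np.full(n, n / 2.0)]),
            pixel_size=1.0,
        )
        q = flux_from_field(field, a, float(n))
        expected = um3_per_s_to_fl_per_min(np.pi * a**2 * vmax / 2.0)
        assert q["Qr"].iloc[40] == pytest.approx(expected, rel=0.01)

    def test_short_centreline_raises(self):
        field = self._plug()
        field.centreline = field.centreline[:10]
        with pytest.raises(GeometryError):
            flux_from_field(field, 5.0, 40.0)

    def test_negative_radius_raises(self):
        with pytest.raises(GeometryError):
            flux_from_field(self._plug(), -1.0, 40.0)

    def test_low_confidence_tail_flagged(self):
        q = flux_from_field(self._plug(), 5.0, 40.0)
        assert q["low_confidence"].iloc[-1]
        assert not q["low_confidence"].iloc[0]

    def test_distal_cutoff_for_apoptosis_inhibited_samples(self):
        from gonad.flux import CED3_X_MIN

        q = flux_from_field(self._plug(), 5.0, 40.0, x_min=CED3_X_MIN)
        assert q["x"].min() >= CED3_X_MIN


class TestCellVolumeFlux:
    def test_zero_velocity(self, default_cells):
        grid = np.linspace(0, 1, 51)
        out = cell_volume_flux(default_cells, 0.0, grid, 250.0)
        assert (out["Qc"] == 0).all()

    def test_uniform_density_and_velocity_constant_flux(self):
        rng = np.random.default_rng(0)
        cells = pd.DataFrame(
            {
                "gonad_id": "g0",
                "x": rng.uniform(0, 1, 60000),
                "volume_fl": 100.0,
                "alive": True,
            }
        )
        grid = np.linspace(0.05, 0.95, 19)
        out = cell_volume_flux(cells, 6.0, grid, 200.0)
        qc = out["Qc"].to_numpy()
        assert np.ptp(qc) / qc.mean() < 0.1

    def test_roundtrip_against_generator_bookkeeping(self):
        from gonad.config import SyntheticConfig

        # enough cells that per-bin density noise sits below the 5% bar
        cfg = SyntheticConfig(seed=11, cells_per_gonad=900)
        cells = generate_cell_table(cfg)
        truth = ground_truth_profiles(cfg)
        grid = truth["x"].to_numpy()
        out = cell_volume_flux(cells, truth["v_c"].to_numpy(), grid, cfg.gonad_length)
        sel = np.abs(truth["Qc"]) > 0.2 * np.abs(truth["Qc"]).max()
        rel = np.abs(out["Qc"][sel] - truth["Qc"][sel]) / np.abs(truth["Qc"][sel])
        assert np.median(rel) < 0.05


class TestDerivatives:
    def test_linear_qr_constant_j(self):
        x = np.linspace(0, 1, 101)
        prof = pd.DataFrame({"x": x, "Qr": 3.0 * x})
        out = infer_J(prof)
        inner = out["J"].to_numpy()[10:-10]
        np.testing.assert_allclose(inner, 3.0, rtol=1e-8)

    def test_j_crosses_zero_at_qr_peak(self):
        x = np.linspace(0, 1, 201)
        prof = pd.DataFrame({"x": x, "Qr": np.sin(np.pi * x)})
        out = infer_J(prof)
        crossing = zero_crossing_x(x, out["J"].to_numpy())
        assert crossing == pytest.approx(0.5, abs=0.01)

    def test_cumtrapz_identity_machine_precision(self, default_truth):
        prof = default_truth[["x", "Qr"]].copy()
        out = infer_J(prof)
        x = out["x"].to_numpy()
        rebuilt = out["Qr_smooth"].iloc[0] + cumulative_trapezoid(out["J"], x, initial=0.0)
        np.testing.assert_allclose(rebuilt, out["Qr_smooth"], rtol=0, atol=1e-12)

    def test_constant_total_flux_zero_uptake(self):
        x = np.linspace(0, 1, 101)
        prof = pd.DataFrame({"x": x, "Qr": np.full(101, 2.0), "Qc": np.full(101, 5.0)})
        out = infer_S(prof)
        np.testing.assert_allclose(out["S"], 0.0, atol=1e-10)

    def test_recovers_planted_uptake_zero_crossing(self, default_cfg, default_truth):
        prof = default_truth[["x", "Qr", "Qc"]].copy()
        out = infer_S(prof)
        crossing = zero_crossing_x(out["x"].to_numpy(), out["S"].to_numpy())
        assert crossing == pytest.approx(default_cfg.transition_position, abs=0.05)

    def test_pure_noise_band_contains_zero(self, rng):
        x = np.linspace(0, 1, 101)
        reps = rng.normal(0, 1.0, size=(12, 101))
        prof = pd.DataFrame({"x": x, "Qr": reps.mean(axis=0), "Qc": 0.0})
        out = infer_S(prof, replicates=reps, n_boot=200, rng=rng)
        contains = (out["S_lo"] <= 0) & (out["S_hi"] >= 0)
        assert contains.mean() >= 0.9

    def test_noise_widens_bootstrap_bands(self, rng):
        x = np.linspace(0, 1, 101)
        base = np.sin(np.pi * x)
        widths = []
        for noise in (0.01, 0.05, 0.2):
            reps = base + rng.normal(0, noise, size=(10, 101))
            out = infer_J(pd.DataFrame({"x": x, "Qr": reps.mean(axis=0)}),
                          replicates=reps, n_boot=100, rng=np.random.default_rng(5))
            widths.append(float((out["J_hi"] - out["J_lo"]).mean()))
        assert widths[0] < widths[1] < widths[2]


def test_unit_roundtrip():
    q = np.array([0.0, 1.0, 17.3])
    np.testing.assert_allclose(fl_per_min_to_um3_per_s(um3_per_s_to_fl_per_min(q)), q, rtol=1e-15)
    assert um3_per_s_to_fl_per_min(1.0) == 60.0
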