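"""Flow fields, circular correlation, decomposition, streamlines and
cross-layer motion statistics."""

import numpy as np
import pytest

from embryoflow import EmbryoSimConfig, simulate_embryo_tracks, to_cartesian
from embryoflow import flows as fl
from embryoflow import geometry as geo
from embryoflow.tracks import Track, TrackSet


def _track(positions, cell_id=0, layer="epiblast"):
    positions = np.asarray(positions, float)
    return Track(
        cell_id=cell_id, frames=np.arange(len(positions)),
        positions=positions, layers=layer,
    )


def _make_field(angles, weights, grid=None):
    """FlowField with one interval from an (n_v, n_u) array of angles."""
    angles = np.asarray(angles, float)
    nv, nu = angles.shape
    if grid is None:
        grid = fl.GridSpec(n_u=nu, n_v=nv, n_intervals=1, frame_range=(0, 9))
    vectors = np.zeros((1, nv, nu, 2))
    vectors[0, ..., 0] = np.cos(angles)
    vectors[0, ..., 1] = np.sin(angles)
    w = np.asarray(weights, int).reshape(1, nv, nu)
    vectors[0][w[0] == 0] = 0.0
    return fl.FlowField(grid=grid, vectors=vectors, magnitude=(w[0] > 0)[None].astype(float), weights=w)


class TestBuildFlowField:
    def test_default_grid_layout(self, small_embryo, frame):
        _, obs, _ = small_embryo
        field = fl.build_flow_field(obs, frame)
        assert field.grid.n_u == 40 and field.grid.n_v == 40
        assert field.grid.n_intervals == 10

    def test_single_straight_track(self, frame):
        # constant direction within one grid cell: unit vector, full count
        n = 6
        theta = 0.5 + np.arange(n) * 1e-4
        pos = to_cartesian(np.full(n, 350.0), theta, np.full(n, -0.3), frame)
        ts = TrackSet([_track(pos)], 120.0)
        field = fl.build_flow_field(ts, frame)
        populated = field.weights > 0
        assert field.weights.sum() == n - 1
        vec = field.vectors[populated]
        assert np.allclose(np.linalg.norm(vec, axis=-1), 1.0)
        # eastward motion: +u direction
        np.testing.assert_allclose(vec, [[1.0, 0.0]] * populated.sum(), atol=1e-6)

    def test_weight_conservation(self, small_embryo, frame):
        _, obs, _ = small_embryo
        field = fl.build_flow_field(obs, frame)
        n_displacements = sum(len(t) - 1 for t in obs)
        # noise keeps every displacement non-degenerate here
        assert field.weights.sum() == n_displacements

    def test_pure_epiboly_aligns_with_reference(self, frame):
        cfg = EmbryoSimConfig(
            n_cells=200, t_end=8.0, seed=1, noise_sd=0.0,
            epiboly_rate=0.4, convergence_rate=0.0, internalize_fraction=0.0,
        )
        obs, _ = simulate_embryo_tracks(cfg)
        field = fl.build_flow_field(obs, frame)
        refs = fl.reference_directions_uv(field.grid)
        populated = field.weights > 0
        cos_angle = np.einsum("tijk,ijk->tij", field.vectors, refs["epi"])[populated]
        assert np.all(np.degrees(np.arccos(np.clip(cos_angle, -1, 1))) < 5.0)


class TestAverageFlowFields:
    def test_identical_fields_unchanged_weights_summed(self):
        rng = np.random.default_rng(0)
        f = _make_field(rng.uniform(-np.pi, np.pi, (4, 4)), rng.integers(1, 5, (4, 4)))
        avg = fl.average_flow_fields([f, f])
        np.testing.assert_allclose(avg.vectors, f.vectors, atol=1e-12)
        np.testing.assert_array_equal(avg.weights, 2 * f.weights)

    def test_opposite_vectors_flagged_incoherent(self):
        a = _make_field(np.zeros((2, 2)), np.ones((2, 2)))
        b = _make_field(np.full((2, 2), np.pi), np.ones((2, 2)))
        avg = fl.average_flow_fields([a, b])
        np.testing.assert_allclose(avg.magnitude, 0.0, atol=1e-12)
        np.testing.assert_allclose(avg.vectors, 0.0, atol=1e-12)

    def test_layout_mismatch_rejected(self):
        a = _make_field(np.zeros((2, 2)), np.ones((2, 2)))
        b = _make_field(np.zeros((3, 3)), np.ones((3, 3)))
        with pytest.raises(ValueError, match="layout"):
            fl.average_flow_fields([a, b])

    def test_averaging_reduces_angular_error(self, frame):
        # three embryos, same dynamics different seeds: the average field is
        # closer to the programmed epiboly direction than single fields
        fields = []
        for seed in (1, 2, 3):
            cfg = EmbryoSimConfig(
                n_cells=120, t_end=8.0, seed=seed, noise_sd=3.0,
                epiboly_rate=0.3, convergence_rate=0.0, internalize_fraction=0.0,
            )
            obs, _ = simulate_embryo_tracks(cfg)
            fields.append(fl.build_flow_field(obs, frame))
        avg = fl.average_flow_fields(fields)
        refs = fl.reference_directions_uv(avg.grid)

        def rms_angle(field):
            populated = field.weights > 0
            c = np.einsum("tijk,ijk->tij", field.vectors, refs["epi"])[populated]
            return np.sqrt(np.mean(np.arccos(np.clip(c, -1, 1)) ** 2))

        assert rms_angle(avg) < min(rms_angle(f) for f in fields)


class TestCircularCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        f = _make_field(rng.uniform(-np.pi, np.pi, (6, 6)), rng.integers(1, 9, (6, 6)))
        rho = fl.circular_correlation(f, f)["rho"]
        np.testing.assert_allclose(rho, 1.0, atol=1e-12)

    def test_pi_rotation_is_minus_one(self):
        rng = np.random.default_rng(2)
        angles = rng.uniform(-np.pi, np.pi, (6, 6))
        w = rng.integers(1, 9, (6, 6))
        a = _make_field(angles, w)
        b = _make_field(angles + np.pi, w)
        rho = fl.circular_correlation(a, b)["rho"]
        np.testing.assert_allclose(rho, -1.0, atol=1e-12)

    def test_symmetric_and_2pi_invariant(self):
        rng = np.random.default_rng(3)
        aa = rng.uniform(-np.pi, np.pi, (5, 5))
        bb = rng.uniform(-np.pi, np.pi, (5, 5))
        w = rng.integers(1, 5, (5, 5))
        a, b = _make_field(aa, w), _make_field(bb, w)
        r1 = fl.circular_correlation(a, b)["rho"].iloc[0]
        r2 = fl.circular_correlation(b, a)["rho"].iloc[0]
        assert r1 == pytest.approx(r2, abs=1e-12)
        b_shift = _make_field(bb + 2 * np.pi, w)
        r3 = fl.circular_correlation(a, b_shift)["rho"].iloc[0]
        assert r3 == pytest.approx(r1, abs=1e-9)

    def test_independent_fields_near_zero(self):
        rng = np.random.default_rng(4)
        shape = (25, 40)  # 1000 sites
        a = _make_field(rng.uniform(-np.pi, np.pi, shape), np.ones(shape))
        b = _make_field(rng.uniform(-np.pi, np.pi, shape), np.ones(shape))
        rho = fl.circular_correlation(a, b)["rho"].iloc[0]
        assert abs(rho) < 3.0 / np.sqrt(1000)

    def test_zero_variance_flagged_nan(self):
        a = _make_field(np.zeros((3, 3)), np.ones((3, 3)))  # sin(alpha) = 0
        b = _make_field(np.full((3, 3), 0.5), np.ones((3, 3)))
        assert np.isnan(fl.circular_correlation(a, b)["rho"].iloc[0])


class TestDecomposition:
    def test_proportion_closed_forms(self):
        assert fl.proportion_from_projection(1.0) == pytest.approx(1.0, abs=1e-12)
        assert fl.proportion_from_projection(0.0) == pytest.approx(0.0, abs=1e-12)
        assert fl.proportion_from_projection(np.cos(np.pi / 4)) == pytest.approx(0.5, abs=1e-12)
        assert fl.proportion_from_projection(-0.7) == 0.0

    def test_pure_epiboly_field_limits(self):
        # flow straight along +v: p_epi = 1 everywhere, p_conv = 0
        f = _make_field(np.full((4, 4), np.pi / 2), np.ones((4, 4)))
        dec = fl.decompose_movement(f)
        assert dec.o_epi[0] == pytest.approx(1.0, abs=1e-12)
        assert dec.o_conv[0] == pytest.approx(0.0, abs=1e-12)

    def test_o_is_convex_combination(self, small_embryo, frame):
        _, obs, _ = small_embryo
        field = fl.build_flow_field(obs, frame)
        dec = fl.decompose_movement(field)
        for t in range(field.grid.n_intervals):
            populated = field.weights[t] > 0
            if populated.any() and np.isfinite(dec.o_epi[t]):
                assert dec.p_epi[t][populated].min() - 1e-12 <= dec.o_epi[t]
                assert dec.o_epi[t] <= dec.p_epi[t][populated].max() + 1e-12

    def test_programmed_switch_recovered(self, frame):
        # epiboly until 9 hpf then convergence: o_epi and o_conv must cross
        # within one interval of the programmed switch
        def epi_rate(t):
            return np.where(np.asarray(t) < 9.0, 0.4, 0.0)

        def conv_rate(t):
            return np.where(np.asarray(t) < 9.0, 0.0, 0.4)

        for seed in (1, 2, 3):
            cfg = EmbryoSimConfig(
                n_cells=200, t_end=14.0, seed=seed, noise_sd=0.5,
                epiboly_rate=epi_rate, convergence_rate=conv_rate,
                internalize_fraction=0.0,
            )
            obs, _ = simulate_embryo_tracks(cfg)
            field = fl.build_flow_field(obs, frame)
            dec = fl.decompose_movement(field)
            diff = dec.o_epi - dec.o_conv
            crossings = np.flatnonzero(np.diff(np.sign(diff)) != 0)
            assert len(crossings) >= 1
            lo, hi = obs.frame_range()
            switch_frame = (9.0 - cfg.t_start) * 3600.0 / cfg.frame_interval
            switch_interval = field.grid.interval_of(np.array([switch_frame]))[0]
            assert abs(crossings[0] - switch_interval) <= 1


class TestStreamlines:
    def test_uniform_eastward_field_gives_horizontal_lines(self):
        f = _make_field(np.zeros((8, 8)), np.ones((8, 8)))
        lines = fl.density_weighted_streamlines(f, interval=0)
        assert lines
        for s in lines:
            v_coords = s["points"][:, 1]
            np.testing.assert_allclose(v_coords, v_coords[0], atol=1e-9)
            du = np.diff(s["points"][:, 0])
            assert np.all(du > 0)

    def test_width_proportional_to_count_at_same_latitude(self):
        w = np.ones((4, 4))
        w[2, 1] = 2.0  # double count, same row (same phi)
        f = _make_field(np.zeros((4, 4)), w)
        lines = fl.density_weighted_streamlines(f, interval=0)
        by_cell = {s["start_cell"]: s["width"] for s in lines}
        assert by_cell[(2, 1)] == pytest.approx(2.0 * by_cell[(2, 2)])

    def test_uniform_sphere_density_gives_uniform_corrected_widths(self, frame):
        # uniform points on the sphere, unit eastward flow: corrected widths
        # must not trend with latitude row
        rng = np.random.default_rng(5)
        phi_lim = 1.2
        v_max = float(np.arctanh(np.sin(phi_lim)))
        n_v, n_u = 12, 8
        grid = fl.GridSpec(
            n_u=n_u, n_v=n_v, n_intervals=1, frame_range=(0, 1),
            v_range=(-v_max, v_max),
        )
        n = 120_000
        phi = np.arcsin(rng.uniform(-1, 1, n))
        theta = rng.uniform(-np.pi, np.pi, n)
        keep = np.abs(phi) < phi_lim
        u, v = geo.mercator_project(theta[keep], phi[keep])
        iu, iv = grid.cell_of(u, v)
        weights = np.zeros((1, n_v, n_u), dtype=int)
        np.add.at(weights, (np.zeros_like(iu), iv, iu), 1)
        vectors = np.zeros((1, n_v, n_u, 2))
        vectors[0, ..., 0] = 1.0
        f = fl.FlowField(
            grid=grid, vectors=vectors, magnitude=np.ones((1, n_v, n_u)),
            weights=weights,
        )
        lines = fl.density_weighted_streamlines(f, interval=0)
        widths = np.zeros((n_v, n_u))
        for s in lines:
            widths[s["start_cell"]] = s["width"]
        row_means = widths.mean(axis=1)
        overall = row_means.mean()
        # MC noise per row plus a small allowance for the finite band width
        # of the central sec^2 evaluation
        rel_sd = 1.0 / np.sqrt(weights[0].sum(axis=1))
        assert np.all(
            np.abs(row_means - overall) < overall * (4 * rel_sd + 0.02)
        )
        # the uncorrected counts vary several-fold across latitude rows
        raw_rows = weights[0].sum(axis=1)
        assert raw_rows.max() / raw_rows.min() > 2.0

    def test_seed_in_empty_cell_not_emitted(self):
        w = np.ones((4, 4))
        w[0, 0] = 0
        f = _make_field(np.zeros((4, 4)), w)
        lines = fl.density_weighted_streamlines(f, interval=0)
        assert (0, 0) not in {s["start_cell"] for s in lines}
        assert len(lines) == 15


class TestLocalMotionCorrelation:
    def _shared_motion_tracks(self, frame, jitter, seed, n=60, layer="epiblast", id0=0):
        rng = np.random.default_rng(seed)
        tracks = []
        n_frames = 8
        for i in range(n):
            r0, th0, ph0 = 340.0, rng.uniform(-2, 2), rng.uniform(-1.0, 0.5)
            base = to_cartesian(r0, th0, ph0, frame)
            drift = np.array([1.0, 0.5, -0.8]) * 2.0  # shared Cartesian motion
            pos = base + np.outer(np.arange(n_frames), drift)
            pos = pos + rng.normal(0, jitter, pos.shape)
            tracks.append(_track(pos, cell_id=id0 + i, layer=layer))
        return TrackSet(tracks, 120.0)

    def test_shared_motion_high_correlation(self, frame):
        ts = self._shared_motion_tracks(frame, jitter=0.01, seed=6)
        df = fl.local_motion_correlation(ts, ts, frame, window_s=600.0)
        assert not df.empty
        for comp in ("rho_r", "rho_theta", "rho_phi"):
            assert df[comp].mean() > 0.9

    def test_independent_motion_near_zero(self, frame):
        a = self._shared_motion_tracks(frame, jitter=5.0, seed=7, n=100)
        # B: same geometry, motions replaced by independent noise
        rng = np.random.default_rng(8)
        b_tracks = []
        for i, t in enumerate(a):
            pos = t.positions[0] + rng.normal(0, 5.0, t.positions.shape)
            b_tracks.append(_track(pos, cell_id=10_000 + i))
        b = TrackSet(b_tracks, 120.0)
        df = fl.local_motion_correlation(a, b, frame, window_s=600.0)
        n_pairs = df["n_pairs"].iloc[0]
        for comp in ("rho_r", "rho_theta", "rho_phi"):
            assert np.all(np.abs(df[comp]) < 4.0 / np.sqrt(n_pairs))


class TestRelativeLayerMotion:
    def _layer(self, frame, drift_phi_um_min, layer, id0, seed, n=200, n_frames=20):
        rng = np.random.default_rng(seed)
        tracks = []
        for i in range(n):
            r = 340.0
            th = rng.uniform(-np.pi, np.pi)
            ph = rng.uniform(-1.0, 0.5)
            phs = ph + np.arange(n_frames) * drift_phi_um_min * 2.0 / r
            pos = to_cartesian(np.full(n_frames, r), np.full(n_frames, th), phs, frame)
            pos = pos + rng.normal(0, 0.5, pos.shape)
            tracks.append(_track(pos, cell_id=id0 + i, layer=layer))
        return TrackSet(tracks, 120.0)

    def test_identical_motion_gives_zero_residual(self, frame):
        epi = self._layer(frame, 0.5, "epiblast", 0, seed=9)
        meso = self._layer(frame, 0.5, "mesendoderm", 10_000, seed=10)
        res = fl.relative_layer_motion(meso, epi, frame, eval_every=3)
        for comp in ("d_r", "d_theta", "d_phi"):
            assert abs(res["residuals"][comp].mean()) < 1.0  # noise floor

    def test_animal_ward_drift_recovered(self, frame):
        # meso drifts 1 um/min toward the animal pole relative to epi:
        # mean residual latitude component ~ -10 um per 10-min window
        epi = self._layer(frame, 0.0, "epiblast", 0, seed=11)
        meso = self._layer(frame, -1.0, "mesendoderm", 10_000, seed=12)
        res = fl.relative_layer_motion(meso, epi, frame, eval_every=3)
        assert res["residuals"]["d_phi"].mean() == pytest.approx(-10.0, rel=0.1)

    def test_inward_drift_shifts_radial_density_negative(self, frame):
        rng = np.random.default_rng(13)
        epi = self._layer(frame, 0.0, "epiblast", 0, seed=14)
        meso_tracks = []
        n_frames = 20
        for i in range(200):
            th = rng.uniform(-np.pi, np.pi)
            ph = rng.uniform(-1.0, 0.5)
            rs = 340.0 - np.arange(n_frames) * 1.0  # inward 0.5 um/min at 2-min frames
            pos = to_cartesian(rs, np.full(n_frames, th), np.full(n_frames, ph), frame)
            meso_tracks.append(_track(pos + rng.normal(0, 0.3, pos.shape), cell_id=20_000 + i))
        meso = TrackSet(meso_tracks, 120.0)
        res = fl.relative_layer_motion(meso, epi, frame, eval_every=3)
        assert res["residuals"]["d_r"].mean() < -3.0
        kdes = res["radial_kde"]
        assert kdes  # density summaries exist for populated intervals
        for kde in kdes.values():
            xs = np.linspace(-20, 20, 201)
            dens = kde(xs)
            assert xs[np.argmax(dens)] < 0  # mass shifted negative

    def test_isolated_cells_excluded_and_counted(self, frame):
        epi = self._layer(frame, 0.0, "epiblast", 0, seed=15, n=30)
        # one meso cell far outside the epiblast cap
        pos = to_cartesian(np.full(20, 340.0), np.zeros(20), np.full(20, 1.4), frame)
        meso = TrackSet([_track(pos, cell_id=99_999)], 120.0)
        res = fl.relative_layer_motion(meso, epi, frame, neighbor_cutoff=50.0, eval_every=5)
        assert res["n_excluded"] > 0
        assert res["residuals"].empty


def test_flow_field_save_load_round_trip(tmp_path, small_embryo, frame):
    _, obs, _ = small_embryo
    field = fl.build_flow_field(obs, frame)
    field.save(tmp_path / "field")
    back = fl.FlowField.load(tmp_path / "field")
    assert back.grid.layout_equal(field.grid)
    np.testing.assert_array_equal(back.weights, field.weights)
    np.testing.assert_allclose(back.vectors, field.vectors)
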