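"""Simulator contracts: determinism, boundary containment, sorting sign,
image fixtures with exact ground truth, TrackMate fixture round trips."""

import numpy as np
import pytest

from spherosort.geometry import (
    SpheroidGeometry,
    classify_compartment,
    delta_distance_index,
)
from spherosort.simulate import (
    ConfigurationError,
    PopulationParams,
    SimulationConfig,
    SyntheticImageSpec,
    brownian_polar_tracks,
    generate_degradation_image,
    generate_trackmate_fixture,
    simulate_spheroid_population,
)
from spherosort.tracks import close_gaps, filter_tracks, read_tracks

GEOM = SpheroidGeometry(center=(0.0, 0.0), a=200.0, b=150.0)


def small_config(**kw):
    defaults = dict(
        geometry=GEOM,
        populations=(
            PopulationParams(name="A", n_cells=10, speed=0.5, persistence_time=30.0),
        ),
        dt=10.0,
        duration=600.0,
        seed=7,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(dt=0.0)

    def test_duration_below_dt_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(duration=5.0)

    def test_negative_speed_rejected(self):
        with pytest.raises(ConfigurationError):
            PopulationParams(name="A", n_cells=1, speed=-1.0, persistence_time=10.0)

    def test_mixing_ratio_overrides_counts(self):
        cfg = small_config(
            populations=(
                PopulationParams(name="A", n_cells=51, speed=0.1, persistence_time=10.0),
                PopulationParams(name="B", n_cells=0, speed=0.1, persistence_time=10.0),
            ),
            mixing_ratio=(1, 50),
        )
        assert cfg.effective_counts() == [1, 50]


class TestTrajectories:
    def test_zero_speed_is_fixed_point(self):
        cfg = small_config(
            populations=(
                PopulationParams(name="A", n_cells=8, speed=0.0, persistence_time=10.0),
            )
        )
        tracks, geom = simulate_spheroid_population(cfg)
        for tr in tracks:
            assert np.all(tr.xy == tr.xy[0])
            assert delta_distance_index(tr, geom)["value"] == 0.0

    def test_seed_determinism_byte_identical(self):
        cfg = small_config()
        t1, _ = simulate_spheroid_population(cfg)
        t2, _ = simulate_spheroid_population(cfg)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.xy, b.xy)
            assert a.track_id == b.track_id

    def test_different_seeds_differ(self):
        t1, _ = simulate_spheroid_population(small_config(seed=1))
        t2, _ = simulate_spheroid_population(small_config(seed=2))
        assert not all(np.array_equal(a.xy, b.xy) for a, b in zip(t1, t2))

    @pytest.mark.parametrize("mode", ["sticky", "reflecting"])
    def test_confining_boundaries_contain_all_positions(self, mode):
        cfg = small_config(
            populations=(
                PopulationParams(
                    name="A",
                    n_cells=15,
                    speed=2.0,
                    persistence_time=60.0,
                    radial_bias=1.0,
                    boundary_mode=mode,
                    initial_placement="edge-only",
                ),
            ),
            duration=1200.0,
        )
        tracks, geom = simulate_spheroid_population(cfg)
        for tr in tracks:
            assert geom.contains(tr.xy).all()

    def test_placement_regions(self):
        for placement, expected in [("core-only", "core"), ("edge-only", "edge")]:
            cfg = small_config(
                populations=(
                    PopulationParams(
                        name="A",
                        n_cells=30,
                        speed=0.0,
                        persistence_time=10.0,
                        initial_placement=placement,
                    ),
                ),
                duration=10.0,
            )
            tracks, geom = simulate_spheroid_population(cfg)
            for tr in tracks:
                assert classify_compartment(tr.xy[0], geom) == expected

    def test_persistent_core_cells_move_outward(self):
        # Monte-Carlo sign check against the construction: sticky + outward
        # drift from a core-only start must raise DI on average
        cfg = small_config(
            populations=(
                PopulationParams(
                    name="pers",
                    n_cells=100,
                    speed=0.5,
                    persistence_time=60.0,
                    radial_bias=0.5,
                    boundary_mode="sticky",
                    initial_placement="core-only",
                ),
            ),
            duration=2640.0,
            seed=11,
        )
        tracks, geom = simulate_spheroid_population(cfg)
        ddis = [delta_distance_index(t, geom)["value"] for t in tracks]
        finals = [delta_distance_index(t, geom)["final_DI"] for t in tracks]
        inits = [delta_distance_index(t, geom)["initial_DI"] for t in tracks]
        assert np.mean(ddis) > 0
        assert np.mean(finals) > np.mean(inits)

    def test_sticky_edge_fraction_non_decreasing_on_average(self):
        cfg = small_config(
            populations=(
                PopulationParams(
                    name="pers",
                    n_cells=80,
                    speed=0.5,
                    persistence_time=60.0,
                    radial_bias=0.5,
                    boundary_mode="sticky",
                    initial_placement="core-only",
                ),
            ),
            duration=2640.0,
            seed=3,
        )
        tracks, geom = simulate_spheroid_population(cfg)
        n_frames = len(tracks[0].spots)
        frac = []
        for k in range(0, n_frames, 24):  # every 4 h
            pos = np.array([t.xy[k] for t in tracks])
            frac.append(np.mean(classify_compartment(pos, geom) == "edge"))
        # monotone on the coarse (4 h) time grid up to small MC wiggle
        assert all(b >= a - 0.05 for a, b in zip(frac, frac[1:]))
        assert frac[-1] > frac[0]

    def test_brownian_radial_walk_msd_slope(self):
        from spherosort.motility import compute_msd

        # time-averaged estimator: every window of each track contributes,
        # so the per-lag slope concentrates tightly around 2D
        pts = brownian_polar_tracks(400, diffusion=1.0, dt=10.0, duration=2640.0, seed=9)
        curve = compute_msd(pts, "radial", max_lag=180.0, time_averaged=True)
        sel = curve.lags > 0
        slopes = curve.msd[sel] / curve.lags[sel]
        np.testing.assert_allclose(slopes, 2.0, rtol=0.10)


class TestDegradationImages:
    def test_zero_holes_zero_area(self):
        img, area = generate_degradation_image(SyntheticImageSpec(shape=(64, 64)))
        assert area == 0.0
        assert np.all(img == 10000)

    def test_single_disc_matches_rasterization_oracle(self):
        spec = SyntheticImageSpec(
            shape=(64, 64), hole_specs=((((30.0, 30.0), 10.0, 5000.0)),)
        )
        img, area = generate_degradation_image(spec)
        yy, xx = np.mgrid[0:64, 0:64]
        oracle = ((xx - 30) ** 2 + (yy - 30) ** 2 <= 100).sum()
        assert area == oracle
        assert (img < 10000).sum() == oracle

    def test_disjoint_discs_are_additive(self):
        one = SyntheticImageSpec(shape=(128, 128), hole_specs=(((30.0, 30.0), 8.0, 5000.0),))
        other = SyntheticImageSpec(shape=(128, 128), hole_specs=(((90.0, 90.0), 12.0, 5000.0),))
        both = SyntheticImageSpec(
            shape=(128, 128),
            hole_specs=(((30.0, 30.0), 8.0, 5000.0), ((90.0, 90.0), 12.0, 5000.0)),
        )
        a1 = generate_degradation_image(one)[1]
        a2 = generate_degradation_image(other)[1]
        assert generate_degradation_image(both)[1] == a1 + a2

    def test_overlapping_discs_use_union(self):
        both = SyntheticImageSpec(
            shape=(64, 64),
            hole_specs=(((30.0, 30.0), 10.0, 5000.0), ((35.0, 30.0), 10.0, 5000.0)),
        )
        img, area = generate_degradation_image(both)
        yy, xx = np.mgrid[0:64, 0:64]
        union = (((xx - 30) ** 2 + (yy - 30) ** 2 <= 100) | ((xx - 35) ** 2 + (yy - 30) ** 2 <= 100)).sum()
        assert area == union

    def test_hole_outside_image_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticImageSpec(shape=(64, 64), hole_specs=(((100.0, 30.0), 5.0, 100.0),))

    def test_noise_is_seeded(self):
        spec = SyntheticImageSpec(shape=(64, 64), noise_sd=50.0)
        i1, _ = generate_degradation_image(spec, seed=4)
        i2, _ = generate_degradation_image(spec, seed=4)
        i3, _ = generate_degradation_image(spec, seed=5)
        assert np.array_equal(i1, i2)
        assert not np.array_equal(i1, i3)


class TestTrackmateFixture:
    def test_round_trip_no_drops(self, tmp_path):
        tracks, _ = simulate_spheroid_population(small_config(duration=100.0))
        path = tmp_path / "fixture.xml"
        generate_trackmate_fixture(tracks, path)
        back = read_tracks(path, dialect="trackmate-xml", calibration=1.0, dt=10.0)
        by_id = {t.track_id: t for t in back}
        for orig in tracks:
            got = by_id[orig.track_id]
            assert np.array_equal(got.xy, orig.xy)

    def test_dropped_frame_restored_at_linear_midpoint(self, tmp_path):
        from conftest import make_track

        tr = make_track([(0.0, 0.0), (4.0, 2.0), (8.0, 4.0)], track_id="g")
        path = tmp_path / "gap.xml"
        generate_trackmate_fixture([tr], path, drop_frames={"g": [1]})
        (back,) = read_tracks(path, dialect="trackmate-xml", calibration=1.0, dt=10.0)
        assert [s.frame for s in back.spots] == [0, 2]
        closed = close_gaps(back)
        assert (closed.spots[1].x, closed.spots[1].y) == (4.0, 2.0)
        assert closed.interpolated_frames == {1}

    def test_length_filter_on_fixture(self, tmp_path):
        from conftest import make_track

        tracks = [
            make_track([(float(i), 0.0) for i in range(n)], track_id=f"len{n}")
            for n in (4, 5, 10)
        ]
        path = tmp_path / "lens.xml"
        generate_trackmate_fixture(tracks, path)
        back = read_tracks(path, dialect="trackmate-xml", calibration=1.0, dt=10.0)
        kept = filter_tracks(back, min_spots=5)
        assert sorted(len(t) for t in kept) == [5, 10]

    def test_empty_tracks_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_trackmate_fixture([], tmp_path / "x.xml")
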