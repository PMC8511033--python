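"""Stimulus construction: placement, pairing, isolation, constraint matching,
rasterization, hulls and spectra."""

import math

import numpy as np
import pytest

from pupilnum.stimgen import (
    Connector,
    Dot,
    DotArrayStimulus,
    GeometryConfig,
    PairingError,
    PlacementError,
    connect_pairs,
    convex_hull_area,
    generate_condition_set,
    ink_area,
    isolate_by_displacement,
    isolate_by_removal,
    match_constraints,
    place_items,
    radial_fourier_amplitude,
    rasterize,
)


def min_clearance(stim):
    items = stim.items()
    return min(
        items[i].distance(items[j])
        for i in range(len(items))
        for j in range(i + 1, len(items))
    )


def gift_wrap_area(points):
    """Brute-force convex hull (gift wrapping) + shoelace area: the oracle."""
    pts = [tuple(p) for p in points]
    start = min(pts)
    hull = [start]
    cur = start
    while True:
        cand = pts[0] if pts[0] != cur else pts[1]
        for p in pts:
            if p == cur:
                continue
            cross = (cand[0] - cur[0]) * (p[1] - cur[1]) - (cand[1] - cur[1]) * (p[0] - cur[0])
            if cross < 0 or (
                cross == 0
                and (p[0] - cur[0]) ** 2 + (p[1] - cur[1]) ** 2
                > (cand[0] - cur[0]) ** 2 + (cand[1] - cur[1]) ** 2
            ):
                cand = p
        cur = cand
        if cur == start:
            break
        hull.append(cur)
    area = 0.0
    for (x1, y1), (x2, y2) in zip(hull, hull[1:] + hull[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


class TestPlacement:
    def test_two_dots_clear_by_min_separation(self, exp1_config):
        stim = place_items(2, exp1_config, rng_seed=0)
        d = stim.dots
        center_dist = math.hypot(d[0].center_x - d[1].center_x, d[0].center_y - d[1].center_y)
        assert center_dist >= 0.5 + d[0].radius + d[1].radius - 1e-9

    def test_default_layout_respects_separation(self, exp1_config):
        stim = place_items(18, exp1_config, rng_seed=3)
        assert stim.numerosity == 18
        assert len(stim.connectors) == 9
        assert min_clearance(stim) >= 0.5 - 1e-6

    def test_infeasible_field_raises(self, exp1_config):
        from dataclasses import replace

        tiny = replace(exp1_config, field_radius=2.0)
        with pytest.raises(PlacementError, match="min_separation"):
            place_items(50, tiny, rng_seed=0, max_attempts=50)

    def test_determinism(self, exp1_config):
        a = place_items(18, exp1_config, rng_seed=7)
        b = place_items(18, exp1_config, rng_seed=7)
        assert a.to_dict() == b.to_dict()


class TestPairing:
    @pytest.mark.parametrize("n,expected", [(18, 9), (24, 12)])
    def test_pairing_counts_and_exclusivity(self, exp1_config, n, expected):
        layout = place_items(n, exp1_config, rng_seed=n)
        conn = connect_pairs(layout, rng_seed=1, config=exp1_config)
        assert len(conn.connectors) == expected
        used = [i for pair in conn.pairs for i in pair]
        assert sorted(used) == list(range(n))  # each dot endpoint exactly once
        lo, hi = exp1_config.connector_length_range
        for c in conn.connectors:
            assert lo - 1e-9 <= c.length <= hi + 1e-9

    def test_connectors_span_dot_gaps(self, exp1_config):
        layout = place_items(18, exp1_config, rng_seed=2)
        conn = connect_pairs(layout, rng_seed=2, config=exp1_config)
        for (i, j), c in zip(conn.pairs, conn.connectors):
            a, b = conn.dots[i], conn.dots[j]
            gap = (
                math.hypot(a.center_x - b.center_x, a.center_y - b.center_y)
                - a.radius
                - b.radius
            )
            assert c.length == pytest.approx(gap, abs=1e-9)

    def test_fixed_distant_dots_cannot_pair(self, exp1_config):
        dots = tuple(Dot(10.0 * k, 0.0, 2.2) for k in range(4))
        layout = DotArrayStimulus(dots=dots, connectors=(), connectedness="isolated-displaced")
        with pytest.raises(PairingError):
            connect_pairs(layout, rng_seed=0, config=exp1_config, move_dots=False)


class TestIsolation:
    def test_displacement_keeps_dots_and_line_count(self, exp1_config):
        layout = place_items(18, exp1_config, rng_seed=5)
        conn = connect_pairs(layout, rng_seed=5, config=exp1_config)
        iso = isolate_by_displacement(conn, rng_seed=5, config=exp1_config)
        assert iso.dots == conn.dots
        assert len(iso.connectors) == 9
        assert min_clearance(iso) >= 0.5 - 1e-6

    def test_displacement_identity_without_connectors(self):
        stim = DotArrayStimulus(
            dots=(Dot(0, 0, 2.0),), connectors=(), connectedness="connected"
        )
        out = isolate_by_displacement(stim, rng_seed=0)
        assert out.dots == stim.dots and not out.connectors

    def test_displacement_never_loses_ink(self, exp1_config):
        # junction overlap (if any) is freed when lines float: union can only grow
        layout = place_items(18, exp1_config, rng_seed=6)
        conn = connect_pairs(layout, rng_seed=6, config=exp1_config)
        iso = isolate_by_displacement(conn, rng_seed=6, config=exp1_config)
        assert ink_area(iso) >= ink_area(conn) - 1e-6

    def test_removal_matches_ink(self, exp2_config):
        layout = place_items(18, exp2_config, rng_seed=4)
        conn = connect_pairs(layout, rng_seed=4, config=exp2_config)
        iso = isolate_by_removal(conn, exp2_config)
        assert not iso.connectors
        assert ink_area(iso) == pytest.approx(ink_area(conn), rel=exp2_config.ink_tolerance)
        assert iso.dots[0].diameter > conn.dots[0].diameter

    def test_removal_single_dumbbell_closed_form(self, exp2_config):
        # enlarged dot area = original dot area + line ink / 2 per dot
        a, b = Dot(0, 0, 2.2), Dot(2.2 + 2.0, 0, 2.2)
        from pupilnum.stimgen import _edge_connector

        c = _edge_connector(a, b, 0.6)
        stim = DotArrayStimulus(dots=(a, b), connectors=(c,), connectedness="connected",
                                pairs=((0, 1),), experiment="exp2")
        iso = isolate_by_removal(stim, exp2_config)
        expected_per_dot = math.pi * 1.1**2 + (0.6 * 2.0) / 2
        got = math.pi * (iso.dots[0].diameter / 2) ** 2
        assert got == pytest.approx(expected_per_dot, rel=1e-3)
        # rasterized oracle agrees
        _, rast = rasterize(iso, exp2_config)
        assert rast == pytest.approx(2 * expected_per_dot, rel=0.02)

    def test_removal_negligible_connectors_keep_diameter(self):
        a, b = Dot(0, 0, 2.2), Dot(5, 0, 2.2)
        from pupilnum.stimgen import _edge_connector

        c = _edge_connector(a, b, 1e-9)
        stim = DotArrayStimulus(dots=(a, b), connectors=(c,), connectedness="connected",
                                pairs=((0, 1),), experiment="exp2")
        iso = isolate_by_removal(stim)
        assert iso.dots[0].diameter == pytest.approx(2.2, abs=1e-6)


class TestMatching:
    def test_matched_input_is_fixed_point(self, exp1_set, exp1_config):
        stim = exp1_set[(18, "connected")]
        out = match_constraints(stim, None, exp1_config)
        assert out is stim  # zero iterations: returned unchanged

    def test_full_set_meets_paper_targets(self, exp1_set, exp1_config):
        inks = [ink_area(s) for s in exp1_set.values()]
        hulls = [convex_hull_area(s) for s in exp1_set.values()]
        for ink in inks:
            assert ink == pytest.approx(92.7, rel=0.01)
        for h in hulls:
            assert h == pytest.approx(513.0, rel=0.01)

    @pytest.mark.parametrize("experiment,seed", [(e, s) for e in (1, 2) for s in range(10)])
    def test_constraint_conservation_across_seeds(self, experiment, seed):
        cfg = GeometryConfig.for_experiment(experiment)
        stimset = generate_condition_set(cfg, rng_seed=100 + seed)
        inks = np.array([ink_area(s) for s in stimset.values()])
        hulls = np.array([convex_hull_area(s) for s in stimset.values()])
        assert (inks.max() - inks.min()) / inks.min() <= 2 * cfg.ink_tolerance
        assert (hulls.max() - hulls.min()) / hulls.min() <= 2 * cfg.hull_tolerance
        for s in stimset.values():
            assert min_clearance(s) >= cfg.min_separation - 1e-6

    def test_hull_scales_quadratically(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-8, 8, size=(18, 2))
        dots = tuple(Dot(x, y, 1e-9) for x, y in pts)
        stim = DotArrayStimulus(dots=dots, connectors=(), connectedness="isolated-removed")
        scaled = DotArrayStimulus(
            dots=tuple(Dot(1.7 * d.center_x, 1.7 * d.center_y, d.diameter) for d in dots),
            connectors=(), connectedness="isolated-removed",
        )
        assert convex_hull_area(scaled) == pytest.approx(
            1.7**2 * convex_hull_area(stim), rel=1e-9
        )


class TestHull:
    def test_right_triangle(self):
        dots = tuple(Dot(x, y, 1e-9) for x, y in [(0, 0), (1, 0), (0, 1)])
        stim = DotArrayStimulus(dots=dots, connectors=(), connectedness="isolated-removed")
        assert convex_hull_area(stim) == pytest.approx(0.5, abs=1e-6)

    def test_unit_square(self):
        dots = tuple(Dot(x, y, 1e-9) for x, y in [(0, 0), (1, 0), (1, 1), (0, 1)])
        stim = DotArrayStimulus(dots=dots, connectors=(), connectedness="isolated-removed")
        assert convex_hull_area(stim) == pytest.approx(1.0, abs=1e-6)

    def test_collinear_raises(self):
        dots = tuple(Dot(x, 0.0, 1e-12) for x in (0, 1, 2))
        stim = DotArrayStimulus(dots=dots, connectors=(), connectedness="isolated-removed")
        with pytest.raises(ValueError):
            convex_hull_area(stim)

    def test_matches_gift_wrapping_oracle(self, exp1_set):
        from pupilnum.stimgen import _support_points

        stim = exp1_set[(18, "isolated")]
        pts = _support_points(stim)
        assert convex_hull_area(stim) == pytest.approx(gift_wrap_area(pts), rel=1e-9)


class TestRasterize:
    def test_single_dot_disc_area(self, exp1_config):
        stim = DotArrayStimulus(dots=(Dot(0, 0, 2.0),), connectors=(),
                                connectedness="isolated-removed")
        _, area = rasterize(stim, exp1_config)
        assert area == pytest.approx(math.pi, rel=0.01)

    def test_union_semantics_idempotent(self, exp1_config):
        one = DotArrayStimulus(dots=(Dot(0, 0, 2.0),), connectors=(),
                               connectedness="isolated-removed")
        two = DotArrayStimulus(dots=(Dot(0, 0, 2.0), Dot(0, 0, 2.0)), connectors=(),
                               connectedness="isolated-removed")
        _, a1 = rasterize(one, exp1_config)
        _, a2 = rasterize(two, exp1_config)
        assert a1 == a2
        assert ink_area(one) == pytest.approx(ink_area(two), rel=1e-9)

    def test_matched_stimulus_ink_near_target(self, exp1_set, exp1_config):
        _, area = rasterize(exp1_set[(24, "connected")], exp1_config)
        assert area == pytest.approx(92.7, rel=0.02)

    def test_polarity_levels(self, exp1_config):
        from dataclasses import replace

        stim = DotArrayStimulus(dots=(Dot(0, 0, 2.0),), connectors=(),
                                connectedness="isolated-removed", polarity="white")
        img_w, _ = rasterize(stim, exp1_config)
        img_b, _ = rasterize(replace(stim, polarity="black"), exp1_config)
        assert img_w.max() == exp1_config.luminance_max
        assert img_b.min() == exp1_config.luminance_min
        assert np.median(img_w) == exp1_config.luminance_background


class TestSpectrum:
    def test_uniform_image_zero_amplitude(self, exp1_config):
        img = np.full((256, 256), exp1_config.luminance_background)
        prof = radial_fourier_amplitude(img, exp1_config)
        assert np.allclose(prof.amplitude, 0.0)
        assert np.all(np.diff(prof.spatial_frequency) > 0)

    def test_grating_peaks_at_its_frequency(self, exp1_config):
        ppd = exp1_config.pixels_per_degree
        n = 512
        x = np.arange(n) / ppd
        f0 = 2.0  # cpd
        img = exp1_config.luminance_background + 10 * np.sin(2 * np.pi * f0 * x)[None, :]
        prof = radial_fourier_amplitude(np.broadcast_to(img, (n, n)).copy(), exp1_config)
        peak = prof.spatial_frequency[np.argmax(prof.amplitude)]
        assert peak == pytest.approx(f0, abs=0.1)

    def test_stimulus_profile_nonnegative(self, exp1_set, exp1_config):
        img, _ = rasterize(exp1_set[(18, "connected")], exp1_config)
        prof = radial_fourier_amplitude(img, exp1_config)
        assert np.all(prof.amplitude >= 0)


def test_stimulus_json_roundtrip(exp1_set):
    stim = exp1_set[(24, "isolated")]
    again = DotArrayStimulus.from_json(stim.to_json())
    assert again.to_dict() == stim.to_dict()


def test_invalid_geometry_rejected():
    with pytest.raises(ValueError):
        Dot(0, 0, -1.0)
    with pytest.raises(ValueError):
        Connector(0, 0, 1, 0, width=0.0)
    with pytest.raises(ValueError):
        GeometryConfig(ink_tolerance=0.0)
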