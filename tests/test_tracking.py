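"""Streamline engine: geometry, protocol semantics, RNG replay, transforms."""

import math
import warnings

import numpy as np
import pytest
from scipy.special import ndtri

from tractoprint import generate_phantom
from tractoprint.tracking import (
    OrientationField, TrackingParams, TractProtocol, _propagate_batch,
    average_tractograms, downsample_volume, draw_streamline_uniforms,
    log_normalize, overlap_fraction, propagate_streamline, run_tractography,
    sample_orientation, threshold_map)

from conftest import free_protocol, uniform_field


# --------------------------------------------------------------------------
# sample_orientation
# --------------------------------------------------------------------------

class TestSampleOrientation:
    def test_antipodal_sign_alignment(self):
        field = uniform_field((4, 4, 4), [0, 1, 0])
        d = sample_orientation(field, [2.0, 2.0, 2.0],
                               previous_dir=[0, -1, 0], mode="deterministic")
        assert np.allclose(d, [0, -1, 0])

    def test_deterministic_mode_is_repeatable(self):
        field = uniform_field((4, 4, 4), [0, 0, 1], dispersion_deg=15.0)
        draws = [sample_orientation(field, [1.5, 1.5, 1.5],
                                    mode="deterministic") for _ in range(5)]
        assert all(np.array_equal(draws[0], d) for d in draws)

    def test_outside_grid_raises(self):
        field = uniform_field((4, 4, 4), [1, 0, 0])
        with pytest.raises(ValueError, match="outside"):
            sample_orientation(field, [9.0, 0.0, 0.0])

    def test_dispersion_matches_folded_normal_mean(self):
        # Monte-Carlo angular deviation vs the closed-form half-normal mean
        sigma_deg = 10.0
        field = uniform_field((4, 4, 4), [0, 1, 0], dispersion_deg=sigma_deg)
        rng = np.random.default_rng(42)
        n = 10_000
        cosines = np.empty(n)
        for i in range(n):
            d = sample_orientation(field, [2.0, 2.0, 2.0],
                                   previous_dir=[0, 1, 0], rng=rng)
            cosines[i] = np.clip(d[1], -1, 1)
        angles = np.degrees(np.arccos(cosines))
        sigma = sigma_deg
        expected_mean = sigma * math.sqrt(2 / math.pi)
        sd = sigma * math.sqrt(1 - 2 / math.pi)
        assert abs(angles.mean() - expected_mean) < 3 * sd / math.sqrt(n)


# --------------------------------------------------------------------------
# propagation
# --------------------------------------------------------------------------

class TestPropagation:
    def test_straight_field_endpoint_is_exact(self, x_field):
        # 10 Euler steps of 0.5 mm through a uniform +x field: 5.0 mm
        proto = free_protocol(x_field.shape)
        s = propagate_streamline(x_field, [5.0, 10.0, 10.0], proto)
        assert np.allclose(s.points[-1], [10.0, 10.0, 10.0])
        assert np.linalg.norm(s.points[-1] - s.points[0]) == pytest.approx(5.0)

    def test_right_angle_violates_curvature_threshold(self):
        # orientation turns from +x to +z at x = 10: cosine 0 < 0.2 stops it
        shape = (20, 20, 20)
        orientations = np.zeros(shape + (1, 3))
        orientations[:10, ..., 0, :] = [1.0, 0.0, 0.0]
        orientations[10:, ..., 0, :] = [0.0, 0.0, 1.0]
        field = OrientationField(
            orientations=orientations, weights=np.ones(shape + (1,)),
            isotropic=np.zeros(shape, bool), dispersion_deg=0.0)
        proto = free_protocol(
            shape, TrackingParams(n_samples=1, max_steps=100, step_length=0.5,
                                  curvature_threshold=0.2,
                                  mode="deterministic"))
        s = propagate_streamline(field, [5.25, 10.0, 10.0], proto)
        # propagation crossed into the +z region and stopped there
        assert s.points[-1][0] <= 10.5
        assert len(s.points) < 101
        assert not s.excluded

    def test_exclusion_mask_deletes_streamline(self, x_field):
        shape = x_field.shape
        exclusion = np.zeros(shape, dtype=bool)
        exclusion[15:, :, :] = True
        proto = TractProtocol(
            name="t", seed_mask=np.ones(shape, bool) & ~exclusion,
            exclusion_masks=[exclusion],
            params=TrackingParams(n_samples=1, max_steps=50, step_length=0.5,
                                  mode="deterministic"))
        s = propagate_streamline(x_field, [5.0, 10.0, 10.0], proto)
        assert s.excluded
        # nothing past the exclusion boundary was recorded
        assert s.visited_voxels[:, 0].max() < 15

    def test_termination_stops_without_deleting(self, x_field):
        shape = x_field.shape
        term = np.zeros(shape, dtype=bool)
        term[15:, :, :] = True
        proto = TractProtocol(
            name="t", seed_mask=np.ones(shape, bool),
            termination_mask=term,
            params=TrackingParams(n_samples=1, max_steps=200, step_length=0.5,
                                  mode="deterministic"))
        s = propagate_streamline(x_field, [5.0, 10.0, 10.0], proto)
        assert s.terminated and not s.excluded
        assert s.visited_voxels[-1, 0] == 15

    def test_batch_equals_single_streamline(self):
        # the vectorized batch and one-at-a-time propagation share the RNG
        # schedule, so they must agree bitwise
        field = uniform_field((12, 12, 12), [0, 1, 0], dispersion_deg=20.0)
        params = TrackingParams(n_samples=1, max_steps=30, step_length=0.5,
                                seed=3)
        n = 8
        _, uniforms = draw_streamline_uniforms(params.seed, range(n),
                                               params.max_steps)
        starts = np.tile([6.0, 2.0, 6.0], (n, 1))
        signs = np.ones(n)
        batch = _propagate_batch(field, starts, signs, params, uniforms)
        for i in range(n):
            single = _propagate_batch(field, starts[i:i + 1], signs[i:i + 1],
                                      params, uniforms[i:i + 1])
            assert np.array_equal(batch.visited[i], single.visited[0])


# --------------------------------------------------------------------------
# retention oracle: independent replay of the RNG stream
# --------------------------------------------------------------------------

def _oracle_streamline(field, start, sign, uniforms, params,
                       exclusion, waypoints, termination):
    """Naive scalar reimplementation of propagation + protocol decisions."""
    shape = field.shape
    vs = field.voxel_size
    sigma = math.radians(field.dispersion_deg)
    pos = [float(v) for v in start]
    prev = None
    visited, hit = set(), set()
    excluded = terminated = False
    for t in range(params.max_steps + 1):
        vox = tuple(int(math.floor(p / vs)) for p in pos)
        if any(v < 0 or v >= s for v, s in zip(vox, shape)):
            break
        if exclusion is not None and exclusion[vox]:
            excluded = True
            break
        visited.add(vox)
        for w, mask in enumerate(waypoints):
            if mask[vox]:
                hit.add(w)
        if termination is not None and termination[vox]:
            terminated = True
            break
        if t == params.max_steps:
            break
        u = uniforms[t * 4:(t + 1) * 4]
        w_vox = field.weights[vox]
        total = float(w_vox.sum())
        if field.isotropic[vox]:
            z = 2.0 * u[3] - 1.0
            r = math.sqrt(max(1.0 - z * z, 0.0))
            phi = 2.0 * math.pi * u[1]
            d = [r * math.cos(phi), r * math.sin(phi), z]
        elif total > 0:
            cum, choice = 0.0, 0
            for k in range(len(w_vox)):
                cum += float(w_vox[k])
                if cum < u[0] * total:
                    choice = k + 1
            choice = min(choice, len(w_vox) - 1)
            d = [float(c) for c in field.orientations[vox][choice]]
            if sigma > 0:
                theta = sigma * float(ndtri(0.5 + 0.5 * u[2]))
                phi = 2.0 * math.pi * u[1]
                helper = [0.0, 1.0, 0.0] if abs(d[0]) > 0.9 else [1.0, 0.0, 0.0]
                p1 = [d[1] * helper[2] - d[2] * helper[1],
                      d[2] * helper[0] - d[0] * helper[2],
                      d[0] * helper[1] - d[1] * helper[0]]
                nrm = math.sqrt(sum(c * c for c in p1))
                p1 = [c / nrm for c in p1]
                p2 = [d[1] * p1[2] - d[2] * p1[1],
                      d[2] * p1[0] - d[0] * p1[2],
                      d[0] * p1[1] - d[1] * p1[0]]
                ct, st = math.cos(theta), math.sin(theta)
                cp, sp = math.cos(phi), math.sin(phi)
                d = [ct * d[i] + st * (cp * p1[i] + sp * p2[i])
                     for i in range(3)]
        else:
            break
        if prev is None:
            d = [sign * c for c in d]
        else:
            cosine = sum(a * b for a, b in zip(prev, d))
            if cosine < 0:
                d = [-c for c in d]
                cosine = -cosine
            if cosine < params.curvature_threshold:
                break
        pos = [p + params.step_length * c for p, c in zip(pos, d)]
        prev = d
    retained = (not excluded) and (len(hit) > 0 if waypoints else True)
    return visited, hit, excluded, terminated, retained


def _small_protocol_world():
    """10^3 grid: one +y bundle, iso background, waypoints/exclusion/term."""
    shape = (10, 10, 10)
    orientations = np.zeros(shape + (1, 3))
    weights = np.zeros(shape + (1,))
    bundle = np.zeros(shape, dtype=bool)
    bundle[4:7, 1:9, 4:7] = True
    orientations[bundle, 0] = [0.0, 1.0, 0.0]
    weights[bundle, 0] = 1.0
    term = np.zeros(shape, dtype=bool)
    term[:, 0, :] = term[:, 9, :] = True
    iso = ~bundle & ~term
    field = OrientationField(orientations, weights, iso,
                             dispersion_deg=12.0, voxel_size=1.0)
    seed = np.zeros(shape, dtype=bool)
    seed[5, 4:6, 5] = True
    wp_a = np.zeros(shape, dtype=bool)
    wp_a[:, 1:3, :] = True
    wp_b = np.zeros(shape, dtype=bool)
    wp_b[:, 7:9, :] = True
    excl = np.zeros(shape, dtype=bool)
    excl[0:2, :, :] = True
    params = TrackingParams(n_samples=10, max_steps=40, step_length=0.5,
                            seed=77)
    protocol = TractProtocol(name="bundle", seed_mask=seed,
                             waypoint_masks=[wp_a, wp_b],
                             exclusion_masks=[excl], termination_mask=term,
                             params=params)
    return field, protocol


def test_retention_decisions_match_bruteforce_oracle():
    """Waypoint-OR retention, exclusion deletion and termination-without-
    deletion agree with an independent replay of the same RNG stream."""
    field, protocol = _small_protocol_world()
    params = protocol.params
    seed_voxels = np.argwhere(protocol.seed_mask)
    n_per = params.n_samples
    half = (n_per + 1) // 2
    n_total = len(seed_voxels) * n_per
    assert n_total <= 20

    agreements = 0
    for sid in range(n_total):
        voxel = seed_voxels[sid // n_per]
        m = sid % n_per
        sign = 1.0 if m < half else -1.0
        rng = np.random.default_rng([params.seed, sid])
        u = rng.random(3 + 4 * params.max_steps)
        start = (voxel + u[:3]) * field.voxel_size

        s = propagate_streamline(field, start, protocol, launch_sign=sign,
                                 uniforms=u[3:])
        (o_visited, o_hit, o_excl, o_term, o_ret) = _oracle_streamline(
            field, start, sign, u[3:], params,
            protocol.exclusion_masks[0], protocol.waypoint_masks,
            protocol.termination_mask)
        assert s.excluded == o_excl
        assert s.terminated == o_term
        assert s.hit_waypoints == o_hit
        assert {tuple(v) for v in s.visited_voxels} == o_visited
        impl_retained = (not s.excluded) and bool(s.hit_waypoints)
        assert impl_retained == o_ret
        agreements += 1
    assert agreements == n_total


# --------------------------------------------------------------------------
# run_tractography
# --------------------------------------------------------------------------

class TestRunTractography:
    def test_waypoint_equals_seed_retains_everything(self):
        field = uniform_field((12, 12, 12), [0, 1, 0])
        seed = np.zeros(field.shape, dtype=bool)
        seed[5:7, 5:7, 5:7] = True
        proto = TractProtocol(
            name="t", seed_mask=seed, waypoint_masks=[seed],
            params=TrackingParams(n_samples=20, max_steps=30,
                                  step_length=0.5, seed=5))
        tg = run_tractography(proto, field)
        assert tg.n_retained == tg.n_generated

    def test_normalization_and_bounds(self):
        field, protocol = _small_protocol_world()
        tg = run_tractography(protocol, field)
        assert tg.n_retained <= tg.n_generated
        if tg.n_retained:
            assert np.array_equal(tg.normalized,
                                  tg.counts / tg.n_retained)
        assert tg.normalized.max() <= 1.0
        assert tg.counts.max() <= tg.n_retained
        # binary per-streamline visitation bounds the total count
        assert tg.counts.sum() <= tg.n_retained * (protocol.params.max_steps + 1)

    def test_decoy_bundle_is_excluded(self):
        # true +y bundle and a parallel decoy; the decoy is an exclusion
        # mask, so retained visitation avoids it entirely
        shape = (16, 16, 16)
        orientations = np.zeros(shape + (1, 3))
        weights = np.zeros(shape + (1,))
        true_tube = np.zeros(shape, dtype=bool)
        true_tube[4:7, :, 4:7] = True
        decoy = np.zeros(shape, dtype=bool)
        decoy[10:13, :, 4:7] = True
        for tube in (true_tube, decoy):
            orientations[tube, 0] = [0, 1, 0]
            weights[tube, 0] = 1.0
        field = OrientationField(orientations, weights,
                                 np.zeros(shape, bool), 5.0)
        seed = np.zeros(shape, dtype=bool)
        seed[5, 7:9, 5] = True
        wp = np.zeros(shape, dtype=bool)
        wp[:, 12:14, :] = True
        proto = TractProtocol(
            name="true", seed_mask=seed, waypoint_masks=[wp],
            exclusion_masks=[decoy],
            params=TrackingParams(n_samples=100, max_steps=60,
                                  step_length=0.5, seed=9))
        tg = run_tractography(proto, field)
        assert tg.n_retained > 0
        assert tg.counts[decoy].sum() == 0

    def test_zero_retention_warns_and_zeroes(self):
        field = uniform_field((10, 10, 10), [1, 0, 0])
        seed = np.zeros(field.shape, dtype=bool)
        seed[2, 5, 5] = True
        wp = np.zeros(field.shape, dtype=bool)
        wp[:, 0:1, 0:1] = False
        wp[5, 0, 0] = True  # unreachable from an x-aligned field
        proto = TractProtocol(
            name="t", seed_mask=seed, waypoint_masks=[wp],
            params=TrackingParams(n_samples=4, max_steps=10,
                                  step_length=0.5, seed=2))
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            tg = run_tractography(proto, field)
        assert tg.n_retained == 0
        assert not tg.normalized.any()
        assert any("no streamlines retained" in str(w.message) for w in rec)


# --------------------------------------------------------------------------
# post-processing transforms
# --------------------------------------------------------------------------

class TestTransforms:
    def test_average_tractograms(self):
        a = np.full((4, 4, 4), 0.2)
        b = np.full((4, 4, 4), 0.4)
        assert np.allclose(average_tractograms([a, b]), 0.3)
        assert np.array_equal(average_tractograms([a]), a)
        assert np.allclose(average_tractograms([b, b, b]), b)
        with pytest.raises(ValueError, match="different grids"):
            average_tractograms([a, np.zeros((2, 2, 2))])

    def test_downsample_block_mean(self):
        vol = np.zeros((2, 2, 2))
        vol[1, 1, 1] = 8.0
        assert downsample_volume(vol, 2)[0, 0, 0] == pytest.approx(1.0)
        const = np.full((4, 4, 4), 3.3)
        assert np.allclose(downsample_volume(const, 2), 3.3)
        assert np.array_equal(downsample_volume(const, 1), const)
        with pytest.raises(ValueError, match="divisible"):
            downsample_volume(np.zeros((3, 4, 4)), 2)
        out, vs = downsample_volume(const, 2, voxel_size=1.0)
        assert vs == 2.0

    def test_log_normalize_properties(self):
        rng = np.random.default_rng(0)
        vol = rng.random((5, 5, 5)) * 10
        out = log_normalize(vol)
        assert out.max() == pytest.approx(1.0)
        assert out.min() >= 0
        # monotone: ordering preserved
        flat_in, flat_out = vol.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= 0)
        with pytest.warns(UserWarning, match="all-zero"):
            z = log_normalize(np.zeros((3, 3, 3)))
        assert not z.any()
        with pytest.raises(ValueError):
            log_normalize(-vol)

    def test_threshold_map(self):
        vol = np.array([[[0.6, 0.7, 0.8]]])
        assert np.array_equal(threshold_map(vol, 0.7),
                              [[[False, True, True]]])

    def test_overlap_fraction(self):
        a = np.zeros((3, 3, 3), dtype=bool)
        a.ravel()[:10] = True
        b = np.zeros_like(a)
        b.ravel()[6:20] = True
        assert overlap_fraction(a, a) == 1.0
        assert overlap_fraction(a, ~a) == 0.0
        assert overlap_fraction(a, b) == pytest.approx(0.4)
        with pytest.raises(ValueError, match="empty"):
            overlap_fraction(np.zeros_like(a), b)


def test_probabilistic_and_deterministic_tracts_agree():
    """On a clean single-bundle phantom the two tracking modes reconstruct
    overlapping tracts: Dice >= 0.7 between the display maps at 0.5."""
    from tractoprint.parcellation import dice
    from tractoprint import study

    spec = study.three_bundle_spec(seed=3, dispersion_deg=5.0)
    ph = generate_phantom(spec)
    # seed at the posterior end of the ILF so streamlines traverse the tube
    tube = ph.bundle_mask("ILF")
    seed = np.zeros_like(tube)
    seed[:, 3:5, :] = tube[:, 3:5, :]
    wp = np.zeros_like(tube)
    wp[:, 28:31, :] = tube[:, 28:31, :]
    maps = {}
    for mode in ("probabilistic", "deterministic"):
        proto = TractProtocol(
            name="ILF", seed_mask=seed, waypoint_masks=[wp],
            termination_mask=ph.gm_mask,
            params=TrackingParams(n_samples=100, max_steps=150,
                                  step_length=0.5, mode=mode, seed=8))
        tg = run_tractography(proto, ph.orientation_field)
        assert tg.n_retained > 0
        maps[mode] = threshold_map(log_normalize(tg.counts), 0.5)
    assert dice(maps["probabilistic"], maps["deterministic"]) >= 0.7


def test_deterministic_mode_is_seed_invariant():
    """Zero-dispersion deterministic tracking ignores the RNG seed."""
    field = uniform_field((12, 12, 12), [0, 1, 0])
    seed = np.zeros(field.shape, dtype=bool)
    seed[5:7, 2:4, 5:7] = True
    maps = []
    for s in (1, 99):
        proto = TractProtocol(
            name="t", seed_mask=seed,
            params=TrackingParams(n_samples=4, max_steps=40, step_length=0.5,
                                  mode="deterministic", seed=s))
        maps.append(run_tractography(proto, field).normalized)
    assert np.array_equal(maps[0], maps[1])
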