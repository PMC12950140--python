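"""Backbone tracing, arc-length projection and rigid registration."""

import numpy as np
import pytest
from scipy import ndimage

import spinedyn as sd
from spinedyn.tracing import Backbone, TracingError, arc_position, arc_positions

from conftest import straight_tube_scene


class TestTraceBackbone:
    def test_straight_tube_centerline_accuracy(self, tube_scene, tube_stack):
        poly = tube_scene.backbone_polyline()
        bb = sd.trace_backbone(tube_stack, [poly[0], poly[-1]])
        truth = Backbone.from_polyline(poly, tube_scene.backbone_radius_um)
        _, offsets = arc_positions(truth, bb.points_um)
        rms = float(np.sqrt((offsets**2).mean()))
        assert rms < 0.5 * min(tube_stack.voxel_pitch_um)

    def test_straight_tube_radius_recovery(self, tube_scene, tube_stack):
        bb = sd.trace_backbone(
            tube_stack,
            [tube_scene.backbone_polyline()[0],
             tube_scene.backbone_polyline()[-1]],
        )
        assert abs(np.mean(bb.radius_um) - 0.5) < 0.25 * 0.5

    def test_seeds_in_background_raise(self, tube_stack):
        with pytest.raises(TracingError):
            sd.trace_backbone(
                tube_stack, [(1.0, 0.5, 1.0), (15.0, 0.5, 1.0)]
            )

    def test_reversed_seeds_give_reversed_polyline(self, tube_scene,
                                                   tube_stack):
        poly = tube_scene.backbone_polyline()
        fwd = sd.trace_backbone(tube_stack, [poly[0], poly[-1]])
        rev = sd.trace_backbone(tube_stack, [poly[-1], poly[0]])
        # reversed trace lies on the forward centerline...
        _, off = arc_positions(fwd, rev.points_um)
        assert np.max(off) < 0.15
        # ...and its arc coordinate maps s -> L - s
        arcs, _ = arc_positions(fwd, rev.points_um)
        expect = fwd.total_length_um - rev.cum_arclength_um
        assert np.max(np.abs(arcs - expect)) < 0.4

    def test_arclength_invariant_under_rigid_shift(self, tube_scene,
                                                   tube_stack):
        poly = tube_scene.backbone_polyline()
        bb = sd.trace_backbone(tube_stack, [poly[0], poly[-1]])
        shift_vox = (1, -2, 3)  # (z, y, x)
        rolled = np.roll(tube_stack.intensities, shift_vox, axis=(0, 1, 2))
        t_um = np.array([3 * 0.18, -2 * 0.18, 1 * 1.0])
        shifted = sd.ImageStack(rolled, tube_stack.voxel_pitch_um, "s")
        bb2 = sd.trace_backbone(shifted, [poly[0] + t_um, poly[-1] + t_um])
        assert bb2.total_length_um == pytest.approx(
            bb.total_length_um, abs=0.3
        )


class TestArcPosition:
    def test_node_projects_to_itself(self):
        pts = np.array([[0, 0, 0], [3, 0, 0], [7, 0, 0], [10.0, 0, 0]])
        bb = Backbone.from_polyline(pts, 0.5)
        arc, off = arc_position(bb, pts[2])
        assert arc == pytest.approx(7.0)
        assert off == pytest.approx(0.0)

    def test_perpendicular_point_midway(self):
        bb = Backbone.from_polyline(
            np.array([[0, 0, 0], [10.0, 0, 0]]), 0.5
        )
        arc, off = arc_position(bb, (5.0, 1.0, 0.0))
        assert (arc, off) == (pytest.approx(5.0), pytest.approx(1.0))

    def test_matches_exhaustive_segment_search(self):
        """Vectorized projection equals a per-segment brute-force scan."""
        rng = np.random.default_rng(0)
        walk = np.cumsum(rng.normal(0, 0.4, size=(200, 3)), axis=0)
        bb = Backbone.from_polyline(walk, 0.5)
        pts = walk[rng.integers(0, 200, 40)] + rng.normal(0, 2, (40, 3))
        arcs, offs = arc_positions(bb, pts)
        for p, arc, off in zip(pts, arcs, offs):
            best = (np.inf, None, None)
            for i in range(len(walk) - 1):
                a, d = walk[i], walk[i + 1] - walk[i]
                t = float(np.clip(np.dot(p - a, d) / np.dot(d, d), 0, 1))
                foot = a + t * d
                dist = float(np.linalg.norm(p - foot))
                if dist < best[0]:
                    s = bb.cum_arclength_um[i] + t * (
                        bb.cum_arclength_um[i + 1] - bb.cum_arclength_um[i]
                    )
                    best = (dist, s)
            assert off == pytest.approx(best[0], abs=1e-9)
            assert arc == pytest.approx(best[1], abs=1e-9)


class TestRegistration:
    def test_identity_is_zero_shift_max_score(self, tube_stack):
        rs = sd.register_sessions(tube_stack, tube_stack)
        assert np.allclose(rs.translation_um, 0.0, atol=1e-6)
        assert rs.score == pytest.approx(1.0)
        assert not rs.low_confidence

    def test_constructed_shifts_recovered(self):
        """Sub-voxel recovery of known shifts at realistic SNR."""
        scene = sd.make_scene(seed=3)
        ref = sd.render_session(scene, "BL")
        mov_base = sd.render_session(scene, "BL", seed=99)
        rng = np.random.default_rng(7)
        pitch = np.array([1.0, 0.18, 0.18])  # (z, y, x)
        for _ in range(5):
            shift_vox = rng.uniform(-4, 4, size=3)
            moved = np.clip(
                ndimage.shift(mov_base.intensities, shift_vox, order=1,
                              mode="constant", cval=10.0), 0, None)
            rs = sd.register_sessions(
                ref, sd.ImageStack(moved, ref.voxel_pitch_um, "m")
            )
            rec_vox = np.array([
                rs.translation_um[2] / 1.0,
                rs.translation_um[1] / 0.18,
                rs.translation_um[0] / 0.18,
            ])
            assert np.all(np.abs(rec_vox + shift_vox) <= 0.5)

    def test_pure_noise_flags_low_confidence(self):
        rng = np.random.default_rng(1)
        a = sd.ImageStack(rng.poisson(10, (8, 32, 32)).astype(float),
                          (0.18, 0.18, 1.0), "a")
        b = sd.ImageStack(rng.poisson(10, (8, 32, 32)).astype(float),
                          (0.18, 0.18, 1.0), "b")
        with pytest.warns(UserWarning, match="low confidence"):
            rs = sd.register_sessions(a, b)
        assert rs.low_confidence


def test_backbone_invariants():
    with pytest.raises(ValueError):
        Backbone(np.zeros((3, 3)), np.array([1.0, -1.0, 1.0]),
                 np.array([0.0, 1.0, 2.0]))
    with pytest.raises(ValueError):
        Backbone(np.zeros((3, 3)), np.ones(3), np.array([0.0, 2.0, 1.0]))
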