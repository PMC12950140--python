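"""Endpoint detection, bottleneck brightest path, inclusion filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import spinedyn as sd
from spinedyn.spines import (
    DetectionParams,
    SpineMark,
    SpinePathError,
    path_bottleneck,
)
from spinedyn.tracing import Backbone


def _mark(protrusion, elevation=0.0, endpoint=(5.0, 5.0, 5.0), arc=5.0):
    return SpineMark(
        endpoint_um=endpoint, path_vox=((5, 5, 5),), attachment_arc_um=arc,
        attachment_point_um=(5.0, 4.0, 5.0),
        protrusion_length_um=protrusion, elevation_deg=elevation,
        included=False, source="automatic",
    )


class TestDetection:
    def test_programmed_endpoints_recovered_on_clean_scene(
            self, clean_scene, clean_stack, clean_backbone):
        marks = sd.analyze_session(clean_stack, clean_backbone)
        present = [i for i, sp in enumerate(clean_scene.spines)
                   if sp.presence[0]]
        truth = np.array([clean_scene.spine_endpoint(i) for i in present])
        det = np.array([m.endpoint_um for m in marks])
        d = np.linalg.norm(truth[:, None, :] - det[None, :, :], axis=2)
        hits = (d.min(axis=1) < 0.5).sum()
        assert hits >= len(present) - 1  # >=9 of 10 within 0.5 µm

    def test_empty_scene_yields_no_candidates(self, tube_stack, tube_scene):
        poly = tube_scene.backbone_polyline()
        bb = sd.trace_backbone(tube_stack, [poly[0], poly[-1]])
        cands = sd.detect_endpoints(tube_stack, bb)
        assert cands == []

    def test_manual_annotations_override_verbatim(self, tube_stack,
                                                  tube_scene):
        poly = tube_scene.backbone_polyline()
        bb = sd.trace_backbone(tube_stack, [poly[0], poly[-1]])
        manual = pd.DataFrame(
            {"x_um": [3.0, 9.0], "y_um": [7.0, 4.5], "z_um": [7.0, 7.0]}
        )
        cands = sd.detect_endpoints(tube_stack, bb, manual=manual)
        assert [c.source for c in cands] == ["manual", "manual"]
        assert [c.point_um for c in cands] == [(3.0, 7.0, 7.0),
                                               (9.0, 4.5, 7.0)]


def _toy_stack(values):
    """Unit-pitch stack from a (nz, ny, nx) array for path oracles."""
    return sd.ImageStack(np.asarray(values, dtype=float),
                         voxel_pitch_um=(1.0, 1.0, 1.0), session="toy")


def _edge_backbone(nx):
    """Backbone along the y=0, z=0 voxel row (tube = that row only)."""
    return Backbone.from_polyline(
        np.array([[0.0, 0.0, 0.0], [nx - 1.0, 0.0, 0.0]]), 0.4
    )


def _bottleneck_oracle(img, start, tube_mask, pitch=(1.0, 1.0, 1.0)):
    """Independent optimum: threshold-connectivity for the bottleneck value,
    then shortest physical length restricted to voxels >= that value."""
    from scipy.ndimage import label

    structure = np.ones((3, 3, 3), dtype=bool)
    best = None
    for t in sorted(np.unique(img))[::-1]:
        mask = img >= t
        lab, _ = label(mask, structure=structure)
        if lab[start] and np.any(lab[tube_mask & mask] == lab[start]):
            best = t
            break
    if best is None:
        return None, None
    # Dijkstra by physical length on the thresholded mask
    import heapq

    mask = img >= best
    offs = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
            for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    steps = [np.linalg.norm([dz * pitch[2], dy * pitch[1], dx * pitch[0]])
             for dz, dy, dx in offs]
    dist = {start: 0.0}
    heap = [(0.0, start)]
    seen = set()
    while heap:
        d, node = heapq.heappop(heap)
        if node in seen:
            continue
        seen.add(node)
        if tube_mask[node]:
            return best, d
        for (dz, dy, dx), sl in zip(offs, steps):
            nb = (node[0] + dz, node[1] + dy, node[2] + dx)
            if all(0 <= nb[k] < img.shape[k] for k in range(3)) \
                    and mask[nb] and nb not in seen:
                nd = d + sl
                if nd < dist.get(nb, np.inf):
                    dist[nb] = nd
                    heapq.heappush(heap, (nd, nb))
    return best, None


class TestBrightestPath:
    def test_prefers_brighter_corridor(self):
        img = np.full((1, 5, 5), 1.0)
        img[0, 0, :] = 100.0        # backbone row
        img[0, :, 1] = 80.0         # bright corridor
        img[0, :, 3] = 40.0         # dim corridor
        img[0, 4, 1:4] = 80.0       # bridge between corridor tops
        stack = _toy_stack(img)
        bb = _edge_backbone(5)
        path = sd.brightest_path(stack, (3.0, 4.0, 0.0), bb, 20.0,
                                 background_level=0.0,
                                 admissible_fraction=0.0)
        # descends through the bright corridor, never the dim one
        assert any(x == 1 for _, y, x in path)
        assert not any(x == 3 and y < 4 for _, y, x in path)
        assert path_bottleneck(stack, path) == 80.0

    @pytest.mark.parametrize("seed", range(50))
    def test_bottleneck_matches_connectivity_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(1, 50, size=(3, 5, 5)).astype(float)
        img[0, 0, :] = 60.0  # tube row at y=0, z=0
        stack = _toy_stack(img)
        bb = _edge_backbone(5)
        start_um = (float(rng.integers(0, 5)), float(rng.integers(2, 5)),
                    float(rng.integers(0, 3)))
        tube_mask = np.zeros_like(img, dtype=bool)
        tube_mask[0, 0, :] = True
        start_vox = (int(start_um[2]), int(start_um[1]), int(start_um[0]))
        path = sd.brightest_path(stack, start_um, bb, 50.0,
                                 background_level=0.0,
                                 admissible_fraction=0.0)
        oracle_b, oracle_len = _bottleneck_oracle(img, start_vox, tube_mask)
        assert path_bottleneck(stack, path) == oracle_b
        pts = np.asarray(path, dtype=float)
        length = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        assert length == pytest.approx(oracle_len, abs=1e-9)

    def test_endpoint_adjacent_to_tube_gives_short_path(self, tube_scene,
                                                        tube_stack):
        poly = tube_scene.backbone_polyline()
        bb = sd.trace_backbone(tube_stack, [poly[0], poly[-1]])
        on_tube = poly[len(poly) // 2] + np.array([0.0, 0.6, 0.0])
        mark = sd.attach_spine(tube_stack, bb, on_tube)
        assert mark.protrusion_length_um < 2 * max(
            tube_stack.voxel_pitch_um[0], tube_stack.voxel_pitch_um[1]
        )

    def test_no_admissible_path_raises(self):
        img = np.full((1, 5, 5), 0.0)
        img[0, 0, :] = 100.0
        img[0, 4, 4] = 90.0  # isolated endpoint, zero-valued surroundings
        stack = _toy_stack(img)
        with pytest.raises(SpinePathError):
            sd.brightest_path(stack, (4.0, 4.0, 0.0), _edge_backbone(5),
                              20.0, background_level=0.0,
                              admissible_fraction=0.5)


class TestInclusionFilters:
    @pytest.mark.parametrize(
        "protrusion,elevation,expected",
        [
            (0.5, 10.0, False),   # too short: the >0.72 µm rule
            (1.0, 30.0, True),    # long enough, in plane
            (1.0, 80.0, False),   # steeper than the orientation cutoff
            (0.72, 0.0, False),   # boundary: strictly greater than
            (0.7201, 0.0, True),
            (1.0, 45.0, True),    # elevation boundary is inclusive
        ],
    )
    def test_inclusion_rule(self, protrusion, elevation, expected):
        out = sd.apply_inclusion_filters([_mark(protrusion, elevation)])
        assert out[0].included is expected

    def test_filter_is_idempotent(self):
        marks = [_mark(p, e) for p in (0.3, 0.8, 2.0) for e in (0, 50)]
        once = sd.apply_inclusion_filters(marks)
        twice = sd.apply_inclusion_filters(once)
        assert once == twice

    def test_included_count_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        marks = [_mark(float(p)) for p in rng.uniform(0.1, 3.0, 60)]
        counts = []
        for thr in np.linspace(0.2, 2.5, 12):
            params = DetectionParams(min_protrusion_um=float(thr),
                                     search_radius_um=3.5)
            out = sd.apply_inclusion_filters(marks, params)
            counts.append(sum(m.included for m in out))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
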