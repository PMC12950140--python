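"""Cross-session matching, dynamics ratios, ROI intensity statistics."""

from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

import spinedyn as sd
from spinedyn.longitudinal import IntensityMeasure, match_pair
from spinedyn.spines import SpineMark
from spinedyn.tracing import Backbone


def _mark(arc, session="", included=True, endpoint=None):
    endpoint = endpoint or (arc, 3.0, 5.0)
    return SpineMark(
        endpoint_um=endpoint, path_vox=(), attachment_arc_um=float(arc),
        attachment_point_um=(float(arc), 1.0, 5.0),
        protrusion_length_um=1.5, elevation_deg=5.0, included=included,
        source="automatic", session=session,
    )


def _match_cost(arcs_a, arcs_b, pairs, tol):
    matched = sum(abs(arcs_a[i] - arcs_b[j]) for i, j in pairs)
    unmatched = (len(arcs_a) - len(pairs)) + (len(arcs_b) - len(pairs))
    return matched + tol * unmatched


def _oracle_cost(arcs_a, arcs_b, tol):
    """DP over all matchings: min total |Δarc| + tol per unmatched spine."""
    arcs_a, arcs_b = tuple(arcs_a), tuple(arcs_b)

    @lru_cache(maxsize=None)
    def go(i, mask):
        if i == len(arcs_a):
            return tol * (len(arcs_b) - bin(mask).count("1"))
        best = tol + go(i + 1, mask)
        for j, b in enumerate(arcs_b):
            if not mask >> j & 1 and abs(arcs_a[i] - b) <= tol:
                best = min(best, abs(arcs_a[i] - b) + go(i + 1, mask | 1 << j))
        return best

    return go(0, 0)


class TestMatching:
    def test_example_assignment(self):
        pairs = match_pair([5.0, 12.0, 20.0], [5.2, 19.8, 30.0], 2.0)
        assert set(pairs) == {(0, 0), (2, 1)}  # 12.0 lost, 30.0 new

    def test_identical_sets_fully_matched(self):
        arcs = [2.0, 7.5, 13.0]
        pairs = match_pair(arcs, arcs, 2.0)
        assert pairs == [(0, 0), (1, 1), (2, 2)]

    @pytest.mark.parametrize("seed", range(50))
    def test_cost_equals_bruteforce_minimum(self, seed):
        rng = np.random.default_rng(seed)
        a = sorted(rng.uniform(0, 20, rng.integers(0, 9)))
        b = sorted(rng.uniform(0, 20, rng.integers(0, 9)))
        pairs = match_pair(a, b, 2.0)
        assert all(abs(a[i] - b[j]) <= 2.0 for i, j in pairs)
        assert _match_cost(a, b, pairs, 2.0) == pytest.approx(
            _oracle_cost(a, b, 2.0)
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_symmetry_under_session_swap(self, seed):
        rng = np.random.default_rng(seed + 1000)
        a = sorted(rng.uniform(0, 20, rng.integers(1, 9)))
        b = sorted(rng.uniform(0, 20, rng.integers(1, 9)))
        fwd = set(match_pair(a, b, 2.0))
        rev = {(j, i) for i, j in match_pair(b, a, 2.0)}
        assert fwd == rev

    def test_tracks_from_marks(self):
        sessions = ("BL", "d3")
        marks = {
            "BL": [_mark(5.0, "BL"), _mark(12.0, "BL"), _mark(20.0, "BL")],
            "d3": [_mark(5.2, "d3"), _mark(19.8, "d3"), _mark(30.0, "d3")],
        }
        tracks = sd.match_spines(marks, sessions)
        presences = sorted(tr.present for tr in tracks)
        assert presences == sorted(
            [(True, True), (True, True), (True, False), (False, True)]
        )
        add, elim, turn = sd.dynamics_ratios(tracks, ("BL", "d3"))
        assert (add, elim, turn) == (
            pytest.approx(1 / 3), pytest.approx(1 / 3), pytest.approx(1 / 3)
        )

    def test_duplicate_manual_link_rejected(self):
        sessions = ("BL", "d3")
        marks = {
            "BL": [_mark(5.0, "BL"), _mark(8.0, "BL")],
            "d3": [_mark(5.0, "d3"), _mark(8.0, "d3")],
        }
        links = pd.DataFrame(
            {"session_a": ["BL", "BL"], "id_a": [0, 1],
             "session_b": ["d3", "d3"], "id_b": [0, 0]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            sd.match_spines(marks, sessions, manual_links=links)

    def test_manual_link_overrides_distance(self):
        sessions = ("BL", "d3")
        marks = {
            "BL": [_mark(5.0, "BL"), _mark(8.0, "BL")],
            "d3": [_mark(5.1, "d3"), _mark(7.9, "d3")],
        }
        links = pd.DataFrame(
            {"session_a": ["BL"], "id_a": [0],
             "session_b": ["d3"], "id_b": [1]}
        )
        tracks = sd.match_spines(marks, sessions, manual_links=links)
        linked = {
            (tr.marks[0].attachment_arc_um, tr.marks[1].attachment_arc_um)
            for tr in tracks
            if tr.marks[0] is not None and tr.marks[1] is not None
        }
        assert (5.0, 7.9) in linked


class TestDensityAndRatios:
    def test_density_counts_per_micron(self):
        bb = Backbone.from_polyline(
            np.array([[0.0, 0, 0], [50.0, 0, 0]]), 0.5
        )
        marks = [_mark(a) for a in np.linspace(2, 48, 10)]
        assert sd.spine_density(marks, bb, (0.0, 50.0)) == pytest.approx(0.2)
        assert sd.spine_density([], bb, (0.0, 50.0)) == 0.0
        with pytest.raises(ValueError):
            sd.spine_density(marks, bb, (10.0, 10.0))

    def test_ratio_formulas(self):
        sessions = ("a", "b")
        tracks = []
        tid = 0
        # 10 at a: 2 lost; 1 gained at b
        for _ in range(8):
            tracks.append(sd.SpineTrack(tid, sessions,
                                        (_mark(1.0), _mark(1.0))))
            tid += 1
        for _ in range(2):
            tracks.append(sd.SpineTrack(tid, sessions, (_mark(2.0), None)))
            tid += 1
        tracks.append(sd.SpineTrack(tid, sessions, (None, _mark(3.0))))
        add, elim, turn = sd.dynamics_ratios(tracks, ("a", "b"))
        assert (add, elim, turn) == (
            pytest.approx(0.1), pytest.approx(0.2), pytest.approx(0.15)
        )
        # no events
        stable = tracks[:8]
        assert sd.dynamics_ratios(stable, ("a", "b")) == (0.0, 0.0, 0.0)
        # undefined when nothing present at the earlier session
        only_new = [tracks[-1]]
        out = sd.dynamics_ratios(only_new, ("a", "b"))
        assert all(np.isnan(v) for v in out)

    def test_conservation_across_intervals(self, demo_clean):
        tracks = demo_clean.tracks
        sessions = demo_clean.scene.sessions
        for t in range(1, len(sessions)):
            prev, cur = sessions[t - 1], sessions[t]
            n_prev = sum(tr.marks[t - 1] is not None for tr in tracks)
            n_cur = sum(tr.marks[t] is not None for tr in tracks)
            g = sum(tr.marks[t] is not None and tr.marks[t - 1] is None
                    for tr in tracks)
            l = sum(tr.marks[t - 1] is not None and tr.marks[t] is None
                    for tr in tracks)
            assert n_cur == n_prev - l + g

    def test_stable_plus_eliminated_fractions_sum_to_one(self, demo_clean):
        tracks = demo_clean.tracks
        baseline = [tr for tr in tracks if tr.marks[0] is not None]
        for t in range(1, 4):
            stable = sum(tr.marks[t] is not None for tr in baseline)
            gone = sum(tr.marks[t] is None for tr in baseline)
            assert stable + gone == len(baseline)


def _uniform_roi_stack(spine_value):
    """Straight tube plus a detached uniform block at the spine endpoint."""
    nz, ny, nx = 11, 64, 64
    img = np.full((nz, ny, nx), 10.0)
    pitch = (0.18, 0.18, 1.0)
    stack = sd.ImageStack(img, pitch, "BL")
    xs, ys, zs = stack.voxel_centers_um()
    y0, z0 = 32 * 0.18, 5.0
    tube = (np.abs(ys[None, :, None] - y0) <= 0.5) & \
           (np.abs(zs[:, None, None] - z0) <= 0.51) & \
           (xs[None, None, :] > -1)
    img[tube] = 100.0
    ep = (5.76, y0 + 2.0, z0)
    ball = ((xs[None, None, :] - ep[0]) ** 2
            + (ys[None, :, None] - ep[1]) ** 2 <= 0.7**2) & \
           (np.abs(zs[:, None, None] - ep[2]) <= 1.51)
    img[ball] = spine_value
    bb = Backbone.from_polyline(
        np.array([[0.5, y0, z0], [11.0, y0, z0]]), 0.5
    )
    mark = SpineMark(
        endpoint_um=ep, path_vox=(), attachment_arc_um=5.26,
        attachment_point_um=(5.76, y0 + 0.5, z0),
        protrusion_length_um=1.5, elevation_deg=0.0, included=True,
        source="manual",
    )
    return stack, bb, mark


class TestIntensity:
    @pytest.mark.parametrize("spine_value,expected", [(100.0, 1.0),
                                                      (55.0, 0.5)])
    def test_normalized_intensity_formula(self, spine_value, expected):
        stack, bb, mark = _uniform_roi_stack(spine_value)
        meas = sd.spine_intensity(stack, mark, bb)
        assert meas.valid
        assert meas.spine_mean == pytest.approx(spine_value)
        assert meas.shaft_mean == pytest.approx(100.0)
        assert meas.background_mean == pytest.approx(10.0)
        assert meas.normalized_intensity == pytest.approx(expected)

    def test_undefined_when_shaft_not_above_background(self):
        m = IntensityMeasure(spine_mean=50.0, shaft_mean=10.0,
                             background_mean=10.0, session="BL")
        assert np.isnan(m.normalized_intensity)

    def test_series_baseline_normalization_contracts(self, demo_clean):
        series = demo_clean.intensity
        sessions = demo_clean.scene.sessions
        baseline = sessions[0]
        # every track in the series is present at baseline with value 1.0
        base_vals = series.matrix[baseline].dropna()
        assert np.allclose(base_vals.to_numpy(), 1.0)
        present_at_baseline = {
            tr.track_id for tr in demo_clean.tracks
            if tr.marks[0] is not None
        }
        assert set(series.matrix.index) <= present_at_baseline
        # a track absent in a session has no entry there
        for tr in demo_clean.tracks:
            if tr.track_id not in series.matrix.index:
                continue
            for t, s in enumerate(sessions):
                if tr.marks[t] is None:
                    assert np.isnan(series.matrix.loc[tr.track_id, s])

    def test_degenerate_cdf_when_all_multipliers_one(self):
        scene_cfg = {"brightness_jitter": 0.0, "n_spines": 5,
                     "losses": (0, 0, 0), "gains": (0, 0, 0)}
        res = sd.run_demo(
            seed=3,
            config=sd.PipelineConfig(seed=3, noise="clean", scene=scene_cfg),
        )
        for s in res.scene.sessions:
            vals, probs = res.intensity.cdf(s)
            assert len(vals) > 0
            assert np.allclose(vals, 1.0, atol=0.06)
            assert probs[-1] == 1.0
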