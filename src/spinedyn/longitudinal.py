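"""Cross-session spine correspondence and longitudinal statistics.

Spines are identified across sessions by their arc-length position on the
shared dendritic backbone: consecutive sessions are matched by the
minimum-total-arc-distance assignment restricted to pairs within a hard
tolerance (default 2 µm), an unmatched spine costing the tolerance (gated
assignment with birth/death cost, as in standard particle-tracking
linkers). Unmatched spines end or start tracks; a spine that
disappears and later reappears starts a new track (recurrence off, the
default convention in longitudinal spine imaging).

From the tracks the standard dynamics statistics follow. With ``N_prev``
spines present at the earlier session, ``G`` gained and ``L`` lost by the
later one:

    addition    = G / N_prev
    elimination = L / N_prev
    turnover    = (G + L) / (2 N_prev)

Spine brightness is expressed as the background-subtracted spine ROI mean
divided by the background-subtracted shaft ROI mean (cancelling session-wise
illumination and expression drift), then normalized to baseline per track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .stack import ImageStack
from .tracing import Backbone, RigidShift, arc_positions
from .spines import SpineMark

__all__ = [
    "SpineTrack",
    "DynamicsSummary",
    "IntensityMeasure",
    "RoiParams",
    "IntensitySeries",
    "match_pair",
    "match_spines",
    "spine_density",
    "dynamics_ratios",
    "dynamics_summary",
    "spine_intensity",
    "intensity_series",
]

_BIG = 1e9  # dominates any feasible assignment total


@dataclass
class SpineTrack:
    """One spine identity followed across the session sequence."""

    track_id: int
    sessions: tuple[str, ...]
    marks: tuple[SpineMark | None, ...]  # None where absent

    def __post_init__(self):
        if len(self.marks) != len(self.sessions):
            raise ValueError("one mark slot per session required")
        if not any(m is not None for m in self.marks):
            raise ValueError("track must be present in >=1 session")

    @property
    def present(self) -> tuple[bool, ...]:
        return tuple(m is not None for m in self.marks)

    @property
    def birth_session(self) -> str:
        return self.sessions[self.present.index(True)]

    @property
    def death_session(self) -> str | None:
        """First session after the last presence, or None if still present."""
        pres = self.present
        last = len(pres) - 1 - pres[::-1].index(True)
        return self.sessions[last + 1] if last + 1 < len(pres) else None


@dataclass
class DynamicsSummary:
    """Per-session densities and per-interval dynamics ratios."""

    sessions: tuple[str, ...]
    density_per_um: tuple[float, ...]
    addition_ratio: tuple[float, ...]      # one per interval; nan if undefined
    elimination_ratio: tuple[float, ...]
    turnover_ratio: tuple[float, ...]
    backbone_length_um: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"session": s, "density_per_um": d}
            for s, d in zip(self.sessions, self.density_per_um)
        ]
        per_session = pd.DataFrame(rows)
        intervals = [
            {
                "interval": f"{self.sessions[i]}->{self.sessions[i + 1]}",
                "addition_ratio": self.addition_ratio[i],
                "elimination_ratio": self.elimination_ratio[i],
                "turnover_ratio": self.turnover_ratio[i],
            }
            for i in range(len(self.sessions) - 1)
        ]
        return per_session, pd.DataFrame(intervals)


@dataclass(frozen=True)
class IntensityMeasure:
    """Raw ROI means and the normalized spine intensity for one session."""

    spine_mean: float
    shaft_mean: float
    background_mean: float
    session: str
    valid: bool = True

    @property
    def normalized_intensity(self) -> float:
        """(spine - background) / (shaft - background); nan if undefined."""
        denom = self.shaft_mean - self.background_mean
        if not self.valid or denom <= 0:
            return float("nan")
        return (self.spine_mean - self.background_mean) / denom


@dataclass(frozen=True)
class RoiParams:
    """Geometry of the spine / shaft / background ROIs (µm).

    All three ROIs extend over ±``z_halfwidth_planes`` z-planes around the
    brightest plane of their structure, mirroring measurement above and
    below the optimal imaging plane.
    """

    spine_radius_um: float = 0.4
    shaft_halflength_um: float = 1.0
    background_offset_um: float = 2.5
    background_radius_um: float = 0.5
    z_halfwidth_planes: int = 1


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_pair(arcs_a, arcs_b, tolerance_um: float = 2.0
               ) -> list[tuple[int, int]]:
    """Optimal gated assignment between two arc-position lists.

    Feasible pairs satisfy ``|a - b| <= tolerance``. The returned matching
    minimizes ``sum of matched |a - b| + tolerance * n_unmatched`` over all
    matchings restricted to feasible pairs (the linear-assignment-with-
    birth/death-cost formulation standard in longitudinal puncta tracking:
    leaving a spine unmatched — an elimination or an addition — costs the
    tolerance, so a chain of near-tolerance links can never be cheaper than
    honestly reporting the gain and the loss).
    """
    arcs_a = np.asarray(arcs_a, dtype=np.float64)
    arcs_b = np.asarray(arcs_b, dtype=np.float64)
    n, m = len(arcs_a), len(arcs_b)
    if n == 0 or m == 0:
        return []
    cost = np.abs(arcs_a[:, None] - arcs_b[None, :])
    feasible = cost <= tolerance_um
    # structural cost ties exist (e.g. two earlier arcs both above two later
    # ones); nudge toward the non-crossing pairing with a symmetric term so
    # the matched pairs are unique and identical under session swap
    cost = cost - 1e-9 * np.outer(arcs_a, arcs_b)
    p = float(tolerance_um)
    full = np.full((n + m, m + n), _BIG)
    full[:n, :m] = np.where(feasible, cost, _BIG)
    full[:n, m:] = np.where(np.eye(n, dtype=bool), p, _BIG)  # a_i unmatched
    full[n:, :m] = np.where(np.eye(m, dtype=bool), p, _BIG)  # b_j unmatched
    full[n:, m:] = 0.0                                        # dummy-dummy
    rows, cols = linear_sum_assignment(full)
    return [
        (int(i), int(j)) for i, j in zip(rows, cols)
        if i < n and j < m and feasible[i, j]
    ]


def match_spines(
    marks_by_session: dict[str, list[SpineMark]],
    sessions: tuple[str, ...],
    tolerance_um: float = 2.0,
    manual_links: pd.DataFrame | None = None,
) -> list[SpineTrack]:
    """Build spine tracks by chaining consecutive-session matches.

    Only marks flagged ``included`` participate, matching the convention
    that all dynamics statistics use the filtered spine set. A manual
    correspondence table (columns session_a, id_a, session_b, id_b, indices
    into each session's included marks) overrides individual links; a spine
    referenced by two manual links in the same direction is rejected.
    """
    included = {
        s: [m for m in marks_by_session.get(s, []) if m.included]
        for s in sessions
    }

    forced: dict[tuple[str, int], int] = {}
    if manual_links is not None:
        seen_a: set[tuple[str, int]] = set()
        seen_b: set[tuple[str, int]] = set()
        for row in manual_links.itertuples():
            ka = (str(row.session_a), int(row.id_a))
            kb = (str(row.session_b), int(row.id_b))
            if ka in seen_a or kb in seen_b:
                raise ValueError(
                    f"duplicate manual link involving {ka} or {kb}"
                )
            seen_a.add(ka)
            seen_b.add(kb)
            forced[ka] = int(row.id_b)

    # track id carried by each (session, mark index)
    carrier: dict[tuple[str, int], int] = {}
    track_marks: dict[int, dict[str, SpineMark]] = {}
    next_id = 0
    for i, m in enumerate(included[sessions[0]]):
        carrier[(sessions[0], i)] = next_id
        track_marks[next_id] = {sessions[0]: m}
        next_id += 1

    for t in range(1, len(sessions)):
        s_prev, s_cur = sessions[t - 1], sessions[t]
        prev_marks = included[s_prev]
        cur_marks = included[s_cur]

        links: dict[int, int] = {}
        manual_prev: set[int] = set()
        manual_cur: set[int] = set()
        for (sa, ia), ib in forced.items():
            if sa == s_prev:
                if ia >= len(prev_marks) or ib >= len(cur_marks):
                    raise ValueError(
                        f"manual link ({sa},{ia})->({s_cur},{ib}) out of range"
                    )
                links[ia] = ib
                manual_prev.add(ia)
                manual_cur.add(ib)

        free_prev = [i for i in range(len(prev_marks)) if i not in manual_prev]
        free_cur = [j for j in range(len(cur_marks)) if j not in manual_cur]
        auto = match_pair(
            [prev_marks[i].attachment_arc_um for i in free_prev],
            [cur_marks[j].attachment_arc_um for j in free_cur],
            tolerance_um,
        )
        for a, b in auto:
            links[free_prev[a]] = free_cur[b]

        for i, j in links.items():
            tid = carrier[(s_prev, i)]
            carrier[(s_cur, j)] = tid
            track_marks[tid][s_cur] = cur_marks[j]
        for j, m in enumerate(cur_marks):
            if (s_cur, j) not in carrier:
                carrier[(s_cur, j)] = next_id
                track_marks[next_id] = {s_cur: m}
                next_id += 1

    return [
        SpineTrack(
            track_id=tid,
            sessions=tuple(sessions),
            marks=tuple(by_session.get(s) for s in sessions),
        )
        for tid, by_session in sorted(track_marks.items())
    ]


# ---------------------------------------------------------------------------
# Density and dynamics
# ---------------------------------------------------------------------------

def spine_density(marks, backbone: Backbone,
                  segment: tuple[float, float] | None = None) -> float:
    """Included spines per µm of backbone within an arc interval."""
    if segment is None:
        segment = (0.0, backbone.total_length_um)
    a, b = float(segment[0]), float(segment[1])
    if not (0.0 <= a < b <= backbone.total_length_um + 1e-9):
        raise ValueError("segment must be a nonempty interval on the backbone")
    count = sum(
        1 for m in marks
        if m.included and a <= m.attachment_arc_um <= b
    )
    return count / (b - a)


def dynamics_ratios(tracks, session_pair: tuple[str, str]
                    ) -> tuple[float, float, float]:
    """(addition, elimination, turnover) for an ordered session pair.

    Undefined (no spines at the earlier session) returns three nans.
    """
    s_prev, s_cur = session_pair
    n_prev = g = l = 0
    for tr in tracks:
        p_prev = tr.marks[tr.sessions.index(s_prev)] is not None
        p_cur = tr.marks[tr.sessions.index(s_cur)] is not None
        n_prev += p_prev
        g += (not p_prev) and p_cur
        l += p_prev and (not p_cur)
    if n_prev == 0:
        return (float("nan"),) * 3
    return (g / n_prev, l / n_prev, (g + l) / (2.0 * n_prev))


def dynamics_summary(tracks, backbone: Backbone,
                     sessions: tuple[str, ...],
                     segment: tuple[float, float] | None = None,
                     reference: str = "previous") -> DynamicsSummary:
    """Densities per session plus ratios per interval.

    ``reference="previous"`` compares each session with the one before it
    (the default); ``reference="baseline"`` compares every follow-up with
    the first session.
    """
    if reference not in ("previous", "baseline"):
        raise ValueError("reference must be 'previous' or 'baseline'")
    densities = []
    for s in sessions:
        marks = [
            tr.marks[tr.sessions.index(s)] for tr in tracks
            if tr.marks[tr.sessions.index(s)] is not None
        ]
        densities.append(spine_density(marks, backbone, segment))
    add, elim, turn = [], [], []
    for t in range(1, len(sessions)):
        prev = sessions[t - 1] if reference == "previous" else sessions[0]
        a, e, u = dynamics_ratios(tracks, (prev, sessions[t]))
        add.append(a)
        elim.append(e)
        turn.append(u)
    return DynamicsSummary(
        sessions=tuple(sessions),
        density_per_um=tuple(densities),
        addition_ratio=tuple(add),
        elimination_ratio=tuple(elim),
        turnover_ratio=tuple(turn),
        backbone_length_um=backbone.total_length_um,
    )


# ---------------------------------------------------------------------------
# ROI intensity
# ---------------------------------------------------------------------------

def _roi_voxels_mask(stack: ImageStack, center_um, radius_um: float,
                     z_center_plane: int, z_half: int) -> np.ndarray:
    """Boolean mask: xy-distance to centre <= radius, z within +/- z_half
    planes of ``z_center_plane``."""
    nz, ny, nx = stack.shape_zyx
    px, py, pz = stack.voxel_pitch_um
    xs = np.arange(nx) * px - center_um[0]
    ys = np.arange(ny) * py - center_um[1]
    xy2 = ys[:, None] ** 2 + xs[None, :] ** 2
    mask = np.zeros((nz, ny, nx), dtype=bool)
    z0 = max(0, z_center_plane - z_half)
    z1 = min(nz - 1, z_center_plane + z_half)
    mask[z0:z1 + 1] = xy2[None, :, :] <= radius_um**2
    return mask


def _brightest_plane(stack: ImageStack, center_um, radius_um: float,
                     z_half: int = 1) -> int:
    """Centre of the brightest ``2*z_half+1``-plane window of an xy-disc.

    Optimizing the window rather than a single plane keeps the ROI stable
    when photon noise reorders two nearly equal planes between sessions.
    """
    full = _roi_voxels_mask(stack, center_um, radius_um, 0, stack.shape_zyx[0])
    sums = np.array(
        [stack.intensities[z][full[z]].mean() if full[z].any() else 0.0
         for z in range(stack.shape_zyx[0])]
    )
    kernel = np.ones(2 * z_half + 1)
    windowed = np.convolve(sums, kernel, mode="same")
    return int(np.argmax(windowed))


def spine_intensity(stack: ImageStack, mark: SpineMark, backbone: Backbone,
                    roi: RoiParams | None = None) -> IntensityMeasure:
    """Spine / shaft / background ROI means for one spine in one session.

    Spine ROI: cylinder of ``spine_radius_um`` around the endpoint over
    ±1 z-plane of its brightest plane. Shaft ROI: backbone tube voxels
    within ``shaft_halflength_um`` of the attachment arc (spine ROI voxels
    excluded). Background ROI: a disc displaced from the attachment point
    away from the spine, on the opposite side of the shaft, containing no
    structure by construction. Pairwise disjointness is enforced; a measure
    whose ROIs would overlap is flagged invalid.
    """
    roi = roi or RoiParams()
    endpoint = np.asarray(mark.endpoint_um)
    attach = np.asarray(mark.attachment_point_um)

    z_spine = _brightest_plane(stack, endpoint, roi.spine_radius_um)
    spine_mask = _roi_voxels_mask(
        stack, endpoint, roi.spine_radius_um, z_spine, roi.z_halfwidth_planes
    )

    # shaft: tube voxels near the attachment arc
    nz, ny, nx = stack.shape_zyx
    px, py, pz = stack.voxel_pitch_um
    lo_arc = mark.attachment_arc_um - roi.shaft_halflength_um
    hi_arc = mark.attachment_arc_um + roi.shaft_halflength_um
    # bounding box around the relevant backbone portion
    seg_pts = backbone.points_um[
        (backbone.cum_arclength_um >= lo_arc - 1.0)
        & (backbone.cum_arclength_um <= hi_arc + 1.0)
    ]
    if len(seg_pts) == 0:
        seg_pts = backbone.points_um
    pad = backbone.radius_um.max() + 0.5
    lo_um = seg_pts.min(axis=0) - pad
    hi_um = seg_pts.max(axis=0) + pad
    lo_idx = np.clip(np.floor(stack.um_to_index(lo_um)).astype(int), 0, None)
    hi_idx = np.minimum(
        np.ceil(stack.um_to_index(hi_um)).astype(int) + 1, [nz, ny, nx]
    )
    zz, yy, xx = np.meshgrid(
        np.arange(lo_idx[0], hi_idx[0]), np.arange(lo_idx[1], hi_idx[1]),
        np.arange(lo_idx[2], hi_idx[2]), indexing="ij",
    )
    centers = np.stack(
        [xx.ravel() * px, yy.ravel() * py, zz.ravel() * pz], axis=1
    )
    arcs, offs = arc_positions(backbone, centers)
    radii = np.interp(arcs, backbone.cum_arclength_um, backbone.radius_um)
    in_tube = (offs <= radii) & (arcs >= lo_arc) & (arcs <= hi_arc)
    shaft_mask = np.zeros((nz, ny, nx), dtype=bool)
    shaft_mask[zz.ravel()[in_tube], yy.ravel()[in_tube],
               xx.ravel()[in_tube]] = True
    # restrict shaft to +/- z planes around its own brightest plane
    z_shaft = _brightest_plane(stack, attach, 0.6)
    zkeep = np.zeros(nz, dtype=bool)
    zkeep[max(0, z_shaft - roi.z_halfwidth_planes):
          z_shaft + roi.z_halfwidth_planes + 1] = True
    shaft_mask &= zkeep[:, None, None]
    shaft_mask &= ~spine_mask  # disjoint by construction

    # background: displaced from the attachment point, away from the spine
    away = attach - endpoint
    away[2] = 0.0
    n = np.linalg.norm(away)
    away = np.array([0.0, 1.0, 0.0]) if n < 1e-9 else away / n
    bg_center = attach + roi.background_offset_um * away
    bg_center = np.clip(bg_center, 0.6, stack.extent_um - 0.6)
    bg_mask = _roi_voxels_mask(
        stack, bg_center, roi.background_radius_um, z_spine,
        roi.z_halfwidth_planes,
    )
    bg_mask &= ~spine_mask
    overlap = bool(np.any(bg_mask & shaft_mask))
    bg_mask &= ~shaft_mask

    valid = (spine_mask.any() and shaft_mask.any() and bg_mask.any()
             and not overlap)
    def _mean(mask):
        return float(stack.intensities[mask].mean()) if mask.any() else float("nan")

    return IntensityMeasure(
        spine_mean=_mean(spine_mask),
        shaft_mean=_mean(shaft_mask),
        background_mean=_mean(bg_mask),
        session=stack.session,
        valid=bool(valid),
    )


@dataclass
class IntensitySeries:
    """Baseline-normalized intensity statistics over tracked spines."""

    sessions: tuple[str, ...]
    matrix: pd.DataFrame          # tracks x sessions, value_t (nan if absent)
    mean: pd.Series               # per-session group mean
    sem: pd.Series                # per-session SEM
    cumulative: dict[str, np.ndarray]  # session -> sorted value_t samples

    def cdf(self, session: str) -> tuple[np.ndarray, np.ndarray]:
        """Empirical CDF support and probabilities for one session."""
        v = self.cumulative[session]
        return v, np.arange(1, len(v) + 1) / len(v)


def intensity_series(tracks, stacks: dict[str, ImageStack],
                     backbone: Backbone, baseline_session: str,
                     roi: RoiParams | None = None,
                     shifts: dict[str, RigidShift] | None = None,
                     ) -> IntensitySeries:
    """Per-track normalized intensity relative to baseline, with summaries.

    Only tracks present at baseline contribute; each track contributes at the
    sessions where it is present and its measurement is valid. ROI geometry
    is evaluated in each session's own frame (marks are stored in the
    reference frame; per-session shifts, when given, map them back).
    """
    roi = roi or RoiParams()
    sessions = tracks[0].sessions if tracks else tuple(stacks)
    if baseline_session not in sessions:
        raise ValueError(f"unknown baseline session {baseline_session!r}")

    values: dict[int, dict[str, float]] = {}
    for tr in tracks:
        base_mark = tr.marks[sessions.index(baseline_session)]
        if base_mark is None:
            continue  # intensity series requires presence at baseline
        per_session: dict[str, float] = {}
        for s, m in zip(sessions, tr.marks):
            if m is None or s not in stacks:
                continue
            mark = m
            bb = backbone
            if shifts is not None and s in shifts:
                t = shifts[s].translation_um
                mark = _shift_mark(m, -t)
                bb = backbone.shifted(-t)
            meas = spine_intensity(stacks[s], mark, bb, roi)
            per_session[s] = meas.normalized_intensity
        base = per_session.get(baseline_session, float("nan"))
        if not math.isfinite(base) or base <= 0:
            continue
        values[tr.track_id] = {
            s: v / base for s, v in per_session.items() if math.isfinite(v)
        }

    matrix = pd.DataFrame.from_dict(values, orient="index",
                                    columns=list(sessions))
    matrix = matrix.reindex(columns=list(sessions))
    mean = matrix.mean(axis=0, skipna=True)
    count = matrix.count(axis=0)
    sem = matrix.std(axis=0, ddof=1, skipna=True) / np.sqrt(
        count.where(count > 0)
    )
    cumulative = {
        s: np.sort(matrix[s].dropna().to_numpy()) for s in sessions
    }
    return IntensitySeries(
        sessions=tuple(sessions), matrix=matrix, mean=mean, sem=sem,
        cumulative=cumulative,
    )


def _shift_mark(mark: SpineMark, translation_um) -> SpineMark:
    from dataclasses import replace

    t = np.asarray(translation_um, dtype=np.float64)
    return replace(
        mark,
        endpoint_um=tuple(np.asarray(mark.endpoint_um) + t),
        attachment_point_um=tuple(np.asarray(mark.attachment_point_um) + t),
    )
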