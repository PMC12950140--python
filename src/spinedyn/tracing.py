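"""Dendritic backbone tracing, arc-length coordinates, session registration.

The backbone is extracted as the minimum-cost bright path between two
operator-provided seed points (cost inversely related to intensity on the
26-connected voxel graph, steps weighted by their physical length), then
each path point is re-centred on the local intensity centroid in its normal
plane and the local radius is estimated as the in-plane half-width at
half-maximum of the perpendicular intensity profile.

Sessions are aligned by translation-only registration (phase correlation
with sub-voxel refinement); in-vivo relocation of the same field is done by
the experimenter, so only a small residual rigid shift is expected and
rotation is neglected.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .stack import ImageStack

__all__ = [
    "Backbone",
    "RigidShift",
    "TracingError",
    "trace_backbone",
    "arc_position",
    "arc_positions",
    "register_sessions",
    "estimate_background",
]


class TracingError(RuntimeError):
    """No acceptable bright path exists between the seeds."""


@dataclass
class Backbone:
    """Ordered centreline polyline with per-point radius and arc length."""

    points_um: np.ndarray        # (n, 3) as (x, y, z) µm
    radius_um: np.ndarray        # (n,)
    cum_arclength_um: np.ndarray  # (n,) nondecreasing, starts at 0

    def __post_init__(self):
        self.points_um = np.asarray(self.points_um, dtype=np.float64)
        self.radius_um = np.asarray(self.radius_um, dtype=np.float64)
        self.cum_arclength_um = np.asarray(self.cum_arclength_um,
                                           dtype=np.float64)
        n = len(self.points_um)
        if not (len(self.radius_um) == len(self.cum_arclength_um) == n):
            raise ValueError("backbone field lengths differ")
        if n < 2:
            raise ValueError("backbone needs >=2 points")
        if np.any(self.radius_um <= 0):
            raise ValueError("backbone radii must be positive")
        if self.cum_arclength_um[0] != 0 or np.any(
            np.diff(self.cum_arclength_um) < 0
        ):
            raise ValueError("arc length must start at 0 and be nondecreasing")

    @classmethod
    def from_polyline(cls, points_um, radius_um) -> "Backbone":
        points_um = np.asarray(points_um, dtype=np.float64)
        radius_um = np.broadcast_to(
            np.asarray(radius_um, dtype=np.float64), (len(points_um),)
        ).copy()
        steps = np.linalg.norm(np.diff(points_um, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(steps)])
        return cls(points_um, radius_um, arc)

    @property
    def total_length_um(self) -> float:
        return float(self.cum_arclength_um[-1])

    def point_at_arc(self, arc_um: float) -> np.ndarray:
        s = self.cum_arclength_um
        arc = float(np.clip(arc_um, 0.0, s[-1]))
        return np.array(
            [np.interp(arc, s, self.points_um[:, k]) for k in range(3)]
        )

    def radius_at_arc(self, arc_um: float) -> float:
        s = self.cum_arclength_um
        return float(np.interp(np.clip(arc_um, 0, s[-1]), s, self.radius_um))

    def reversed(self) -> "Backbone":
        steps = np.linalg.norm(np.diff(self.points_um[::-1], axis=0), axis=1)
        return Backbone(
            self.points_um[::-1].copy(),
            self.radius_um[::-1].copy(),
            np.concatenate([[0.0], np.cumsum(steps)]),
        )

    def shifted(self, translation_um) -> "Backbone":
        return Backbone(
            self.points_um + np.asarray(translation_um, dtype=np.float64),
            self.radius_um.copy(),
            self.cum_arclength_um.copy(),
        )


@dataclass
class RigidShift:
    """Translation mapping a moving stack into the reference frame.

    ``reference_point = moving_point + translation_um``.
    """

    translation_um: np.ndarray
    score: float
    low_confidence: bool = False

    def __post_init__(self):
        self.translation_um = np.asarray(self.translation_um, dtype=np.float64)
        if not np.isfinite(self.score):
            raise ValueError("registration score must be finite")


# ---------------------------------------------------------------------------
# Arc-length projection
# ---------------------------------------------------------------------------

def arc_positions(backbone: Backbone, points_um) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto the backbone; vectorized over points.

    Returns ``(arc_um, lateral_offset_um)`` arrays: the cumulative arc length
    of the foot point on the nearest segment, and the perpendicular distance
    to it. Ties between equidistant segments resolve to the lowest segment
    index, which makes the result deterministic.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=np.float64))
    a = backbone.points_um[:-1]            # (m, 3)
    d = backbone.points_um[1:] - a         # (m, 3)
    seg_len2 = np.einsum("ij,ij->i", d, d)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)

    # (n, m) projection parameter of each point on each segment
    diff = pts[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("nmj,mj->nm", diff, d) / seg_len2, 0.0, 1.0)
    foot = a[None, :, :] + t[..., None] * d[None, :, :]
    dist = np.linalg.norm(pts[:, None, :] - foot, axis=2)

    best = np.argmin(dist, axis=1)
    rows = np.arange(len(pts))
    seg_arc = backbone.cum_arclength_um[:-1]
    seg_span = np.diff(backbone.cum_arclength_um)
    arc = seg_arc[best] + t[rows, best] * seg_span[best]
    return arc, dist[rows, best]


def arc_position(backbone: Backbone, point_um) -> tuple[float, float]:
    """Arc-length coordinate and lateral offset of a single point."""
    arc, off = arc_positions(backbone, np.asarray(point_um)[None, :])
    return float(arc[0]), float(off[0])


# ---------------------------------------------------------------------------
# Backbone tracing
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = np.array(
    [(dz, dy, dx)
     for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz, dy, dx) != (0, 0, 0)],
    dtype=np.int64,
)


def estimate_background(stack: ImageStack) -> float:
    """Background level: the median voxel (structures are sparse)."""
    return float(np.median(stack.intensities))


def _min_cost_path(stack: ImageStack, start_vox, goal_vox,
                   passable: np.ndarray) -> list[tuple[int, int, int]]:
    """Dijkstra minimum-cost path on passable voxels, 26-connectivity.

    Step cost = physical step length / (mean intensity of the two voxels
    above background), so bright voxels are cheap and the optimum follows
    the dendrite.
    """
    img = stack.intensities
    shape = np.array(img.shape)
    bg = estimate_background(stack)
    weight = np.clip(img - bg, 1e-6, None)
    pitch_zyx = np.array(
        [stack.voxel_pitch_um[2], stack.voxel_pitch_um[1],
         stack.voxel_pitch_um[0]]
    )
    step_len = np.linalg.norm(_NEIGHBOR_OFFSETS * pitch_zyx, axis=1)

    start = tuple(start_vox)
    goal = tuple(goal_vox)
    if not (passable[start] and passable[goal]):
        raise TracingError("seed lies in background (no dendrite signal)")

    dist: dict[tuple[int, int, int], float] = {start: 0.0}
    prev: dict[tuple[int, int, int], tuple[int, int, int]] = {}
    heap: list[tuple[float, tuple[int, int, int]]] = [(0.0, start)]
    visited: set[tuple[int, int, int]] = set()
    while heap:
        d0, node = heapq.heappop(heap)
        if node in visited:
            continue
        if node == goal:
            break
        visited.add(node)
        nz, ny, nx = node
        for k, (dz, dy, dx) in enumerate(_NEIGHBOR_OFFSETS):
            nb = (nz + dz, ny + dy, nx + dx)
            if not (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1]
                    and 0 <= nb[2] < shape[2]):
                continue
            if not passable[nb] or nb in visited:
                continue
            w = 2.0 * step_len[k] / (weight[node] + weight[nb])
            nd = d0 + w
            if nd < dist.get(nb, math.inf):
                dist[nb] = nd
                prev[nb] = node
                heapq.heappush(heap, (nd, nb))
    else:
        raise TracingError("no bright path connects the seeds")
    if goal not in prev and goal != start:
        raise TracingError("no bright path connects the seeds")

    path = [goal]
    while path[-1] != start:
        path.append(prev[path[-1]])
    path.reverse()
    return path


def _resample_polyline(points: np.ndarray, step_um: float) -> np.ndarray:
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = np.concatenate([[True], steps > 1e-9])
    points = points[keep]
    if len(points) < 2:
        return points
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    new_s = np.arange(0.0, s[-1] + step_um / 2, step_um)
    new_s[-1] = min(new_s[-1], s[-1])
    return np.stack(
        [np.interp(new_s, s, points[:, k]) for k in range(3)], axis=1
    )


def _normal_frame(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane normal and the completing normal for a unit tangent."""
    t = tangent / max(np.linalg.norm(tangent), 1e-12)
    n1 = np.array([-t[1], t[0], 0.0])
    if np.linalg.norm(n1) < 1e-6:          # tangent along z: any xy direction
        n1 = np.array([1.0, 0.0, 0.0])
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(t, n1)
    n2 /= max(np.linalg.norm(n2), 1e-12)
    return n1, n2


def _interp_intensity(stack: ImageStack, points_um: np.ndarray) -> np.ndarray:
    idx = stack.um_to_index(points_um)      # (..., 3) fractional (z, y, x)
    coords = np.moveaxis(idx, -1, 0)
    return ndimage.map_coordinates(stack.intensities, coords, order=1,
                                   mode="nearest")


def _center_points(stack: ImageStack, points: np.ndarray, bg: float,
                   half_window_um: float = 0.8, step_um: float = 0.06,
                   n_iter: int = 3) -> np.ndarray:
    """Pull each point to the intensity centroid in its normal plane."""
    offsets = np.arange(-half_window_um, half_window_um + step_um / 2, step_um)
    uu, vv = np.meshgrid(offsets, offsets, indexing="ij")
    centred = points.copy()
    for _ in range(n_iter):
        grad = np.gradient(centred, axis=0)
        for i in range(len(centred)):
            n1, n2 = _normal_frame(grad[i])
            plane = (centred[i]
                     + uu[..., None] * n1[None, None, :]
                     + vv[..., None] * n2[None, None, :])
            vals = np.clip(_interp_intensity(stack, plane) - bg, 0.0, None)
            total = vals.sum()
            if total <= 0:
                continue
            du = (vals * uu).sum() / total
            dv = (vals * vv).sum() / total
            centred[i] = centred[i] + du * n1 + dv * n2
    return centred


def _estimate_radii(stack: ImageStack, points: np.ndarray, bg: float,
                    max_radius_um: float = 1.5,
                    step_um: float = 0.03) -> np.ndarray:
    """Per-point in-plane half-width at half-maximum of the radial profile."""
    offsets = np.arange(0.0, max_radius_um + step_um / 2, step_um)
    grad = np.gradient(points, axis=0)
    radii = np.empty(len(points))
    for i in range(len(points)):
        n1, _ = _normal_frame(grad[i])
        widths = []
        for direction in (n1, -n1):
            line = points[i] + offsets[:, None] * direction[None, :]
            prof = _interp_intensity(stack, line) - bg
            if prof[0] <= 0:
                continue
            half = prof[0] / 2.0
            below = np.nonzero(prof < half)[0]
            if len(below) == 0:
                widths.append(offsets[-1])
                continue
            j = below[0]
            if j == 0:
                widths.append(step_um / 2)
                continue
            frac = (prof[j - 1] - half) / max(prof[j - 1] - prof[j], 1e-12)
            widths.append(offsets[j - 1] + frac * step_um)
        # min of the two sides: a spine on one side inflates that side's
        # half-width, the opposite side still reads the true shaft radius
        radii[i] = np.min(widths) if widths else np.nan
    if np.all(np.isnan(radii)):
        raise TracingError("radius estimation failed everywhere on the path")
    med = np.nanmedian(radii)
    radii = np.where(np.isnan(radii), med, radii)
    # rolling median knocks out residual spine-adjacent outliers
    if len(radii) >= 5:
        from scipy.ndimage import median_filter

        radii = median_filter(radii, size=5, mode="nearest")
    return np.clip(radii, 0.05, None)


def trace_backbone(stack: ImageStack, seeds, *,
                   passable_fraction: float = 0.1,
                   resample_step_um: float = 0.2,
                   smooth_window: int = 9) -> Backbone:
    """Trace the dendritic backbone between seed points.

    Parameters
    ----------
    stack : ImageStack
    seeds : sequence of >=2 points (x, y, z) µm
        Operator-style initialisation near the two ends of the dendrite
        segment (intermediate seeds are currently unused beyond validation).
    passable_fraction : float
        Voxels must exceed ``background + fraction * (max - background)``
        to be traversable.

    Raises ``TracingError`` when a seed sits in background or no bright
    path connects the seeds.
    """
    seeds = np.asarray(seeds, dtype=np.float64)
    if seeds.ndim != 2 or len(seeds) < 2 or seeds.shape[1] != 3:
        raise ValueError("need >=2 seed points of (x, y, z) µm")
    for s in seeds:
        if not stack.in_bounds(s):
            raise ValueError(f"seed {s} outside stack bounds")

    img = stack.intensities
    bg = estimate_background(stack)
    thresh = bg + passable_fraction * (float(img.max()) - bg)
    if img.max() <= bg:
        raise TracingError("stack has no structure above background")
    passable = img > thresh

    start = stack.nearest_voxel(seeds[0])
    goal = stack.nearest_voxel(seeds[-1])
    path_vox = _min_cost_path(stack, start, goal, passable)
    points = stack.index_to_um(np.asarray(path_vox, dtype=np.float64))
    points = _resample_polyline(points, resample_step_um)
    points = _center_points(stack, points, bg)
    if smooth_window > 1 and len(points) > smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        sm = points.copy()
        for k in range(3):
            sm[:, k] = np.convolve(
                np.pad(points[:, k], smooth_window // 2, mode="edge"),
                kernel, mode="valid",
            )[: len(points)]
        points = sm
    points = _resample_polyline(points, resample_step_um)
    radii = _estimate_radii(stack, points, bg)
    return Backbone.from_polyline(points, radii)


# ---------------------------------------------------------------------------
# Session registration
# ---------------------------------------------------------------------------

def register_sessions(reference: ImageStack, moving: ImageStack, *,
                      upsample_factor: int = 20,
                      score_floor: float = 0.2) -> RigidShift:
    """Recover the rigid translation aligning ``moving`` onto ``reference``.

    Phase correlation with sub-voxel refinement; the returned score is the
    Pearson correlation of the overlapping regions after applying the
    integer part of the shift. A score below ``score_floor`` flags the
    result as low-confidence (the pipeline continues with a warning).
    """
    if reference.voxel_pitch_um != moving.voxel_pitch_um:
        raise ValueError("stacks must share a voxel pitch")
    # stage 1: integer-voxel grid search (FFT correlation); stage 2:
    # sub-voxel refinement on the cropped overlap only, so content that
    # slid out of the field cannot bias the fractional part
    coarse, _e1, _p1 = phase_cross_correlation(
        reference.intensities, moving.intensities,
        upsample_factor=1, normalization=None,
    )
    coarse = np.rint(coarse).astype(int)
    sl_ref, sl_mov = [], []
    for ax in range(3):
        s, n = int(coarse[ax]), reference.intensities.shape[ax]
        if abs(s) >= n - 2:
            sl_ref, sl_mov = None, None
            break
        if s >= 0:
            sl_ref.append(slice(s, n))
            sl_mov.append(slice(0, n - s))
        else:
            sl_ref.append(slice(0, n + s))
            sl_mov.append(slice(-s, n))
    if sl_ref is None:
        shift_vox = coarse.astype(np.float64)
    else:
        fine, _e2, _p2 = phase_cross_correlation(
            reference.intensities[tuple(sl_ref)],
            moving.intensities[tuple(sl_mov)],
            upsample_factor=upsample_factor, normalization=None,
        )
        shift_vox = coarse + fine
    # shift_vox is (z, y, x): moving displaced by +shift matches reference
    px, py, pz = reference.voxel_pitch_um
    translation_um = np.array(
        [shift_vox[2] * px, shift_vox[1] * py, shift_vox[0] * pz]
    )
    score = _overlap_correlation(
        reference.intensities, moving.intensities,
        np.rint(shift_vox).astype(int),
    )
    low = bool(score < score_floor)
    if low:
        import warnings

        warnings.warn(
            f"session registration low confidence (score={score:.3f})",
            stacklevel=2,
        )
    return RigidShift(translation_um, float(score), low)


def _overlap_correlation(ref: np.ndarray, mov: np.ndarray,
                         shift_vox: np.ndarray) -> float:
    """Pearson correlation of ref with integer-shifted mov on their overlap."""
    slices_ref, slices_mov = [], []
    for axis in range(3):
        s = int(shift_vox[axis])
        n = ref.shape[axis]
        if abs(s) >= n:
            return 0.0
        if s >= 0:
            slices_ref.append(slice(s, n))
            slices_mov.append(slice(0, n - s))
        else:
            slices_ref.append(slice(0, n + s))
            slices_mov.append(slice(-s, n))
    a = ref[tuple(slices_ref)].ravel()
    b = mov[tuple(slices_mov)].ravel()
    if a.size < 8 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
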