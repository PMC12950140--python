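"""3-D image stack container and coordinate conventions.

Conventions used throughout the package:

* Arrays are indexed ``[z, y, x]`` (z-pages first, matching multi-page TIFF
  layout).
* Physical points are length-3 vectors ``(x, y, z)`` in micrometres.
* Voxel indices are 0-based; the physical position of voxel ``(iz, iy, ix)``
  is its centre, ``(ix * px, iy * py, iz * pz)`` µm, where
  ``(px, py, pz)`` is the voxel pitch.

On-disk files always store micrometres, never voxel indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """One imaging session's single-channel 3-D intensity grid.

    Parameters
    ----------
    intensities : ndarray, shape (nz, ny, nx)
        Non-negative intensity values.
    voxel_pitch_um : tuple of float
        Voxel pitch ``(x, y, z)`` in µm. Default matches in-vivo two-photon
        acquisition of apical dendrites: 0.18 µm laterally, 1 µm z-step.
    session : str
        Session label, e.g. ``"BL"``, ``"d3"``.
    """

    intensities: np.ndarray
    voxel_pitch_um: tuple[float, float, float] = (0.18, 0.18, 1.0)
    session: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array (z, y, x)")
        if min(self.intensities.shape) < 1:
            raise ValueError("stack must have >=1 voxel per axis")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        self.voxel_pitch_um = tuple(float(p) for p in self.voxel_pitch_um)
        if len(self.voxel_pitch_um) != 3 or min(self.voxel_pitch_um) <= 0:
            raise ValueError("voxel pitch must be three positive values")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def extent_um(self) -> np.ndarray:
        """Physical field size (x, y, z) in µm."""
        nz, ny, nx = self.intensities.shape
        px, py, pz = self.voxel_pitch_um
        return np.array([nx * px, ny * py, nz * pz])

    def index_to_um(self, idx_zyx) -> np.ndarray:
        """Voxel index/indices ``(z, y, x)`` -> point(s) ``(x, y, z)`` µm."""
        idx = np.asarray(idx_zyx, dtype=np.float64)
        px, py, pz = self.voxel_pitch_um
        return np.stack(
            [idx[..., 2] * px, idx[..., 1] * py, idx[..., 0] * pz], axis=-1
        )

    def um_to_index(self, point_um) -> np.ndarray:
        """Point(s) ``(x, y, z)`` µm -> fractional voxel index ``(z, y, x)``."""
        p = np.asarray(point_um, dtype=np.float64)
        px, py, pz = self.voxel_pitch_um
        return np.stack([p[..., 2] / pz, p[..., 1] / py, p[..., 0] / px], axis=-1)

    def nearest_voxel(self, point_um) -> tuple[int, int, int]:
        """Nearest in-bounds voxel index (z, y, x) to a physical point."""
        idx = np.rint(self.um_to_index(point_um)).astype(int)
        idx = np.clip(idx, 0, np.array(self.intensities.shape) - 1)
        return tuple(int(i) for i in idx)

    def in_bounds(self, point_um) -> bool:
        p = np.asarray(point_um, dtype=np.float64)
        half = np.array(self.voxel_pitch_um) / 2.0
        return bool(np.all(p >= -half) and np.all(p <= self.extent_um - half))

    def voxel_centers_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D centre coordinate arrays (x_of_ix, y_of_iy, z_of_iz) in µm."""
        nz, ny, nx = self.intensities.shape
        px, py, pz = self.voxel_pitch_um
        return (
            np.arange(nx) * px,
            np.arange(ny) * py,
            np.arange(nz) * pz,
        )
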