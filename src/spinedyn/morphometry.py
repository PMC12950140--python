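"""Reconstruction morphometry: Sholl profiles and tree summaries.

Trees are SWC-style rooted morphologies (astrocytes or biocytin-filled
pyramidal neurons reconstructed from confocal stacks). The Sholl profile
counts process crossings of concentric spheres around the soma; the summary
statistics are total process length, the number of primary processes
(children of the root) and the volume obtained by treating every
parent-child segment as a conical frustum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import load_swc

__all__ = ["MorphTree", "sholl_profile", "morphology_summary"]


@dataclass
class MorphTree:
    """Rooted tree morphology: node positions (µm), radii (µm), parents.

    ``parent[i]`` is the index of node i's parent, or -1 for the single
    root (the soma centre). Parents must precede children, which also rules
    out cycles.
    """

    positions_um: np.ndarray  # (n, 3)
    radii_um: np.ndarray      # (n,)
    parents: np.ndarray       # (n,) int, -1 for root

    def __post_init__(self):
        self.positions_um = np.asarray(self.positions_um, dtype=np.float64)
        self.radii_um = np.asarray(self.radii_um, dtype=np.float64)
        self.parents = np.asarray(self.parents, dtype=np.int64)
        n = len(self.positions_um)
        if n == 0:
            raise ValueError("empty tree")
        if not (len(self.radii_um) == len(self.parents) == n):
            raise ValueError("tree field lengths differ")
        roots = np.nonzero(self.parents == -1)[0]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        for i, p in enumerate(self.parents):
            if p != -1 and not 0 <= p < i:
                raise ValueError("parents must precede children")

    @property
    def root(self) -> int:
        return int(np.nonzero(self.parents == -1)[0][0])

    @classmethod
    def from_swc(cls, path) -> "MorphTree":
        df = load_swc(path)
        id_to_idx = {int(i): k for k, i in enumerate(df["id"])}
        parents = np.array(
            [-1 if p == -1 else id_to_idx[int(p)] for p in df["parent"]]
        )
        return cls(df[["x", "y", "z"]].to_numpy(), df["radius"].to_numpy(),
                   parents)

    def segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Parent/child endpoint arrays and radii for all non-root nodes."""
        child = np.nonzero(self.parents != -1)[0]
        par = self.parents[child]
        return (self.positions_um[par], self.positions_um[child],
                self.radii_um[par], self.radii_um[child])


def sholl_profile(tree: MorphTree, radii_um) -> np.ndarray:
    """Count tree segments crossing each sphere centred on the root.

    A segment whose endpoints straddle radius ``r`` (one strictly inside,
    one strictly outside) counts once; tangency — an endpoint exactly on
    the sphere — is ignored (measure-zero case, fixed deterministically).
    """
    radii_um = np.asarray(radii_um, dtype=np.float64)
    if len(radii_um) == 0:
        return np.zeros(0, dtype=int)
    if np.any(radii_um <= 0) or np.any(np.diff(radii_um) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    root_pos = tree.positions_um[tree.root]
    p, c, _, _ = tree.segments()
    if len(p) == 0:
        return np.zeros(len(radii_um), dtype=int)
    dp = np.linalg.norm(p - root_pos, axis=1)
    dc = np.linalg.norm(c - root_pos, axis=1)
    counts = np.empty(len(radii_um), dtype=int)
    for k, r in enumerate(radii_um):
        counts[k] = int(np.sum((dp - r) * (dc - r) < 0))
    return counts


def _frustum_volume(length: float, r1: float, r2: float) -> float:
    return math.pi * length * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0


def morphology_summary(tree: MorphTree) -> tuple[float, int, float]:
    """(total_length_um, n_primary_processes, volume_um3).

    Primary processes are the root's children; length sums all segment
    lengths; volume sums conical frusta over segments using the per-node
    radii.
    """
    p, c, rp, rc = tree.segments()
    if len(p) == 0:
        return 0.0, 0, 0.0
    lengths = np.linalg.norm(c - p, axis=1)
    total_length = float(lengths.sum())
    n_primary = int(np.sum(tree.parents == tree.root))
    volume = float(
        sum(_frustum_volume(l, a, b) for l, a, b in zip(lengths, rp, rc))
    )
    return total_length, n_primary, volume
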