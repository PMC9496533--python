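"""Heme-anchored pocket frame and binary occupancy voxelization.

The pocket frame is anchored on the four meso carbons (CHA-CHD): its origin
is their mean, its xy-plane is their least-squares plane, x points along the
in-plane projection of CHC - CHA, and the z sign follows the right-handed
triple-product rule so the frame is reproducible across implementations.

Protein atoms (heme and all other non-protein molecules removed) are
rasterized into a cube of 1 A cells centered on the origin.  A cell is
occupied in the channel of element e in {C, N, O, S} when a sphere of half
the Van der Waals diameter of e centered on any such atom intersects the
closed cell cube.  Masking of outer/inner cubic shells reproduces the
information-discarding ablation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .curation import StructureModel

#: Channel order of the occupancy grid.
CHANNELS: tuple[str, ...] = ("C", "N", "O", "S")

#: Van der Waals diameters (A); the voxel occupancy radius is half of these.
VDW_DIAMETER: Mapping[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

#: Full Van der Waals radii (A), used for cavity exclusion (see cavity module).
VDW_RADIUS: Mapping[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

OUTER_HALF_WIDTH = 12.0  # A, half-edge of the ablation outer cube


@dataclass(frozen=True)
class PocketFrame:
    """Heme-anchored orthonormal frame.

    ``axes`` rows are the x, y, z unit vectors in file coordinates; a point
    ``p`` maps to local coordinates ``axes @ (p - origin)``.
    """

    origin: np.ndarray  # (3,)
    axes: np.ndarray    # (3, 3), rows x, y, z; proper rotation

    def to_local(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, dtype=float) - self.origin) @ self.axes.T


def compute_frame(skeleton: Mapping[str, np.ndarray]) -> PocketFrame:
    """Frame from the four meso carbons CHA, CHB, CHC, CHD.

    The plane normal is the smallest-variance direction of the centered
    points; x is the unit in-plane projection of CHC - CHA; the z sign makes
    ``z . [(CHB-CHA) x (CHC-CHA)]`` positive; y completes the right-handed
    frame as z cross x.
    """
    try:
        pts = np.array([np.asarray(skeleton[n], dtype=float) for n in ("CHA", "CHB", "CHC", "CHD")])
    except KeyError as exc:
        raise ValueError(f"meso atom {exc} missing; cannot define the pocket frame") from exc
    origin = pts.mean(axis=0)
    centered = pts - origin
    # smallest-variance direction of the centered meso atoms
    _, svals, vt = np.linalg.svd(centered)
    if svals[1] <= 1e-9 * max(svals[0], 1.0):
        raise ValueError("meso atoms are collinear or duplicated; plane undefined")
    normal = vt[2]
    chord = pts[2] - pts[0]  # CHC - CHA
    x = chord - np.dot(chord, normal) * normal
    nx = np.linalg.norm(x)
    if nx <= 1e-9:
        raise ValueError("CHC - CHA is perpendicular to the meso plane; x-axis undefined")
    x = x / nx
    handed = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    z = normal if np.dot(normal, handed) > 0 else -normal
    y = np.cross(z, x)
    axes = np.vstack([x, y, z])
    return PocketFrame(origin=origin, axes=axes)


@dataclass
class VoxelGrid:
    """Binary occupancy grid: ``data[channel, i, j, k]`` over 1 A cells.

    Cell i spans ``[-edge/2 + i, -edge/2 + i + 1)`` along each local axis;
    cell centers therefore sit at half-integer local coordinates.
    """

    data: np.ndarray                   # (n_channels, L, L, L) uint8, values {0, 1}
    edge: int
    channels: tuple[str, ...] = CHANNELS
    spacing: float = 1.0

    def __post_init__(self) -> None:
        L = int(self.edge)
        if self.data.shape[1:] != (L, L, L):
            raise ValueError(f"grid data shape {self.data.shape} inconsistent with edge {self.edge}")

    @property
    def side(self) -> int:
        return int(self.edge)

    def cell_centers_1d(self) -> np.ndarray:
        L = self.side
        return -L / 2.0 + np.arange(L) + 0.5


def voxelize(model: StructureModel, frame: PocketFrame, edge: int) -> VoxelGrid:
    """Rasterize the protein environment into a 4-channel occupancy grid.

    Heme and every other non-protein molecule are excluded (only ATOM-record
    protein atoms contribute); hydrogens are ignored since only C/N/O/S
    channels are defined.  Occupancy uses the sphere-intersects-closed-cell
    predicate with half-diameter radii.
    """
    if edge != int(edge) or edge <= 0:
        raise ValueError(f"edge must be a positive multiple of the 1 A spacing, got {edge}")
    L = int(edge)
    coords, elements = model.protein_coords(elements=CHANNELS)
    grid = np.zeros((len(CHANNELS), L, L, L), dtype=np.uint8)
    if len(coords):
        local = frame.to_local(coords)
        for ch_idx, elem in enumerate(CHANNELS):
            mask = [e == elem for e in elements]
            if any(mask):
                _rasterize(grid[ch_idx], local[np.array(mask)], VDW_DIAMETER[elem] / 2.0, L)
    return VoxelGrid(data=grid, edge=L)


def _rasterize(channel: np.ndarray, local: np.ndarray, radius: float, L: int) -> None:
    """Set cells whose closed cube lies within ``radius`` of any atom center."""
    half = L / 2.0
    for p in local:
        lo = np.floor(p - radius + half).astype(int)
        hi = np.floor(p + radius + half).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, L - 1)
        if np.any(lo > hi):
            continue
        ii, jj, kk = np.meshgrid(*(np.arange(lo[d], hi[d] + 1) for d in range(3)), indexing="ij")
        # clamp the atom center into each candidate closed cell cube
        cx = np.clip(p[0], ii - half, ii + 1 - half)
        cy = np.clip(p[1], jj - half, jj + 1 - half)
        cz = np.clip(p[2], kk - half, kk + 1 - half)
        d2 = (cx - p[0]) ** 2 + (cy - p[1]) ** 2 + (cz - p[2]) ** 2
        hit = d2 <= radius * radius
        channel[ii[hit], jj[hit], kk[hit]] = 1


def collapse_channels(grid: VoxelGrid) -> VoxelGrid:
    """Elementwise OR of the four channels -> one-channel grid."""
    if grid.data.shape[0] != len(CHANNELS):
        raise ValueError("collapse_channels expects a 4-channel grid")
    merged = (grid.data.max(axis=0, keepdims=True) > 0).astype(np.uint8)
    return VoxelGrid(data=merged, edge=grid.edge, channels=("any",), spacing=grid.spacing)


@dataclass(frozen=True)
class MaskSpec:
    """Ablation mask: which cubic region of a 24 A grid is zeroed.

    ``outside`` zeroes cells whose centers fall outside the inner cube of
    half-width ``12 - r``; ``inside`` zeroes cells whose centers fall inside
    the inner cube of half-width ``r``.  The inner cube is centered at the
    origin with axis-parallel edges and is treated as closed, so a center on
    its face is kept in both modes.
    """

    mode: Literal["outside", "inside"]
    r: float

    def __post_init__(self) -> None:
        if self.mode not in ("outside", "inside"):
            raise ValueError(f"mask mode must be 'outside' or 'inside', got {self.mode!r}")
        if not (0 <= self.r < OUTER_HALF_WIDTH):
            raise ValueError(f"r must satisfy 0 <= r < {OUTER_HALF_WIDTH}, got {self.r}")

    @property
    def inner_half_width(self) -> float:
        return OUTER_HALF_WIDTH - self.r if self.mode == "outside" else self.r

    @property
    def inner_edge(self) -> float:
        """Edge length of the inner cube in angstroms."""
        return 2.0 * self.inner_half_width


def _zero_mask_1d(L: int, spec: MaskSpec) -> np.ndarray:
    centers = -L / 2.0 + np.arange(L) + 0.5
    h = spec.inner_half_width
    inside = np.abs(centers) < h  # centers sit at half-integers: no face ties for integral h
    return inside


def mask_cells(L: int, spec: MaskSpec) -> np.ndarray:
    """(L, L, L) boolean array marking cells to be zeroed."""
    inside_1d = _zero_mask_1d(L, spec)
    inside = inside_1d[:, None, None] & inside_1d[None, :, None] & inside_1d[None, None, :]
    return ~inside if spec.mode == "outside" else inside


def mask_grid(grid: VoxelGrid, spec: MaskSpec) -> VoxelGrid:
    """Apply an ablation mask to a 24 A grid; untouched cells are preserved."""
    if grid.side != int(2 * OUTER_HALF_WIDTH):
        raise ValueError(f"ablation masks are defined for 24 A grids, got edge {grid.edge}")
    zero = mask_cells(grid.side, spec)
    data = grid.data.copy()
    data[:, zero] = 0
    return VoxelGrid(data=data, edge=grid.edge, channels=grid.channels, spacing=grid.spacing)


def mask_batch(x: np.ndarray, spec: MaskSpec) -> np.ndarray:
    """Apply a mask to a batch of grids shaped (n, channels, L, L, L)."""
    L = x.shape[-1]
    if L != int(2 * OUTER_HALF_WIDTH):
        raise ValueError(f"ablation masks are defined for 24 A grids, got side {L}")
    out = x.copy()
    out[..., mask_cells(L, spec)] = 0
    return out


def retained_volume(spec: MaskSpec, edge: float = 24.0) -> float:
    """Volume (A^3) of the region whose information survives the mask."""
    if not (0 <= spec.r < OUTER_HALF_WIDTH):
        raise ValueError(f"r must satisfy 0 <= r < {OUTER_HALF_WIDTH}")
    if spec.mode == "outside":
        return (edge - 2.0 * spec.r) ** 3
    return edge ** 3 - (2.0 * spec.r) ** 3
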