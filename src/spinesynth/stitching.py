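"""Fuse vertically chunked whole-spine acquisitions into one volume.

Whole-spine MR is often acquired as two or three vertically limited blocks
("chunks") that are stored as separate volumes in a shared world coordinate
frame.  This module computes the minimal world bounding box over all chunks,
resamples each chunk onto that grid, and blends overlap regions with
distance-based weights ``w_x = 1 - d_x / sum_i d_i``, where ``d_i`` is the
distance from an overlap voxel to the nearest voxel covered *only* by chunk
``i`` — a linear cross-fade for stacked chunks that generalizes to lateral
(scoliotic) offsets.  Translation-only registration by normalized
cross-correlation aligns the axial Dixon stack to the sagittal T2w frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .volume import ImageVolume

__all__ = [
    "ChunkSet",
    "RegistrationResult",
    "global_bounding_box",
    "overlap_weights",
    "blend",
    "register_translation",
]

#: peak NCC below this value marks a failed registration
DEFAULT_NCC_FAILURE_THRESHOLD = 0.3


@dataclass
class ChunkSet:
    """Ordered chunks of one modality sharing a world frame."""

    chunks: list
    modality: str = ""

    def __post_init__(self) -> None:
        if len(self.chunks) == 0:
            raise ValueError("ChunkSet needs at least one chunk")
        codes = {c.orientation for c in self.chunks}
        if len(codes) != 1:
            raise ValueError(f"chunks mix orientations: {sorted(codes)}")

    def __len__(self) -> int:
        return len(self.chunks)

    def __iter__(self):
        return iter(self.chunks)


@dataclass
class RegistrationResult:
    """Outcome of translation-only cross-correlation registration."""

    shift_mm: np.ndarray
    shift_vox: np.ndarray
    score: float
    failed: bool
    message: str = ""


@dataclass
class TargetGrid:
    """Shape + affine of the fused output grid."""

    shape: tuple
    affine: np.ndarray

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


def _world_corners(vol: ImageVolume) -> np.ndarray:
    """World coordinates of the 8 voxel-center corners of a volume."""
    s = np.asarray(vol.shape) - 1
    corners = np.array(
        [[i * s[0], j * s[1], k * s[2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
        dtype=float,
    )
    return np.atleast_2d(vol.voxel_to_world(corners))


def global_bounding_box(cs: ChunkSet, reference_spacing) -> TargetGrid:
    """Minimal axis-aligned world box over all chunks, gridded at ``reference_spacing``.

    The grid inherits the axis directions of the first chunk (all chunks share
    one orientation code), scaled to the requested spacing; every chunk voxel
    center falls inside the box.
    """
    spacing = np.asarray(reference_spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("reference spacing must be positive")
    ref = cs.chunks[0]
    directions = ref.affine[:3, :3] / ref.spacing  # unit columns
    # express corners in the direction basis so the box is axis-aligned there
    inv_dir = np.linalg.inv(directions)
    pts = np.vstack([_world_corners(c) for c in cs.chunks])
    local = (inv_dir @ pts.T).T
    lo, hi = local.min(axis=0), local.max(axis=0)
    shape = tuple(int(np.floor((hi[a] - lo[a]) / spacing[a] + 0.5)) + 1 for a in range(3))
    affine = np.eye(4)
    affine[:3, :3] = directions @ np.diag(spacing)
    affine[:3, 3] = directions @ lo
    return TargetGrid(shape, affine)


def _resample_to_grid(vol: ImageVolume, grid: TargetGrid, order: int = 1):
    """Resample a chunk onto the target grid; returns (values, coverage mask)."""
    matrix = np.linalg.inv(vol.affine) @ grid.affine
    # snap aligned grids: scipy's constant mode yields cval for samples an
    # epsilon outside the domain, so near-integer coefficients must be exact
    near = np.round(matrix)
    matrix = np.where(np.abs(matrix - near) < 1e-9, near, matrix)
    data = ndimage.affine_transform(
        np.asarray(vol.data, dtype=float),
        matrix[:3, :3],
        offset=matrix[:3, 3],
        output_shape=grid.shape,
        order=order,
        mode="constant",
        cval=0.0,
    )
    # coverage: grid voxel centers whose interpolation support lies fully
    # inside the chunk (no contamination from the constant fill)
    idx = np.indices(grid.shape, dtype=float).reshape(3, -1)
    src = matrix[:3, :3] @ idx + matrix[:3, 3][:, None]
    shp = np.asarray(vol.shape, dtype=float)[:, None]
    eps = 1e-6
    inside = np.all((src >= -eps) & (src <= shp - 1 + eps), axis=0)
    return data, inside.reshape(grid.shape)


def overlap_weights(cs: ChunkSet, grid: TargetGrid):
    """Per-chunk blending weight maps on the target grid.

    For a voxel covered by several chunks, ``d_i`` is the Euclidean distance
    (in grid voxels) to the nearest voxel covered exclusively by chunk ``i``
    and the raw weight of chunk ``x`` is ``1 - d_x / sum_i d_i``; raw weights
    are renormalized to sum to one (for two chunks they already do).  Sole
    coverage gives weight 1.  Returns (weights, values, coverage_count).
    """
    values, masks = [], []
    for c in cs.chunks:
        v, m = _resample_to_grid(c, grid)
        values.append(v)
        masks.append(m)
    masks = np.asarray(masks)
    count = masks.sum(axis=0)
    overlap = count >= 2

    weights = np.zeros((len(cs.chunks),) + tuple(grid.shape))
    for i, m in enumerate(masks):
        weights[i][m & ~overlap] = 1.0

    if overlap.any():
        dists = np.empty_like(weights)
        for i, m in enumerate(masks):
            exclusive = m & (count == 1)
            if exclusive.any():
                dists[i] = ndimage.distance_transform_edt(~exclusive)
            else:
                dists[i] = np.inf  # no safe region: weight goes to 0 below
        d_ov = np.where(masks[:, overlap], dists[:, overlap], 0.0)
        total = d_ov.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(masks[:, overlap], 1.0 - d_ov / total, 0.0)
        raw[~np.isfinite(raw)] = 0.0
        # degenerate: all distances 0 (or no finite distance) -> equal weights
        norm = raw.sum(axis=0)
        k = masks[:, overlap].sum(axis=0)
        bad = norm <= 0
        raw[:, bad] = masks[:, overlap][:, bad] / k[bad]
        norm = raw.sum(axis=0)
        weights[:, overlap] = raw / norm
    return weights, np.asarray(values), count


def blend(cs: ChunkSet, grid: TargetGrid):
    """Fuse chunks on the grid: weighted sum over covering chunks.

    Voxels covered by no chunk are filled with -1 (background).  Returns the
    fused :class:`ImageVolume` and a uint8 coverage mask.
    """
    weights, values, count = overlap_weights(cs, grid)
    fused = (weights * values).sum(axis=0)
    fused[count == 0] = -1.0
    return ImageVolume(fused, grid.affine.copy()), (count > 0).astype(np.uint8)


def register_translation(
    moving: ImageVolume,
    fixed: ImageVolume,
    max_shift: float = 30.0,
    failure_threshold: float = DEFAULT_NCC_FAILURE_THRESHOLD,
) -> RegistrationResult:
    """Integer-voxel translation maximizing normalized cross-correlation.

    ``max_shift`` bounds the search radius in mm.  The returned shift moves
    ``moving`` onto ``fixed`` (apply by adding ``shift_mm`` to the moving
    affine's translation).  ``failed`` is set when the peak NCC falls below
    ``failure_threshold`` or an input has no intensity variance.
    """
    a = np.asarray(fixed.data, dtype=float)
    b = np.asarray(moving.data, dtype=float)
    if a.shape != b.shape:
        raise ValueError("register_translation expects volumes on comparable grids")
    if a.std() == 0 or b.std() == 0:
        return RegistrationResult(
            np.zeros(3), np.zeros(3, int), 0.0, True, "constant-valued input: NCC undefined"
        )
    spacing = fixed.spacing
    max_vox = np.maximum(0, np.floor(max_shift / spacing)).astype(int)

    az = a - a.mean()
    bz = b - b.mean()
    corr = fftconvolve(az, bz[::-1, ::-1, ::-1], mode="full")
    center = np.asarray(b.shape) - 1
    lo = center - max_vox
    hi = center + max_vox + 1
    window = corr[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    peak = np.unravel_index(np.argmax(window), window.shape)
    shift_vox = np.asarray(peak) - max_vox  # displacement of moving -> fixed

    score = _ncc_at_shift(az, bz, shift_vox)
    failed = score < failure_threshold
    msg = "peak NCC below failure threshold" if failed else ""
    shift_mm = (fixed.affine[:3, :3] @ shift_vox.astype(float))
    return RegistrationResult(shift_mm, shift_vox, float(score), bool(failed), msg)


def _ncc_at_shift(az: np.ndarray, bz: np.ndarray, shift) -> float:
    """NCC of zero-mean arrays over their overlap after integer shift of ``bz``."""
    sl_a, sl_b = [], []
    for s, n in zip(shift, az.shape):
        s = int(s)
        if s >= 0:
            sl_a.append(slice(s, n))
            sl_b.append(slice(0, n - s))
        else:
            sl_a.append(slice(0, n + s))
            sl_b.append(slice(-s, n))
    aa = az[tuple(sl_a)]
    bb = bz[tuple(sl_b)]
    if aa.size == 0:
        return 0.0
    aa = aa - aa.mean()
    bb = bb - bb.mean()
    denom = np.sqrt((aa**2).sum() * (bb**2).sum())
    if denom == 0:
        return 0.0
    return float((aa * bb).sum() / denom)
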