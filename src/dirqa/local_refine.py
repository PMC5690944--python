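"""Box-based rigid refinement of a deformable registration, and DVF locks.

The workflow mirrors user-guided refinement tools in clinical registration
software: the user drops a box around a mis-registered feature, the tool
finds the translation that best aligns the box contents between the fixed
and moving volumes by minimizing the sum (here: mean) of squared intensity
differences, and the resulting correspondence is "locked" — the deformation
vector at the box centre is replaced by the new one before the deformable
algorithm is re-run. Only the literal vector replacement is implemented;
propagating a lock's influence through a deformable solver is the job of
the (external) registration engine.

The alignment search is translation-only over integer voxel offsets — an
exhaustive scan, so the returned minimum is global within the search range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volume_io import ImageVolume, VectorField

__all__ = ["RefineBox", "Lock", "box_ssd_align", "apply_locks", "lock_from_alignment"]


@dataclass
class RefineBox:
    """A registration box on the fixed grid, all in (z, y, x) voxel units.

    The box spans ``center ± half_size`` inclusive; candidate translations
    range over ``±search_radius`` per axis.
    """

    center: tuple[int, int, int]
    half_size: tuple[int, int, int]
    search_radius: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.center = tuple(int(v) for v in self.center)
        self.half_size = tuple(int(v) for v in self.half_size)
        self.search_radius = tuple(int(v) for v in self.search_radius)
        if any(h < 0 for h in self.half_size) or any(s < 0 for s in self.search_radius):
            raise ValueError("half_size and search_radius must be non-negative")


@dataclass
class Lock:
    """A user-asserted correspondence: displacement (mm, x/y/z) at a DVF voxel."""

    position: tuple[int, int, int]  # (z, y, x) index on the DVF grid
    displacement: tuple[float, float, float]  # mm, (x, y, z)

    def __post_init__(self) -> None:
        self.position = tuple(int(v) for v in self.position)
        self.displacement = tuple(float(v) for v in self.displacement)
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("lock displacement must be finite")


def _box_slices(center: Sequence[int], half: Sequence[int],
                offset: Sequence[int] = (0, 0, 0)) -> tuple[slice, slice, slice]:
    return tuple(
        slice(c - h + o, c + h + o + 1) for c, h, o in zip(center, half, offset)
    )


def box_ssd_align(
    fixed: ImageVolume, moving: ImageVolume, box: RefineBox
) -> tuple[np.ndarray, float]:
    """Exhaustive translation search minimizing the mean squared difference.

    Compares the fixed box contents against the moving volume's box shifted
    by every integer-voxel candidate in ``±search_radius``. Returns the
    minimizing translation in mm (x, y, z order, i.e. voxel offset times
    spacing) and the attained mean squared difference (HU²). Ties are broken
    by the smallest translation L2 norm, then lexicographically in (z, y, x).

    The mean (not sum) of squared differences is minimized so scores are
    comparable across box sizes; for a fixed box the minimizer is identical.
    """
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving volumes must share a grid")
    c, h, r = box.center, box.half_size, box.search_radius
    shape = fixed.shape
    for ax in range(3):
        if c[ax] - h[ax] < 0 or c[ax] + h[ax] >= shape[ax]:
            raise ValueError(f"box exceeds fixed volume bounds on axis {ax}")
        if c[ax] - h[ax] - r[ax] < 0 or c[ax] + h[ax] + r[ax] >= shape[ax]:
            raise ValueError(
                f"box at maximum search offset exceeds moving volume bounds on axis {ax}"
            )
    ref = fixed.voxels[_box_slices(c, h)]
    best: tuple[float, float, tuple[int, int, int]] | None = None
    best_t = (0, 0, 0)
    for tz in range(-r[0], r[0] + 1):
        for ty in range(-r[1], r[1] + 1):
            for tx in range(-r[2], r[2] + 1):
                cand = moving.voxels[_box_slices(c, h, (tz, ty, tx))]
                ssd = float(np.mean((ref - cand) ** 2))
                key = (ssd, float(tz * tz + ty * ty + tx * tx), (tz, ty, tx))
                if best is None or key < best:
                    best = key
                    best_t = (tz, ty, tx)
    tz, ty, tx = best_t
    translation_mm = np.array(
        [tx * fixed.spacing[0], ty * fixed.spacing[1], tz * fixed.spacing[2]]
    )
    return translation_mm, best[0]


def apply_locks(field: VectorField, locks: Sequence[Lock]) -> VectorField:
    """Replace DVF vectors at the locked positions; everything else untouched.

    Later locks at the same position win. The input field is not modified.
    """
    out = field.vectors.copy()
    shape = field.grid_shape
    for lk in locks:
        z, y, x = lk.position
        if not (0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]):
            raise ValueError(f"lock position {lk.position} outside grid {shape}")
        out[z, y, x] = lk.displacement
    return VectorField(
        vectors=out,
        spacing=field.spacing.copy(),
        origin=field.origin.copy(),
        direction_tag=field.direction_tag,
    )


def lock_from_alignment(
    fixed: ImageVolume, moving: ImageVolume, box: RefineBox
) -> Lock:
    """Run the box alignment and package the result as a lock at the box centre."""
    translation, _ = box_ssd_align(fixed, moving, box)
    return Lock(position=box.center, displacement=tuple(translation))
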