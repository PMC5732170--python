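"""Smoothing, lung masking, seeded nodule growing, mask editing, and the
peritumoral shell.

The nodule is segmented by constrained seeded region growing: the mask is the
connected component (26-neighbourhood by default) of voxels whose HU lies in a
configurable band around the seed, followed by per-slice hole filling.  The
default band [-750, 200] HU spans ground-glass through solid attenuation.

The "10 mm surrounding" shell of tumor-free lung is built from the anisotropic
Euclidean distance transform of the nodule complement: a lung voxel belongs to
the shell when its distance to the nearest nodule voxel is at most the shell
width (measured in physical mm, honouring slice thickness), and it is not
itself part of the nodule.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grid import CTVolume, GeometryError, SeedPoint, VoxelMask

__all__ = [
    "DEFAULT_GROW_BOUNDS",
    "median_filter_inplane",
    "segment_lung",
    "grow_nodule",
    "edit_mask",
    "peritumoral_shell",
    "mask_volume_cc",
]

#: HU band for seeded region growing (ground glass through solid).
DEFAULT_GROW_BOUNDS = (-750.0, 200.0)


def median_filter_inplane(volume: CTVolume) -> CTVolume:
    """3 x 3 in-plane (axial) median smoothing, edges handled by reflection.

    Used to remove edge-enhancing reconstruction-kernel artifact before
    texture analysis; each voxel becomes the median of its 9-voxel axial
    neighbourhood, slices are never mixed.
    """
    out = ndimage.median_filter(volume.data, size=(3, 3, 1), mode="reflect")
    return CTVolume(out, spacing=volume.spacing, origin=volume.origin,
                    orientation=volume.orientation)


def segment_lung(volume: CTVolume, air_threshold: float = -400.0) -> VoxelMask:
    """Segment aerated lung parenchyma by thresholding and component analysis.

    Voxels below ``air_threshold`` HU are candidate air/parenchyma; connected
    components touching the volume border (outside air) are discarded and the
    largest remaining components are kept, followed by 3-D hole filling.

    Raises
    ------
    ValueError
        If no interior lung-like component exists.
    """
    low = volume.data < air_threshold
    labels, n = ndimage.label(low)
    if n == 0:
        raise ValueError("no lung-like component found below threshold")
    border_labels = set(np.unique(labels[0, :, :])) | set(np.unique(labels[-1, :, :]))
    border_labels |= set(np.unique(labels[:, 0, :])) | set(np.unique(labels[:, -1, :]))
    border_labels |= set(np.unique(labels[:, :, 0])) | set(np.unique(labels[:, :, -1]))
    border_labels.discard(0)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    for lab in border_labels:
        counts[lab] = 0
    if counts.sum() == 0:
        raise ValueError("no lung-like component found (all candidates touch the border)")
    # keep components at least 5% the size of the largest: both lungs survive,
    # stray noise voxels do not
    keep = np.flatnonzero(counts >= 0.05 * counts.max())
    mask = np.isin(labels, keep)
    mask = ndimage.binary_fill_holes(mask)
    return VoxelMask(mask, spacing=volume.spacing, origin=volume.origin)


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def grow_nodule(
    volume: CTVolume,
    seed: SeedPoint,
    hu_low: float = DEFAULT_GROW_BOUNDS[0],
    hu_high: float = DEFAULT_GROW_BOUNDS[1],
    connectivity: int = 26,
) -> VoxelMask:
    """Constrained seeded region growing restricted to an HU band.

    The returned mask is the connected set of voxels with HU in
    ``[hu_low, hu_high]`` reachable from the seed, hole-filled per axial
    slice.  A seed whose HU falls outside the band signals a mis-placed seed
    and raises ``ValueError``.
    """
    seed.check_inside(volume)
    if hu_low >= hu_high:
        raise ValueError("hu_low must be below hu_high")
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    seed_hu = float(volume.data[seed.as_tuple()])
    if not (hu_low <= seed_hu <= hu_high):
        raise ValueError(
            f"seed voxel HU {seed_hu:.0f} outside growing bounds "
            f"[{hu_low:.0f}, {hu_high:.0f}]; re-place the seed"
        )
    in_range = (volume.data >= hu_low) & (volume.data <= hu_high)
    labels, _ = ndimage.label(in_range, structure=_STRUCTS[connectivity])
    mask = labels == labels[seed.as_tuple()]
    for z in range(mask.shape[2]):  # in-plane hole filling
        mask[:, :, z] = ndimage.binary_fill_holes(mask[:, :, z])
    return VoxelMask(mask, spacing=volume.spacing, origin=volume.origin)


def edit_mask(
    mask: VoxelMask,
    additions: "set[tuple[int, int, int]] | np.ndarray | None" = None,
    removals: "set[tuple[int, int, int]] | np.ndarray | None" = None,
    edit_log: list | None = None,
) -> VoxelMask:
    """Manual mask editing: union with additions, then subtract removals.

    Removals win on conflict.  If ``edit_log`` is given, a record of the edit
    is appended to it (voxel lists, before/after counts).
    """
    def _as_array(vox):
        if vox is None:
            return np.empty((0, 3), dtype=int)
        arr = np.asarray(sorted(vox) if isinstance(vox, set) else vox, dtype=int)
        return arr.reshape(-1, 3)

    add = _as_array(additions)
    rem = _as_array(removals)
    for arr, name in ((add, "addition"), (rem, "removal")):
        if arr.size and (
            (arr < 0).any() or (arr >= np.array(mask.shape)).any()
        ):
            raise IndexError(f"{name} voxel index out of grid bounds")
    out = mask.data.copy()
    if add.size:
        out[tuple(add.T)] = True
    if rem.size:
        out[tuple(rem.T)] = False
    if edit_log is not None:
        edit_log.append(
            {
                "added": [tuple(int(i) for i in v) for v in add],
                "removed": [tuple(int(i) for i in v) for v in rem],
                "count_before": mask.count,
                "count_after": int(out.sum()),
            }
        )
    return mask.like(out)


def peritumoral_shell(
    nodule: VoxelMask, lung: VoxelMask, distance_mm: float = 10.0
) -> VoxelMask:
    """The rind of tumor-free lung within ``distance_mm`` of the nodule.

    Distance is Euclidean in physical millimetres (anisotropic spacing),
    measured from the nodule boundary via the distance transform of the
    nodule complement.  The shell is intersected with the lung mask and the
    nodule itself is excluded, so shell ∩ nodule = ∅ and shell ⊆ lung.
    """
    if not nodule.same_geometry(lung):
        raise GeometryError("nodule and lung masks must share grid geometry")
    if distance_mm <= 0:
        raise ValueError("distance_mm must be positive")
    if nodule.count == 0:
        raise ValueError("empty nodule mask")
    dist = ndimage.distance_transform_edt(~nodule.data, sampling=nodule.spacing)
    shell = (dist <= distance_mm) & lung.data & ~nodule.data
    return nodule.like(shell)


def mask_volume_cc(mask: VoxelMask) -> float:
    """Mask volume in cc (voxel count x voxel volume in mm^3 / 1000)."""
    return mask.volume_cc
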