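"""Synthetic CT phantoms: aerated lung with emphysema/fibrosis textures and
implanted part-solid nodules.

The phantom is a deliberately simple stand-in for a thoracic HRCT: a soft
tissue "body" (HU >= 0) containing two ellipsoidal lungs of normally
distributed aerated parenchyma.  Two parenchymal pathologies can be mixed in:

* **Emphysema** — low-attenuation blobs (mean well below -950 HU) occupying a
  requested fraction of the lung, placed by thresholding a smoothed Gaussian
  random field so the realised fraction is exact to the voxel.
* **Fibrosis** — subpleural bands of ground-glass/reticular texture whose
  extent grows monotonically with ``fibrosis_severity``: voxels are ranked by
  a fixed score combining pleural proximity and a smooth noise field, and the
  top fraction is relabelled, so for a fixed seed the fibrotic region at a
  lower severity is a subset of the region at any higher severity.

Nodules are approximately spherical, split into an outer ground-glass
(lepidic-like) compartment and a solid core; ``lepidic_fraction`` sets the
ground-glass share of the nodule volume, with the core radius chosen as
``r * (1 - lepidic_fraction)**(1/3)`` so the volume split is exact for a
continuous ball.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import CTVolume, VoxelMask

__all__ = ["PhantomSpec", "NoduleSpec", "LungPhantom", "make_lung_phantom", "implant_nodule"]

#: HU texture parameters for the pathological parenchyma classes.
EMPHYSEMA_HU = (-980.0, 12.0)
FIBROSIS_HU = (-480.0, 70.0)
SOFT_TISSUE_HU = (50.0, 15.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture parameters of a synthetic thoracic CT."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_mean: float = -850.0
    background_sd: float = 40.0
    emphysema_fraction: float = 0.0
    fibrosis_severity: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 32 for n in self.shape):
            raise ValueError(f"phantom shape must be at least (32,32,32), got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        for name in ("emphysema_fraction", "fibrosis_severity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class NoduleSpec:
    """A part-solid spherical nodule: ground-glass rim around a solid core."""

    center: tuple[int, int, int]
    radius_mm: float = 5.0
    lepidic_fraction: float = 0.5
    solid_mean: float = 30.0
    solid_sd: float = 25.0
    gg_mean: float = -550.0
    gg_sd: float = 60.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if not 0.0 <= self.lepidic_fraction <= 1.0:
            raise ValueError("lepidic_fraction must be in [0, 1]")
        if self.gg_mean >= self.solid_mean:
            raise ValueError("ground-glass mean HU must be below solid mean HU")


@dataclass
class LungPhantom:
    """A generated phantom with its ground-truth masks."""

    volume: CTVolume
    lung: VoxelMask
    emphysema: VoxelMask
    fibrosis: VoxelMask
    spec: PhantomSpec


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[[slice(0, n) for n in shape]]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _smooth_field(shape, rng, sigma=3.0) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)


def _top_fraction(score: np.ndarray, region: np.ndarray, frac: float) -> np.ndarray:
    """Boolean mask of the ``frac`` highest-scoring voxels inside ``region``.

    Selection is by rank, so for a fixed score the selected set is nested
    (monotone) in ``frac``.
    """
    n_sel = int(round(frac * region.sum()))
    out = np.zeros_like(region)
    if n_sel == 0:
        return out
    idx = np.argwhere(region)
    vals = score[region]
    order = np.argsort(vals, kind="stable")[::-1][:n_sel]
    chosen = idx[order]
    out[tuple(chosen.T)] = True
    return out


def make_lung_phantom(spec: PhantomSpec) -> LungPhantom:
    """Generate a thoracic CT phantom with ground-truth masks.

    Reproducible: identical spec (including ``rng_seed``) gives bit-identical
    output.  The emphysema and fibrosis masks are disjoint subsets of the
    lung mask; the realised emphysema fraction of lung voxels equals the
    requested fraction to within one voxel of rounding.
    """
    rng = np.random.default_rng(spec.rng_seed)
    nx, ny, nz = spec.shape

    body = np.clip(rng.normal(*SOFT_TISSUE_HU, size=spec.shape), 0.0, None)

    lung = _ellipsoid(spec.shape, (0.30 * nx, 0.52 * ny, 0.50 * nz),
                      (0.21 * nx, 0.36 * ny, 0.42 * nz))
    lung |= _ellipsoid(spec.shape, (0.70 * nx, 0.52 * ny, 0.50 * nz),
                       (0.21 * nx, 0.36 * ny, 0.42 * nz))

    hu = body
    hu[lung] = rng.normal(spec.background_mean, spec.background_sd, size=int(lung.sum()))

    emph_field = _smooth_field(spec.shape, rng)
    emphysema = _top_fraction(emph_field, lung, spec.emphysema_fraction)
    if emphysema.any():
        hu[emphysema] = rng.normal(*EMPHYSEMA_HU, size=int(emphysema.sum()))

    # Subpleural weighting: distance into the lung from its boundary, in voxels.
    depth = ndimage.distance_transform_edt(lung)
    fib_score = 0.7 * np.exp(-depth / 4.0) + 0.3 * _smooth_field(spec.shape, rng)
    fibrosis = _top_fraction(fib_score, lung & ~emphysema, 0.5 * spec.fibrosis_severity)
    if fibrosis.any():
        hu[fibrosis] = rng.normal(*FIBROSIS_HU, size=int(fibrosis.sum()))

    volume = CTVolume(hu, spacing=spec.spacing)
    mk = lambda m: VoxelMask(m, spacing=spec.spacing)
    return LungPhantom(volume, mk(lung), mk(emphysema), mk(fibrosis), spec)


def implant_nodule(
    volume: CTVolume,
    lung: VoxelMask,
    nodule: NoduleSpec,
    rng_seed: int = 0,
) -> tuple[CTVolume, VoxelMask]:
    """Implant a part-solid spherical nodule; returns (volume, truth mask).

    The mask is purely geometric (identical across seeds); only the HU
    texture noise depends on ``rng_seed``.  The outer ``lepidic_fraction`` of
    the nodule volume receives ground-glass HU, the core solid HU.
    """
    if not volume.same_geometry(lung):
        raise ValueError("volume and lung mask must share geometry")
    cx, cy, cz = (int(c) for c in nodule.center)
    if not volume.contains_index((cx, cy, cz)) or not lung.data[cx, cy, cz]:
        raise ValueError(f"nodule center {nodule.center} is not inside the lung")
    sp = np.asarray(volume.spacing)
    half = np.ceil(nodule.radius_mm / sp).astype(int)
    lo = np.array([cx, cy, cz]) - half
    hi = np.array([cx, cy, cz]) + half
    if (lo < 0).any() or (hi >= np.array(volume.shape)).any():
        raise ValueError("nodule sphere exceeds volume bounds")

    grids = np.ogrid[[slice(0, n) for n in volume.shape]]
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, (cx, cy, cz), sp))
    dist = np.sqrt(d2)
    mask = dist <= nodule.radius_mm
    core_r = nodule.radius_mm * (1.0 - nodule.lepidic_fraction) ** (1.0 / 3.0)
    # fully lepidic nodule has no solid core at all (not even the centre voxel)
    core = (dist <= core_r) if nodule.lepidic_fraction < 1.0 else np.zeros_like(mask)
    rim = mask & ~core

    rng = np.random.default_rng(rng_seed)
    out = volume.data.copy()
    out[core] = rng.normal(nodule.solid_mean, nodule.solid_sd, size=int(core.sum()))
    out[rim] = rng.normal(nodule.gg_mean, nodule.gg_sd, size=int(rim.sum()))
    return (
        CTVolume(out, spacing=volume.spacing, origin=volume.origin),
        VoxelMask(mask, spacing=volume.spacing, origin=volume.origin),
    )
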