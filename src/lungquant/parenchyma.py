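"""Peritumoral parenchyma classification into the five interstitial classes.

The tumor-free shell around a nodule is tiled into 15 x 15 x 15-voxel volumes
of interest (VOIs) and each VOI is assigned one of five parenchymal classes:
normal (N), low attenuation (LA, emphysema-like), ground glass (GG),
reticular densities (R) and honeycomb change (HC).  The fibrosis score is the
summed GG + R + HC fraction; LA alone is the low-attenuation score.

Classification is a transparent rule table on simple VOI statistics (mean HU,
HU standard deviation, fraction of voxels below -950 HU, and a cyst-wall
adjacency score for honeycombing).  All thresholds are configuration, with
defaults documented on :class:`ParenchymaThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import CTVolume, VoxelMask

__all__ = [
    "VOI_SIZE",
    "VOI",
    "ParenchymaThresholds",
    "ParenchymaSummary",
    "tile_vois",
    "classify_voi",
    "summarize_parenchyma",
]

VOI_SIZE = 15
CLASSES = ("N", "LA", "GG", "R", "HC")


@dataclass
class VOI:
    """One 15^3 block of HU values plus its in-shell voxel coordinates."""

    values: np.ndarray  # (15, 15, 15) HU
    corner: tuple[int, int, int]  # lower corner of the block in the volume grid
    in_shell: np.ndarray  # boolean (15, 15, 15): which block voxels lie in the shell

    def __post_init__(self) -> None:
        if self.values.shape != (VOI_SIZE,) * 3:
            raise ValueError(f"VOI must be {VOI_SIZE}^3")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VOI values must be finite")

    @property
    def n_in_shell(self) -> int:
        return int(self.in_shell.sum())


@dataclass(frozen=True)
class ParenchymaThresholds:
    """Rule-table thresholds for the five-class parenchyma classifier.

    Defaults: a VOI is LA when over half its voxels fall below -950 HU
    (emphysematous air); HC when the cyst-wall score exceeds 0.05; otherwise
    the mean-HU band decides N ([-950, -700], quiet texture) versus GG
    ((-700, -300], moderate texture), with reticular densities (R) taking any
    band whose HU standard deviation exceeds its texture limit or any denser
    mean.
    """

    la_frac_below_950: float = 0.5
    normal_band: tuple[float, float] = (-950.0, -700.0)
    normal_sd_max: float = 80.0
    gg_band_upper: float = -300.0
    gg_sd_max: float = 120.0
    hc_score_min: float = 0.05
    cyst_hu: float = -910.0
    wall_hu: float = -300.0


def tile_vois(
    volume: CTVolume,
    shell: VoxelMask,
    voi_size: int = VOI_SIZE,
    min_occupancy: float = 0.3,
) -> list[VOI]:
    """Tile the shell's bounding box with non-overlapping ``voi_size``^3 blocks.

    Blocks are kept when at least ``min_occupancy`` of their voxels lie in
    the shell; each retained block records its in-shell voxel set so class
    fractions can be weighted by shell voxels.  Blocks at the bounding-box
    edge are zero-padded (padding voxels are never in-shell).
    """
    if shell.count == 0:
        raise ValueError("empty shell")
    if not shell.same_geometry(volume):
        raise ValueError("shell and volume must share geometry")
    idx = shell.indices()
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    vois = []
    for x0 in range(lo[0], hi[0], voi_size):
        for y0 in range(lo[1], hi[1], voi_size):
            for z0 in range(lo[2], hi[2], voi_size):
                block = np.zeros((voi_size,) * 3, dtype=np.float32)
                inshell = np.zeros((voi_size,) * 3, dtype=bool)
                x1 = min(x0 + voi_size, volume.shape[0])
                y1 = min(y0 + voi_size, volume.shape[1])
                z1 = min(z0 + voi_size, volume.shape[2])
                block[: x1 - x0, : y1 - y0, : z1 - z0] = volume.data[x0:x1, y0:y1, z0:z1]
                inshell[: x1 - x0, : y1 - y0, : z1 - z0] = shell.data[x0:x1, y0:y1, z0:z1]
                if inshell.sum() >= min_occupancy * voi_size**3:
                    vois.append(VOI(block, (int(x0), int(y0), int(z0)), inshell))
    return vois


def _cyst_wall_score(values: np.ndarray, valid: np.ndarray, thr: ParenchymaThresholds) -> float:
    """Fraction of valid voxels that are cystic air touching a dense wall.

    Honeycombing is clustered subpleural cysts with thick walls: air-density
    voxels (< ``cyst_hu``) directly adjacent (6-neighbourhood) to wall-density
    voxels (> ``wall_hu``).  Both sides of the adjacency are restricted to
    valid (in-shell) voxels so tumor tissue cannot masquerade as cyst walls.
    """
    cyst = (values < thr.cyst_hu) & valid
    wall = (values > thr.wall_hu) & valid
    if not cyst.any() or not wall.any():
        return 0.0
    near_wall = ndimage.binary_dilation(
        wall, structure=ndimage.generate_binary_structure(3, 1)
    )
    return float((cyst & near_wall).sum()) / valid.sum()


def classify_voi(voi: "VOI | np.ndarray", thresholds: ParenchymaThresholds | None = None) -> str:
    """Assign one of N / LA / GG / R / HC to a VOI by the rule table.

    For a :class:`VOI` the statistics are computed over its in-shell voxels,
    so blocks straddling the nodule or the pleura are judged on parenchyma
    alone; a bare 15^3 array is classified over all its voxels.
    """
    thr = thresholds or ParenchymaThresholds()
    if isinstance(voi, VOI):
        block, valid = voi.values, voi.in_shell
        if not valid.any():
            raise ValueError("VOI has no in-shell voxels")
    else:
        block = np.asarray(voi, dtype=float)
        valid = np.ones_like(block, dtype=bool)
    values = block[valid]
    frac_950 = float((values < -950.0).mean())
    if frac_950 > thr.la_frac_below_950:
        return "LA"
    if _cyst_wall_score(block, valid, thr) > thr.hc_score_min:
        return "HC"
    mean = float(values.mean())
    sd = float(values.std())
    if mean < thr.normal_band[0]:
        return "LA"
    if mean <= thr.normal_band[1]:
        return "N" if sd < thr.normal_sd_max else "R"
    if mean <= thr.gg_band_upper:
        return "GG" if sd < thr.gg_sd_max else "R"
    return "R"


@dataclass
class ParenchymaSummary:
    """Shell-level class fractions; fibrosis = GG + R + HC, LA stands alone."""

    fraction_normal: float
    fraction_LA: float
    fraction_GG: float
    fraction_reticular: float
    fraction_HC: float

    def __post_init__(self) -> None:
        fr = self.fractions()
        if any(f < 0 for f in fr.values()) or abs(sum(fr.values()) - 1.0) > 1e-6:
            raise ValueError("class fractions must be non-negative and sum to 1")

    def fractions(self) -> dict[str, float]:
        return {
            "N": self.fraction_normal,
            "LA": self.fraction_LA,
            "GG": self.fraction_GG,
            "R": self.fraction_reticular,
            "HC": self.fraction_HC,
        }

    @property
    def fibrosis(self) -> float:
        return self.fraction_GG + self.fraction_reticular + self.fraction_HC

    @property
    def low_attenuation(self) -> float:
        return self.fraction_LA


def summarize_parenchyma(
    volume: CTVolume,
    shell: VoxelMask,
    thresholds: ParenchymaThresholds | None = None,
    voi_size: int = VOI_SIZE,
    min_occupancy: float = 0.3,
) -> ParenchymaSummary:
    """Classify the shell and report per-class voxel fractions.

    Every retained VOI is classified and contributes its in-shell voxel count
    to its class; fractions are over all in-shell voxels of retained VOIs.
    When the shell is too thin for any VOI to reach ``min_occupancy``, the
    summary falls back to per-voxel HU banding of the shell itself.
    """
    thr = thresholds or ParenchymaThresholds()
    counts = dict.fromkeys(CLASSES, 0)
    vois = tile_vois(volume, shell, voi_size=voi_size, min_occupancy=min_occupancy)
    if vois:
        for voi in vois:
            counts[classify_voi(voi, thr)] += voi.n_in_shell
    else:
        # thin-shell fallback: band each shell voxel by its own HU
        hu = volume.data[shell.data]
        counts["LA"] = int((hu < -950.0).sum())
        counts["N"] = int(((hu >= -950.0) & (hu <= thr.normal_band[1])).sum())
        counts["GG"] = int(((hu > thr.normal_band[1]) & (hu <= thr.gg_band_upper)).sum())
        counts["R"] = int((hu > thr.gg_band_upper).sum())
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no classified shell voxels")
    return ParenchymaSummary(
        fraction_normal=counts["N"] / total,
        fraction_LA=counts["LA"] / total,
        fraction_GG=counts["GG"] / total,
        fraction_reticular=counts["R"] / total,
        fraction_HC=counts["HC"] / total,
    )
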