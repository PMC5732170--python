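"""Texture-exemplar learning and nearest-exemplar voxel classification.

A nodule's texture is summarised by nine colour-coded exemplars — Violet (V),
Indigo (I), Blue (B), Green (G), Yellow (Y), Orange (O), Red (R), Cyan (C)
and Pink (P) — learned by affinity propagation over pairwise similarities of
9 x 9 in-plane HU patches.  Every nodule voxel is assigned the colour of its
most similar exemplar; the per-nodule distribution over colours is the glyph,
and the composite groups V-I-R-O (solid/invasive-like), B-C-G (ground-glass/
lepidic-like) and Y-P partition the glyph.

The patch feature map is the 81 raw HU values clipped to [-1024, 200] and
scaled to [0, 1]; similarity is the negative squared Euclidean distance in
that feature space.  The map is pluggable (pass ``feature_fn``) so histogram
or gradient features can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import CTVolume, VoxelMask

__all__ = [
    "CANONICAL_COLORS",
    "COLOR_GROUPS",
    "HU_RANK_ORDER",
    "ROIPatch",
    "Exemplar",
    "ExemplarModel",
    "Glyph",
    "CompositeFeatures",
    "APResult",
    "patch_features",
    "extract_rois",
    "roi_similarity",
    "affinity_propagation",
    "fit_exemplar_model",
    "classify_voxels",
    "default_exemplar_model",
    "glyph_to_svg",
    "compute_glyph",
    "composite_features",
    "apply_cutoff",
    "assign_risk_groups",
    "DEFAULT_CUTOFFS",
]

PATCH_SIZE = 9
_HALF = PATCH_SIZE // 2
HU_CLIP = (-1024.0, 200.0)

#: Fixed colour precedence used for tie-breaking (lowest index wins).
CANONICAL_COLORS: tuple[str, ...] = ("V", "I", "B", "G", "Y", "O", "R", "C", "P")

#: Composite groups partitioning the nine colours.
COLOR_GROUPS: dict[str, tuple[str, ...]] = {
    "VIRO": ("V", "I", "R", "O"),
    "BCG": ("B", "C", "G"),
    "YP": ("Y", "P"),
}

#: Colour assignment by ascending mean exemplar HU: ground-glass-like codes
#: (B, C, G) map to the lowest attenuations, solid-like codes to the highest.
HU_RANK_ORDER: tuple[str, ...] = ("B", "C", "G", "Y", "P", "V", "I", "R", "O")

#: Registered clinical cutoffs on composite features (percent of tumor
#: volume): a V-I-R-O share <= 71 % or a Y-P share >= 23.5 % flags a nodule
#: as likely EGFR-mutant.
DEFAULT_CUTOFFS: dict[str, tuple[float, str]] = {
    "VIRO": (71.0, "le"),
    "YP": (23.5, "ge"),
}


@dataclass
class ROIPatch:
    """A 9 x 9 in-plane HU region of interest."""

    values: np.ndarray
    location: tuple[int, int, int] = (0, 0, 0)
    volume_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"ROI patch must be {PATCH_SIZE}x{PATCH_SIZE}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ROI patch values must be finite")

    @property
    def mean_hu(self) -> float:
        return float(self.values.mean())


@dataclass
class Exemplar:
    color: str
    patch: ROIPatch
    group: str


@dataclass
class ExemplarModel:
    """Nine labelled texture exemplars plus the similarity-metric parameters."""

    exemplars: dict[str, Exemplar]
    hu_clip: tuple[float, float] = HU_CLIP
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.exemplars) != set(CANONICAL_COLORS):
            raise ValueError("model must hold exactly the nine canonical colours")

    def feature_matrix(self) -> np.ndarray:
        """(9, 81) exemplar features, rows in canonical colour order."""
        return np.stack(
            [patch_features(self.exemplars[c].patch.values, self.hu_clip)
             for c in CANONICAL_COLORS]
        )

    def to_json(self, path) -> None:
        """Serialise the model (patches included) as JSON text."""
        import json

        payload = {
            "hu_clip": list(self.hu_clip),
            "provenance": self.provenance,
            "exemplars": {
                c: {
                    "group": e.group,
                    "values": e.patch.values.tolist(),
                    "location": list(e.patch.location),
                    "volume_id": e.patch.volume_id,
                }
                for c, e in self.exemplars.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ExemplarModel":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        exemplars = {
            c: Exemplar(
                color=c,
                patch=ROIPatch(np.array(d["values"]),
                               location=tuple(d["location"]),
                               volume_id=d["volume_id"]),
                group=d["group"],
            )
            for c, d in payload["exemplars"].items()
        }
        return cls(exemplars, hu_clip=tuple(payload["hu_clip"]),
                   provenance=payload.get("provenance", {}))


def patch_features(values: np.ndarray, hu_clip: tuple[float, float] = HU_CLIP) -> np.ndarray:
    """Default patch feature map: clip HU to ``hu_clip``, scale to [0, 1], flatten."""
    lo, hi = hu_clip
    return ((np.clip(np.asarray(values, dtype=float), lo, hi) - lo) / (hi - lo)).ravel()


def roi_similarity(a: ROIPatch, b: ROIPatch, hu_clip: tuple[float, float] = HU_CLIP) -> float:
    """Negative squared Euclidean feature distance; 0 iff features identical."""
    d = patch_features(a.values, hu_clip) - patch_features(b.values, hu_clip)
    return -float(d @ d)


def extract_rois(volume: CTVolume, mask: VoxelMask, stride: int = 1) -> list[ROIPatch]:
    """9 x 9 in-plane patches centred on mask voxels, decimated by ``stride``.

    Centres whose window would overlap the grid edge are skipped; the stride
    keeps centres whose index is a multiple of ``stride`` on each axis.
    """
    if mask.count == 0:
        raise ValueError("empty mask")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    nx, ny, _ = volume.shape
    rois = []
    for x, y, z in mask.indices():
        if not (_HALF <= x < nx - _HALF and _HALF <= y < ny - _HALF):
            continue
        if x % stride or y % stride or z % stride:
            continue
        patch = volume.data[x - _HALF:x + _HALF + 1, y - _HALF:y + _HALF + 1, z]
        rois.append(ROIPatch(patch.copy(), location=(int(x), int(y), int(z))))
    return rois


@dataclass
class APResult:
    exemplar_indices: np.ndarray
    labels: np.ndarray
    converged: bool
    n_iter: int


def affinity_propagation(
    S: np.ndarray,
    preference: float | np.ndarray | None = None,
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_window: int = 50,
) -> APResult:
    """Affinity propagation clustering by responsibility/availability passing.

    ``S`` is a square similarity matrix (higher = more similar); its diagonal
    is overwritten with ``preference`` (default: median off-diagonal
    similarity).  Messages are damped by ``damping`` in (0, 1); the run
    converges when the exemplar set is stable for ``conv_window`` iterations,
    otherwise the result is returned with ``converged=False``.
    """
    S = np.array(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not (0.0 < damping < 1.0):
        raise ValueError("damping must be in (0, 1)")
    n = S.shape[0]
    if n == 1:
        return APResult(np.array([0]), np.array([0]), True, 0)
    if preference is None:
        off = S[~np.eye(n, dtype=bool)]
        preference = float(np.median(off))
    np.fill_diagonal(S, preference)
    # deterministic symmetry breaking: exact duplicates would otherwise lock
    # the message passing into a degenerate fixed point; an infinitesimal
    # penalty on higher-index exemplars makes the lowest index win ties
    scale = float(np.abs(S).max()) or 1.0
    S = S - (1e-9 * scale / n) * np.arange(n)[None, :]

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    prev_exemplars: frozenset[int] | None = None
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities: r(i,k) = s(i,k) - max_{k' != k} (a(i,k') + s(i,k'))
        AS = A + S
        first = AS.argmax(axis=1)
        max1 = AS[idx, first]
        AS[idx, first] = -np.inf
        max2 = AS.max(axis=1)
        Rnew = S - max1[:, None]
        Rnew[idx, first] = S[idx, first] - max2
        R = damping * R + (1.0 - damping) * Rnew

        # availabilities: a(i,k) = min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))
        Rp = np.maximum(R, 0.0)
        Rp[idx, idx] = R[idx, idx]
        colsum = Rp.sum(axis=0)
        Anew = colsum[None, :] - Rp
        diag = Anew[idx, idx].copy()
        Anew = np.minimum(Anew, 0.0)
        Anew[idx, idx] = diag
        A = damping * A + (1.0 - damping) * Anew

        exemplars = frozenset(np.flatnonzero((A + R)[idx, idx] > 0).tolist())
        if exemplars and exemplars == prev_exemplars:
            stable += 1
            if stable >= conv_window:
                break
        else:
            stable = 0
            prev_exemplars = exemplars

    E = np.flatnonzero((A + R)[idx, idx] > 0)
    if E.size == 0:  # degenerate: fall back to the best single candidate
        E = np.array([int((A + R)[idx, idx].argmax())])
    labels_of = S[:, E].argmax(axis=1)  # first max -> lowest-index exemplar on ties
    labels = E[labels_of]
    labels[E] = E
    converged = stable >= conv_window
    return APResult(E, labels, converged, it)


def _similarity_matrix(features: np.ndarray) -> np.ndarray:
    sq = (features ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * features @ features.T
    return -np.maximum(d2, 0.0)


def tune_preference_for_k(
    S: np.ndarray,
    k_target: int,
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_window: int = 50,
    max_attempts: int = 60,
) -> tuple[APResult, float]:
    """Bisect the affinity-propagation preference until exactly ``k_target``
    exemplars emerge (the exemplar count grows with the preference).

    Returns the AP result and the preference that produced it; raises
    ``RuntimeError`` when the attempt budget is exhausted.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    off = S[~np.eye(n, dtype=bool)]
    med = float(np.median(off))
    lo = float(off.min()) * 2 * n - 1.0  # very negative -> few exemplars
    hi = 0.0  # at 0 every point prefers itself

    pref = med if med < 0 else (lo + hi) / 2
    for _ in range(max_attempts):
        res = affinity_propagation(S, preference=pref, damping=damping,
                                   max_iter=max_iter, conv_window=conv_window)
        k = res.exemplar_indices.size
        if k == k_target:
            return res, pref
        if k > k_target:
            hi = pref
        else:
            lo = pref
        pref = (lo + hi) / 2.0
    raise RuntimeError(
        f"could not reach {k_target} exemplars within {max_attempts} attempts"
    )


def fit_exemplar_model(
    rois: list[ROIPatch],
    k_target: int = 9,
    seed: int = 0,
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_window: int = 50,
    max_attempts: int = 60,
    hu_clip: tuple[float, float] = HU_CLIP,
) -> ExemplarModel | list[ROIPatch]:
    """Learn ``k_target`` exemplars from ROI patches.

    Affinity propagation's preference is tuned by bisection until exactly
    ``k_target`` exemplars emerge.  With the default ``k_target=9``, colours
    are assigned to the exemplars by ranking mean patch HU from lowest to
    highest onto :data:`HU_RANK_ORDER` (ground-glass-like colours land on the
    least dense textures) and an :class:`ExemplarModel` is returned.  For any
    other ``k_target`` the selected exemplar patches themselves are returned
    (useful e.g. for checking the ``k_target=1`` medoid limit).

    Raises
    ------
    RuntimeError
        If the attempt budget is exhausted before ``k_target`` exemplars
        are found.
    ValueError
        If fewer ROIs than ``k_target`` are supplied.
    """
    if len(rois) < k_target:
        raise ValueError(f"need at least {k_target} ROIs, got {len(rois)}")
    feats = np.stack([patch_features(r.values, hu_clip) for r in rois])
    S = _similarity_matrix(feats)
    n = len(rois)
    best, pref = tune_preference_for_k(
        S, k_target, damping=damping, max_iter=max_iter,
        conv_window=conv_window, max_attempts=max_attempts,
    )

    if k_target != 9:
        return [rois[i] for i in best.exemplar_indices]

    ex_idx = best.exemplar_indices
    means = np.array([rois[i].mean_hu for i in ex_idx])
    order = ex_idx[np.argsort(means, kind="stable")]
    exemplars = {
        color: Exemplar(
            color=color,
            patch=rois[i],
            group=next(g for g, cs in COLOR_GROUPS.items() if color in cs),
        )
        for color, i in zip(HU_RANK_ORDER, order)
    }
    return ExemplarModel(
        exemplars,
        hu_clip=hu_clip,
        provenance={
            "seed": seed,
            "preference": pref,
            "iterations": best.n_iter,
            "converged": best.converged,
            "n_rois": n,
        },
    )


def classify_voxels(volume: CTVolume, mask: VoxelMask, model: ExemplarModel) -> np.ndarray:
    """Label every mask voxel with the colour index of its nearest exemplar.

    The voxel's 9 x 9 in-plane neighbourhood (reflect-padded at grid edges)
    is compared with all nine exemplars under the model's similarity; ties go
    to the lowest index in the canonical colour order.  Returns an int grid
    shaped like the volume: -1 outside the mask, else an index into
    :data:`CANONICAL_COLORS`.
    """
    if mask.count == 0:
        raise ValueError("empty mask")
    if not mask.same_geometry(volume):
        raise ValueError("mask and volume must share geometry")
    ex_feats = model.feature_matrix()  # (9, 81), canonical colour order
    labels = np.full(volume.shape, -1, dtype=np.int8)
    padded = np.pad(volume.data, ((_HALF, _HALF), (_HALF, _HALF), (0, 0)), mode="reflect")
    from numpy.lib.stride_tricks import sliding_window_view

    for z in np.unique(mask.indices()[:, 2]):
        inplane = mask.data[:, :, z]
        xs, ys = np.nonzero(inplane)
        windows = sliding_window_view(padded[:, :, z], (PATCH_SIZE, PATCH_SIZE))
        patches = windows[xs, ys].reshape(len(xs), -1)
        lo, hi = model.hu_clip
        feats = (np.clip(patches, lo, hi) - lo) / (hi - lo)
        # similarity = -||f - e||^2; argmax over exemplars = argmin distance
        d2 = ((feats[:, None, :] - ex_feats[None, :, :]) ** 2).sum(axis=2)
        labels[xs, ys, z] = d2.argmin(axis=1)  # first min -> colour precedence
    return labels


@dataclass
class Glyph:
    """Per-nodule proportion of each exemplar colour, in percent."""

    percentages: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.percentages) != set(CANONICAL_COLORS):
            raise ValueError("glyph needs all nine colours")
        vals = np.array([self.percentages[c] for c in CANONICAL_COLORS], dtype=float)
        if (vals < 0).any() or abs(vals.sum() - 100.0) > 1e-6:
            raise ValueError("glyph percentages must be non-negative and sum to 100")

    def as_vector(self) -> np.ndarray:
        return np.array([self.percentages[c] for c in CANONICAL_COLORS])

    def __getitem__(self, color: str) -> float:
        return self.percentages[color]


@dataclass
class CompositeFeatures:
    """Composite exemplar percentages of nodule volume."""

    viro: float
    yp: float
    bcg: float
    y: float
    g: float
    y_plus_g: float

    def value(self, name: str) -> float:
        key = name.replace("-", "").replace("+", "plus").replace(" ", "").lower()
        aliases = {"viro": "viro", "yp": "yp", "bcg": "bcg", "y": "y", "g": "g",
                   "yplusg": "y_plus_g", "ypg": "y_plus_g"}
        if key not in aliases:
            raise KeyError(f"unknown composite feature {name!r}")
        return getattr(self, aliases[key])


def compute_glyph(labels: np.ndarray, mask: VoxelMask) -> Glyph:
    """Percentage of mask voxels carrying each colour label."""
    if mask.count == 0:
        raise ValueError("empty mask")
    lab = labels[mask.data]
    if (lab < 0).any():
        raise ValueError("every mask voxel must be labelled")
    counts = np.bincount(lab, minlength=len(CANONICAL_COLORS))
    pct = 100.0 * counts / counts.sum()
    return Glyph({c: float(p) for c, p in zip(CANONICAL_COLORS, pct)})


def composite_features(glyph: Glyph) -> CompositeFeatures:
    g = glyph.percentages
    viro = sum(g[c] for c in COLOR_GROUPS["VIRO"])
    yp = sum(g[c] for c in COLOR_GROUPS["YP"])
    bcg = sum(g[c] for c in COLOR_GROUPS["BCG"])
    return CompositeFeatures(viro=viro, yp=yp, bcg=bcg, y=g["Y"], g=g["G"],
                             y_plus_g=g["Y"] + g["G"])


def apply_cutoff(
    features: CompositeFeatures,
    feature_name: str,
    threshold: float | None = None,
    direction: str | None = None,
) -> bool:
    """Flag a nodule by a composite-feature cutoff (boundary inclusive).

    With no explicit threshold/direction the registered defaults apply:
    V-I-R-O <= 71 % or Y-P >= 23.5 % of tumor volume.
    """
    value = features.value(feature_name)
    key = feature_name.replace("-", "").upper()
    if threshold is None or direction is None:
        if key not in DEFAULT_CUTOFFS:
            raise KeyError(f"no registered cutoff for {feature_name!r}")
        threshold, direction = DEFAULT_CUTOFFS[key]
    if direction not in ("le", "ge"):
        raise ValueError("direction must be 'le' or 'ge'")
    return value <= threshold if direction == "le" else value >= threshold


def _k_medoids(X: np.ndarray, k: int, seed: int, max_iter: int = 100) -> np.ndarray:
    """Plain PAM-style k-medoids on squared Euclidean distance; returns labels."""
    n = X.shape[0]
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    rng = np.random.default_rng(seed)
    medoids = list(rng.choice(n, size=k, replace=False))
    for _ in range(max_iter):
        labels = np.argmin(d2[:, medoids], axis=1)
        new = []
        for j in range(k):
            members = np.flatnonzero(labels == j)
            if members.size == 0:
                new.append(medoids[j])
                continue
            costs = d2[np.ix_(members, members)].sum(axis=0)
            new.append(int(members[costs.argmin()]))
        if new == medoids:
            break
        medoids = new
    return np.argmin(d2[:, medoids], axis=1)


def default_exemplar_model(seed: int = 0, n_per_level: int = 8) -> ExemplarModel:
    """A synthetic reference exemplar model.

    Trains the nine exemplars on noisy patches drawn around nine evenly
    spaced HU plateaus from -950 (aerated lung) to +100 (soft tissue) —
    a stand-in texture library spanning ground glass through solid, for use
    when no study-specific ROI training set is available.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rois = []
    for lv in np.linspace(-950.0, 100.0, 9):
        for _ in range(n_per_level):
            rois.append(ROIPatch(rng.normal(lv, 5.0, (PATCH_SIZE, PATCH_SIZE))))
    model = fit_exemplar_model(rois, seed=seed)
    model.provenance["training"] = "synthetic nine-plateau library"
    return model


def glyph_to_svg(glyph: Glyph, path) -> None:
    """Render a glyph as a simple SVG bar chart (one bar per colour)."""
    fills = {"V": "#7f00ff", "I": "#4b0082", "B": "#0000ff", "G": "#008000",
             "Y": "#ffd700", "O": "#ff8c00", "R": "#ff0000", "C": "#00ced1",
             "P": "#ff69b4"}
    width, height, bar = 270, 120, 30
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" '
             f'width="{width}" height="{height}">']
    for i, c in enumerate(CANONICAL_COLORS):
        h = glyph[c] / 100.0 * (height - 20)
        parts.append(
            f'<rect x="{i * bar}" y="{height - 14 - h:.2f}" width="{bar - 4}" '
            f'height="{h:.2f}" fill="{fills[c]}"/>'
            f'<text x="{i * bar + bar / 2 - 2}" y="{height - 2}" '
            f'font-size="10" text-anchor="middle">{c}</text>')
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("".join(parts))


def assign_risk_groups(glyphs: list[Glyph], seed: int = 0) -> list[str]:
    """Cohort-wise Good/Intermediate/Poor stratification of nodule glyphs.

    The nine-dimensional glyph vectors are clustered into three groups by
    k-medoids; groups are ordered by ascending mean V-I-R-O share and
    labelled G, I, P in that order (more solid texture = worse prognosis).
    Identical glyphs are a degenerate cohort: everyone is assigned I with a
    warning.
    """
    if len(glyphs) < 3:
        raise ValueError("need at least 3 nodules to stratify")
    X = np.stack([g.as_vector() for g in glyphs])
    if np.allclose(X, X[0]):
        warnings.warn("all glyphs identical; assigning every nodule to group I")
        return ["I"] * len(glyphs)
    labels = _k_medoids(X, 3, seed)
    viro_cols = [CANONICAL_COLORS.index(c) for c in COLOR_GROUPS["VIRO"]]
    means = []
    for j in range(3):
        members = X[labels == j]
        means.append(members[:, viro_cols].sum(axis=1).mean() if members.size else np.inf)
    order = np.argsort(means, kind="stable")
    name_of = {int(cluster): grp for grp, cluster in zip("GIP", order)}
    return [name_of[int(l)] for l in labels]
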