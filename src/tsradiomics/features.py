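"""The 60-feature CT radiomics panel.

Per lesion the extractor emits exactly 60 named features in five families:

* 19 whole-ROI histogram features (first-order intensity statistics),
* 9 outer-rim + 9 delta (core minus rim) histogram features computed on the
  volume-based core/rim partition,
* 10 shape features,
* 11 gray-level co-occurrence matrix (GLCM) features from a 256-level,
  13-direction averaged matrix,
* 2 intensity size-zone (ISZ) features from a 32-level zone matrix.

Intensity statistics use population (1/N) central moments; kurtosis is the
Pearson (non-excess) convention, so a Gaussian scores 3.  A feature whose
definition degenerates on a given ROI (e.g. skewness of a constant region)
is reported as NaN with a recorded reason — never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .io import ImageVolume, LesionRecord, ROIMask
from .partition import PartitionedROI, partition_roi

__all__ = [
    "FeatureConfig",
    "FeatureMap",
    "FeatureVector",
    "GLCMatrix",
    "ISZMatrix",
    "EmptyGLCMError",
    "feature_names",
    "feature_categories",
    "histogram_features",
    "partition_features",
    "shape_features",
    "glcm_matrix",
    "glcm_features",
    "glcm_offsets",
    "iszm",
    "iszm_features",
    "extract_all",
    "N_FEATURES",
]

N_FEATURES = 60

#: the 9 first-order statistics computed on the core/rim sub-ROIs
PARTITION_SUBSET = (
    "mean", "median", "sd", "minimum", "maximum",
    "skewness", "kurtosis", "energy", "entropy",
)


def _load_manifest() -> dict:
    with resources.files(__package__).joinpath("manifest.yaml").open() as fh:
        return yaml.safe_load(fh)


_MANIFEST = _load_manifest()


def feature_categories() -> dict[str, list[str]]:
    """Mapping category -> ordered feature names, from the shipped manifest."""
    return {k: list(v) for k, v in _MANIFEST["categories"].items()}


def feature_names() -> list[str]:
    """The 60 panel feature names in canonical (manifest) order."""
    names = [n for cat in _MANIFEST["categories"].values() for n in cat]
    assert len(names) == N_FEATURES, "manifest must define exactly 60 features"
    return names


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable panel parameters.

    hist_bins / glcm_levels / isz_levels are the discretization bin counts
    for the histogram-entropy, GLCM and ISZ computations; all discretize to
    fixed-width bins over the ROI's own [min, max] intensity range.
    """

    hist_bins: int = 256
    glcm_levels: int = 256
    isz_levels: int = 32

    @classmethod
    def from_yaml(cls, path) -> "FeatureConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


class FeatureMap(dict):
    """A dict of feature name -> value with per-feature failure reasons.

    Undefined features hold NaN; ``missing`` maps their names to a reason
    string.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.missing: dict[str, str] = {}

    def mark_missing(self, name: str, reason: str) -> None:
        self[name] = float("nan")
        self.missing[name] = reason


@dataclass
class FeatureVector:
    """The full 60-feature panel for one lesion."""

    values: dict[str, float]
    missing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = feature_names()
        if list(self.values) != expected:
            raise ValueError(
                "feature vector must carry exactly the 60 manifest features "
                f"in order; got {len(self.values)} keys"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in feature_names()], dtype=float)


# ---------------------------------------------------------------------------
# histogram features
# ---------------------------------------------------------------------------

def _discretize(values: np.ndarray, levels: int) -> np.ndarray:
    """Fixed-width binning of ``values`` into ``levels`` bins over [min, max].

    A constant input maps entirely to bin 0.
    """
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.zeros(values.shape, dtype=np.int64)
    idx = np.floor((values - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(idx, 0, levels - 1)


def _bin_probabilities(values: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Histogram probabilities and bin centers over [min, max]."""
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        p = np.zeros(bins)
        p[0] = 1.0
        centers = np.full(bins, lo)
        return p, centers
    counts = np.bincount(_discretize(values, bins), minlength=bins).astype(float)
    p = counts / counts.sum()
    edges = np.linspace(lo, hi, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return p, centers


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def histogram_features(values, bins: int = 256) -> FeatureMap:
    """First-order statistics of the ROI intensity distribution (19 features).

    Moments are population (1/N); skewness = m3/m2^1.5 and kurtosis = m4/m2^2
    (Pearson).  energy = sum(x^2); rms = sqrt(energy/N); entropy uses
    ``bins`` fixed-width bins over [min, max]; upp sums squared bin
    probabilities over bins whose center lies above 0 HU; mad is the mean
    absolute deviation from the mean; percentiles interpolate linearly.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 intensity values")
    out = FeatureMap()
    n = x.size
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    out["mean"] = mean
    out["median"] = float(np.median(x))
    out["minimum"] = float(x.min())
    out["maximum"] = float(x.max())
    out["range"] = out["maximum"] - out["minimum"]
    out["sd"] = math.sqrt(m2)
    out["variance"] = m2
    if m2 > 0:
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        out["skewness"] = m3 / m2 ** 1.5
        out["kurtosis"] = m4 / m2 ** 2
    else:
        out.mark_missing("skewness", "constant intensities: second moment is zero")
        out.mark_missing("kurtosis", "constant intensities: second moment is zero")
    energy = float((x ** 2).sum())
    out["energy"] = energy
    p, centers = _bin_probabilities(x, bins)
    out["entropy"] = _entropy_bits(p)
    out["rms"] = math.sqrt(energy / n)
    q = np.percentile(x, [2.5, 25, 75, 97.5])
    out["iqr"] = float(q[2] - q[1])
    out["mad"] = float(np.abs(x - mean).mean())
    out["upp"] = float((p[centers > 0.0] ** 2).sum())
    out["p2_5"] = float(q[0])
    out["p25"] = float(q[1])
    out["p75"] = float(q[2])
    out["p97_5"] = float(q[3])
    return out


def _subset9(values: np.ndarray, bins: int) -> FeatureMap:
    full = histogram_features(values, bins=bins)
    sub = FeatureMap({k: full[k] for k in PARTITION_SUBSET})
    sub.missing = {k: v for k, v in full.missing.items() if k in PARTITION_SUBSET}
    return sub


def partition_features(
    image: ImageVolume, part: PartitionedROI, bins: int = 256
) -> FeatureMap:
    """Outer-rim and delta (core minus rim) first-order features (18 total).

    The 9-statistic subset is computed separately on core and rim
    intensities; the emitted values are the rim statistics (``_outer``) and
    core-minus-rim differences (``_delta``).  Core values are intermediate
    only.  Undefined statistics on a constant sub-ROI propagate as NaN with
    reasons.
    """
    inner_vals = image.voxels[part.inner.voxels]
    outer_vals = image.voxels[part.outer.voxels]
    inner = _subset9(inner_vals, bins)
    outer = _subset9(outer_vals, bins)
    out = FeatureMap()
    for k in PARTITION_SUBSET:
        if k in outer.missing:
            out.mark_missing(f"{k}_outer", f"outer ROI: {outer.missing[k]}")
        else:
            out[f"{k}_outer"] = outer[k]
        reason = inner.missing.get(k) or outer.missing.get(k)
        if reason is not None:
            side = "inner ROI" if k in inner.missing else "outer ROI"
            out.mark_missing(f"{k}_delta", f"{side}: {reason}")
        else:
            out[f"{k}_delta"] = inner[k] - outer[k]
    return out


# ---------------------------------------------------------------------------
# shape features
# ---------------------------------------------------------------------------

def _convex_hull_voxel_count(mask: ROIMask) -> tuple[int, ConvexHull]:
    """Voxelized convex hull: count of grid voxels whose center lies in the
    hull of the foreground voxel centers.

    Comparing voxel counts (rather than voxel volume vs continuous hull
    volume) keeps convexity <= 1 and makes a convex digital shape score ~1.
    """
    sp = np.asarray(mask.spacing)
    pts = np.argwhere(mask.voxels).astype(float) * sp
    hull = ConvexHull(pts)
    lo = np.floor(pts.min(axis=0) / sp).astype(int)
    hi = np.ceil(pts.max(axis=0) / sp).astype(int)
    grids = np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo, hi)], indexing="ij")
    centers = np.stack([g.ravel() for g in grids], axis=1) * sp
    A, b = hull.equations[:, :3], hull.equations[:, 3]
    inside = (centers @ A.T + b <= 1e-9).all(axis=1)
    return int(inside.sum()), hull


def shape_features(mask: ROIMask, image: ImageVolume) -> FeatureMap:
    """Morphology of the ROI (10 features).

    volume is the voxel-count volume (mm^3); surface_area triangulates the
    0.5-isosurface of the binary mask (mm^2); compactness = V/(sqrt(pi) *
    A^1.5); sphericity = pi^(1/3) * (6V)^(2/3) / A; convexity is the ratio
    of foreground voxels to voxels inside the convex hull of the foreground
    centers (voxelized hull, so convexity <= 1);
    max_3d_diameter is the farthest foreground pair (mm); elongation is
    sqrt(lambda2/lambda1) of the physical-coordinate covariance (1 for a
    sphere); density = mean HU + 1000 (water-referenced linear rescale) and
    mass = volume * density.
    """
    n = mask.n_foreground
    if n < 27:
        raise ValueError(f"need >= 27 foreground voxels for shape features, got {n}")
    out = FeatureMap()
    sp = np.asarray(mask.spacing)
    volume = n * float(np.prod(sp))
    out["volume"] = volume

    padded = np.pad(mask.voxels.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(sp))
    area = float(measure.mesh_surface_area(verts, faces))
    out["surface_area"] = area
    out["surface_to_volume_ratio"] = area / volume
    out["compactness"] = volume / (math.sqrt(math.pi) * area ** 1.5)
    out["sphericity"] = math.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area

    coords = np.argwhere(mask.voxels).astype(float) * sp
    try:
        n_hull, hull = _convex_hull_voxel_count(mask)
        out["convexity"] = n / n_hull
        hv = hull.points[hull.vertices]
        diff = hv[:, None, :] - hv[None, :, :]
        out["max_3d_diameter"] = float(np.sqrt((diff ** 2).sum(-1)).max())
    except QhullError:
        out.mark_missing("convexity", "degenerate (planar/linear) mask: hull undefined")
        out.mark_missing("max_3d_diameter", "degenerate (planar/linear) mask: hull undefined")

    cov = np.cov(coords, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    if eig[0] > 0:
        out["elongation"] = math.sqrt(max(eig[1], 0.0) / eig[0])
    else:
        out.mark_missing("elongation", "degenerate mask: zero principal variance")

    density = float(image.voxels[mask.voxels].mean()) + 1000.0
    out["density"] = density
    out["mass"] = volume * density
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

class EmptyGLCMError(ValueError):
    """No co-occurring foreground pair exists in any direction."""


@dataclass(frozen=True)
class GLCMatrix:
    """Symmetric, unit-sum gray-level co-occurrence matrix (averaged)."""

    matrix: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (self.levels, self.levels):
            raise ValueError("GLCM shape does not match level count")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("GLCM must be symmetric")
        if abs(m.sum() - 1.0) > 1e-12:
            raise ValueError("GLCM entries must sum to 1")


def glcm_offsets() -> list[tuple[int, int, int]]:
    """The 13 unique distance-1 3D direction offsets (26-neighborhood mod sign)."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                if (dx, dy, dz) > (0, 0, 0):  # lexicographically positive half
                    offs.append((dx, dy, dz))
    assert len(offs) == 13
    return offs


def glcm_matrix(image: ImageVolume, mask: ROIMask, levels: int = 256) -> GLCMatrix:
    """Direction-averaged GLCM of the ROI at ``levels`` gray levels.

    ROI intensities are discretized to fixed-width bins over the ROI's own
    [min, max].  For each of the 13 offsets, co-occurrences between
    foreground pairs are accumulated, symmetrized and normalized to sum 1;
    the matrices of all directions with at least one pair are averaged
    element-wise.
    """
    vox = image.voxels
    fg = mask.voxels
    disc = np.full(vox.shape, -1, dtype=np.int64)
    disc[fg] = _discretize(vox[fg], levels)

    acc = np.zeros((levels, levels))
    n_dirs = 0
    for off in glcm_offsets():
        a, b = _offset_pairs(disc, off)
        if a.size == 0:
            continue
        counts = np.bincount(a * levels + b, minlength=levels * levels).astype(float)
        c = counts.reshape(levels, levels)
        c = c + c.T
        acc += c / c.sum()
        n_dirs += 1
    if n_dirs == 0:
        raise EmptyGLCMError("no co-occurring foreground pair in any direction")
    return GLCMatrix(acc / n_dirs, levels)


def _offset_pairs(disc: np.ndarray, off: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Discretized values of all in-mask voxel pairs separated by ``off``."""
    slabs_a, slabs_b = [], []
    for d, size in zip(off, disc.shape):
        if d >= 0:
            slabs_a.append(slice(0, size - d))
            slabs_b.append(slice(d, size))
        else:
            slabs_a.append(slice(-d, size))
            slabs_b.append(slice(0, size + d))
    a = disc[tuple(slabs_a)].ravel()
    b = disc[tuple(slabs_b)].ravel()
    keep = (a >= 0) & (b >= 0)
    return a[keep], b[keep]


def glcm_features(G: GLCMatrix) -> FeatureMap:
    """The 11 GLCM texture features; bin labels i, j are 1-based."""
    p = G.matrix
    L = G.levels
    i = np.arange(1, L + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    out = FeatureMap()
    px = p.sum(axis=1)  # symmetric: marginal of either index
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())
    out["glcm_autocorrelation"] = float((I * J * p).sum())
    out["glcm_contrast"] = float(((I - J) ** 2 * p).sum())
    if var > 0:
        out["glcm_correlation"] = (out["glcm_autocorrelation"] - mu * mu) / var
    else:
        out.mark_missing("glcm_correlation", "zero marginal variance (single gray level)")
    out["glcm_dissimilarity"] = float((np.abs(I - J) * p).sum())
    out["glcm_energy"] = float((p ** 2).sum())
    out["glcm_entropy"] = _entropy_bits(p.ravel())
    out["glcm_homogeneity"] = float((p / (1.0 + np.abs(I - J))).sum())
    out["glcm_cluster_shade"] = float(((I + J - 2 * mu) ** 3 * p).sum())
    out["glcm_cluster_prominence"] = float(((I + J - 2 * mu) ** 4 * p).sum())
    out["glcm_sum_average"] = float(((I + J) * p).sum())
    out["glcm_variance"] = var
    return out


# ---------------------------------------------------------------------------
# ISZ (intensity size-zone)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ISZMatrix:
    """Zone counts P(g, s): zones of gray level g and size s voxels."""

    matrix: np.ndarray  # G x S_max integer counts
    levels: int
    n_zones: int

    def __post_init__(self) -> None:
        if int(self.matrix.sum()) != self.n_zones or self.n_zones < 1:
            raise ValueError("ISZ matrix entries must sum to the zone count (>= 1)")


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def iszm(image: ImageVolume, mask: ROIMask, levels: int = 32) -> ISZMatrix:
    """Intensity size-zone matrix at ``levels`` gray levels.

    Zones are 26-connected components of equal discretized level within the
    ROI.
    """
    fg = mask.voxels
    disc = np.full(fg.shape, -1, dtype=np.int64)
    disc[fg] = _discretize(image.voxels[fg], levels)
    zone_sizes: dict[int, list[int]] = {}
    max_size = 1
    for g in range(levels):
        lab, n = ndimage.label(disc == g, structure=_CONN26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zone_sizes[g] = sizes.tolist()
        max_size = max(max_size, int(sizes.max()))
    mat = np.zeros((levels, max_size), dtype=np.int64)
    for g, sizes in zone_sizes.items():
        for s in sizes:
            mat[g, s - 1] += 1
    return ISZMatrix(mat, levels, int(mat.sum()))


def iszm_features(image: ImageVolume, mask: ROIMask, levels: int = 32) -> FeatureMap:
    """Intensity variability and size-zone variability (2 features).

    With row sums r_g (zones per gray level) and column sums c_s (zones per
    size), IV = sum(r_g^2)/Nz and SZV = sum(c_s^2)/Nz.  Low values mean
    zones are spread over many levels/sizes — a heterogeneity signature.
    """
    m = iszm(image, mask, levels=levels)
    nz = m.n_zones
    row = m.matrix.sum(axis=1).astype(float)
    col = m.matrix.sum(axis=0).astype(float)
    out = FeatureMap()
    out["intensity_variability"] = float((row ** 2).sum() / nz)
    out["size_zone_variability"] = float((col ** 2).sum() / nz)
    return out


# ---------------------------------------------------------------------------
# full panel
# ---------------------------------------------------------------------------

def extract_all(lesion: LesionRecord, config: FeatureConfig | None = None) -> FeatureVector:
    """Compute the full 60-feature panel for one lesion.

    Deterministic for fixed input; per-feature failures are recorded in
    ``FeatureVector.missing`` rather than dropped.
    """
    if lesion.image is None or lesion.mask is None:
        raise ValueError(f"lesion {lesion.lesion_id} has no image/mask")
    cfg = config or FeatureConfig()
    image, mask = lesion.image, lesion.mask

    blocks: list[FeatureMap] = []
    blocks.append(histogram_features(image.voxels[mask.voxels], bins=cfg.hist_bins))
    part = partition_roi(mask)
    blocks.append(partition_features(image, part, bins=cfg.hist_bins))
    blocks.append(shape_features(mask, image))
    blocks.append(glcm_features(glcm_matrix(image, mask, levels=cfg.glcm_levels)))
    blocks.append(iszm_features(image, mask, levels=cfg.isz_levels))

    merged: dict[str, float] = {}
    missing: dict[str, str] = {}
    for b in blocks:
        merged.update(b)
        missing.update(b.missing)
    ordered = {name: merged[name] for name in feature_names()}
    return FeatureVector(values=ordered, missing=missing)
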