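"""Per-lesion radiomic feature extraction.

Computes, for a segmented 3-D lesion patch, the standard IBSI-style feature
set: 14 shape features (mask geometry only), 18 first-order intensity
statistics, and 75 texture features drawn from five texture-matrix families
(24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM).  The non-shape features are
computed on the original image and, optionally, on Laplacian-of-Gaussian
filtered images (one per scale sigma) and on the eight sub-bands of a
single-level stationary 3-D wavelet decomposition.  With the default
configuration (five LoG scales, eight wavelet sub-bands) the vector has

    14 shape + 93 x (1 + 5 + 8) = 1316 entries.

Feature names follow the ``<imagetype>_<class>_<Name>`` convention, e.g.
``original_firstorder_Mean`` or ``log-sigma-3-mm_glcm_Contrast``.

Undefined values on degenerate inputs (single-voxel masks, constant
intensity, texture families with no admissible voxel pairs) are emitted as
the NaN sentinel and are treated as missing by the downstream imputation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pywt
from numba import njit
from scipy import ndimage
from skimage import measure

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LesionImage:
    """A lesion patch: HU-like intensities, binary mask, voxel spacing in mm."""

    intensities: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensities.shape != self.mask.shape:
            raise ValueError(
                f"intensity shape {self.intensities.shape} != mask shape {self.mask.shape}"
            )
        if self.intensities.ndim != 3:
            raise ValueError("lesion patches must be 3-D")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings.

    log_sigmas_mm
        Scales of the Laplacian-of-Gaussian band-pass filter, in mm.
    wavelet
        Wavelet name for the single-level stationary 3-D decomposition
        (8 sub-bands), or None to disable the wavelet image types.
    bin_width
        Fixed intensity bin width (HU-equivalent) for the texture-matrix
        discretization and for the histogram-based first-order features.
    resample_spacing
        Optional isotropic spacing (mm) to resample to before extraction
        (linear for intensities, nearest-neighbour for the mask).  None
        leaves the grid untouched.
    """

    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    wavelet: str | None = "coif1"
    bin_width: float = 25.0
    resample_spacing: float | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ValueError("LoG sigmas must be positive")

    @property
    def wavelet_subbands(self) -> tuple[str, ...]:
        if self.wavelet is None:
            return ()
        return tuple("".join(p) for p in itertools.product("LH", repeat=3))

    @property
    def image_types(self) -> tuple[str, ...]:
        names = ["original"]
        names += [f"log-sigma-{_fmt_sigma(s)}-mm" for s in self.log_sigmas_mm]
        names += [f"wavelet-{b}" for b in self.wavelet_subbands]
        return tuple(names)


def _fmt_sigma(s: float) -> str:
    return f"{s:g}".replace(".", "-")


SHAPE_FEATURES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)

FIRSTORDER_FEATURES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)

GLCM_FEATURES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)

GLRLM_FEATURES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_FEATURES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

_TEXTURE_CLASSES = (
    ("glcm", GLCM_FEATURES),
    ("glrlm", GLRLM_FEATURES),
    ("glszm", GLSZM_FEATURES),
    ("gldm", GLDM_FEATURES),
    ("ngtdm", NGTDM_FEATURES),
)


def feature_schema(config: ExtractionConfig | None = None) -> list[str]:
    """Ordered list of feature names for a configuration.

    Shape features come first (mask geometry, computed once); then, per image
    type in the order original / LoG scales / wavelet sub-bands: the 18
    first-order and 75 texture features.
    """
    config = config or ExtractionConfig()
    names = [f"original_shape_{f}" for f in SHAPE_FEATURES]
    for itype in config.image_types:
        names += [f"{itype}_firstorder_{f}" for f in FIRSTORDER_FEATURES]
        for cls, feats in _TEXTURE_CLASSES:
            names += [f"{itype}_{cls}_{f}" for f in feats]
    return names


# ---------------------------------------------------------------------------
# image filters
# ---------------------------------------------------------------------------


def _log_filter(img: np.ndarray, sigma_mm: float, spacing: tuple[float, ...]) -> np.ndarray:
    # scale-normalized LoG, sign-flipped so bright blobs give positive response
    sigma_vox = [sigma_mm / s for s in spacing]
    return -(sigma_mm ** 2) * ndimage.gaussian_laplace(img, sigma=sigma_vox)


def _wavelet_subbands(img: np.ndarray, wavelet: str) -> dict[str, np.ndarray]:
    """Single-level stationary 3-D wavelet transform, cropped to input shape.

    Sub-band labels use L (approximation) / H (detail), one letter per array
    axis in axis order.
    """
    pads = [(0, s % 2) for s in img.shape]
    padded = np.pad(img, pads, mode="symmetric")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    out = {}
    crop = tuple(slice(0, s) for s in img.shape)
    for key, arr in coeffs.items():
        label = key.replace("a", "L").replace("d", "H")
        out[f"wavelet-{label}"] = arr[crop]
    return out


def _derived_images(image: LesionImage, config: ExtractionConfig) -> dict[str, np.ndarray]:
    img = image.intensities
    out = {"original": img}
    for s in config.log_sigmas_mm:
        out[f"log-sigma-{_fmt_sigma(s)}-mm"] = _log_filter(img, s, image.spacing)
    if config.wavelet is not None:
        out.update(_wavelet_subbands(img, config.wavelet))
    return out


def _resample(image: LesionImage, spacing: float) -> LesionImage:
    zoom = [s / spacing for s in image.spacing]
    img = ndimage.zoom(image.intensities, zoom, order=1)
    mask = ndimage.zoom(image.mask.astype(np.uint8), zoom, order=0).astype(bool)
    if not mask.any():  # tiny lesion vanished under the coarser grid
        mask = np.zeros_like(mask)
        mask[tuple(np.array(mask.shape) // 2)] = True
    return LesionImage(img, mask, (spacing, spacing, spacing))


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


def _discretize(img: np.ndarray, mask: np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    """Map in-mask intensities to integer gray levels 1..Ng; 0 outside mask."""
    vals = img[mask]
    lo = vals.min()
    levels = np.zeros(img.shape, dtype=np.int64)
    levels[mask] = np.floor((img[mask] - lo) / bin_width).astype(np.int64) + 1
    ng = int(levels.max())
    return levels, ng


# ---------------------------------------------------------------------------
# shape features
# ---------------------------------------------------------------------------


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    a = verts[faces[:, 0]]
    b = verts[faces[:, 1]]
    c = verts[faces[:, 2]]
    return abs(float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 400:
        try:
            from scipy.spatial import ConvexHull

            points = points[ConvexHull(points).vertices]
        except Exception:  # flat/degenerate point clouds
            pass
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def shape_features(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    """The 14 mask-geometry features (intensity independent)."""
    mask = np.asarray(mask).astype(bool)
    spacing = np.asarray(spacing, dtype=float)
    nvox = int(mask.sum())
    voxvol = float(np.prod(spacing))
    out: dict[str, float] = {}
    out["VoxelVolume"] = nvox * voxvol

    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    mesh_v = _mesh_volume(verts, faces)
    area = float(measure.mesh_surface_area(verts, faces))
    out["MeshVolume"] = mesh_v
    out["SurfaceArea"] = area
    out["SurfaceVolumeRatio"] = area / mesh_v if mesh_v > 0 else np.nan
    out["Sphericity"] = (36.0 * np.pi * mesh_v ** 2) ** (1.0 / 3.0) / area if area > 0 else np.nan

    coords = np.argwhere(mask) * spacing  # physical voxel centres
    out["Maximum3DDiameter"] = _max_pairwise(coords)
    # projected maximum diameters; axes: 0 = slice direction, 1 = row, 2 = column
    out["Maximum2DDiameterSlice"] = _max_pairwise(coords[:, [1, 2]])
    out["Maximum2DDiameterColumn"] = _max_pairwise(coords[:, [0, 2]])
    out["Maximum2DDiameterRow"] = _max_pairwise(coords[:, [0, 1]])

    if nvox > 1:
        cov = np.cov(coords, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    out["MajorAxisLength"] = 4.0 * np.sqrt(eig[0])
    out["MinorAxisLength"] = 4.0 * np.sqrt(eig[1])
    out["LeastAxisLength"] = 4.0 * np.sqrt(eig[2])
    out["Elongation"] = np.sqrt(eig[1] / eig[0]) if eig[0] > 0 else np.nan
    out["Flatness"] = np.sqrt(eig[2] / eig[0]) if eig[0] > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# first-order features
# ---------------------------------------------------------------------------


def firstorder_features(vals: np.ndarray, voxel_volume: float, bin_width: float) -> dict[str, float]:
    vals = np.asarray(vals, dtype=np.float64)
    n = vals.size
    mean = float(vals.mean())
    var = float(vals.var())
    out: dict[str, float] = {}
    out["Energy"] = float((vals ** 2).sum())
    out["TotalEnergy"] = out["Energy"] * voxel_volume
    counts = np.bincount(np.floor((vals - vals.min()) / bin_width).astype(int))
    p = counts[counts > 0] / n
    out["Entropy"] = float(-(p * np.log2(p)).sum())
    out["Uniformity"] = float((p ** 2).sum())
    out["Minimum"] = float(vals.min())
    out["Maximum"] = float(vals.max())
    p10, p25, p50, p75, p90 = np.percentile(vals, [10, 25, 50, 75, 90])
    out["10Percentile"] = float(p10)
    out["90Percentile"] = float(p90)
    out["Mean"] = mean
    out["Median"] = float(p50)
    out["InterquartileRange"] = float(p75 - p25)
    out["Range"] = out["Maximum"] - out["Minimum"]
    out["MeanAbsoluteDeviation"] = float(np.abs(vals - mean).mean())
    robust = vals[(vals >= p10) & (vals <= p90)]
    out["RobustMeanAbsoluteDeviation"] = (
        float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    )
    out["RootMeanSquared"] = float(np.sqrt((vals ** 2).mean()))
    if var > 0:
        m3 = float(((vals - mean) ** 3).mean())
        m4 = float(((vals - mean) ** 4).mean())
        out["Skewness"] = m3 / var ** 1.5
        out["Kurtosis"] = m4 / var ** 2
    else:  # constant region: moments undefined, use the 0/0 -> 0 convention
        out["Skewness"] = 0.0
        out["Kurtosis"] = 0.0
    out["Variance"] = var
    return out


# ---------------------------------------------------------------------------
# texture matrices
# ---------------------------------------------------------------------------

# the 13 unique direction vectors of the 26-neighbourhood (half-space)
_OFFSETS_13 = np.array(
    [
        (0, 0, 1), (0, 1, 0), (1, 0, 0),
        (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)


def _shift_slices(shape, off):
    src, dst = [], []
    for dim, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, dim - o))
            dst.append(slice(o, dim))
        else:
            src.append(slice(-o, dim))
            dst.append(slice(0, dim + o))
    return tuple(src), tuple(dst)


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _glcm_single(P: np.ndarray) -> dict[str, float]:
    """Features of one normalized symmetric co-occurrence matrix."""
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())           # == mu_x == mu_y by symmetry
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(k_sum.size)
    np.add.at(p_sum, (I + J).ravel() - 2, P.ravel())
    k_diff = np.arange(0, ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(I - J).ravel(), P.ravel())

    out: dict[str, float] = {}
    out["Autocorrelation"] = float((I * J * P).sum())
    out["JointAverage"] = mu
    out["ClusterProminence"] = float(((I + J - 2 * mu) ** 4 * P).sum())
    out["ClusterShade"] = float(((I + J - 2 * mu) ** 3 * P).sum())
    out["ClusterTendency"] = float(((I + J - 2 * mu) ** 2 * P).sum())
    out["Contrast"] = float(((I - J) ** 2 * P).sum())
    if sigma2 > 0:
        out["Correlation"] = (out["Autocorrelation"] - mu * mu) / sigma2
    else:
        out["Correlation"] = 1.0  # single gray level: perfectly correlated
    da = float((k_diff * p_diff).sum())
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = _entropy2(p_diff)
    out["DifferenceVariance"] = float(((k_diff - da) ** 2 * p_diff).sum())
    out["JointEnergy"] = float((P ** 2).sum())
    hxy = _entropy2(P.ravel())
    out["JointEntropy"] = hxy
    hx = _entropy2(px)
    pxpy = np.outer(px, px)
    nz = (P > 0) & (pxpy > 0)
    hxy1 = float(-(P[nz] * np.log2(pxpy[nz])).sum())
    hxy2 = _entropy2(pxpy.ravel())
    out["Imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    out["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0
    absdiff = np.abs(I - J)
    out["Idm"] = float((P / (1.0 + (I - J) ** 2)).sum())
    out["Idmn"] = float((P / (1.0 + ((I - J) / ng) ** 2)).sum())
    out["Id"] = float((P / (1.0 + absdiff)).sum())
    out["Idn"] = float((P / (1.0 + absdiff / ng)).sum())
    off = absdiff > 0
    out["InverseVariance"] = float((P[off] / absdiff[off] ** 2).sum()) if off.any() else 0.0
    out["MaximumProbability"] = float(P.max())
    out["SumAverage"] = float((k_sum * p_sum).sum())
    out["SumEntropy"] = _entropy2(p_sum)
    out["SumSquares"] = float(((I - mu) ** 2 * P).sum())
    # maximal correlation coefficient
    if ng == 1:
        out["MCC"] = 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            Q = np.einsum("ik,jk->ij", P / np.where(px[:, None] > 0, px[:, None], 1.0),
                          np.where(px[None, :] > 0, P / px[None, :], 0.0))
        Q = np.nan_to_num(Q)
        ev = np.sort(np.abs(np.linalg.eigvals(Q)))[::-1]
        out["MCC"] = float(np.sqrt(max(0.0, ev[1].real))) if ev.size > 1 else 1.0
    return out


def glcm_features(levels: np.ndarray, ng: int) -> dict[str, float]:
    """Gray-level co-occurrence features, distance 1, symmetric, averaged
    over the 13 unique 3-D directions (directions with no admissible voxel
    pair are skipped)."""
    acc: list[dict[str, float]] = []
    for off in _OFFSETS_13:
        src, dst = _shift_slices(levels.shape, off)
        a = levels[src]
        b = levels[dst]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        counts = np.bincount(
            (a[valid] - 1) * ng + (b[valid] - 1), minlength=ng * ng
        ).reshape(ng, ng).astype(np.float64)
        P = counts + counts.T
        P /= P.sum()
        acc.append(_glcm_single(P))
    if not acc:
        return {f: np.nan for f in GLCM_FEATURES}
    return {f: float(np.mean([d[f] for d in acc])) for f in GLCM_FEATURES}


@njit(cache=True)
def _glrlm_counts(levels, ng, dirs, out):  # pragma: no cover - numba kernel
    nz, ny, nx = levels.shape
    for d in range(dirs.shape[0]):
        dz, dy, dx = dirs[d, 0], dirs[d, 1], dirs[d, 2]
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    g = levels[z, y, x]
                    if g == 0:
                        continue
                    pz, py, px = z - dz, y - dy, x - dx
                    if 0 <= pz < nz and 0 <= py < ny and 0 <= px < nx:
                        if levels[pz, py, px] == g:
                            continue  # interior of a run, not its start
                    run = 1
                    cz, cy, cx = z + dz, y + dy, x + dx
                    while 0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx:
                        if levels[cz, cy, cx] != g:
                            break
                        run += 1
                        cz += dz
                        cy += dy
                        cx += dx
                    out[d, g - 1, run - 1] += 1.0


def _rl_style_features(
    g: np.ndarray, s: np.ndarray, c: np.ndarray, n_total: float, np_voxels: int,
    names: tuple[str, ...], size_word: str,
) -> dict[str, float]:
    """Shared feature formulas of the run-length / size-zone families.

    g: gray level per cell, s: run length or zone size, c: cell count,
    n_total: number of runs/zones, np_voxels: in-mask voxel count.
    """
    p = c / n_total
    mu_g = float((p * g).sum())
    mu_s = float((p * s).sum())
    # marginal sums per gray level / per size
    gl_sums: dict[int, float] = {}
    sz_sums: dict[int, float] = {}
    for gi, si, ci in zip(g, s, c):
        gl_sums[gi] = gl_sums.get(gi, 0.0) + ci
        sz_sums[si] = sz_sums.get(si, 0.0) + ci
    gln = sum(v * v for v in gl_sums.values()) / n_total
    szn = sum(v * v for v in sz_sums.values()) / n_total
    short, long_, low, high = ("ShortRun", "LongRun", "LowGrayLevelRun", "HighGrayLevelRun")
    if size_word == "zone":
        short, long_, low, high = ("SmallArea", "LargeArea", "LowGrayLevelZone", "HighGrayLevelZone")
    vals = {
        f"{short}Emphasis": float((p / s ** 2).sum()),
        f"{long_}Emphasis": float((p * s ** 2).sum()),
        "GrayLevelNonUniformity": gln,
        "GrayLevelNonUniformityNormalized": gln / n_total,
        "GrayLevelVariance": float((p * (g - mu_g) ** 2).sum()),
        f"{low}Emphasis": float((p / g ** 2).sum()),
        f"{high}Emphasis": float((p * g ** 2).sum()),
        f"{short}LowGrayLevelEmphasis" if size_word == "zone" else "ShortRunLowGrayLevelEmphasis":
            float((p / (g ** 2 * s ** 2)).sum()),
        f"{short}HighGrayLevelEmphasis" if size_word == "zone" else "ShortRunHighGrayLevelEmphasis":
            float((p * g ** 2 / s ** 2).sum()),
        f"{long_}LowGrayLevelEmphasis" if size_word == "zone" else "LongRunLowGrayLevelEmphasis":
            float((p * s ** 2 / g ** 2).sum()),
        f"{long_}HighGrayLevelEmphasis" if size_word == "zone" else "LongRunHighGrayLevelEmphasis":
            float((p * s ** 2 * g ** 2).sum()),
    }
    if size_word == "run":
        vals["RunLengthNonUniformity"] = szn
        vals["RunLengthNonUniformityNormalized"] = szn / n_total
        vals["RunPercentage"] = n_total / np_voxels
        vals["RunVariance"] = float((p * (s - mu_s) ** 2).sum())
        vals["RunEntropy"] = _entropy2(p)
    else:
        vals["SizeZoneNonUniformity"] = szn
        vals["SizeZoneNonUniformityNormalized"] = szn / n_total
        vals["ZonePercentage"] = n_total / np_voxels
        vals["ZoneVariance"] = float((p * (s - mu_s) ** 2).sum())
        vals["ZoneEntropy"] = _entropy2(p)
    return {name: vals[name] for name in names}


def glrlm_features(levels: np.ndarray, ng: int, np_voxels: int) -> dict[str, float]:
    """Gray-level run-length features averaged over the 13 directions."""
    lmax = max(levels.shape)
    out = np.zeros((_OFFSETS_13.shape[0], ng, lmax))
    _glrlm_counts(levels, ng, _OFFSETS_13, out)
    acc = []
    for d in range(out.shape[0]):
        R = out[d]
        n_runs = R.sum()
        if n_runs == 0:
            continue
        gi, si = np.nonzero(R)
        acc.append(
            _rl_style_features(gi + 1, si + 1.0, R[gi, si], n_runs, np_voxels,
                               GLRLM_FEATURES, "run")
        )
    if not acc:
        return {f: np.nan for f in GLRLM_FEATURES}
    return {f: float(np.mean([d[f] for d in acc])) for f in GLRLM_FEATURES}


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_features(levels: np.ndarray, ng: int, np_voxels: int) -> dict[str, float]:
    """Gray-level size-zone features; zones are 26-connected."""
    gs, ss = [], []
    for g in range(1, ng + 1):
        lab, nlab = ndimage.label(levels == g, structure=_STRUCT26)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        gs.extend([g] * nlab)
        ss.extend(sizes.tolist())
    if not gs:
        return {f: np.nan for f in GLSZM_FEATURES}
    g = np.asarray(gs, dtype=float)
    s = np.asarray(ss, dtype=float)
    # collapse duplicate (g, s) cells so the zone-entropy uses cell probabilities
    key = (g * (s.max() + 1) + s).astype(np.int64)
    uniq, inv = np.unique(key, return_inverse=True)
    c = np.bincount(inv).astype(float)
    gu = np.floor(uniq / (s.max() + 1))
    su = uniq - gu * (s.max() + 1)
    return _rl_style_features(gu, su, c, float(len(gs)), np_voxels, GLSZM_FEATURES, "zone")


def gldm_features(levels: np.ndarray, ng: int) -> dict[str, float]:
    """Gray-level dependence features (distance 1, alpha = 0: a neighbour is
    dependent iff it has the identical discretized level)."""
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in np.vstack([_OFFSETS_13, -_OFFSETS_13]):
        src, dst = _shift_slices(levels.shape, off)
        eq = (levels[src] == levels[dst]) & mask[src] & mask[dst]
        tmp = np.zeros(levels.shape, dtype=bool)
        tmp[dst] = eq
        dep += tmp
    g = levels[mask]
    j = dep[mask] + 1  # dependence size (centre voxel included)
    nd = float(g.size)
    counts = np.bincount((g - 1) * 28 + j, minlength=ng * 28).astype(float)
    idx = np.nonzero(counts)[0]
    gi = idx // 28 + 1
    ji = idx % 28
    c = counts[idx]
    p = c / nd
    mu_g = float((p * gi).sum())
    mu_j = float((p * ji).sum())
    gl_sums = np.bincount(gi.astype(int), weights=c)
    dp_sums = np.bincount(ji.astype(int), weights=c)
    gln = float((gl_sums ** 2).sum()) / nd
    dn = float((dp_sums ** 2).sum()) / nd
    return {
        "SmallDependenceEmphasis": float((p / ji ** 2).sum()),
        "LargeDependenceEmphasis": float((p * ji ** 2).sum()),
        "GrayLevelNonUniformity": gln,
        "DependenceNonUniformity": dn,
        "DependenceNonUniformityNormalized": dn / nd,
        "GrayLevelVariance": float((p * (gi - mu_g) ** 2).sum()),
        "DependenceVariance": float((p * (ji - mu_j) ** 2).sum()),
        "DependenceEntropy": _entropy2(p),
        "LowGrayLevelEmphasis": float((p / gi ** 2).sum()),
        "HighGrayLevelEmphasis": float((p * gi ** 2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (gi ** 2 * ji ** 2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * gi ** 2 / ji ** 2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * ji ** 2 / gi ** 2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * ji ** 2 * gi ** 2).sum()),
    }


def ngtdm_features(levels: np.ndarray, ng: int) -> dict[str, float]:
    """Neighbourhood gray-tone difference features (26-neighbourhood)."""
    mask = levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nsum = ndimage.correlate(np.where(mask, levels, 0).astype(float), kernel, mode="constant")
    ncnt = ndimage.correlate(mask.astype(float), kernel, mode="constant")
    valid = mask & (ncnt > 0)
    g = levels[valid].astype(float)
    nbar = nsum[valid] / ncnt[valid]
    diffs = np.abs(g - nbar)
    n_total = float(valid.sum())
    if n_total == 0:
        return {f: np.nan for f in NGTDM_FEATURES}
    s = np.zeros(ng + 1)
    n = np.zeros(ng + 1)
    np.add.at(s, g.astype(int), diffs)
    np.add.at(n, g.astype(int), 1.0)
    p = n / n_total
    present = np.nonzero(p)[0]
    ngp = present.size
    i = present.astype(float)
    pi, si = p[present], s[present]
    out: dict[str, float] = {}
    den = float((pi * si).sum())
    out["Coarseness"] = 1.0 / den if den > 0 else 1e6
    if ngp > 1:
        ii, jj = np.meshgrid(i, i, indexing="ij")
        ppij = np.outer(pi, pi)
        out["Contrast"] = float(
            (ppij * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * (si.sum() / n_total)
        )
        bus_den = float(np.abs(np.subtract.outer(i * pi, i * pi)).sum())
        out["Busyness"] = den / bus_den if bus_den > 0 else 0.0
        pp_sum = np.add.outer(pi, pi)
        psps = np.add.outer(pi * si, pi * si)
        out["Complexity"] = float((np.abs(ii - jj) * psps / pp_sum).sum() / n_total)
        strength_num = float((pp_sum * (ii - jj) ** 2).sum())
        out["Strength"] = strength_num / si.sum() if si.sum() > 0 else 0.0
    else:
        out["Contrast"] = 0.0
        out["Busyness"] = 0.0
        out["Complexity"] = 0.0
        out["Strength"] = 0.0
    return out


# ---------------------------------------------------------------------------
# extraction driver
# ---------------------------------------------------------------------------


def extract_lesion_features(
    image: LesionImage, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Extract the full feature vector for one lesion.

    Returns an ordered mapping matching :func:`feature_schema` exactly.
    Single-voxel masks are degenerate: shape features are emitted, and the
    intensity/texture features that need at least one voxel pair are NaN.
    """
    config = config or ExtractionConfig()
    if config.resample_spacing is not None:
        image = _resample(image, config.resample_spacing)
    schema = feature_schema(config)
    out = dict.fromkeys(schema, np.nan)

    for name, val in shape_features(image.mask, image.spacing).items():
        out[f"original_shape_{name}"] = val

    mask = image.mask
    np_voxels = int(mask.sum())
    for itype, img in _derived_images(image, config).items():
        vals = img[mask]
        for name, val in firstorder_features(vals, image.voxel_volume, config.bin_width).items():
            out[f"{itype}_firstorder_{name}"] = val
        if np_voxels < 2:
            continue  # texture undefined on a single voxel -> NaN sentinel
        levels, ng = _discretize(img, mask, config.bin_width)
        for name, val in glcm_features(levels, ng).items():
            out[f"{itype}_glcm_{name}"] = val
        for name, val in glrlm_features(levels, ng, np_voxels).items():
            out[f"{itype}_glrlm_{name}"] = val
        for name, val in glszm_features(levels, ng, np_voxels).items():
            out[f"{itype}_glszm_{name}"] = val
        for name, val in gldm_features(levels, ng).items():
            out[f"{itype}_gldm_{name}"] = val
        for name, val in ngtdm_features(levels, ng).items():
            out[f"{itype}_ngtdm_{name}"] = val
    return out


def is_degenerate(image: LesionImage) -> bool:
    """True when the mask cannot support texture features (single voxel)."""
    return int(image.mask.sum()) < 2
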