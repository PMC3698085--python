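"""Feature extraction for all detector types.

Each detector (global blood vessel GBV, global haemorrhage GH, global
microaneurysm GMA, local blood vessel LBV, local background LB, local dark
lesion LDL, local bright lesion LBL) consumes a fixed subset of a common
feature catalogue.  The detector-to-feature map is shipped as data
(``FEATURE_TABLE``) so that individual rows can be toggled per detector
without code changes.

Global detectors score candidate *regions* (connected components with a
surrounding complement); local detectors score 32x32 *tiles*.  The
microaneurysm context model consumes 15x15 patches reduced to 9-symbol
observation sequences: the patch is split into a 3x3 block grid, each block
summarised by (mean shade-corrected intensity, intensity sd, gradient
energy) and vector-quantized against a k-means codebook.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.feature import graycomatrix, graycoprops

from .image_ops import CandidateRegion

__all__ = [
    "FEATURE_TABLE",
    "SCHEMAS",
    "FeatureVector",
    "region_features",
    "tile_features",
    "BlockCodebook",
    "hmm_observation_sequence",
    "feature_names",
]

#: Sentinel replacing any division-by-zero ratio (never NaN).
RATIO_SENTINEL = 1e6

# ---------------------------------------------------------------------------
# Detector / feature matrix, one row per catalogue feature.  True = the
# detector uses the feature.  Transcribed row-for-row from the published
# detector matrix; flip entries here to re-route features per detector.
_DETECTORS = ("GBV", "GH", "GMA", "LBV", "LB", "LDL", "LBL")
FEATURE_TABLE: dict[str, dict[str, bool]] = {
    row: dict(zip(_DETECTORS, flags))
    for row, flags in {
        "green_mean_region":        (1, 1, 1, 1, 0, 0, 0),
        "green_mean_outside":       (1, 1, 1, 0, 0, 0, 0),
        "hsi_mean_region":          (1, 1, 1, 0, 0, 0, 0),
        "hsi_intensity_ratio":      (0, 1, 1, 1, 0, 0, 0),
        "green_ratio":              (1, 1, 1, 0, 0, 0, 0),
        "area":                     (1, 1, 1, 1, 0, 0, 0),
        "perimeter":                (1, 1, 1, 0, 0, 0, 0),
        "bbox_stats":               (1, 0, 0, 0, 0, 0, 0),
        "dimension_ratio":          (1, 0, 0, 0, 0, 0, 0),
        "circularity":              (0, 1, 1, 0, 0, 0, 0),
        "colour_histogram":         (0, 0, 0, 0, 1, 1, 1),
        "fourier_spectra":          (0, 0, 0, 0, 1, 0, 0),
        "colour_pca":               (0, 0, 0, 0, 1, 1, 0),
        "phase_symmetry":           (0, 0, 0, 1, 0, 0, 1),
        "texture":                  (0, 0, 0, 1, 0, 0, 0),
        "shade_corrected_mean":     (0, 0, 0, 1, 0, 0, 0),
        "region_length":            (0, 0, 0, 1, 0, 0, 0),
    }.items()
}

GLOBAL_SCHEMAS = ("GBV", "GH", "GMA")
LOCAL_SCHEMAS = ("LBV", "LB", "LDL", "LBL")
SCHEMAS = GLOBAL_SCHEMAS + LOCAL_SCHEMAS

# number of scalar values each catalogue feature expands to
_FEATURE_WIDTH = {
    "green_mean_region": 1,
    "green_mean_outside": 1,
    "hsi_mean_region": 3,
    "hsi_intensity_ratio": 1,
    "green_ratio": 1,
    "area": 1,
    "perimeter": 1,
    "bbox_stats": 3,
    "dimension_ratio": 1,
    "circularity": 1,
    "colour_histogram": 24,   # 8 bins x 3 channels
    "fourier_spectra": 9,     # low-frequency magnitudes, 3x3 corner
    "colour_pca": 6,          # 3 eigenvalues + first-PC loadings
    "phase_symmetry": 2,      # mean, max response
    "texture": 3,             # GLCM contrast, energy, homogeneity
    "shade_corrected_mean": 1,
    "region_length": 1,
}


def schema_rows(schema_id: str) -> list[str]:
    if schema_id not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_id!r}")
    return [row for row, flags in FEATURE_TABLE.items() if flags[schema_id]]


def feature_names(schema_id: str) -> list[str]:
    names = []
    for row in schema_rows(schema_id):
        width = _FEATURE_WIDTH[row]
        if width == 1:
            names.append(row)
        else:
            names.extend(f"{row}_{i}" for i in range(width))
    return names


@dataclass
class FeatureVector:
    values: np.ndarray
    schema_id: str
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != len(self.names):
            raise ValueError("feature vector length does not match its schema")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


# ---------------------------------------------------------------------------
# colour helpers

def rgb_to_hsi(rgb: np.ndarray) -> np.ndarray:
    """Classic HSI: I=(R+G+B)/3, S=1-min/I, H from the arccos formulation."""
    rgb = np.asarray(rgb, dtype=np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    i = (r + g + b) / 3.0
    mn = np.minimum(np.minimum(r, g), b)
    s = np.where(i > 1e-9, 1.0 - mn / np.maximum(i, 1e-9), 0.0)
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    theta = np.arccos(np.clip(num / np.maximum(den, 1e-9), -1.0, 1.0))
    h = np.where(b <= g, theta, 2.0 * np.pi - theta)
    h = np.where(den < 1e-9, 0.0, h)
    return np.stack([h, s, i], axis=-1)


def _safe_ratio(a: float, b: float) -> float:
    if abs(b) < 1e-12:
        return RATIO_SENTINEL
    return float(a / b)


def _perimeter_px(mask: np.ndarray) -> int:
    """Boundary pixel count: mask pixels with a 4-neighbour outside the mask."""
    er = ndi.binary_erosion(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return int((mask & ~er).sum())


# ---------------------------------------------------------------------------
# global (region) features

def region_features(region: CandidateRegion, img, background_estimate: np.ndarray,
                    schema_id: str, context_margin: int = 6) -> FeatureVector:
    """Feature vector for one candidate region under a global schema.

    The region's complement ("outside") is an annulus ``context_margin``
    pixels wide around the region.  Any ratio whose denominator vanishes is
    set to a sentinel and flagged by value, never NaN.
    """
    if schema_id not in GLOBAL_SCHEMAS:
        raise ValueError(f"{schema_id!r} is not a global-detector schema")
    rgb = img.rgb if hasattr(img, "rgb") else np.asarray(img)
    mask = region.mask
    if mask.sum() == 0:
        raise ValueError("empty region")
    r0, c0, r1, c1 = region.bbox
    pad = context_margin + 1
    rr0, cc0 = max(0, r0 - pad), max(0, c0 - pad)
    rr1, cc1 = min(mask.shape[0], r1 + pad), min(mask.shape[1], c1 + pad)
    sub = mask[rr0:rr1, cc0:cc1]
    sub_rgb = rgb[rr0:rr1, cc0:cc1].astype(np.float64)
    sub_bg = background_estimate[rr0:rr1, cc0:cc1]
    ring = ndi.binary_dilation(sub, iterations=context_margin) & ~sub

    green = sub_rgb[..., 1]
    hsi = rgb_to_hsi(sub_rgb)

    props = measure.regionprops(sub.astype(np.uint8))[0]
    values: list[float] = []
    for row in schema_rows(schema_id):
        if row == "green_mean_region":
            values.append(float(green[sub].mean()))
        elif row == "green_mean_outside":
            values.append(float(green[ring].mean()) if ring.any() else RATIO_SENTINEL)
        elif row == "hsi_mean_region":
            values.extend(float(hsi[..., k][sub].mean()) for k in range(3))
        elif row == "hsi_intensity_ratio":
            inside = float(hsi[..., 2][sub].mean())
            outside = float(hsi[..., 2][ring].mean()) if ring.any() else 0.0
            values.append(_safe_ratio(inside, outside))
        elif row == "green_ratio":
            inside = float(green[sub].mean())
            outside = float(green[ring].mean()) if ring.any() else 0.0
            values.append(_safe_ratio(inside, outside))
        elif row == "area":
            values.append(float(sub.sum()))
        elif row == "perimeter":
            values.append(float(_perimeter_px(sub)))
        elif row == "bbox_stats":
            bh, bw = r1 - r0, c1 - c0
            values.extend([float(bh), float(bw), _safe_ratio(sub.sum(), bh * bw)])
        elif row == "dimension_ratio":
            values.append(_safe_ratio(props.axis_major_length,
                                      max(props.axis_minor_length, 1e-9))
                          if props.axis_minor_length > 1e-9 else RATIO_SENTINEL)
        elif row == "circularity":
            # 4*pi*A/P^2 with the Crofton-style perimeter estimate, which is
            # unbiased on rasterized discs (raw boundary-pixel counts are not)
            per = measure.perimeter(sub, neighborhood=4)
            values.append(_safe_ratio(4.0 * np.pi * sub.sum(), per * per))
        else:  # pragma: no cover - table rows are closed
            raise KeyError(row)
    v = np.asarray(values)
    v[~np.isfinite(v)] = RATIO_SENTINEL
    return FeatureVector(values=v, schema_id=schema_id, names=feature_names(schema_id))


# ---------------------------------------------------------------------------
# local (tile) features

def _phase_symmetry(gray: np.ndarray) -> np.ndarray:
    """Even-symmetry line-feature response.

    Second-derivative (difference-of-offsets) energy over 4 orientations,
    normalised by local amplitude — peaks on ridge/valley structures such as
    vessels and compact lesions, stays near zero on flat or pure-edge tiles.
    """
    g = gray.astype(np.float64)
    responses = []
    for scale in (1, 2):
        for dy, dx in [(0, 1), (1, 0), (1, 1), (1, -1)]:
            sy, sx = dy * scale, dx * scale
            plus = np.roll(np.roll(g, sy, axis=0), sx, axis=1)
            minus = np.roll(np.roll(g, -sy, axis=0), -sx, axis=1)
            even = np.abs(plus + minus - 2.0 * g)   # symmetric (ridge) component
            odd = np.abs(plus - minus)              # antisymmetric (edge) component
            responses.append(np.maximum(even - odd, 0.0))
    resp = np.maximum.reduce(responses)
    resp[:2, :] = resp[-2:, :] = 0.0                # roll wrap-around guard
    resp[:, :2] = resp[:, -2:] = 0.0
    return resp


def tile_features(tile: np.ndarray, schema_id: str,
                  background_tile: np.ndarray | None = None,
                  dark_margin: float = 10.0) -> FeatureVector:
    """Feature vector for one tile under a local schema.

    The tile doubles as its own context: region-style rows in the local
    schemas are computed on the tile's thresholded dark subregion (LBV needs
    structure statistics), with the tile median standing in for the
    background when no background tile is supplied.
    """
    if schema_id not in LOCAL_SCHEMAS:
        raise ValueError(f"{schema_id!r} is not a local-detector schema")
    tile = np.asarray(tile)
    if tile.ndim == 2:
        tile = np.stack([tile] * 3, axis=-1)
    tile = tile.astype(np.float64)
    green = tile[..., 1]
    bg = background_tile.astype(np.float64) if background_tile is not None \
        else np.full_like(green, np.median(green))
    sc = green - bg
    dark = sc < -dark_margin
    hsi = rgb_to_hsi(tile)

    values: list[float] = []
    for row in schema_rows(schema_id):
        if row == "green_mean_region":
            values.append(float(green.mean()))
        elif row == "hsi_intensity_ratio":
            if dark.any() and (~dark).any():
                values.append(_safe_ratio(float(hsi[..., 2][dark].mean()),
                                          float(hsi[..., 2][~dark].mean())))
            else:
                values.append(1.0)
        elif row == "area":
            values.append(float(dark.sum()))
        elif row == "colour_histogram":
            for ch in range(3):
                hist, _ = np.histogram(tile[..., ch], bins=8, range=(0, 256))
                values.extend(hist / tile[..., ch].size)
        elif row == "fourier_spectra":
            spec = np.abs(np.fft.fft2(green - green.mean()))
            values.extend(spec[:3, :3].ravel() / green.size)
        elif row == "colour_pca":
            flat = tile.reshape(-1, 3)
            flat = flat - flat.mean(axis=0)
            if float(np.abs(flat).max()) < 1e-9:
                values.extend([0.0] * 6)   # constant tile: PCA defined as zero
            else:
                cov = flat.T @ flat / flat.shape[0]
                evals, evecs = np.linalg.eigh(cov)
                order = np.argsort(evals)[::-1]
                evals, evecs = evals[order], evecs[:, order]
                lead = evecs[:, 0] * np.sign(evecs[np.argmax(np.abs(evecs[:, 0])), 0])
                values.extend(list(evals) + list(lead))
        elif row == "phase_symmetry":
            resp = _phase_symmetry(green)
            values.extend([float(resp.mean()), float(resp.max())])
        elif row == "texture":
            q = np.clip(green / 32.0, 0, 7).astype(np.uint8)
            glcm = graycomatrix(q, distances=[1],
                                angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                                levels=8, symmetric=True, normed=True)
            values.extend([
                float(graycoprops(glcm, "contrast").mean()),
                float(graycoprops(glcm, "energy").mean()),
                float(graycoprops(glcm, "homogeneity").mean()),
            ])
        elif row == "shade_corrected_mean":
            values.append(float(sc.mean()))
        elif row == "region_length":
            if dark.any():
                lab = measure.label(dark)
                props = max(measure.regionprops(lab), key=lambda p: p.area)
                values.append(float(props.axis_major_length))
            else:
                values.append(0.0)
        else:  # pragma: no cover
            raise KeyError(row)
    v = np.asarray(values)
    v[~np.isfinite(v)] = RATIO_SENTINEL
    return FeatureVector(values=v, schema_id=schema_id, names=feature_names(schema_id))


# ---------------------------------------------------------------------------
# HMM observation sequences

class UnfittedCodebookError(RuntimeError):
    pass


def block_features(patch: np.ndarray, background_patch: np.ndarray | None = None,
                   grid: int = 3) -> np.ndarray:
    """(grid*grid, 3) block descriptors in row-major scan order.

    Per block: mean shade-corrected intensity, intensity sd, gradient energy.
    """
    patch = np.asarray(patch)
    green = patch[..., 1].astype(np.float64) if patch.ndim == 3 else patch.astype(np.float64)
    h, w = green.shape
    if min(h, w) < grid * 3:
        raise ValueError(f"patch {h}x{w} too small for a {grid}x{grid} block grid")
    bg = background_patch.astype(np.float64) if background_patch is not None \
        else np.full_like(green, np.median(green))
    sc = green - bg
    gy, gx = np.gradient(green)
    grad = gy * gy + gx * gx
    rows = np.array_split(np.arange(h), grid)
    cols = np.array_split(np.arange(w), grid)
    out = []
    for rs in rows:
        for cs in cols:
            blk = sc[np.ix_(rs, cs)]
            gblk = grad[np.ix_(rs, cs)]
            out.append([blk.mean(), blk.std(), gblk.mean()])
    return np.asarray(out)


class BlockCodebook:
    """k-means vector quantizer for block descriptors (sklearn-style).

    Parameters
    ----------
    n_symbols : int
        Codebook size (default 16).
    random_state : int
        Seed for k-means initialisation; fixed seed gives a fixed codebook.
    """

    def __init__(self, n_symbols: int = 16, random_state: int = 0, grid: int = 3):
        self.n_symbols = n_symbols
        self.random_state = random_state
        self.grid = grid

    def get_params(self, deep: bool = True) -> dict:
        return {"n_symbols": self.n_symbols, "random_state": self.random_state,
                "grid": self.grid}

    def set_params(self, **params) -> "BlockCodebook":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, blocks: np.ndarray) -> "BlockCodebook":
        """Learn centroids from an (n, 3) array of block descriptors."""
        from sklearn.cluster import KMeans

        blocks = np.asarray(blocks, dtype=np.float64)
        self.scale_ = blocks.std(axis=0)
        self.scale_[self.scale_ < 1e-9] = 1.0
        km = KMeans(n_clusters=min(self.n_symbols, len(blocks)), n_init=4,
                    random_state=self.random_state)
        km.fit(blocks / self.scale_)
        self.centroids_ = km.cluster_centers_ * self.scale_
        return self

    def fit_patches(self, patches: list[np.ndarray]) -> "BlockCodebook":
        blocks = np.concatenate([block_features(p, grid=self.grid) for p in patches])
        return self.fit(blocks)

    def quantize(self, blocks: np.ndarray) -> np.ndarray:
        if not hasattr(self, "centroids_"):
            raise UnfittedCodebookError("codebook not fitted")
        blocks = np.asarray(blocks, dtype=np.float64) / self.scale_
        cent = self.centroids_ / self.scale_
        d = ((blocks[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d, axis=1)

    def to_json(self) -> dict:
        return {"n_symbols": self.n_symbols, "random_state": self.random_state,
                "grid": self.grid, "centroids": self.centroids_.tolist(),
                "scale": self.scale_.tolist()}

    @classmethod
    def from_json(cls, d: dict) -> "BlockCodebook":
        cb = cls(n_symbols=d["n_symbols"], random_state=d["random_state"],
                 grid=d.get("grid", 3))
        cb.centroids_ = np.asarray(d["centroids"])
        cb.scale_ = np.asarray(d["scale"])
        return cb


def hmm_observation_sequence(patch: np.ndarray, codebook: BlockCodebook,
                             background_patch: np.ndarray | None = None) -> np.ndarray:
    """9-symbol observation sequence for one context-model patch."""
    blocks = block_features(patch, background_patch, grid=codebook.grid)
    return codebook.quantize(blocks)
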