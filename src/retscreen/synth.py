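"""Synthetic fundus images with exact ground truth.

Real screening images cannot be redistributed, so every trainable stage in
this package is exercised on simulated retinas that reproduce the signs the
detectors target: a bright optic disc, a darker macula roughly two disc
diameters away, a branching vessel tree rooted at the disc rim, small dark
circular microaneurysms kept off the vessels, larger irregular dark
haemorrhages, bright exudate clusters, background pigment variation and a
multiplicative illumination gradient.  The per-pixel label mask and region
list are recorded *before* the illumination gradient is applied, so
detectors are always scored against physical rather than photometric truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import measure

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "SynthConfig",
    "Region",
    "LabeledFundus",
    "PlacementError",
    "generate_image",
    "sample_subimages",
    "save_labeled_fundus",
    "load_labeled_fundus",
]

#: Categorical label codes used in every label mask.
LABELS = {"BG": 0, "BV": 1, "MA": 2, "HAEM": 3, "BRIGHT": 4, "OD": 5, "MACULA": 6}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

#: Sign classes that count as lesions (their presence makes an image abnormal).
LESION_CLASSES = ("MA", "HAEM", "BRIGHT")

# Green-channel levels before illumination.  Chosen so that the
# class-conditional ordering BRIGHT > BG > {BV, MA, HAEM} holds by
# construction: exudates are well contrasted bright deposits while vessels
# and red lesions share similar dark intensities.
_BG_LEVEL = 120.0
_DARK_DELTA = -38.0       # vessels, MAs, haemorrhages
_BRIGHT_DELTA = 62.0      # exudate clusters
_OD_DELTA = 95.0          # optic disc is the brightest structure
_MACULA_DELTA = -26.0


class PlacementError(RuntimeError):
    """Raised when a requested object cannot be placed; names the class."""

    def __init__(self, cls: str, msg: str = "") -> None:
        self.cls = cls
        super().__init__(f"cannot place object of class {cls!r}: {msg}")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic retina generator.

    All randomness flows from ``rng_seed`` through one explicit generator;
    two calls with the same config are bit-identical.
    """

    image_size: tuple[int, int] = (512, 512)
    # vessel tree
    vessel_depth: int = 5
    vessel_width: float = 5.0
    vessel_width_decay: float = 0.75
    n_trunks: int = 5
    # lesions
    n_ma: int = 0
    ma_radius_range: tuple[float, float] = (1.0, 3.0)
    n_haem: int = 0
    haem_radius_range: tuple[float, float] = (6.0, 12.0)
    n_bright: int = 0
    bright_cluster_radius: float = 9.0
    # anatomy
    od_radius: float | None = None   # default: 8% of min image dim
    # photometry
    illumination_gradient: float = 0.25
    pigment_noise_sd: float = 6.0
    ma_vessel_clearance: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_size) < 64:
            raise ValueError("image_size must be at least 64x64")
        if self.ma_radius_range[1] >= self.haem_radius_range[0]:
            raise ValueError(
                "ma_radius_range max must be < haem_radius_range min: "
                "MAs are small dots, haemorrhages are larger"
            )
        for name in ("n_ma", "n_haem", "n_bright"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.illumination_gradient <= 1.0:
            raise ValueError("illumination_gradient must lie in [0, 1]")

    @property
    def od_radius_px(self) -> float:
        return self.od_radius if self.od_radius is not None else 0.08 * min(self.image_size)


@dataclass
class Region:
    """One connected ground-truth component."""

    cls: str
    centroid: tuple[float, float]          # (row, col)
    bbox: tuple[int, int, int, int]        # (row0, col0, row1, col1) half-open
    mask: np.ndarray                       # boolean, full-image shape

    def to_json(self) -> dict:
        return {
            "class": self.cls,
            "centroid": [float(self.centroid[0]), float(self.centroid[1])],
            "bbox": [int(v) for v in self.bbox],
        }


@dataclass
class LabeledFundus:
    """RGB image plus exhaustive ground truth.

    ``label_mask`` holds mutually exclusive class codes (see ``LABELS``);
    ``regions`` lists each lesion/anatomy component consistent with the mask.
    ``green_pre`` and ``background_truth`` keep the pre-illumination green
    channel and the lesion-free illumination-times-pigment surface so that
    background-estimation accuracy can be scored exactly.
    """

    rgb: np.ndarray                        # H x W x 3 uint8
    label_mask: np.ndarray                 # H x W uint8
    regions: list[Region] = field(default_factory=list)
    od_center: tuple[float, float] | None = None
    od_radius: float | None = None
    macula_center: tuple[float, float] | None = None
    green_pre: np.ndarray | None = None
    background_truth: np.ndarray | None = None
    illumination: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_mask.shape

    def green(self) -> np.ndarray:
        """Green channel as float64 (the working channel for all contrast ops)."""
        return self.rgb[..., 1].astype(np.float64)

    def count(self, cls: str) -> int:
        return sum(1 for r in self.regions if r.cls == cls)

    def is_normal(self) -> bool:
        return all(self.count(c) == 0 for c in LESION_CLASSES)


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = skdraw.disk(center, radius, shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def _draw_vessel_tree(
    shape: tuple[int, int],
    od_center: tuple[float, float],
    od_radius: float,
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recursive midpoint-displaced branching from the OD rim.

    Segment width decays geometrically with branch level, emulating vessels
    that gradually thin with distance from the disc.
    """
    mask = np.zeros(shape, dtype=bool)
    h, w = shape

    def draw_segment(p0: np.ndarray, p1: np.ndarray, width: float) -> None:
        # midpoint displacement for a gently curved segment
        mid = (p0 + p1) / 2.0
        norm = np.array([-(p1 - p0)[1], (p1 - p0)[0]])
        seg_len = float(np.hypot(*(p1 - p0))) + 1e-9
        mid = mid + norm / seg_len * rng.normal(0.0, 0.12 * seg_len)
        pts = [p0, mid, p1]
        for a, b in zip(pts[:-1], pts[1:]):
            rr, cc = skdraw.line(int(round(a[0])), int(round(a[1])),
                                 int(round(b[0])), int(round(b[1])))
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            seg = np.zeros(shape, dtype=bool)
            seg[rr[keep], cc[keep]] = True
            r = max(0, int(round(width / 2.0)) - 0)
            if r > 0:
                seg = ndi.binary_dilation(seg, structure=_disk_struct(r))
            mask[:] |= seg

    def grow(p: np.ndarray, direction: np.ndarray, width: float, depth: int) -> None:
        if depth <= 0 or width < 0.8:
            return
        seg_len = rng.uniform(0.10, 0.16) * min(h, w)
        p1 = p + direction * seg_len
        draw_segment(p, p1, width)
        if not (0 <= p1[0] < h and 0 <= p1[1] < w):
            return
        n_children = 2 if rng.random() < 0.8 else 1
        for _ in range(n_children):
            ang = rng.normal(0.0, 0.5)
            rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            grow(p1, rot @ direction, width * cfg.vessel_width_decay, depth - 1)

    od = np.array(od_center, dtype=float)
    centre = np.array([h / 2.0, w / 2.0])
    for k in range(cfg.n_trunks):
        ang = 2.0 * np.pi * (k + rng.uniform(-0.2, 0.2)) / cfg.n_trunks
        direction = np.array([np.sin(ang), np.cos(ang)])
        # bias trunks away from the image border
        to_centre = centre - od
        to_centre /= np.hypot(*to_centre) + 1e-9
        direction = direction + 0.6 * to_centre
        direction /= np.hypot(*direction) + 1e-9
        start = od + direction * od_radius * 0.9
        grow(start, direction, cfg.vessel_width, cfg.vessel_depth)
    return mask


def _disk_struct(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1), dtype=bool)
    y, x = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    return (y * y + x * x) <= radius * radius


def _place_lesion(
    label: np.ndarray,
    lesion_mask: np.ndarray,
    cls: str,
    forbidden: np.ndarray,
) -> bool:
    """Commit a lesion if it only covers BG pixels and stays clear of
    previously placed structure (keeps components disjoint)."""
    if lesion_mask.sum() == 0:
        return False
    if (forbidden & lesion_mask).any():
        return False
    label[lesion_mask] = LABELS[cls]
    return True


def generate_image(cfg: SynthConfig) -> LabeledFundus:
    """Render one synthetic retina with exact ground truth.

    Raises
    ------
    PlacementError
        If a requested object cannot be placed without colliding with
        existing structure; the error names the failing class.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    h, w = cfg.image_size
    shape = (h, w)
    od_r = cfg.od_radius_px
    if 6.0 * od_r > min(h, w):
        raise PlacementError("OD", f"od_radius {od_r:.1f} too large for image {shape}")

    # --- anatomy ---------------------------------------------------------
    # OD off-centre, macula two OD diameters towards the image centre.
    margin = od_r * 1.3
    for _ in range(200):
        od_center = np.array([
            rng.uniform(h * 0.30, h * 0.70),
            rng.uniform(margin, w - margin),
        ])
        to_centre = np.array([h / 2.0, w / 2.0]) - od_center
        d = np.hypot(*to_centre)
        if d < 1.0:
            continue
        mac_center = od_center + to_centre / d * (4.0 * od_r)
        if margin <= mac_center[0] < h - margin and margin <= mac_center[1] < w - margin:
            break
    else:  # pragma: no cover - practically unreachable at supported sizes
        raise PlacementError("MACULA", "no OD/macula layout fits this image")

    label = np.zeros(shape, dtype=np.uint8)
    od_mask = _disc_mask(shape, tuple(od_center), od_r)
    mac_mask = _disc_mask(shape, tuple(mac_center), od_r * 0.9)
    label[od_mask] = LABELS["OD"]
    label[mac_mask & ~od_mask] = LABELS["MACULA"]

    vessel = _draw_vessel_tree(shape, tuple(od_center), od_r, cfg, rng)
    label[vessel] = LABELS["BV"]  # vessels overwrite OD/macula where they cross

    # --- lesions ---------------------------------------------------------
    # Lesions may only occupy background pixels and must not touch existing
    # structure (2 px clearance) so every ground-truth component stays a
    # distinct connected component.
    sep = _disk_struct(2)
    vessel_clear = ndi.binary_dilation(vessel, _disk_struct(max(cfg.ma_vessel_clearance, 0))) \
        if cfg.ma_vessel_clearance > 0 else vessel

    def forbidden_for(cls: str) -> np.ndarray:
        occ = ndi.binary_dilation(label > 0, sep)
        if cls == "MA":
            occ = occ | vessel_clear
        return occ

    border = int(np.ceil(cfg.haem_radius_range[1])) + 2

    def place_many(cls: str, n: int, build) -> None:
        for _ in range(n):
            occ = forbidden_for(cls)
            ok = False
            for _try in range(400):
                cy = rng.uniform(border, h - border)
                cx = rng.uniform(border, w - border)
                m = build((cy, cx))
                if _place_lesion(label, m, cls, occ):
                    ok = True
                    break
            if not ok:
                raise PlacementError(cls, f"no free site after 400 attempts ({shape})")

    place_many("MA", cfg.n_ma,
               lambda c: _disc_mask(shape, c, rng.uniform(*cfg.ma_radius_range)))

    def build_haem(c):
        # irregular blob: union of displaced discs
        r0 = rng.uniform(*cfg.haem_radius_range)
        m = _disc_mask(shape, c, r0)
        for _ in range(rng.integers(2, 5)):
            off = rng.normal(0.0, r0 * 0.45, size=2)
            m |= _disc_mask(shape, (c[0] + off[0], c[1] + off[1]), r0 * rng.uniform(0.4, 0.8))
        return m

    place_many("HAEM", cfg.n_haem, build_haem)

    def build_bright(c):
        # exudate cluster: several small bright dots around a centre
        m = np.zeros(shape, dtype=bool)
        n_dots = int(rng.integers(3, 8))
        for _ in range(n_dots):
            off = rng.normal(0.0, cfg.bright_cluster_radius * 0.5, size=2)
            m |= _disc_mask(shape, (c[0] + off[0], c[1] + off[1]), rng.uniform(1.2, 3.0))
        # keep the cluster one connected component
        m = ndi.binary_closing(m, _disk_struct(3))
        lab, n = ndi.label(m)
        if n > 1:
            sizes = ndi.sum(m, lab, index=np.arange(1, n + 1))
            m = lab == (1 + int(np.argmax(sizes)))
        return m

    place_many("BRIGHT", cfg.n_bright, build_bright)

    # --- photometry ------------------------------------------------------
    # smoothing a white-noise field shrinks its sd by ~2*sqrt(pi)*sigma, so
    # pre-scale to land near the requested pigment sd after filtering
    pigment = _BG_LEVEL + ndi.gaussian_filter(
        rng.normal(0.0, cfg.pigment_noise_sd * 2.0 * np.sqrt(np.pi) * 12.0, size=shape),
        sigma=12.0,
    )

    green = pigment.copy()
    green[od_mask] += _OD_DELTA
    green[mac_mask & ~od_mask] += _MACULA_DELTA
    green[label == LABELS["BV"]] += _DARK_DELTA
    green[label == LABELS["MA"]] += _DARK_DELTA
    green[label == LABELS["HAEM"]] += _DARK_DELTA
    green[label == LABELS["BRIGHT"]] += _BRIGHT_DELTA
    green += rng.normal(0.0, 1.5, size=shape)          # sensor noise
    green = ndi.gaussian_filter(green, sigma=0.6)      # soften hard edges
    green_pre = np.clip(green, 0.0, 255.0)

    # multiplicative illumination gradient at a random orientation
    ang = rng.uniform(0.0, 2.0 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    g = (np.cos(ang) * (xx / (w - 1) - 0.5) + np.sin(ang) * (yy / (h - 1) - 0.5)) + 0.5
    illum = 1.0 - cfg.illumination_gradient * g
    green_final = np.clip(green_pre * illum, 0.0, 255.0)

    background_truth = np.clip((pigment) * illum, 0.0, 255.0)

    rgb = np.empty((h, w, 3), dtype=np.uint8)
    rgb[..., 0] = np.clip(green_final * 1.35 + 20.0, 0, 255).astype(np.uint8)
    rgb[..., 1] = np.clip(green_final, 0, 255).astype(np.uint8)
    rgb[..., 2] = np.clip(green_final * 0.35, 0, 255).astype(np.uint8)

    # --- ground-truth regions -------------------------------------------
    regions: list[Region] = []
    for cls in ("MA", "HAEM", "BRIGHT", "OD", "MACULA"):
        lab_img, n = ndi.label(label == LABELS[cls])
        for p in measure.regionprops(lab_img):
            r0, c0, r1, c1 = p.bbox
            regions.append(Region(cls=cls, centroid=tuple(p.centroid),
                                  bbox=(r0, c0, r1, c1),
                                  mask=lab_img == p.label))

    return LabeledFundus(
        rgb=rgb,
        label_mask=label,
        regions=regions,
        od_center=tuple(od_center),
        od_radius=od_r,
        macula_center=tuple(mac_center),
        green_pre=green_pre,
        background_truth=background_truth,
        illumination=illum,
    )


@dataclass
class Patch:
    """A square sub-image with its class label and centre pixel."""

    pixels: np.ndarray       # size x size x 3 uint8
    center: tuple[int, int]  # (row, col) in the source image
    cls: str


class SampleShortfall(UserWarning):
    """Fewer valid patch centres than requested."""


def sample_subimages(
    img: LabeledFundus,
    cls: str,
    size: int = 15,
    n: int = 0,
    seed: int = 0,
) -> list[Patch]:
    """Sample ``n`` square patches centred on pixels of class ``cls``.

    Lesion patches are drawn one per connected component first (component
    centroids), then additional random in-class pixels; background/vessel
    patches are random in-class pixels.  If fewer than ``n`` valid centres
    exist, all available are returned and a :class:`SampleShortfall` warning
    is emitted.
    """
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    half = size // 2
    h, w = img.shape
    code = LABELS[cls]
    valid = np.zeros(img.shape, dtype=bool)
    valid[half:h - half, half:w - half] = True
    candidates = np.argwhere((img.label_mask == code) & valid)
    if len(candidates) == 0:
        warnings.warn(f"no valid centres for class {cls}", SampleShortfall)
        return []

    centers: list[tuple[int, int]] = []
    if cls in LESION_CLASSES:
        for r in img.regions:
            if r.cls != cls:
                continue
            cy, cx = int(round(r.centroid[0])), int(round(r.centroid[1]))
            if half <= cy < h - half and half <= cx < w - half and len(centers) < n:
                centers.append((cy, cx))
    n_extra = n - len(centers)
    if n_extra > 0:
        idx = rng.choice(len(candidates), size=min(n_extra, len(candidates)), replace=False)
        centers.extend((int(r), int(c)) for r, c in candidates[idx])
    centers = centers[:n]
    if len(centers) < n:
        warnings.warn(
            f"requested {n} patches of class {cls}, only {len(centers)} valid centres",
            SampleShortfall,
        )
    return [
        Patch(pixels=img.rgb[cy - half:cy - half + size, cx - half:cx - half + size].copy(),
              center=(cy, cx), cls=cls)
        for cy, cx in centers
    ]


# --- synthetic sequence task for the context-model experiments -----------

def synthetic_context_models(separation: float = 0.35, n_symbols: int = 16,
                             n_states: int = 3, seed: int = 0) -> dict:
    """Three generating HMMs (MA, BV, BG) with controllable class overlap.

    Each class's emission rows are biased toward its own band of codebook
    symbols; ``separation`` scales the bias (0 = indistinguishable classes,
    ~1 = nearly disjoint symbol usage).  Used to reproduce the shape of the
    context-model experiments without real sub-images.
    """
    from .hmm import DiscreteHMM

    rng = np.random.default_rng(seed)
    models = {}
    band_width = max(2, n_symbols // 4)
    for i, cls in enumerate(("MA", "BV", "BG")):
        A = rng.dirichlet(np.ones(n_states) * 2.0, size=n_states)
        B = rng.dirichlet(np.ones(n_symbols) * 0.6, size=n_states)
        band = np.zeros(n_symbols)
        lo = (i * band_width) % n_symbols
        band[lo:lo + band_width + 1] = separation * 3.0
        B = B + band[None, :]
        B = B / B.sum(axis=1, keepdims=True)
        pi = rng.dirichlet(np.ones(n_states))
        models[cls] = DiscreteHMM.from_params(pi, A, B)
    return models


def synthetic_sequence_data(models: dict, n_train_per_class: int,
                            n_eval_total: int, seed: int = 0, length: int = 9):
    """Sample train/eval observation sequences from per-class generators.

    Returns ``(train: {class: (n, length)}, eval_X, eval_y)`` with the
    evaluation set balanced across classes.
    """
    rng = np.random.default_rng(seed)
    train = {c: m.sample(n_train_per_class, length, rng) for c, m in models.items()}
    per = n_eval_total // len(models)
    Xe, ye = [], []
    for c, m in models.items():
        Xe.append(m.sample(per, length, rng))
        ye.extend([c] * per)
    return train, np.concatenate(Xe), np.asarray(ye)


# --- serialization -------------------------------------------------------

def save_labeled_fundus(img: LabeledFundus, stem: str | Path) -> None:
    """Write image + label mask as PNG and the region list as JSON."""
    import imageio.v3 as iio

    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(stem.with_suffix(".png"), img.rgb)
    iio.imwrite(stem.parent / (stem.name + "_labels.png"), img.label_mask)
    meta = {
        "od_center": list(img.od_center) if img.od_center else None,
        "od_radius": img.od_radius,
        "macula_center": list(img.macula_center) if img.macula_center else None,
        "regions": [r.to_json() for r in img.regions],
    }
    (stem.parent / (stem.name + "_regions.json")).write_text(json.dumps(meta, indent=1))


def load_labeled_fundus(stem: str | Path) -> LabeledFundus:
    """Read back the PNG/PNG/JSON triplet written by :func:`save_labeled_fundus`."""
    import imageio.v3 as iio

    stem = Path(stem)
    rgb = iio.imread(stem.with_suffix(".png"))
    label = iio.imread(stem.parent / (stem.name + "_labels.png")).astype(np.uint8)
    meta = json.loads((stem.parent / (stem.name + "_regions.json")).read_text())
    regions = []
    for rj in meta["regions"]:
        lab_img, _ = ndi.label(label == LABELS[rj["class"]])
        cy, cx = int(round(rj["centroid"][0])), int(round(rj["centroid"][1]))
        comp = lab_img[min(cy, label.shape[0] - 1), min(cx, label.shape[1] - 1)]
        mask = lab_img == comp if comp > 0 else label == -1
        regions.append(Region(cls=rj["class"], centroid=tuple(rj["centroid"]),
                              bbox=tuple(rj["bbox"]), mask=mask))
    return LabeledFundus(
        rgb=rgb,
        label_mask=label,
        regions=regions,
        od_center=tuple(meta["od_center"]) if meta["od_center"] else None,
        od_radius=meta["od_radius"],
        macula_center=tuple(meta["macula_center"]) if meta["macula_center"] else None,
    )
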