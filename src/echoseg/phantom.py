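"""Synthetic speckled neck-cross-section phantoms.

Generates 2-D grayscale "ultrasound-like" frames with 6-class integer label
maps (background, thyroid, trachea, NoV, esophagus, carotid) and ordered
multi-frame sweeps cut from 3-D ellipsoids, so the segmentation, training and
reconstruction code can be exercised end to end without clinical data.

The image model is deliberately simple, not anatomical: a piecewise-constant
echogenicity map derived from the label map, multiplied by i.i.d. mean-1
gamma speckle (the fully-developed-speckle approximation) and blurred by a
Gaussian point-spread function.  Geometry mimics a transverse neck section
qualitatively: a bright wide thyroid ellipse, a dark tracheal disc with a
bright air-interface rim, 1–3 hypoechoic nodule-or-vessel (NoV) ellipses
carved strictly inside the thyroid, a small esophagus disc beside the
trachea, and a dark carotid disc lateral to the thyroid.

Label semantics: the NoV class only ever occupies pixels that would be
thyroid if NoV were absent; later-drawn structures overwrite earlier ones in
the fixed order background → thyroid → NoV → trachea → esophagus → carotid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

CLASS_NAMES = ("background", "thyroid", "trachea", "NoV", "esophagus", "carotid")
NUM_CLASSES = len(CLASS_NAMES)
BACKGROUND, THYROID, TRACHEA, NOV, ESOPHAGUS, CAROTID = range(NUM_CLASSES)
#: z-stack rendering priority (later overwrites earlier)
DRAW_ORDER = (THYROID, NOV, TRACHEA, ESOPHAGUS, CAROTID)

#: display palette: red carotid, blue trachea, green thyroid, yellow NoV, purple esophagus
CLASS_COLORS = {
    "background": (0, 0, 0),
    "thyroid": (0, 200, 0),
    "trachea": (0, 80, 255),
    "NoV": (255, 220, 0),
    "esophagus": (160, 32, 240),
    "carotid": (255, 0, 0),
}


class PhantomConfigError(ValueError):
    """Raised when requested geometry cannot fit in the image."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the 2-D phantom.

    Geometry ranges are in unit coordinates (fractions of ``image_size``) so
    one spec scales to any resolution.  ``speckle_shape`` is the gamma shape
    ``k`` of the multiplicative noise (variance ``1/k``); ``None`` or
    ``inf`` disables speckle.  ``psf_sigma`` is in pixels.
    """

    image_size: int = 256
    echogenicity: dict[str, float] = field(
        default_factory=lambda: {
            "background": 0.30,
            "thyroid": 0.62,
            "trachea": 0.06,
            "NoV": 0.40,
            "esophagus": 0.45,
            "carotid": 0.10,
        }
    )
    rim_echogenicity: float = 0.90  # bright air interface ring around the trachea
    rim_width_px: int = 2
    speckle_shape: float | None = 3.0
    psf_sigma: float = 1.0
    thyroid_center: tuple = ((0.46, 0.54), (0.36, 0.44))  # (x range, y range)
    thyroid_axes: tuple = ((0.28, 0.34), (0.13, 0.17))
    trachea_center: tuple = ((0.47, 0.53), (0.59, 0.65))
    trachea_radius: tuple = (0.075, 0.10)
    nov_count: tuple = (1, 3)
    nov_axes: tuple = (0.030, 0.060)
    esophagus_radius: tuple = (0.028, 0.042)
    carotid_radius: tuple = (0.050, 0.070)

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise PhantomConfigError("image_size must be at least 16")
        if set(self.echogenicity) != set(CLASS_NAMES):
            raise PhantomConfigError("echogenicity must name exactly the 6 classes")
        for name, v in self.echogenicity.items():
            if not 0.0 <= v <= 1.0:
                raise PhantomConfigError(f"echogenicity[{name}]={v} outside [0, 1]")
        for lo, hi in (
            *self.thyroid_axes,
            self.trachea_radius,
            (self.nov_axes if isinstance(self.nov_axes[0], float) else self.nov_axes[0]),
            self.esophagus_radius,
            self.carotid_radius,
        ):
            if not 0 < lo <= hi:
                raise PhantomConfigError("geometry ranges must be positive and ordered")
            if hi >= 0.5:
                raise PhantomConfigError(
                    "structure radius must be smaller than half the image size"
                )


def check_label_map(labels: np.ndarray, num_classes: int = NUM_CLASSES) -> np.ndarray:
    """Validate a label map: 2-D integer array with entries in range."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label map must be 2-D")
    if labels.size and (labels.min() < 0 or labels.max() >= num_classes):
        raise ValueError(f"labels outside [0, {num_classes})")
    return labels


def _ellipse_mask(size: int, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    """Pixel-center point-in-ellipse test on a ``size``×``size`` grid."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def _u(rng: np.random.Generator, lo_hi: tuple) -> float:
    lo, hi = lo_hi
    return float(rng.uniform(lo, hi))


def _sample_geometry(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    """Sample one cross-section layout; all values in pixels."""
    s = spec.image_size
    thy_cx, thy_cy = _u(rng, spec.thyroid_center[0]) * s, _u(rng, spec.thyroid_center[1]) * s
    thy_ax, thy_ay = _u(rng, spec.thyroid_axes[0]) * s, _u(rng, spec.thyroid_axes[1]) * s
    tra_cx, tra_cy = _u(rng, spec.trachea_center[0]) * s, _u(rng, spec.trachea_center[1]) * s
    tra_r = _u(rng, spec.trachea_radius) * s
    eso_r = _u(rng, spec.esophagus_radius) * s
    # esophagus sits against the lower-left of the trachea
    eso_cx = tra_cx - (tra_r + eso_r + 0.01 * s)
    eso_cy = tra_cy + 0.4 * tra_r
    car_r = _u(rng, spec.carotid_radius) * s
    side = 1 if rng.uniform() < 0.5 else -1
    car_cx = thy_cx + side * (thy_ax + car_r + 0.02 * s)
    car_cy = thy_cy + rng.uniform(-0.05, 0.05) * s
    car_cx = float(np.clip(car_cx, car_r + 1, s - car_r - 2))
    geom = {
        "thyroid": (thy_cx, thy_cy, thy_ax, thy_ay),
        "trachea": (tra_cx, tra_cy, tra_r, tra_r),
        "esophagus": (eso_cx, eso_cy, eso_r, eso_r),
        "carotid": (car_cx, car_cy, car_r, car_r),
    }
    for name, (cx, cy, ax, ay) in geom.items():
        if max(ax, ay) >= s / 2:
            raise PhantomConfigError(f"{name} radius {max(ax, ay):.1f}px >= half image size")
    return geom


def _sample_nov(
    spec: PhantomSpec,
    rng: np.random.Generator,
    thyroid_mask: np.ndarray,
    forbidden: np.ndarray,
) -> np.ndarray:
    """NoV ellipses strictly inside the thyroid and clear of later structures."""
    s = spec.image_size
    n = int(rng.integers(spec.nov_count[0], spec.nov_count[1] + 1))
    allowed = thyroid_mask & ~forbidden
    ys, xs = np.nonzero(allowed)
    nov = np.zeros_like(thyroid_mask)
    placed = 0
    for _ in range(200):
        if placed >= n:
            break
        i = int(rng.integers(len(xs)))
        cx, cy = float(xs[i]), float(ys[i])
        ax = _u(rng, spec.nov_axes) * s
        ay = _u(rng, spec.nov_axes) * s
        cand = _ellipse_mask(s, cx, cy, ax, ay)
        if cand.sum() == 0 or not (cand <= allowed).all():
            continue
        nov |= cand
        placed += 1
    if placed == 0:
        # guaranteed fallback: a small disc at the thyroid pixel farthest
        # from the forbidden region
        from scipy.ndimage import distance_transform_edt

        dist = distance_transform_edt(allowed)
        cy, cx = np.unravel_index(int(dist.argmax()), dist.shape)
        r = max(1.0, min(dist[cy, cx] - 1.0, spec.nov_axes[1] * s))
        nov = _ellipse_mask(s, float(cx), float(cy), r, r) & allowed
    return nov


def sample_label_map(
    spec: PhantomSpec, rng: np.random.Generator, return_masks: bool = False
):
    """Draw one random 6-class label map; every class occupies ≥ 1 pixel.

    With ``return_masks`` the per-structure boolean masks (before the
    draw-order overwrite) are returned alongside the map.
    """
    s = spec.image_size
    for _ in range(20):
        geom = _sample_geometry(spec, rng)
        masks = {
            name: _ellipse_mask(s, *geom[name])
            for name in ("thyroid", "trachea", "esophagus", "carotid")
        }
        forbidden = masks["trachea"] | masks["esophagus"] | masks["carotid"]
        masks["NoV"] = _sample_nov(spec, rng, masks["thyroid"], forbidden)
        labels = np.zeros((s, s), dtype=np.uint8)
        paint = {
            THYROID: masks["thyroid"],
            NOV: masks["NoV"],
            TRACHEA: masks["trachea"],
            ESOPHAGUS: masks["esophagus"],
            CAROTID: masks["carotid"],
        }
        for cls in DRAW_ORDER:
            labels[paint[cls]] = cls
        if len(np.unique(labels)) == NUM_CLASSES:
            return (labels, masks) if return_masks else labels
    raise PhantomConfigError("could not place all 6 classes; geometry ranges too tight")


def reflectivity_map(labels: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Piecewise-constant echogenicity as a function of the label map.

    Adds the bright tracheal air-interface rim: the ring of non-trachea
    pixels within ``rim_width_px`` of the trachea, derived from the labels
    by binary dilation, so the map remains a pure function of the labels.
    """
    labels = check_label_map(labels)
    lut = np.array([spec.echogenicity[name] for name in CLASS_NAMES], dtype=np.float64)
    refl = lut[labels]
    if spec.rim_width_px > 0:
        from scipy.ndimage import binary_dilation

        tra = labels == TRACHEA
        if tra.any():
            ring = binary_dilation(tra, iterations=spec.rim_width_px) & ~tra
            refl[ring] = spec.rim_echogenicity
    return refl


def speckle_field(shape: tuple, speckle_shape: float | None, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. multiplicative gamma noise with mean 1 and variance 1/k."""
    if speckle_shape is None or not np.isfinite(speckle_shape):
        return np.ones(shape)
    if speckle_shape <= 0:
        raise PhantomConfigError("speckle_shape must be positive")
    return rng.gamma(speckle_shape, 1.0 / speckle_shape, size=shape)


def render_image(labels: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """blur(reflectivity(labels) × speckle), clipped to [0, 1]."""
    refl = reflectivity_map(labels, spec)
    img = refl * speckle_field(refl.shape, spec.speckle_shape, rng)
    if spec.psf_sigma > 0:
        img = gaussian_filter(img, spec.psf_sigma)
    return np.clip(img, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """One (image, label map) pair; bit-identical for identical (spec, seed)."""
    rng = np.random.default_rng(seed)
    labels = sample_label_map(spec, rng)
    image = render_image(labels, spec, rng)
    return image, labels


def generate_dataset(
    spec: PhantomSpec, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stack of ``n`` independent phantoms seeded from ``seed``."""
    images, labels = [], []
    for k in range(n):
        img, lab = generate_phantom(spec, seed * 100003 + k)
        images.append(img)
        labels.append(lab)
    return np.stack(images), np.stack(labels)


# ---------------------------------------------------------------------------
# sweeps: ordered frame sequences cut from 3-D ellipsoids


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center (x, y in px; z in length units)."""

    class_index: int
    center: tuple[float, float, float]  # (x, y, z)
    semi_axes: tuple[float, float, float]  # (a_x px, b_y px, c_z units)

    def cross_section(self, z: float) -> tuple[float, float, float, float] | None:
        cx, cy, cz = self.center
        a, b, c = self.semi_axes
        t = (z - cz) / c
        if abs(t) >= 1.0:
            return None
        scale = float(np.sqrt(1.0 - t * t))
        return cx, cy, a * scale, b * scale


@dataclass(frozen=True)
class SweepSpec:
    """An ordered stack of frames sampled at uniform z spacing from z=0."""

    n_frames: int
    slice_spacing: float
    structures: tuple[Ellipsoid, ...]

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("a sweep needs at least 2 frames")
        if self.slice_spacing <= 0:
            raise ValueError("slice spacing must be positive")

    @property
    def z_positions(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.slice_spacing


def default_sweep_spec(
    phantom_spec: PhantomSpec, n_frames: int = 64, slice_spacing: float = 1.0
) -> SweepSpec:
    """A neck-like sweep layout scaled to the phantom image size.

    Structures are ellipsoids spanning most of the z range; the trachea and
    carotid are elongated tubes, the NoV ellipsoid is strictly inside the
    thyroid ellipsoid.
    """
    s = phantom_spec.image_size
    z_mid = (n_frames - 1) * slice_spacing / 2.0
    z_len = n_frames * slice_spacing
    structures = (
        Ellipsoid(THYROID, (0.50 * s, 0.40 * s, z_mid), (0.31 * s, 0.15 * s, 0.46 * z_len)),
        Ellipsoid(NOV, (0.58 * s, 0.40 * s, z_mid), (0.05 * s, 0.05 * s, 0.18 * z_len)),
        Ellipsoid(TRACHEA, (0.50 * s, 0.62 * s, z_mid), (0.085 * s, 0.085 * s, 0.60 * z_len)),
        Ellipsoid(ESOPHAGUS, (0.38 * s, 0.66 * s, z_mid), (0.035 * s, 0.035 * s, 0.50 * z_len)),
        Ellipsoid(CAROTID, (0.87 * s, 0.40 * s, z_mid), (0.06 * s, 0.06 * s, 0.60 * z_len)),
    )
    return SweepSpec(n_frames=n_frames, slice_spacing=slice_spacing, structures=structures)


def sweep_label_frames(spec: SweepSpec, image_size: int) -> list[np.ndarray]:
    """Per-frame label maps: each frame is the z cross-section of the ellipsoids."""
    order = {cls: rank for rank, cls in enumerate(DRAW_ORDER)}
    structures = sorted(
        spec.structures, key=lambda e: order.get(e.class_index, len(order))
    )
    seen = {e.class_index: False for e in spec.structures}
    frames = []
    for z in spec.z_positions:
        labels = np.zeros((image_size, image_size), dtype=np.uint8)
        for ell in structures:
            sec = ell.cross_section(float(z))
            if sec is None:
                continue
            mask = _ellipse_mask(image_size, *sec)
            if mask.any():
                labels[mask] = ell.class_index
                seen[ell.class_index] = True
        frames.append(labels)
    for cls, hit in seen.items():
        if not hit:
            logger.warning(
                "structure of class %s lies outside the sampled z range", CLASS_NAMES[cls]
            )
    return frames


def generate_sweep(
    spec: SweepSpec, phantom_spec: PhantomSpec, seed: int
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Ordered (frames, label_frames) of a sweep; deterministic given seed."""
    label_frames = sweep_label_frames(spec, phantom_spec.image_size)
    rng = np.random.default_rng(seed)
    frames = [render_image(lab, phantom_spec, rng) for lab in label_frames]
    return frames, label_frames


# ---------------------------------------------------------------------------
# file output


def save_image_png(image: np.ndarray, path) -> None:
    """8-bit grayscale PNG of an image in [0, 1]."""
    arr = np.clip(np.round(np.asarray(image) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def save_labels_png(labels: np.ndarray, path) -> None:
    """8-bit indexed PNG with the class display palette."""
    labels = check_label_map(labels).astype(np.uint8)
    im = Image.fromarray(labels, mode="P")
    palette = []
    for name in CLASS_NAMES:
        palette.extend(CLASS_COLORS[name])
    palette.extend([0] * (768 - len(palette)))
    im.putpalette(palette)
    im.save(path)


def load_labels_png(path) -> np.ndarray:
    im = Image.open(path)
    return np.asarray(im, dtype=np.uint8)


def load_image_png(path) -> np.ndarray:
    im = Image.open(path).convert("L")
    return np.asarray(im, dtype=np.float64) / 255.0


def scaled_spec(spec: PhantomSpec, image_size: int) -> PhantomSpec:
    """Same layout at a different resolution."""
    return replace(spec, image_size=image_size)
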