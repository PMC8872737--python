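"""Synthetic plate images and size-based bead/cell detection.

The dispensing robot carries a wide-field, low-resolution camera whose only
job is to find the marker beads (10/20/30 µm polystyrene, symbols A/T/C) and
cells on the porous membrane filter and report their coordinates, accurate
to about a pixel, for later robotic pickup.  The porous membrane itself
shows up as a dense pattern of small (≤5 µm) dark-ish pores that must be
removed before objects are measured.

This module renders such images synthetically (anti-aliased disks over a
pore background plus noise), removes the pore pattern, detects and
size-classifies objects, and registers coordinates relative to the first
marker bead in dispensing order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import filters, measure

#: Default diameter bands (µm) used to call marker classes from measured
#: equivalent diameters.  Real cells overlap the 20/30 µm bead sizes; bands
#: are per-experiment configuration, these defaults suit synthetic fixtures
#: with separable sizes.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "marker_A": (7.0, 14.0),
    "cell": (14.0, 19.0),
    "marker_T": (19.0, 25.0),
    "marker_C": (26.0, 36.0),
}

MARKER_CLASSES = ("marker_A", "marker_T", "marker_C")
SIZE_TO_CLASS = {10.0: "marker_A", 20.0: "marker_T", 30.0: "marker_C"}

_BACKGROUND = 0.08
_PORE_INTENSITY = 0.38
_OBJECT_INTENSITY = 1.0


@dataclass
class PlateImage:
    """Grayscale plate image with micron pixel calibration.

    Pixel (row, col) has its centre at physical position
    ``x = (col + 0.5) * pixel_size``, ``y = (row + 0.5) * pixel_size`` µm.
    """

    pixels: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("plate image must be 2D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")

    def save(self, path, sidecar: bool = True) -> None:
        """Write TIFF/PNG; pixel calibration goes to a JSON sidecar."""
        path = str(path)
        arr = np.clip(self.pixels, 0, 1)
        if path.lower().endswith((".tif", ".tiff")):
            import tifffile

            tifffile.imwrite(path, arr.astype(np.float32))
        else:
            import imageio.v3 as iio

            iio.imwrite(path, (arr * 65535).astype(np.uint16))
        if sidecar:
            with open(path + ".json", "w") as fh:
                json.dump({"pixel_size_um": self.pixel_size, "origin": list(self.origin)}, fh)

    @classmethod
    def load(cls, path) -> "PlateImage":
        path = str(path)
        if path.lower().endswith((".tif", ".tiff")):
            import tifffile

            arr = np.asarray(tifffile.imread(path), dtype=float)
        else:
            import imageio.v3 as iio

            arr = np.asarray(iio.imread(path), dtype=float)
            if arr.dtype != float or arr.max() > 1.5:
                arr = arr / 65535.0
        with open(path + ".json") as fh:
            meta = json.load(fh)
        return cls(arr, meta["pixel_size_um"], tuple(meta.get("origin", (0.0, 0.0))))


@dataclass
class DetectedObject:
    centroid: tuple[float, float]  # (x, y) µm
    equivalent_diameter: float  # µm
    object_class: str = "unknown"

    def __post_init__(self):
        if not self.equivalent_diameter > 0:
            raise ValueError("diameter must be positive")


@dataclass
class PlateGroundTruth:
    """True layout used to synthesise an image."""

    centroids: list[tuple[float, float]]
    diameters: list[float]
    classes: list[str]

    def __post_init__(self):
        if not len(self.centroids) == len(self.diameters) == len(self.classes):
            raise ValueError("ground-truth arrays differ in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": [c[0] for c in self.centroids],
                "y_um": [c[1] for c in self.centroids],
                "diameter_um": self.diameters,
                "object_class": self.classes,
            }
        )


def _render_disks(img: np.ndarray, centers_px: np.ndarray, radii_px: np.ndarray,
                  intensity: float) -> None:
    """Accumulate anti-aliased disks (smooth 1-px edge) into ``img``."""
    h, w = img.shape
    for (cy, cx), r in zip(centers_px, radii_px):
        y0, y1 = max(0, int(cy - r - 2)), min(h, int(cy + r + 3))
        x0, x1 = max(0, int(cx - r - 2)), min(w, int(cx + r + 3))
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(yy + 0.5 - cy, xx + 0.5 - cx)
        cover = np.clip(r - d + 0.5, 0.0, 1.0)  # linear edge over one pixel
        patch = img[y0:y1, x0:x1]
        np.maximum(patch, _BACKGROUND + (intensity - _BACKGROUND) * cover, out=patch)


def synth_plate(
    layout: list[tuple[tuple[float, float], float, str]],
    pore_density: float = 200.0,  # pores per mm^2
    pore_diameter: float = 4.0,  # µm
    noise_sd: float = 0.02,
    pixel_size: float = 2.5,
    shape_um: tuple[float, float] | None = None,
    seed: int | None = None,
    allow_overlap: bool = False,
) -> tuple[PlateImage, PlateGroundTruth]:
    """Render a synthetic plate image and return it with its ground truth.

    ``layout`` entries are ``((x_um, y_um), diameter_um, object_class)``.
    Objects are bright anti-aliased disks on a background of dimmer pore
    disks placed at Poisson-random positions, plus additive Gaussian noise.
    Overlapping layout objects are rejected unless ``allow_overlap`` (for
    doublet fixtures).
    """
    rng = np.random.default_rng(seed)
    if pore_density < 0 or pore_diameter < 0 or noise_sd < 0 or pixel_size <= 0:
        raise ValueError("negative image-synthesis parameter")
    for (_, d, _) in layout:
        if d <= pixel_size:
            raise ValueError(f"object diameter {d} µm not resolvable at {pixel_size} µm/px")
    if not allow_overlap and len(layout) > 1:
        pts = np.array([c for c, _, _ in layout], dtype=float)
        rad = np.array([d / 2 for _, d, _ in layout])
        dist = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        rsum = rad[:, None] + rad[None, :]
        close = (dist < rsum) & ~np.eye(len(layout), dtype=bool)
        if np.any(close):
            raise ValueError("layout contains overlapping objects")

    if shape_um is None:
        if layout:
            xs = [c[0] for c, _, _ in layout]
            ys = [c[1] for c, _, _ in layout]
            margin = max(d for _, d, _ in layout)
            shape_um = (max(ys) + margin + 50.0, max(xs) + margin + 50.0)
        else:
            shape_um = (250.0, 250.0)
    h = int(round(shape_um[0] / pixel_size))
    w = int(round(shape_um[1] / pixel_size))
    img = np.full((h, w), _BACKGROUND)

    area_mm2 = (h * pixel_size) * (w * pixel_size) / 1e6
    n_pores = rng.poisson(pore_density * area_mm2)
    if n_pores and pore_diameter > 0:
        centers = np.column_stack(
            [rng.uniform(0, h, n_pores), rng.uniform(0, w, n_pores)]
        )
        radii = np.full(n_pores, pore_diameter / 2 / pixel_size)
        _render_disks(img, centers, radii, _PORE_INTENSITY)

    if layout:
        centers = np.array([(c[1] / pixel_size, c[0] / pixel_size) for c, _, _ in layout])
        radii = np.array([d / 2 / pixel_size for _, d, _ in layout])
        _render_disks(img, centers, radii, _OBJECT_INTENSITY)

    if noise_sd:
        img = img + rng.normal(0.0, noise_sd, img.shape)

    truth = PlateGroundTruth(
        centroids=[tuple(map(float, c)) for c, _, _ in layout],
        diameters=[float(d) for _, d, _ in layout],
        classes=[cls for _, _, cls in layout],
    )
    return PlateImage(img, pixel_size), truth


def remove_pores(
    image: PlateImage,
    max_pore_diameter: float = 8.0,
    threshold: str | float = "otsu",
    blur_sigma: float = 0.5,
) -> np.ndarray:
    """Foreground mask with all pore-sized components removed.

    The image is lightly blurred, thresholded (global Otsu by default, or a
    fixed intensity), and every connected component whose equivalent
    diameter is at most ``max_pore_diameter`` µm is erased.  The cutoff must
    stay below the smallest object of interest (10 µm beads).
    """
    if max_pore_diameter >= 10.0:
        raise ValueError("max_pore_diameter must be below the 10 µm bead size")
    img = filters.gaussian(image.pixels, sigma=blur_sigma) if blur_sigma else image.pixels
    if threshold == "otsu":
        thr = filters.threshold_otsu(img)
    else:
        thr = float(threshold)
    mask = img > thr
    if max_pore_diameter <= 0:
        return mask
    max_area_px = np.pi * (max_pore_diameter / 2.0) ** 2 / image.pixel_size**2
    labels = measure.label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    keep = areas > max_area_px
    keep[0] = False
    return keep[labels]


def detect_objects(
    mask: np.ndarray,
    pixel_size: float,
    intensity_image: np.ndarray | None = None,
) -> list[DetectedObject]:
    """One object per connected component of the mask.

    Centroids are intensity-weighted when an intensity image is supplied,
    otherwise plain mask centroids; reported in µm with the pixel-centre
    convention.  Equivalent diameter is that of the equal-area circle.
    """
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    objects = []
    for region in measure.regionprops(labels, intensity_image=intensity_image):
        cy, cx = (
            region.centroid_weighted if intensity_image is not None else region.centroid
        )
        objects.append(
            DetectedObject(
                centroid=((cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size),
                equivalent_diameter=float(region.equivalent_diameter_area) * pixel_size,
            )
        )
    return objects


def classify_by_size(
    objects: list[DetectedObject],
    bands: dict[str, tuple[float, float]] | None = None,
) -> list[DetectedObject]:
    """Assign classes by diameter band membership; outside all bands -> unknown."""
    bands = bands if bands is not None else DEFAULT_BANDS
    items = sorted(bands.items(), key=lambda kv: kv[1][0])
    for (name1, (lo1, hi1)), (name2, (lo2, hi2)) in zip(items, items[1:]):
        if hi1 > lo2:
            raise ValueError(f"size bands {name1} and {name2} overlap")
    for lo, hi in bands.values():
        if not lo < hi:
            raise ValueError("band bounds must satisfy min < max")

    out = []
    for obj in objects:
        cls = "unknown"
        for name, (lo, hi) in bands.items():
            if lo <= obj.equivalent_diameter < hi:
                cls = name
                break
        out.append(DetectedObject(obj.centroid, obj.equivalent_diameter, cls))
    return out


def register_coordinates(
    objects: list[DetectedObject],
) -> tuple[list[DetectedObject], DetectedObject]:
    """Re-express coordinates relative to the first marker bead.

    The first marker in dispensing order (ascending x, then y) becomes the
    (0, 0) origin, as in a plate registration table whose first row is
    "marker #1 at (0, 0)".  Returns the translated objects and the
    reference marker (in original coordinates).
    """
    markers = [o for o in objects if o.object_class in MARKER_CLASSES]
    if not markers:
        raise ValueError("registration requires at least one detected marker bead")
    ref = min(markers, key=lambda o: (o.centroid[0], o.centroid[1]))
    x0, y0 = ref.centroid
    translated = [
        DetectedObject(
            (o.centroid[0] - x0, o.centroid[1] - y0), o.equivalent_diameter, o.object_class
        )
        for o in objects
    ]
    return translated, ref


def detections_to_frame(objects: list[DetectedObject]) -> pd.DataFrame:
    """Detections as a CSV-ready table compatible with the mapping stage."""
    return pd.DataFrame(
        {
            "entity": [
                "marker" if o.object_class in MARKER_CLASSES else o.object_class
                for o in objects
            ],
            "object_class": [o.object_class for o in objects],
            "x_um": [o.centroid[0] for o in objects],
            "y_um": [o.centroid[1] for o in objects],
            "diameter_um": [o.equivalent_diameter for o in objects],
        }
    )
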