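"""Synthetic mid-sagittal phantom images with known geometry and intensities.

The phantom is a deliberately simple stand-in for a sagittal T1-weighted
cervical MRI slice: a column of vertebral bodies separated by disc gaps, a
posterior CSF column spanning all levels, and a subchondral band of
configurable depth (default 3 mm) adjacent to each endplate.  Every tissue
class draws its pixel intensities from a configured normal distribution,
plus additive zero-mean Gaussian noise, clipped at zero.

Because the ground truth carries the exact annotations used to rasterize
the tissue classes, the phantom is an oracle for the EBQ estimator: with
all standard deviations at zero, the EBQ measured on the ground-truth ROIs
equals ``tissue_means['endplate_band'] / tissue_means['csf']`` exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ebq import CsfRegion, EbqMeasurement, EndplateAnnotation, compute_ebq, extract_band, polygon_mask
from .image import Image2D

__all__ = [
    "TISSUE_CLASSES",
    "PhantomConfig",
    "SchmorlSpec",
    "PhantomGroundTruth",
    "generate_phantom",
    "inject_schmorl",
    "measure_phantom",
]

TISSUE_CLASSES = ("background", "vertebral_bone", "disc", "csf", "endplate_band")

#: Plausible 8-bit-range T1W means: marrow fat bright, CSF dark, so that the
#: default band/CSF ratio (4.25) sits near the centre of the clinical EBQ range.
DEFAULT_TISSUE_MEANS = {
    "background": 5.0,
    "vertebral_bone": 140.0,
    "disc": 60.0,
    "csf": 40.0,
    "endplate_band": 170.0,
}

DEFAULT_LEVELS = ("C3/4", "C4/5", "C5/6", "C6/7")


@dataclass(frozen=True)
class SchmorlSpec:
    """A Schmorl node: a disc-shaped lesion indenting one endplate."""

    level: str
    radius_mm: float
    lesion_mean: float
    role: str = "upper_endplate"
    center_offset_mm: float = 0.0  # along the endplate, from its midpoint

    def __post_init__(self) -> None:
        if self.radius_mm < 0:
            raise ValueError("radius_mm must be nonnegative")
        if self.lesion_mean < 0:
            raise ValueError("lesion_mean must be nonnegative")
        if self.role not in ("upper_endplate", "lower_endplate"):
            raise ValueError(f"unknown endplate role {self.role!r}")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, tissue statistics and noise level of a phantom image."""

    image_height_px: int = 144
    image_width_px: int = 64
    pixel_spacing_mm: float = 0.5
    levels: tuple = DEFAULT_LEVELS
    tissue_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    tissue_sds: dict = field(default_factory=dict)
    band_depth_mm: float = 3.0
    noise_sd: float = 5.0
    endplate_wave_amp_mm: float = 0.0  # sinusoidal endplate curvature, 0 = flat
    disc_height_mm: float = 2.0
    margin_mm: float = 2.0
    csf_width_mm: float = 4.0
    csf_gap_mm: float = 4.0
    schmorl: Optional[SchmorlSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if not self.levels:
            raise ValueError("at least one disc level is required")
        missing = [k for k in TISSUE_CLASSES if k not in self.tissue_means]
        if missing:
            raise ValueError(f"tissue_means missing classes: {missing}")
        if any(v < 0 for v in self.tissue_means.values()):
            raise ValueError("tissue means must be nonnegative")
        if any(v < 0 for v in self.tissue_sds.values()):
            raise ValueError("tissue sds must be nonnegative")
        if self.band_depth_mm <= 0:
            raise ValueError("band_depth_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.schmorl is not None and self.schmorl.level not in self.levels:
            raise ValueError(
                f"schmorl level {self.schmorl.level!r} is not one of {list(self.levels)}")

    @property
    def height_mm(self) -> float:
        return self.image_height_px * self.pixel_spacing_mm

    @property
    def width_mm(self) -> float:
        return self.image_width_px * self.pixel_spacing_mm


@dataclass
class PhantomGroundTruth:
    """Exact geometry and configured statistics behind a phantom image."""

    levels: tuple
    annotations: dict  # level -> (upper EndplateAnnotation, lower EndplateAnnotation)
    csf: CsfRegion
    tissue_means: dict
    true_ebq: float
    band_depth_mm: float
    spacing_mm: float
    exclusions: dict = field(default_factory=dict)  # level -> [polygon_mm, ...]
    class_map: Optional[np.ndarray] = None  # int codes, index into TISSUE_CLASSES

    def exclusions_for(self, level: str) -> list:
        return list(self.exclusions.get(level, []))


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------


def _layout(config: PhantomConfig) -> dict:
    """Compute body/disc/CSF rectangles in mm; raise on geometry that cannot fit."""
    n_lev = len(config.levels)
    n_bodies = n_lev + 1
    m = config.margin_mm
    body_w = config.width_mm - 2 * m - config.csf_gap_mm - config.csf_width_mm
    if body_w <= 0:
        raise ValueError(
            f"image_width_px={config.image_width_px} too small: vertebral body "
            f"width would be {body_w:.1f} mm")
    body_h = (config.height_mm - 2 * m - n_lev * config.disc_height_mm) / n_bodies
    if body_h <= config.band_depth_mm:
        raise ValueError(
            f"image_height_px={config.image_height_px} too small: vertebral body "
            f"height {body_h:.1f} mm must exceed band_depth_mm={config.band_depth_mm}")
    x0 = m
    x1 = m + body_w
    bodies = []
    discs = []
    y = m
    for k in range(n_bodies):
        bodies.append((x0, y, x1, y + body_h))
        y += body_h
        if k < n_lev:
            discs.append((x0, y, x1, y + config.disc_height_mm))
            y += config.disc_height_mm
    csf_x0 = x1 + config.csf_gap_mm
    csf = (csf_x0, m, csf_x0 + config.csf_width_mm, config.height_mm - m)
    return {"bodies": bodies, "discs": discs, "csf": csf, "body_w": body_w, "body_h": body_h}


def _rect_polygon(rect) -> np.ndarray:
    x0, y0, x1, y1 = rect
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


def _endplate_polyline(x0: float, x1: float, y: float, amp: float, into_body: float) -> np.ndarray:
    """A straight or sinusoidally curved endplate spanning [x0, x1] at height y.

    ``into_body`` is +1/-1: the curve bulges toward the vertebral body
    (a concave endplate as seen from the disc), vanishing at the ends.
    """
    if amp == 0.0:
        return np.array([[x0, y], [x1, y]], dtype=float)
    xs = np.linspace(x0, x1, 33)
    ys = y + into_body * amp * np.sin(np.pi * (xs - x0) / (x1 - x0))
    return np.column_stack([xs, ys])


def _build_annotations(config: PhantomConfig, lay: dict) -> dict:
    """One (upper, lower) endplate annotation pair per disc level."""
    anns = {}
    amp = config.endplate_wave_amp_mm
    for k, level in enumerate(config.levels):
        dx0, dy0, dx1, dy1 = lay["discs"][k]
        body_above = lay["bodies"][k]
        body_below = lay["bodies"][k + 1]
        upper = EndplateAnnotation(
            level=level, role="upper_endplate",
            polyline_mm=_endplate_polyline(dx0, dx1, dy0, amp, into_body=-1.0),
            body_side_hint_mm=np.array([(dx0 + dx1) / 2, (body_above[1] + body_above[3]) / 2]),
        )
        lower = EndplateAnnotation(
            level=level, role="lower_endplate",
            polyline_mm=_endplate_polyline(dx0, dx1, dy1, amp, into_body=+1.0),
            body_side_hint_mm=np.array([(dx0 + dx1) / 2, (body_below[1] + body_below[3]) / 2]),
        )
        anns[level] = (upper, lower)
    return anns


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_phantom(config: PhantomConfig) -> tuple[Image2D, PhantomGroundTruth]:
    """Rasterize a phantom image and its exact ground truth.

    The tissue-class map is painted from the very annotations stored in the
    ground truth (band masks via :func:`~ebqspine.ebq.extract_band`, CSF via
    its polygon), so measured and generated geometry agree pixel-for-pixel.
    Identical config and seed give bit-identical output.
    """
    lay = _layout(config)
    shape = (config.image_height_px, config.image_width_px)
    blank = Image2D(np.zeros(shape), config.pixel_spacing_mm)

    class_map = np.zeros(shape, dtype=np.int8)  # 0 = background
    code = {name: i for i, name in enumerate(TISSUE_CLASSES)}
    for rect in lay["bodies"]:
        class_map[polygon_mask(blank, _rect_polygon(rect)).mask] = code["vertebral_bone"]
    for rect in lay["discs"]:
        class_map[polygon_mask(blank, _rect_polygon(rect)).mask] = code["disc"]
    csf_poly = _rect_polygon(lay["csf"])
    class_map[polygon_mask(blank, csf_poly).mask] = code["csf"]

    annotations = _build_annotations(config, lay)
    for upper, lower in annotations.values():
        class_map[extract_band(blank, upper, config.band_depth_mm).mask] = code["endplate_band"]
        class_map[extract_band(blank, lower, config.band_depth_mm).mask] = code["endplate_band"]

    means = np.array([config.tissue_means[n] for n in TISSUE_CLASSES])
    sds = np.array([config.tissue_sds.get(n, 0.0) for n in TISSUE_CLASSES])
    rng = np.random.default_rng(config.seed)
    pixels = means[class_map] + sds[class_map] * rng.standard_normal(shape)
    if config.noise_sd > 0:
        pixels = pixels + config.noise_sd * rng.standard_normal(shape)
    pixels = np.clip(pixels, 0.0, None)

    image = Image2D(pixels, config.pixel_spacing_mm)
    gt = PhantomGroundTruth(
        levels=tuple(config.levels),
        annotations=annotations,
        csf=CsfRegion(csf_poly),
        tissue_means=dict(config.tissue_means),
        true_ebq=config.tissue_means["endplate_band"] / config.tissue_means["csf"],
        band_depth_mm=config.band_depth_mm,
        spacing_mm=config.pixel_spacing_mm,
        exclusions={},
        class_map=class_map,
    )
    if config.schmorl is not None:
        image, gt = inject_schmorl(image, gt, config.schmorl)
    return image, gt


def _polyline_point_at(polyline: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Point at a fraction of the polyline's arclength, and the local tangent."""
    seg = np.diff(polyline, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    target = frac * cum[-1]
    i = int(np.searchsorted(cum[1:], target, side="left"))
    i = min(i, len(seg_len) - 1)
    t = 0.0 if seg_len[i] == 0 else (target - cum[i]) / seg_len[i]
    point = polyline[i] + t * seg[i]
    tangent = seg[i] / seg_len[i] if seg_len[i] > 0 else np.array([1.0, 0.0])
    return point, tangent


def inject_schmorl(
    image: Image2D, gt: PhantomGroundTruth, spec: SchmorlSpec
) -> tuple[Image2D, PhantomGroundTruth]:
    """Stamp a disc-shaped lesion onto an endplate and record its exclusion.

    The lesion centre sits on the endplate polyline (offset from its midpoint
    along the endplate), so the node indents the subchondral band.  Pixels
    within ``radius_mm`` of the centre take the lesion intensity exactly (no
    added noise); the ground truth gains a circumscribed-polygon exclusion so
    that an exclusion-aware measurement removes every lesion pixel.
    """
    if spec.level not in gt.annotations:
        raise ValueError(f"level {spec.level!r} not present in the phantom")
    if spec.radius_mm > gt.band_depth_mm:
        raise ValueError(
            f"lesion radius {spec.radius_mm} mm exceeds the band depth "
            f"{gt.band_depth_mm} mm")
    if spec.radius_mm == 0:
        return image, gt

    upper, lower = gt.annotations[spec.level]
    ann = upper if spec.role == "upper_endplate" else lower
    mid, tangent = _polyline_point_at(ann.polyline_mm, 0.5)
    center = mid + spec.center_offset_mm * tangent

    xs, ys = image.pixel_centers()
    inside = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= spec.radius_mm**2
    pixels = image.pixels.copy()
    pixels[inside] = spec.lesion_mean
    new_image = Image2D(pixels, image.spacing_mm)

    # circumscribed 64-gon: covers the full lesion disc, with a sliver of
    # over-exclusion of clean pixels (harmless for a mean)
    n_vert = 64
    ang = 2 * np.pi * np.arange(n_vert) / n_vert
    r_out = spec.radius_mm / np.cos(np.pi / n_vert)
    circle = np.column_stack([center[0] + r_out * np.cos(ang), center[1] + r_out * np.sin(ang)])

    exclusions = {k: list(v) for k, v in gt.exclusions.items()}
    exclusions.setdefault(spec.level, []).append(circle)
    new_gt = dataclasses.replace(gt, exclusions=exclusions)
    return new_image, new_gt


def measure_phantom(
    image: Image2D,
    gt: PhantomGroundTruth,
    depth_mm: Optional[float] = None,
    use_exclusions: bool = True,
    rater_id: Optional[str] = None,
) -> list[EbqMeasurement]:
    """Measure the EBQ of every level using the ground-truth annotations."""
    depth = gt.band_depth_mm if depth_mm is None else depth_mm
    out = []
    for level in gt.levels:
        upper, lower = gt.annotations[level]
        excl = gt.exclusions_for(level) if use_exclusions else None
        out.append(compute_ebq(image, upper, lower, gt.csf,
                               exclusions=excl, depth_mm=depth, rater_id=rater_id))
    return out
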