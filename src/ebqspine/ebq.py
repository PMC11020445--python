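"""Endplate bone quality (EBQ) scoring on a mid-sagittal T1-weighted slice.

The EBQ score of an operated disc level is the mean signal intensity of the
two subchondral endplate bands (a 3-mm-deep strip of bone adjacent to each
endplate bounding the disc space), divided by the mean signal of a
cerebrospinal-fluid reference region.  On T1-weighted images marrow fat is
bright and dense bone is dark, so a higher EBQ means fattier, weaker
subchondral bone.

Geometry conventions
--------------------
Annotations live in continuous mm coordinates (see :mod:`ebqspine.image`).
A pixel belongs to an endplate band iff its centre

* lies strictly within ``depth_mm`` of the endplate polyline,
* projects orthogonally onto the polyline (points past the free ends of the
  polyline are outside the band — the band is the strip *under* the endplate
  span, with no rounded end caps), and
* sits on the same side of the polyline as the ``body_side_hint``.

Side-of-polyline is decided by the sign of the 2-D cross product against the
nearest segment; pixels exactly on the polyline belong to neither side.
Distances are exact point-to-segment Euclidean distances — the bands are
small, so exactness is cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from matplotlib.path import Path as _MplPath
from shapely.geometry import Polygon as _ShapelyPolygon

from .image import Image2D

__all__ = [
    "EndplateAnnotation",
    "CsfRegion",
    "RegionMask",
    "EbqMeasurement",
    "RaterPanel",
    "UnmeasurableROIError",
    "ReconciliationError",
    "extract_band",
    "polygon_mask",
    "mask_mean",
    "compute_ebq",
    "reconcile",
]


class UnmeasurableROIError(ValueError):
    """Raised when a region of interest contains no usable pixels."""


class ReconciliationError(ValueError):
    """Raised when rater measurements disagree and no arbiter is available."""


# ---------------------------------------------------------------------------
# annotation types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EndplateAnnotation:
    """An endplate traced as a polyline, with a hint marking the bone side.

    ``role`` names which endplate of the operated disc space this is:
    ``upper_endplate`` is the endplate above the disc (the inferior endplate
    of the upper vertebra); ``lower_endplate`` the one below it.
    """

    level: str
    role: str  # {"upper_endplate", "lower_endplate"}
    polyline_mm: np.ndarray = field(repr=False)  # (N >= 2, 2)
    body_side_hint_mm: np.ndarray = field(repr=False)  # (2,)

    def __post_init__(self) -> None:
        if self.role not in ("upper_endplate", "lower_endplate"):
            raise ValueError(f"unknown endplate role {self.role!r}")
        pl = np.asarray(self.polyline_mm, dtype=float)
        if pl.ndim != 2 or pl.shape[0] < 2 or pl.shape[1] != 2:
            raise ValueError("polyline must be an (N>=2, 2) array of mm points")
        seg_len = np.hypot(*(np.diff(pl, axis=0).T))
        if not np.any(seg_len > 0):
            raise ValueError("polyline has zero length")
        hint = np.asarray(self.body_side_hint_mm, dtype=float).reshape(2)
        d, _, cross, _ = _polyline_distance_side(hint[None, :], pl)
        if d[0] == 0.0 or cross[0] == 0.0:
            raise ValueError("body_side_hint lies on the polyline; side is ambiguous")
        object.__setattr__(self, "polyline_mm", pl)
        object.__setattr__(self, "body_side_hint_mm", hint)

    @property
    def name(self) -> str:
        return f"{self.level}:{self.role}"


@dataclass(frozen=True)
class CsfRegion:
    """The cerebrospinal-fluid reference region (a simple polygon in mm).

    By convention the CSF is sampled at the upper T1 vertebral station on the
    same slice; any annotated CSF polygon is accepted.
    """

    polygon_mm: np.ndarray = field(repr=False)  # (N >= 3, 2)

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon_mm, dtype=float)
        if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
            raise ValueError("CSF polygon must be an (N>=3, 2) array of mm points")
        sh = _ShapelyPolygon(poly)
        if not sh.is_simple or not sh.is_valid:
            raise ValueError("CSF polygon is self-intersecting")
        if sh.area <= 0:
            raise ValueError("CSF polygon has zero area")
        object.__setattr__(self, "polygon_mm", poly)


@dataclass(frozen=True)
class RegionMask:
    """A boolean pixel mask congruent with its source image."""

    mask: np.ndarray = field(repr=False)
    provenance: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def __and__(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(self.mask & other.mask, f"({self.provenance})&({other.provenance})")

    def __or__(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(self.mask | other.mask, f"({self.provenance})|({other.provenance})")


@dataclass(frozen=True)
class EbqMeasurement:
    """Per-level signal means and the resulting EBQ score."""

    level: str
    si_upper: float
    si_lower: float
    si_csf: float
    ebq: float
    rater_id: Optional[str] = None
    n_pixels: dict = field(default_factory=dict)
    excluded_pixels: dict = field(default_factory=dict)

    @property
    def ebq_display(self) -> float:
        """EBQ rounded to 2 decimals, the reporting convention."""
        return round(self.ebq, 2)


@dataclass(frozen=True)
class RaterPanel:
    """Two primary raters plus an optional arbiter for one disc level.

    Discrepancies larger than ``discrepancy_threshold`` (in EBQ units,
    default 2.0) trigger the arbiter's confirmatory re-measurement.
    """

    measurements: Sequence[Union[EbqMeasurement, float]]
    discrepancy_threshold: float = 2.0
    arbiter: Optional[Union[EbqMeasurement, float]] = None

    def __post_init__(self) -> None:
        if len(self.measurements) < 2:
            raise ValueError("a rater panel needs at least 2 primary measurements")
        if not self.discrepancy_threshold > 0:
            raise ValueError("discrepancy_threshold must be positive")
        levels = {m.level for m in self.measurements if isinstance(m, EbqMeasurement)}
        if len(levels) > 1:
            raise ValueError(f"panel mixes disc levels: {sorted(levels)}")


def _ebq_value(m: Union[EbqMeasurement, float]) -> float:
    return float(m.ebq) if isinstance(m, EbqMeasurement) else float(m)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _polyline_distance_side(points: np.ndarray, polyline: np.ndarray):
    """Distance, cap flag and side of each point relative to a polyline.

    Returns ``(dist, cap, cross, seg_idx)`` where ``dist`` is the exact
    point-to-polyline Euclidean distance, ``cap`` flags points whose nearest
    polyline point is a free end they project past (the end-cap region),
    ``cross`` is the 2-D cross product against the nearest segment (its sign
    is the side; 0 means on the line) and ``seg_idx`` the nearest segment.
    """
    pts = np.asarray(points, dtype=float)
    a = polyline[:-1]  # (S, 2)
    b = polyline[1:]
    d = b - a
    len2 = np.einsum("ij,ij->i", d, d)
    # degenerate (repeated) vertices: avoid 0/0, treat as points
    safe_len2 = np.where(len2 > 0, len2, 1.0)
    rel = pts[:, None, :] - a[None, :, :]  # (M, S, 2)
    t_un = np.einsum("msk,sk->ms", rel, d) / safe_len2[None, :]
    t_un = np.where(len2[None, :] > 0, t_un, 0.0)
    t_cl = np.clip(t_un, 0.0, 1.0)
    proj = a[None, :, :] + t_cl[:, :, None] * d[None, :, :]
    diff = pts[:, None, :] - proj
    dist_all = np.hypot(diff[:, :, 0], diff[:, :, 1])  # (M, S)
    seg_idx = np.argmin(dist_all, axis=1)
    m_idx = np.arange(pts.shape[0])
    dist = dist_all[m_idx, seg_idx]
    d_near = d[seg_idx]
    rel_near = rel[m_idx, seg_idx]
    cross = d_near[:, 0] * rel_near[:, 1] - d_near[:, 1] * rel_near[:, 0]
    t_near = t_un[m_idx, seg_idx]
    n_seg = a.shape[0]
    cap = ((seg_idx == 0) & (t_near < 0.0)) | ((seg_idx == n_seg - 1) & (t_near > 1.0))
    return dist, cap, cross, seg_idx


def extract_band(image: Image2D, ann: EndplateAnnotation, depth_mm: float) -> RegionMask:
    """Rasterize the subchondral band of an endplate annotation.

    The mask holds pixels whose centres are strictly within ``depth_mm`` of
    the polyline, project orthogonally onto it (no end caps) and lie on the
    ``body_side_hint`` side.
    """
    if not depth_mm > 0:
        raise ValueError("depth_mm must be positive")
    pl = ann.polyline_mm
    if (pl[:, 0].min() < 0 or pl[:, 1].min() < 0
            or pl[:, 0].max() > image.width_mm or pl[:, 1].max() > image.height_mm):
        raise ValueError(
            f"polyline of {ann.name} extends outside the image "
            f"({image.width_mm:.1f} x {image.height_mm:.1f} mm)")
    xs, ys = image.pixel_centers()
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    dist, cap, cross, _ = _polyline_distance_side(pts, pl)
    hd, _, hcross, _ = _polyline_distance_side(ann.body_side_hint_mm[None, :], pl)
    hint_sign = np.sign(hcross[0])
    inside = (dist < depth_mm) & ~cap & (np.sign(cross) == hint_sign) & (cross != 0)
    mask = inside.reshape(image.shape)
    if not mask.any():
        raise UnmeasurableROIError(
            f"band of {ann.name} at depth {depth_mm} mm contains no pixel centres")
    return RegionMask(mask, provenance=f"band:{ann.name}")


def polygon_mask(image: Image2D, polygon_mm: np.ndarray, provenance: str = "polygon") -> RegionMask:
    """Pixels whose centres fall inside a polygon given in mm coordinates."""
    poly = np.asarray(polygon_mm, dtype=float)
    xs, ys = image.pixel_centers()
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    path = _MplPath(poly, closed=True)
    inside = path.contains_points(pts)
    return RegionMask(inside.reshape(image.shape), provenance=provenance)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------


def mask_mean(
    image: Image2D,
    roi: RegionMask,
    exclusions: Optional[RegionMask] = None,
) -> tuple[float, int]:
    """Arithmetic mean of the image inside ``roi`` minus ``exclusions``.

    Returns ``(mean, n_used)``; raises :class:`UnmeasurableROIError` when no
    pixel survives the exclusion.
    """
    if roi.mask.shape != image.shape:
        raise ValueError("ROI mask shape does not match the image")
    use = roi.mask
    n_roi = int(use.sum())
    if exclusions is not None:
        if exclusions.mask.shape != image.shape:
            raise ValueError("exclusion mask shape does not match the image")
        use = use & ~exclusions.mask
    n_used = int(use.sum())
    if n_used == 0:
        raise UnmeasurableROIError(
            f"ROI {roi.provenance!r} has no pixels left after exclusion "
            f"({n_roi} before)")
    return float(image.pixels[use].mean()), n_used


def compute_ebq(
    image: Image2D,
    upper: EndplateAnnotation,
    lower: EndplateAnnotation,
    csf: CsfRegion,
    exclusions: Optional[Sequence[np.ndarray]] = None,
    depth_mm: float = 3.0,
    rater_id: Optional[str] = None,
    pooled: bool = False,
) -> EbqMeasurement:
    """Measure the EBQ score of one operated level.

    EBQ = ((mean SI of upper band + mean SI of lower band) / 2) / mean CSF SI.
    The two endplate bands contribute their *per-ROI means* averaged with
    equal weight (the reference convention); ``pooled=True`` instead pools
    all band pixels into one mean, which differs when the band areas differ.

    ``exclusions`` is an optional list of polygons (mm) — e.g. a Schmorl
    node outline — removed from both endplate bands before averaging.
    """
    if upper.level != lower.level:
        raise ValueError(f"endplate levels differ: {upper.level} vs {lower.level}")
    excl_mask: Optional[RegionMask] = None
    if exclusions:
        acc = np.zeros(image.shape, dtype=bool)
        for poly in exclusions:
            acc |= polygon_mask(image, poly, "exclusion").mask
        excl_mask = RegionMask(acc, provenance="exclusions")

    band_u = extract_band(image, upper, depth_mm)
    band_l = extract_band(image, lower, depth_mm)
    csf_roi = polygon_mask(image, csf.polygon_mm, provenance="csf")
    if csf_roi.n_pixels == 0:
        raise UnmeasurableROIError("CSF polygon contains no pixel centres")

    si_upper, n_u = mask_mean(image, band_u, excl_mask)
    si_lower, n_l = mask_mean(image, band_l, excl_mask)
    si_csf, n_c = mask_mean(image, csf_roi, None)
    if si_csf == 0:
        raise ZeroDivisionError("CSF mean signal is zero; EBQ is undefined")

    if pooled:
        numer = (si_upper * n_u + si_lower * n_l) / (n_u + n_l)
    else:
        numer = (si_upper + si_lower) / 2.0
    ebq = numer / si_csf

    n_excl_u = band_u.n_pixels - n_u
    n_excl_l = band_l.n_pixels - n_l
    return EbqMeasurement(
        level=upper.level,
        rater_id=rater_id,
        si_upper=si_upper,
        si_lower=si_lower,
        si_csf=si_csf,
        ebq=ebq,
        n_pixels={"upper": n_u, "lower": n_l, "csf": n_c},
        excluded_pixels={"upper": n_excl_u, "lower": n_excl_l},
    )


def reconcile(panel: RaterPanel) -> tuple[float, bool]:
    """Resolve a rater panel into a final EBQ value.

    If the primary raters agree within ``discrepancy_threshold`` the final
    score is their mean and no arbiter is used; otherwise the arbiter's
    confirmatory re-measurement is adopted.  Raises
    :class:`ReconciliationError` when the arbiter is needed but missing.
    """
    values = [_ebq_value(m) for m in panel.measurements]
    spread = max(values) - min(values)
    if spread <= panel.discrepancy_threshold:
        return float(np.mean(values)), False
    if panel.arbiter is None:
        raise ReconciliationError(
            f"rater discrepancy {spread:.3f} exceeds threshold "
            f"{panel.discrepancy_threshold:.3f} and no arbiter measurement "
            "was supplied; confirmatory re-measurement required")
    return _ebq_value(panel.arbiter), True
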