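"""Minimal 2-D grayscale image container with physical pixel spacing.

All measurement geometry in this package works in continuous millimetre
coordinates: x grows rightward, y grows downward, and the centre of pixel
(row i, col j) sits at ((j + 0.5) * spacing, (i + 0.5) * spacing).  Masks
are decided by pixel-centre tests against that coordinate frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Image2D"]


@dataclass(frozen=True)
class Image2D:
    """A 2-D nonnegative grayscale raster with isotropic pixel spacing.

    Parameters
    ----------
    pixels
        ``(H, W)`` array of nonnegative, finite intensities (row 0 at top).
    spacing_mm
        Physical edge length of one pixel, in millimetres (isotropic).
    """

    pixels: np.ndarray = field(repr=False)
    spacing_mm: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("pixels array is empty")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain NaN or infinite values")
        if px.min() < 0:
            raise ValueError("pixels must be nonnegative")
        if not (float(self.spacing_mm) > 0):
            raise ValueError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "spacing_mm", float(self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height_mm(self) -> float:
        return self.pixels.shape[0] * self.spacing_mm

    @property
    def width_mm(self) -> float:
        return self.pixels.shape[1] * self.spacing_mm

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of pixel-centre coordinates in mm.

        Both arrays have the image's ``(H, W)`` shape.
        """
        h, w = self.pixels.shape
        s = self.spacing_mm
        x = (np.arange(w) + 0.5) * s
        y = (np.arange(h) + 0.5) * s
        return np.meshgrid(x, y)

    def scaled(self, factor: float) -> "Image2D":
        """Return a copy with every intensity multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("factor must be positive")
        return Image2D(self.pixels * factor, self.spacing_mm)
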