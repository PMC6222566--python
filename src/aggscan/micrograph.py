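"""Micrograph: a 2D intensity grid with a physical pixel scale.

All imaging operations in this package are scale-aware: object sizes
(cell areas, puncta diameters, filter scales) are specified in microns
and converted to pixels through ``pixel_size`` (um per pixel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Micrograph"]


@dataclass
class Micrograph:
    """A single-channel fluorescence or DIC image.

    Parameters
    ----------
    pixels
        2D array of non-negative, finite intensities.
    pixel_size
        Physical size of one pixel in micrometres (um / pixel), > 0.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D image, got ndim={self.pixels.ndim}")
        if self.pixels.size == 0:
            raise ValueError("empty image")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in um^2."""
        return self.pixel_size ** 2

    def um_to_px(self, length_um: float) -> float:
        return length_um / self.pixel_size

    def to_uint16(self) -> np.ndarray:
        """Clip and round intensities into the 16-bit range for file output."""
        return np.clip(np.rint(self.pixels), 0, 65535).astype(np.uint16)
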