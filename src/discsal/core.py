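"""Shared domain types for fundus-image saliency evaluation.

The package evaluates how CNN glaucoma classifiers distribute attribution
over the optic disc.  Everything downstream operates on three anchors: a
fundus-like image (:class:`FundusSample`), the disc/cup geometry that frames
the sector analysis (:class:`DiscCupAnnotation`), and the eye's laterality,
which decides which side of the image is temporal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Class labels, index-aligned with the classifier's output units.
LABELS = ("healthy", "glaucoma")
HEALTHY, GLAUCOMA = 0, 1

#: Laterality codes: OD = right eye, OS = left eye.
LATERALITIES = ("OD", "OS")


class ConfigurationError(ValueError):
    """Raised when a configuration violates its documented invariants."""


class ContractError(RuntimeError):
    """Raised when a model adapter lacks a capability a method requires."""


class NumericalError(ArithmeticError):
    """Raised when a saliency computation produces non-finite values."""


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned-by-default ellipse in image (row, col) pixel coordinates.

    ``rotation_deg`` rotates the semi-axis frame counter-clockwise in the
    conventional x/y sense (i.e. clockwise on screen, where row grows down).
    """

    center_row: float
    center_col: float
    semi_axis_row: float
    semi_axis_col: float
    rotation_deg: float = 0.0

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Binary mask of pixels whose integer-coordinate centers fall inside."""
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        dr = rows - self.center_row
        dc = cols - self.center_col
        t = np.deg2rad(self.rotation_deg)
        # rotate offsets into the ellipse frame
        u = np.cos(t) * dc + np.sin(t) * dr
        v = -np.sin(t) * dc + np.cos(t) * dr
        return (u / self.semi_axis_col) ** 2 + (v / self.semi_axis_row) ** 2 <= 1.0

    def mirrored(self, width: int) -> "Ellipse":
        """The ellipse after flipping the image left-right."""
        return Ellipse(
            center_row=self.center_row,
            center_col=(width - 1) - self.center_col,
            semi_axis_row=self.semi_axis_row,
            semi_axis_col=self.semi_axis_col,
            rotation_deg=-self.rotation_deg,
        )


@dataclass
class FundusSample:
    """One synthetic fundus image with its label and laterality."""

    image: np.ndarray  # H x W x 3, float in [0, 1]
    laterality: str  # "OD" | "OS"
    label: int  # index into LABELS
    sample_id: str

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ConfigurationError("image must be H x W x 3")
        if self.image.shape[0] < 32 or self.image.shape[1] < 32:
            raise ConfigurationError("image must be at least 32 x 32")
        if not np.all(np.isfinite(self.image)):
            raise ConfigurationError("image intensities must be finite")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ConfigurationError("image intensities must lie in [0, 1]")
        if self.laterality not in LATERALITIES:
            raise ConfigurationError(f"unknown laterality {self.laterality!r}")


@dataclass
class DiscCupAnnotation:
    """Disc and cup regions anchoring the sector geometry.

    Regions are stored as ellipses; rasterized masks are derived on demand.
    The cup mask is intersected with the disc mask so the containment
    invariant holds pixel-exactly even when the cup ellipse grazes the disc
    boundary.
    """

    disc: Ellipse
    cup: Ellipse
    laterality: str

    def disc_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = self.disc.rasterize(shape)
        if not mask.any():
            raise ConfigurationError("disc region is empty at this image shape")
        if mask.all():
            raise ConfigurationError("disc region covers the whole image")
        return mask

    def cup_mask(self, shape: tuple[int, int]) -> np.ndarray:
        return self.cup.rasterize(shape) & self.disc_mask(shape)

    def mirrored(self, width: int) -> "DiscCupAnnotation":
        other = "OS" if self.laterality == "OD" else "OD"
        return DiscCupAnnotation(
            disc=self.disc.mirrored(width),
            cup=self.cup.mirrored(width),
            laterality=other,
        )


def measured_cdr(disc_mask: np.ndarray, cup_mask: np.ndarray) -> float:
    """Cup-to-disc ratio measured from rasterized masks.

    Uses the square root of the area ratio, which for similar concentric
    ellipses equals the axis ratio and is far less sensitive to pixel
    quantization than extent-based diameters.
    """
    disc_area = int(disc_mask.sum())
    if disc_area == 0:
        raise ConfigurationError("disc mask is empty")
    return float(np.sqrt(cup_mask.sum() / disc_area))
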