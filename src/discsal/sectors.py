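"""Optic-disc sector geometry and sector discretization of saliency maps.

The disc is partitioned into six anatomical sectors — nasal (N), nasal
inferior (NI), temporal inferior (TI), temporal (T), temporal superior (TS)
and nasal superior (NS) — plus a background sector B covering everything
outside the disc.  A saliency map is discretized by thresholding it at a
fraction (default 75%) of its maximum and measuring what fraction of the
retained pixels falls inside each sector:

    score(sec) = |M_sec ∩ M_sal| / |M_sal|

Angles are measured from the temporal horizontal axis of the disc,
positive toward superior, so the same scheme serves both eyes: for a left
eye (OS) the geometry is the horizontal mirror of the right eye (OD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .core import ConfigurationError, DiscCupAnnotation

#: Canonical sector order used for every vectorization.
SECTOR_ORDER = ("N", "NI", "TI", "T", "TS", "NS", "B")
DISC_SECTORS = SECTOR_ORDER[:-1]

#: Image side that is temporal for a right eye (OD); the fovea lies temporal
#: to the disc, which for a disc-centered right-eye photograph is the left
#: side of the frame.  OS mirrors this.
OD_TEMPORAL_SIDE = "left"


@dataclass(frozen=True)
class SectorScheme:
    """Angular spans (half-open arcs, degrees) of the six disc sectors.

    0° is the temporal horizontal axis; angles increase toward superior.
    """

    spans: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if set(self.spans) != set(DISC_SECTORS):
            raise ConfigurationError("scheme must define exactly the six disc sectors")
        total = 0.0
        for start, end in self.spans.values():
            total += (end - start) % 360 or 360
        if not np.isclose(total, 360.0):
            raise ConfigurationError("sector spans must tile [0, 360)")

    @staticmethod
    def garway_heath() -> "SectorScheme":
        """The standard 90/40/40/110/40/40-degree clinical sectorization."""
        return SectorScheme(
            {
                "T": (315.0, 45.0),
                "TS": (45.0, 85.0),
                "NS": (85.0, 125.0),
                "N": (125.0, 235.0),
                "NI": (235.0, 275.0),
                "TI": (275.0, 315.0),
            }
        )

    @staticmethod
    def equal_sixths() -> "SectorScheme":
        """Six equal 60-degree wedges centered like the clinical scheme."""
        return SectorScheme(
            {
                "T": (330.0, 30.0),
                "TS": (30.0, 90.0),
                "NS": (90.0, 150.0),
                "N": (150.0, 210.0),
                "NI": (210.0, 270.0),
                "TI": (270.0, 330.0),
            }
        )

    def mid_angle(self, sector: str) -> float:
        """Mid-arc angle of a sector, wrap-aware, in [0, 360)."""
        start, end = self.spans[sector]
        width = (end - start) % 360 or 360
        return (start + width / 2.0) % 360


@dataclass
class SectorMaskSet:
    """Seven binary masks partitioning the image, keyed by sector id."""

    masks: dict[str, np.ndarray]
    laterality: str

    def __getitem__(self, sector: str) -> np.ndarray:
        return self.masks[sector]

    def as_label_image(self) -> np.ndarray:
        """7-valued label image (0..6 in canonical sector order)."""
        shape = self.masks["B"].shape
        label = np.zeros(shape, dtype=np.uint8)
        for i, sec in enumerate(SECTOR_ORDER):
            label[self.masks[sec]] = i
        return label


@dataclass
class DiscreteSaliency:
    """Seven-sector fraction vector: the discretized saliency map."""

    scores: dict[str, float]
    sample_id: str = ""
    method: str = ""
    threshold: float = 0.75

    def vector(self) -> np.ndarray:
        return np.array([self.scores[sec] for sec in SECTOR_ORDER])


def temporal_side(laterality: str, od_temporal_side: str = OD_TEMPORAL_SIDE) -> str:
    if laterality == "OD":
        return od_temporal_side
    return "right" if od_temporal_side == "left" else "left"


def _angle_in_span(angles: np.ndarray, span: tuple[float, float]) -> np.ndarray:
    start, end = span[0] % 360, span[1] % 360
    if start < end:
        return (angles >= start) & (angles < end)
    return (angles >= start) | (angles < end)


def build_sector_masks(
    annotation: DiscCupAnnotation,
    image_shape: tuple[int, int],
    scheme: Optional[SectorScheme] = None,
    rim_only: bool = False,
    od_temporal_side: str = OD_TEMPORAL_SIDE,
) -> SectorMaskSet:
    """Assign every disc pixel to a sector by the angle of its offset from
    the disc center; B is the complement of the disc (plus the cup when
    ``rim_only``)."""
    scheme = scheme or SectorScheme.garway_heath()
    disc = annotation.disc_mask(image_shape)
    region = disc & ~annotation.cup_mask(image_shape) if rim_only else disc

    rows, cols = np.mgrid[0 : image_shape[0], 0 : image_shape[1]]
    dr = rows - annotation.disc.center_row
    dc = cols - annotation.disc.center_col
    side = temporal_side(annotation.laterality, od_temporal_side)
    toward_temporal = (-dc if side == "left" else dc) + 0.0  # +0.0 kills signed zeros
    toward_superior = -dr + 0.0  # row index grows downward
    angles = np.degrees(np.arctan2(toward_superior, toward_temporal)) % 360

    masks = {}
    for sec in DISC_SECTORS:
        masks[sec] = region & _angle_in_span(angles, scheme.spans[sec])
    masks["B"] = ~region
    return SectorMaskSet(masks=masks, laterality=annotation.laterality)


def threshold_saliency(values: np.ndarray, tau: float = 0.75) -> np.ndarray:
    """Binary mask of pixels at or above ``tau`` times the map's maximum.

    The maximizing pixel is always retained, so the mask is never empty.  A
    constant map keeps every pixel (and triggers a warning, since the whole
    image then counts as salient).
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ConfigurationError("saliency map contains non-finite values")
    vmax = values.max()
    if values.min() == vmax:
        warnings.warn("constant saliency map: threshold mask covers the whole image")
        return np.ones_like(values, dtype=bool)
    mask = values >= tau * vmax
    mask |= values == vmax  # guards tau*max > max when max < 0
    return mask


def discretize_saliency(
    saliency,  # SaliencyMap or ndarray
    masks: SectorMaskSet,
    tau: float = 0.75,
) -> DiscreteSaliency:
    """Eq.-style sector discretization: fraction of thresholded pixels per sector."""
    values = getattr(saliency, "values", saliency)
    method = getattr(saliency, "method", "")
    sample_id = getattr(saliency, "sample_id", "") or ""
    if values.shape != masks.masks["B"].shape:
        raise ConfigurationError("saliency map and sector masks have different shapes")
    m_sal = threshold_saliency(values, tau)
    total = int(m_sal.sum())
    if total == 0:
        raise ConfigurationError("empty saliency mask (custom mask violated the threshold rule)")
    scores = {sec: float((masks[sec] & m_sal).sum() / total) for sec in SECTOR_ORDER}
    return DiscreteSaliency(scores=scores, sample_id=sample_id, method=method, threshold=tau)
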