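"""Global sector relevance: where does the top discrete score land?

For each image, the sector holding the largest discretized saliency score
is recorded; the global relevance of a sector is the probability, over a
test set, that it holds that top score.  Probabilities are grouped by the
model's *predicted* class (healthy / glaucoma) with an additional pooled
"both" row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import LABELS, ConfigurationError
from .sectors import SECTOR_ORDER, DiscreteSaliency

GROUPS = ("both",) + LABELS


@dataclass
class RelevanceTable:
    """Per-group sector probabilities; rows sum to 1 when the group is non-empty.

    ``probabilities`` is indexed by group ("both", "healthy", "glaucoma");
    a group with no images is absent from the frame (not a zero row) and has
    ``n_images[group] == 0``.
    """

    probabilities: pd.DataFrame  # index: group, columns: SECTOR_ORDER
    n_images: dict[str, int]
    method: str = ""
    model_id: str = ""

    def as_percent(self) -> pd.DataFrame:
        return self.probabilities * 100.0


def argmax_sector(d: DiscreteSaliency) -> str:
    """Sector with the maximal score; ties go to the earliest sector in
    canonical (N, NI, TI, T, TS, NS, B) order."""
    vec = d.vector()
    return SECTOR_ORDER[int(np.argmax(vec))]


def global_relevance(
    discrete_maps: Sequence[DiscreteSaliency],
    predicted_classes: Sequence[int],
    method: str = "",
    model_id: str = "",
) -> RelevanceTable:
    """Probability that each sector holds the top discrete score, per
    predicted class, pooled over all supplied images with equal weight."""
    if len(discrete_maps) == 0:
        raise ConfigurationError("empty collection of discrete maps")
    if len(discrete_maps) != len(predicted_classes):
        raise ConfigurationError("one predicted class per map is required")
    tops = np.array([argmax_sector(d) for d in discrete_maps])
    classes = np.asarray(predicted_classes)
    rows = {}
    n_images = {}
    for group in GROUPS:
        if group == "both":
            sel = np.ones(len(tops), dtype=bool)
        else:
            sel = classes == LABELS.index(group)
        n = int(sel.sum())
        n_images[group] = n
        if n == 0:
            continue  # absent, not zero
        counts = pd.Series(tops[sel]).value_counts()
        rows[group] = [counts.get(sec, 0) / n for sec in SECTOR_ORDER]
    probabilities = pd.DataFrame.from_dict(rows, orient="index", columns=list(SECTOR_ORDER))
    return RelevanceTable(probabilities=probabilities, n_images=n_images,
                          method=method, model_id=model_id)
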