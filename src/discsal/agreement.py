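"""Spearman agreement analyses and randomization sanity checks.

Collections of discretized saliency maps over a fixed image list are
flattened to vectors (7 sector scores per image, canonical order) and
compared with Spearman's rank correlation.  Two sanity checks probe whether
a method actually depends on what the model learned:

* **parameter randomization** — compare a trained model's discrete maps with
  those of a freshly reinitialized (untrained) copy; high |rho| means the
  method ignores the learned weights;
* **label randomization** — retrain with a fraction (default 50%) of the
  training labels flipped and compare; methods whose median |rho| stays at
  or above the discard threshold (default 0.5) are flagged for discard.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .core import ConfigurationError, ContractError
from .fixtures import randomize_labels, train_toy_model
from .sectors import SECTOR_ORDER, DiscreteSaliency


@dataclass
class DiscreteSaliencyCollection:
    """Ordered discrete maps of one (model, method) over a fixed image list."""

    entries: list[DiscreteSaliency]
    model_id: str = ""
    method: str = ""
    dataset_id: str = ""

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(d.sample_id for d in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AgreementResult:
    """One Spearman comparison between two discrete-saliency vectors."""

    rho: float
    p_value: float
    pair: tuple[str, str]
    kind: str  # methods | folds | architectures | parameter_randomization | label_randomization
    n_elements: int


def to_vector(collection: DiscreteSaliencyCollection) -> np.ndarray:
    """Flatten to a 7 * n_images vector: image order, then canonical sector order."""
    return np.concatenate([d.vector() for d in collection.entries])


def spearman(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("vectors must have equal length")
    if len(a) < 3:
        raise ConfigurationError("need at least 3 elements")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant vector: Spearman correlation undefined")
        return float("nan"), float("nan")
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def _compare(c1: DiscreteSaliencyCollection, c2: DiscreteSaliencyCollection,
             kind: str, pair: tuple[str, str]) -> AgreementResult:
    if c1.sample_ids != c2.sample_ids:
        raise ConfigurationError("collections cover different image lists")
    v1, v2 = to_vector(c1), to_vector(c2)
    rho, p = spearman(v1, v2)
    return AgreementResult(rho=rho, p_value=p, pair=pair, kind=kind, n_elements=len(v1))


def pairwise_agreement(
    groups: Mapping[str, Mapping[str, DiscreteSaliencyCollection]],
    kind: str = "methods",
) -> list[AgreementResult]:
    """All unordered within-group pairs; n members yield n(n-1)/2 pairs.

    ``groups`` maps a group label (e.g. a model id) to the named collections
    to be compared within it (e.g. one per method).  Singleton groups emit a
    warning and contribute no pairs.
    """
    results = []
    for group, members in groups.items():
        names = list(members)
        if len(names) < 2:
            warnings.warn(f"group {group!r} has fewer than two collections; skipped")
            continue
        for n1, n2 in itertools.combinations(names, 2):
            res = _compare(members[n1], members[n2], kind, (f"{group}:{n1}", f"{group}:{n2}"))
            results.append(res)
    return results


def summarize(results: Sequence[AgreementResult]) -> dict[str, float]:
    """Boxplot-style five-number summary of the rho values."""
    rhos = np.array([r.rho for r in results], dtype=float)
    rhos = rhos[np.isfinite(rhos)]
    if len(rhos) == 0:
        return {"n": 0}
    q1, med, q3 = np.percentile(rhos, [25, 50, 75])
    return {
        "n": int(len(rhos)),
        "min": float(rhos.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(rhos.max()),
    }


# ---------------------------------------------------------------------------
# Sanity checks


@dataclass
class SanityReport:
    """Randomization-test correlations per method, plus discard flags."""

    parameter_rho: dict[str, list[float]] = field(default_factory=dict)
    label_rho: dict[str, list[float]] = field(default_factory=dict)
    discard_threshold: float = 0.5
    convergence_warning: bool = False

    def discarded_methods(self) -> list[str]:
        """Methods whose median label-randomization |rho| reaches the threshold."""
        flagged = []
        for method, rhos in self.label_rho.items():
            vals = np.abs(np.asarray(rhos, dtype=float))
            vals = vals[np.isfinite(vals)]
            if len(vals) and np.median(vals) >= self.discard_threshold:
                flagged.append(method)
        return flagged

    def max_abs_parameter_rho(self) -> float:
        vals = [abs(r) for rhos in self.parameter_rho.values() for r in rhos if np.isfinite(r)]
        return max(vals) if vals else float("nan")


def _collections_for(model, samples, annotations, methods, config, scheme, tau):
    # local import: pipeline depends on this module's types
    from .pipeline import compute_discrete_collections

    return compute_discrete_collections(model, samples, annotations, methods,
                                        config=config, scheme=scheme, tau=tau)


def parameter_randomization_test(
    trained,
    samples,
    annotations,
    methods: Sequence[str],
    config=None,
    n_replicates: int = 5,
    seed: int = 0,
    scheme=None,
    tau: float = 0.75,
    report: Optional[SanityReport] = None,
) -> SanityReport:
    """Trained model vs. freshly reinitialized copies, one rho per (method, replicate)."""
    if not hasattr(trained, "reinitialize"):
        raise ContractError("adapter does not support reinitialize")
    report = report or SanityReport()
    trained_cols, _ = _collections_for(trained, samples, annotations, methods, config, scheme, tau)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   np.random.SeedSequence(seed).spawn(n_replicates)]
    for rep_seed in child_seeds:
        random_model = trained.reinitialize(rep_seed)
        rand_cols, _ = _collections_for(random_model, samples, annotations, methods,
                                        config, scheme, tau)
        for method in methods:
            res = _compare(trained_cols[method], rand_cols[method],
                           "parameter_randomization", (trained.model_id, random_model.model_id))
            report.parameter_rho.setdefault(method, []).append(res.rho)
    return report


def label_randomization_test(
    trained,
    train_samples,
    train_labels,
    samples,
    annotations,
    methods: Sequence[str],
    config=None,
    seed: int = 0,
    flip_fraction: float = 0.5,
    hyperparams=None,
    scheme=None,
    tau: float = 0.75,
    report: Optional[SanityReport] = None,
) -> SanityReport:
    """Cleanly trained vs. retrained-on-flipped-labels model, one rho per method."""
    report = report or SanityReport()
    if flip_fraction == 0:
        corrupted_labels = np.asarray(train_labels)  # degenerate control: identical retraining
    else:
        corrupted_labels = randomize_labels(np.asarray(train_labels), flip_fraction, seed)
    corrupted = train_toy_model(train_samples, corrupted_labels, hyperparams, seed=seed)
    if not all(np.isfinite(h["loss"]) for h in corrupted.history):
        warnings.warn("label-randomized training diverged (non-finite loss)")
        report.convergence_warning = True
    trained_cols, _ = _collections_for(trained, samples, annotations, methods, config, scheme, tau)
    corrupt_cols, _ = _collections_for(corrupted, samples, annotations, methods,
                                       config, scheme, tau)
    for method in methods:
        res = _compare(trained_cols[method], corrupt_cols[method],
                       "label_randomization", (trained.model_id, corrupted.model_id))
        report.label_rho.setdefault(method, []).append(res.rho)
    return report
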