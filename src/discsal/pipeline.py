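"""Orchestration helpers tying fixtures, saliency, sectors and analyses together.

These functions are the library-level pipeline the CLI wraps: compute
saliency maps for a model over a sample list, discretize them against the
per-image sector geometry, and run the two desk-scale experiments used for
validation — the parameter-randomization ceiling and the planted
sector-localized rim-loss recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .agreement import (
    DiscreteSaliencyCollection,
    SanityReport,
    parameter_randomization_test,
    spearman,
    to_vector,
)
from .core import GLAUCOMA, DiscCupAnnotation, FundusSample
from .fixtures import GeneratorConfig, generate_dataset, train_toy_model
from .nn import Hyperparams, ModelAdapter
from .relevance import RelevanceTable, global_relevance
from .saliency import RETAINED_METHODS, SaliencyConfig, SaliencyMap, compute_map
from .sectors import SectorScheme, build_sector_masks, discretize_saliency


def compute_saliency_maps(
    model: ModelAdapter,
    samples: Sequence[FundusSample],
    methods: Sequence[str],
    config: Optional[SaliencyConfig] = None,
) -> dict[tuple[str, str], SaliencyMap]:
    """One map per (sample_id, method), explaining each sample's predicted class."""
    config = config or SaliencyConfig()
    return {
        (s.sample_id, method): compute_map(method, model, s, config)
        for s in samples
        for method in methods
    }


def compute_discrete_collections(
    model: ModelAdapter,
    samples: Sequence[FundusSample],
    annotations: Sequence[DiscCupAnnotation],
    methods: Sequence[str],
    config: Optional[SaliencyConfig] = None,
    scheme: Optional[SectorScheme] = None,
    tau: float = 0.75,
) -> tuple[dict[str, DiscreteSaliencyCollection], np.ndarray]:
    """Discretized collections per method plus the model's predicted classes."""
    config = config or SaliencyConfig()
    scheme = scheme or SectorScheme.garway_heath()
    mask_sets = [
        build_sector_masks(ann, s.image.shape[:2], scheme)
        for s, ann in zip(samples, annotations)
    ]
    predicted = np.array([model.predicted_class(s.image) for s in samples])
    collections = {}
    for method in methods:
        entries = []
        for s, masks in zip(samples, mask_sets):
            smap = compute_map(method, model, s, config)
            entries.append(discretize_saliency(smap, masks, tau))
        collections[method] = DiscreteSaliencyCollection(
            entries=entries, model_id=model.model_id, method=method
        )
    return collections, predicted


# ---------------------------------------------------------------------------
# Desk-scale experiments


@dataclass
class RandomizationExperiment:
    """Outcome of the trained-vs-reinitialized agreement ceiling."""

    report: SanityReport
    n_test_images: int
    train_balanced_accuracy: float

    @property
    def max_abs_rho(self) -> float:
        return self.report.max_abs_parameter_rho()


def parameter_randomization_experiment(
    seed: int = 0,
    n_train_per_class: int = 50,
    n_test_per_class: int = 75,
    methods: Sequence[str] = RETAINED_METHODS,
    n_replicates: int = 5,
    generator: Optional[GeneratorConfig] = None,
    hyperparams: Optional[Hyperparams] = None,
    saliency_config: Optional[SaliencyConfig] = None,
) -> RandomizationExperiment:
    """Train the toy classifier on a separable synthetic set, then measure the
    maximum |Spearman rho| between its sector-discretized maps and those of
    freshly reinitialized copies over a held-out synthetic test set."""
    from .fixtures import balanced_accuracy  # deferred to keep import light

    root = np.random.SeedSequence(seed)
    gen_seed, train_seed, test_seed, rand_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)
    )
    generator = generator or GeneratorConfig(seed=gen_seed)
    train_samples, _, _ = generate_dataset(
        GeneratorConfig(**{**generator.__dict__, "seed": gen_seed}), n_train_per_class
    )
    test_samples, test_annotations, _ = generate_dataset(
        GeneratorConfig(**{**generator.__dict__, "seed": test_seed}), n_test_per_class
    )
    labels = [s.label for s in train_samples]
    model = train_toy_model(train_samples, labels, hyperparams, seed=train_seed)
    preds = [model.predicted_class(s.image) for s in train_samples]
    train_bal_acc = balanced_accuracy(preds, labels)
    config = saliency_config or SaliencyConfig(seed=seed)
    report = parameter_randomization_test(
        model, test_samples, test_annotations, methods,
        config=config, n_replicates=n_replicates, seed=rand_seed,
    )
    return RandomizationExperiment(
        report=report,
        n_test_images=len(test_samples),
        train_balanced_accuracy=train_bal_acc,
    )


@dataclass
class PlantedSignalExperiment:
    """Outcome of one planted rim-loss recovery replicate."""

    relevance: RelevanceTable
    modal_sector: Optional[str]
    test_balanced_accuracy: float


def planted_rim_loss_experiment(
    seed: int = 0,
    sector: str = "TI",
    method: str = "Occl",
    n_train_per_class: int = 100,
    n_test_per_class: int = 30,
    rim_loss_strength: float = 0.9,
    cdr_range: tuple[float, float] = (0.4, 0.5),
    hyperparams: Optional[Hyperparams] = None,
) -> PlantedSignalExperiment:
    """Plant sector-localized rim loss as the *only* class difference and ask
    whether the saliency method's global relevance for glaucoma-predicted
    images is modal in the planted sector.

    Both classes share the same CDR range; glaucomatous samples differ only
    by the eccentric cup displacement toward ``sector``.
    """
    from .fixtures import balanced_accuracy
    from .relevance import argmax_sector

    root = np.random.SeedSequence(seed)
    gen_seed, train_seed, test_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)
    )
    def config(s):
        return GeneratorConfig(
            seed=s,
            healthy_cdr_range=cdr_range,
            glaucoma_cdr_range=cdr_range,
            rim_loss_sector=sector,
            rim_loss_strength=rim_loss_strength,
        )

    train_samples, _, _ = generate_dataset(config(gen_seed), n_train_per_class)
    test_samples, test_annotations, _ = generate_dataset(config(test_seed), n_test_per_class)
    labels = [s.label for s in train_samples]
    model = train_toy_model(train_samples, labels, hyperparams, seed=train_seed)
    test_preds = [model.predicted_class(s.image) for s in test_samples]
    test_bal_acc = balanced_accuracy(test_preds, [s.label for s in test_samples])
    collections, predicted = compute_discrete_collections(
        model, test_samples, test_annotations, [method], config=SaliencyConfig(seed=seed)
    )
    table = global_relevance(collections[method].entries, predicted,
                             method=method, model_id=model.model_id)
    if "glaucoma" in table.probabilities.index:
        modal = table.probabilities.loc["glaucoma"].idxmax()
    else:
        modal = None
    return PlantedSignalExperiment(
        relevance=table, modal_sector=modal, test_balanced_accuracy=test_bal_acc
    )
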