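"""Pairwise method agreement and the parameter-randomization sanity check.

Sector-discretized maps of several methods over a small test set are
flattened to 7-per-image vectors and compared with Spearman's rank
correlation. The same machinery then compares the trained model against a
freshly reinitialized (untrained) copy: a method whose maps barely change
under weight randomization would be useless as an explanation.
"""

from discsal import GeneratorConfig, generate_dataset, train_toy_model
from discsal.agreement import pairwise_agreement, parameter_randomization_test, summarize
from discsal.pipeline import compute_discrete_collections
from discsal.saliency import SaliencyConfig

train, _, _ = generate_dataset(GeneratorConfig(seed=13), n_per_class=50)
model = train_toy_model(train, [s.label for s in train], seed=3)
test, annotations, _ = generate_dataset(GeneratorConfig(seed=17), n_per_class=15)

methods = ["Grad", "IGrad", "Occl", "GCam"]
collections, _ = compute_discrete_collections(
    model, test, annotations, methods, SaliencyConfig(seed=0)
)

results = pairwise_agreement({"toy-model": collections}, kind="methods")
print("pairwise Spearman agreement between methods (30 test images):")
for r in sorted(results, key=lambda r: -r.rho):
    a, b = (p.split(":")[1] for p in r.pair)
    print(f"  {a:6s} vs {b:6s}  rho={r.rho:+.3f}  (n={r.n_elements})")
print("summary:", {k: round(v, 3) for k, v in summarize(results).items()})

report = parameter_randomization_test(
    model, test, annotations, methods, config=SaliencyConfig(seed=0),
    n_replicates=2, seed=5,
)
print("\ntrained vs reinitialized copies (2 replicates):")
for method, rhos in report.parameter_rho.items():
    print(f"  {method:6s} " + "  ".join(f"{r:+.3f}" for r in rhos))
print("\nLow |rho| here is the desired outcome: the maps depend on learned weights.")
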