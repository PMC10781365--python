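"""Discretize a saliency map into the seven optic-disc sector scores.

The disc is split into the six clinical sectors (temporal T, temporal
superior TS, nasal superior NS, nasal N, nasal inferior NI, temporal
inferior TI) plus background B. A saliency map is thresholded at 75% of its
maximum and each sector's score is the fraction of retained pixels it
contains; the seven scores always sum to 1.
"""

from discsal import GeneratorConfig, generate_dataset, train_toy_model
from discsal.saliency import SaliencyConfig, occlusion_map
from discsal.sectors import SECTOR_ORDER, build_sector_masks, discretize_saliency

samples, annotations, _ = generate_dataset(GeneratorConfig(seed=13), n_per_class=50)
model = train_toy_model(samples, [s.label for s in samples], seed=3)

sample, annotation = samples[60], annotations[60]
masks = build_sector_masks(annotation, sample.image.shape[:2])
smap = occlusion_map(model, sample, SaliencyConfig(seed=0))
discrete = discretize_saliency(smap, masks, tau=0.75)

print(f"occlusion saliency of {sample.sample_id} ({sample.laterality}), "
      f"threshold {discrete.threshold:.2f} x max")
for sec in SECTOR_ORDER:
    bar = "#" * int(round(discrete.scores[sec] * 40))
    print(f"  {sec:2s} {discrete.scores[sec]:6.3f} {bar}")
print(f"  sum {sum(discrete.scores.values()):.3f}")
print("\nEach score is the share of top-quartile saliency pixels inside that sector.")
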