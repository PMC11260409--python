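"""Augment an annotated image and split a dataset 9:1.

Each original image yields exactly three derivatives — translated,
rotated, affine-transformed — with the transform returned so annotation
masks can be warped identically (order=0 keeps them boolean).
"""

import numpy as np

from voidspot import synthetic as syn

config = syn.SceneConfig(
    height=120, width=160, rng_seed=1,
    spots=(syn.SpotSpec(center=(60, 80), final_radius=18),),
)
image, truth = syn.render_image(config)
mask = truth.spots[0].final_mask

derivatives = syn.augment(image, rng_seed=5)
print(f"{len(derivatives)} derivative images from one original")
for name, (derived, tf) in zip(("translated", "rotated", "affine"), derivatives):
    warped_mask = syn.apply_transform(mask, tf, order=0)
    print(f"  {name:10s}: mask {mask.sum()} px -> {warped_mask.sum()} px after the same transform")

items = [f"img_{i:03d}" for i in range(40)]
train, val = syn.split_dataset(items, ratio=0.9, rng_seed=0)
print(f"dataset of {len(items)} images split {len(train)}:{len(val)} (train:validation)")
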