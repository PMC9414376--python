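"""Build aroma digital fingerprints: Z-score + PCA -> 128x128 RGB images.

Each image encodes a block of up to 100 recordings: the first three
principal-component scores of each recording become the R, G, B color of
one cell in a 10x10 mosaic, min-max scaled per channel over the block.
"""

import tempfile
from pathlib import Path

import numpy as np

from enosekit import (
    SimulationConfig,
    StableWindow,
    build_fingerprint_library,
    default_profiles,
    default_sensor_array,
    extract_stable_window,
    generate_dataset,
    pca_fit,
    subdivide_and_average,
    zscore_apply,
    zscore_fit,
)

dataset = generate_dataset(
    default_profiles(), 10, default_sensor_array(), SimulationConfig(), seed=3
)
fvs = [
    subdivide_and_average(extract_stable_window(m, StableWindow(500, 1500)), 8)
    for m in dataset
]
X = np.vstack([f.values for f in fvs])

norm = zscore_fit(X)
pca = pca_fit(zscore_apply(X, norm), 3)
ratios = pca.explained_variance_ratio()
print("variance explained by PC1-3: " + ", ".join(f"{r:.1%}" for r in ratios))

out = Path(tempfile.mkdtemp(prefix="fingerprints_"))
manifest = build_fingerprint_library(
    X, [f.label for f in fvs], [f.source_id for f in fvs], pca, norm, out
)
print(f"{manifest['n_images']} fingerprint PNGs written to {out}")
for entry in manifest["images"][:3]:
    print(f"  {entry['label']:12s} -> {entry['file']} ({len(entry['source_ids'])} samples)")
# Each origin's 10 recordings occupy one block; the image is its stored,
# comparable aroma signature.
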