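"""Stain-unmixing round trip on a rendered tile.

Renders an RGB tile from known hematoxylin/eosin concentration fields
(Beer-Lambert), then estimates the stain basis from the tile alone and
recovers the hematoxylin plane.  The correlation with the true field
shows how faithful the unmixing is.
"""

import numpy as np

from pleoscore import stain
from pleoscore.synthetic import default_stain_basis, render_he

rng = np.random.default_rng(3)
h_true = rng.uniform(0.05, 1.5, size=(64, 64))
e_true = rng.uniform(0.05, 1.5, size=(64, 64))
rgb = render_he(h_true, e_true, default_stain_basis())

od = stain.rgb_to_od(rgb)
basis = stain.estimate_stain_basis(od)
h_rec = stain.extract_h_channel(od, basis)

corr = np.corrcoef(h_true.ravel(), h_rec.ravel())[0, 1]
print(f"estimated H direction: {np.round(basis.h_vector, 3)}")
print(f"estimated E direction: {np.round(basis.e_vector, 3)}")
print(f"Pearson correlation true vs recovered H field: {corr:.4f}")
print("\nValues near 1 mean chromatin intensity downstream reflects the")
print("actual hematoxylin uptake, not color mixing artifacts.")
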