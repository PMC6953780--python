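"""Segment a synthetic 4-block image with hierarchical-histogram thresholding.

Builds a seeded fixture (four color blocks, sigma=4 Gaussian noise), runs the
full pipeline at the standard settings (w=15, T_n=0.1%, T_d=20) and prints
the recovered cluster table next to the generating palette.
"""

import numpy as np

from ahht import segment_ahht
from ahht.synthetic import make_block_image

fx = make_block_image(k=4, size=(96, 128), noise_sigma=4.0, seed=7)
seg = segment_ahht(fx.image, w=15.0, T_n=0.001, T_d=20.0)

print(f"initial colors: {seg.provenance['initial_colors']}")
print(f"final clusters: {seg.n_clusters}")
print(f"{'cluster':>7} {'pixels':>7}  mean RGB            nearest palette color")
for row in seg.cluster_table():
    mean = np.array([row["mean_R"], row["mean_G"], row["mean_B"]])
    nearest = tuple(
        int(v)
        for v in fx.palette[
            np.argmin(np.sqrt(((fx.palette.astype(float) - mean) ** 2).sum(axis=1)))
        ]
    )
    print(
        f"{row['id']:>7} {row['count']:>7}  "
        f"({mean[0]:6.2f}, {mean[1]:6.2f}, {mean[2]:6.2f})  {nearest}"
    )
print(
    "\nEach cluster mean should sit within a few intensity units of one "
    "palette color:\nthe thresholder has recovered the generating blocks "
    "despite the pixel noise."
)
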