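"""Watch the hierarchical histogram collapse a noisy two-mode channel.

The red plane of the image holds two intensity modes (40 and 200); each
hierarchy level merges the bell-shaped regions between valleys into wider
bins until nothing changes.  The top level is what the segmenter thresholds
the plane with.
"""

import numpy as np

from ahht import build_hierarchical_histogram

rng = np.random.default_rng(0)
vals = np.concatenate(
    [
        np.clip(rng.normal(40, 4, 1600), 28, 52),
        np.clip(rng.normal(200, 4, 1600), 188, 212),
    ]
)
img = np.zeros((40, 80, 3), dtype=np.uint8)
img[:, :, 0] = np.floor(vals + 0.5).reshape(40, 80)

hh = build_hierarchical_histogram(img, w=15.0)
print(f"merge budget w_R = {hh.w_i['R']:.3f} intensity units")
for level in hh.levels["R"]:
    populated = [b for b in level.bins if b.count > 0]
    desc = ", ".join(
        f"(n={b.count}, l={b.rep_intensity}, lR={b.right_endpoint})"
        for b in populated[:6]
    )
    more = "" if len(populated) <= 6 else f" ... {len(populated)} bins total"
    print(f"level {level.level}: {len(populated):3d} populated bins  {desc}{more}")
print(
    "\nAlmost all pixels end up in one dominant bin per intensity mode "
    "(reps near 40\nand 200).  Small satellite bins at mode edges can "
    "survive when a valley\npersists between them and the mode body; the "
    "region-merging stage of the\nsegmenter absorbs those at segmentation "
    "time."
)
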