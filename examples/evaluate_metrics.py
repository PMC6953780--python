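"""Score a segmentation with the internal and ground-truth metrics.

Segments a noisy block fixture, then evaluates the quantized result against
the original image (MSE, F, Q) and against the known block partition
(PRI, VOI, GCE, BDE).
"""

from ahht import evaluate, segment_ahht
from ahht.synthetic import make_block_image

fx = make_block_image(k=4, size=(96, 128), noise_sigma=4.0, seed=7)
seg = segment_ahht(fx.image)
report = evaluate(fx.image, seg.quantized, ground_truths=[fx.truth])

print(f"MSE  = {report.mse:8.4f}   mean per-pixel color error vs. the original")
print(f"F    = {report.f_measure:8.4f}   region-residual penalty (Liu-Yang)")
print(f"Q    = {report.q_measure:8.4f}   refined penalty incl. small regions (Borsotti)")
print(f"PRI  = {report.pri:8.4f}   pairwise label agreement with truth (1 = perfect)")
print(f"VOI  = {report.voi:8.4f}   information distance to truth in bits (0 = perfect)")
print(f"GCE  = {report.gce:8.4f}   refinement inconsistency (0 = one refines the other)")
print(f"BDE  = {report.bde:8.4f}   mean boundary displacement in pixels (0 = aligned)")
print(
    "\nMSE stays near the noise level (the quantized colors sit at the block "
    "means)\nwhile the external metrics hit their ideal values: the recovered "
    "partition\nmatches the generating blocks exactly."
)
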