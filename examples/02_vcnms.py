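"""Vegetation-Cover-Aware NMS versus greedy NMS on pathological proposals.

Generates a scene plus a detector-style proposal set (nested duplicate
crops and high-confidence multi-plant union boxes), runs both suppression
algorithms and prints how many boxes each keeps and how well they match
the ground truth.
"""

import warnings

from greenprompt import (
    ProposalConfig,
    SceneConfig,
    VcnmsConfig,
    generate_proposals,
    generate_scene,
    greedy_nms,
    match,
    vc_nms,
)

warnings.simplefilter("ignore")
scene = generate_scene(SceneConfig(n_plants=6, seed=11))
proposals = generate_proposals(scene, ProposalConfig(seed=11))
print(f"{scene.n_plants} plants, {len(proposals)} detector proposals")

for name, result in (
    ("VC-NMS", vc_nms(scene.image, proposals, VcnmsConfig())),
    ("greedy", greedy_nms([b for b in proposals if b.score >= 0.1])),
):
    table = match(result.kept, scene.gt_boxes, 0.5)
    print(f"{name:7s} kept {len(result.kept):2d} boxes -> "
          f"TP {table.tp}, FP {table.fp}, missed plants {table.fn}")
# VC-NMS keeps one box per plant: union boxes are wiped by the
# overlap-count attenuation and nested crops by the RIoU-Gaussian decay.
# Greedy NMS trusts the area-biased confidences and keeps union boxes,
# which cover two plants each and match neither at IoU 0.5.

reasons = {}
for s in vc_nms(scene.image, proposals, VcnmsConfig()).suppressed:
    reasons[s.reason] = reasons.get(s.reason, 0) + 1
print("VC-NMS suppression reasons:", dict(sorted(reasons.items())))
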