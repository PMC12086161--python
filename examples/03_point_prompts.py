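"""Similarity-map base points and max-distance enhanced points.

Takes the boxes VC-NMS keeps, selects the highest-composite-score box as
the reference plant, and builds a 2-positive / 2-negative prompt set per
box: base points from the cosine-similarity map against the pooled
reference features, enhanced points at the farthest foreground/background
pixel from the base points.
"""

import warnings

from greenprompt import (
    MockEmbedder,
    ProposalConfig,
    SceneConfig,
    generate_prompt_sets,
    generate_proposals,
    generate_scene,
    vc_nms,
)

warnings.simplefilter("ignore")
scene = generate_scene(SceneConfig(n_plants=4, seed=13))
kept = vc_nms(scene.image, generate_proposals(scene, ProposalConfig(seed=13))).kept

prompt_sets = generate_prompt_sets(
    scene.image, [(b, b.score) for b in kept], MockEmbedder(), n_pos=2, n_neg=2
)
for ps in prompt_sets:
    b = ps.box
    print(f"box {b.id} at ({b.x_min:.0f},{b.y_min:.0f})-"
          f"({b.x_max:.0f},{b.y_max:.0f})  composite score {ps.y_n:.3f}")
    for p in ps.points:
        print(f"    {p.label:8s} {p.kind:8s} at ({p.x}, {p.y})")
# Positive points sit on the plant (base: most reference-like pixel;
# enhanced: farthest vegetation pixel from it), negative points in the
# substrate - together they spread the cues over the whole box instead of
# clustering, which is what a promptable segmenter needs.
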