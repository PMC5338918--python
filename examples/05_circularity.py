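"""Tissue-boundary circularity as a smoothness / tension proxy.

Traces the placode boundary of a scene whose rim is smoothed (emulating
the supracellular actomyosin cable) and compares its circularity
C = 4*pi*area/perimeter^2 with the boundaries shifted one cell layer
outward and inward.
"""

from placodekit import (SceneConfig, generate_scene, shift_boundary,
                        trace_placode_boundary)

cfg = SceneConfig(n_cells=80, surround_layers=2, smooth_boundary=True,
                  seed=7)
scene = generate_scene(cfg)
lab = scene.label_image
px = cfg.pixel_size

placode = trace_placode_boundary(lab, scene.placode_ids, px)
outer = shift_boundary(lab, scene.placode_ids, "outer", px)
inner = shift_boundary(lab, scene.placode_ids, "inner", px)

for tr in (placode, outer, inner):
    print(f"{tr.which:8s}: perimeter {tr.perimeter:6.1f} µm, "
          f"area {tr.area:7.1f} µm², C = {tr.circularity:.3f}")
# The smooth placode rim approaches C = 1; the one-cell-layer shifted
# boundaries follow jagged cell outlines and score markedly lower --
# the signature of a taut boundary cable.
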