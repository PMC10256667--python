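"""Two-condition contrast: uptake intensity ratio and network density.

Generates a matched pair of scenes emulating passive vs receptor-mediated
uptake — condition 2 carries a three-fold nanoparticle amplitude, a higher
co-localized fraction and a denser network — and recovers the contrast
from the images alone.
"""

from lipnet import (
    SceneParams,
    cytoplasm_intensity,
    estimate_background,
    fold_change,
    generate_condition_pair,
    segment_cells,
)

params = SceneParams(
    image_size=576, n_cells=20, network_branch_target=8,
    intensity_ratio=3.0, cell_radius_px=34.0, snr=10.0, seed=4,
)
(img1, truth1), (img2, truth2) = generate_condition_pair(params)

means = []
for img in (img1, img2):
    seg = segment_cells(img, "nucleus", "clld", smooth_sigma=1.5)
    bg = estimate_background(img.channels["aunc"], seg.cell_labels > 0)
    means.append(
        [cytoplasm_intensity(img.channels["aunc"], seg.cytoplasm_mask(i))[0] - bg
         for i in range(seg.n_cells)]
    )

ratio, lo, hi = fold_change(means[0], means[1], seed=params.seed)
b1 = sum(len(g.edges) for g in truth1.true_skeletons)
b2 = sum(len(g.edges) for g in truth2.true_skeletons)

print(f"cells per condition: {len(means[0])} vs {len(means[1])}")
print(f"recovered intensity fold change: {ratio:.2f} (95% CI {lo:.2f}-{hi:.2f}); generated: 3.0")
print(f"true network branches, condition 1 vs 2: {b1} vs {b2}")
print(
    "\nThe fold change is estimated from background-subtracted cytoplasm means "
    "of segmented\ncells only — the generated 3x amplitude contrast is "
    "recovered from the images."
)
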