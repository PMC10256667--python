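"""Intensity profile along a line through one cell.

Samples every channel on the Bresenham path between two points — the
single-cell view used to show whether probe peaks coincide with tracer
peaks along a transect.
"""

import numpy as np

from lipnet import SceneParams, generate_scene, line_profile

image, truth = generate_scene(SceneParams(image_size=256, n_cells=1, seed=5,
                                          cell_radius_px=60.0, coloc_fraction=0.8))
rows, cols = np.nonzero(truth.cell_labels == 1)
p0 = (int(rows.min()), int(np.median(cols)))
p1 = (int(rows.max()), int(np.median(cols)))

prof = line_profile(image, p0, p1, channels=["clld", "aunc"])
print(f"line {p0} -> {p1}: {prof.distances.size} samples")
peak_clld = prof.distances[np.argmax(prof.intensities["clld"])]
peak_aunc = prof.distances[np.argmax(prof.intensities["aunc"])]
print(f"tracer peak at {peak_clld:.1f} px, nanoparticle peak at {peak_aunc:.1f} px")
head = ", ".join(
    f"({d:.0f}px: clld={c}, aunc={a})"
    for d, c, a in list(zip(prof.distances, prof.intensities["clld"],
                            prof.intensities["aunc"]))[::20]
)
print("every 20th sample:", head)
print("\nCoincident peaks along the transect indicate probe signal sitting on "
      "labeled structures.")
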