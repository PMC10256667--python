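# lipnet

Single-cell image analysis for fluorescence studies of nanoparticle uptake:
co-localization quantification between a nanocluster channel and a membrane
marker or lipophilic tracer, line-intensity profiling, cytoplasm-gated
intensity quantification with condition fold changes, and an *intracellular
branched network analysis* (IBNA) that measures how the membrane-bound
organelle network of a cell is organized. A seeded synthetic scene
generator provides exact ground truth for every stage, so each measurement
can be validated against known answers.

The package is aimed at microscopists and image analysts who quantify
multi-channel confocal images of cultured cells (e.g. a nuclear stain, a
lipophilic tracer dye such as a dialkylcarbocyanine, an antibody channel
such as MT1-MMP, and a fluorescent nanoparticle probe) and want these
measurements reproducible and scripted rather than produced interactively.

## The statistics at the core

For two intensity channels $A$ and $B$ over a set of analyzed pixels (the
whole image or a gated region):

* **slope / intercept** — ordinary least squares of $B$ on $A$, the
  regression line of the two-channel scatter plot.
* **automatic thresholds** — a Costes-style search: candidate thresholds
  $t_A$ step downward through the distinct intensities of $A$ with
  $t_B = \mathrm{slope}\cdot t_A + \mathrm{intercept}$, stopping at the
  highest $t_A$ for which the pixels *outside* the co-localized quadrant
  (i.e. $A \le t_A$ or $B \le t_B$) are uncorrelated
  ($r_\text{below} \le 0$).
* **Rcoloc** — Pearson correlation restricted to pixels with $A > t_A$ and
  $B > t_B$ (undefined, and reported as `null`, when that quadrant has
  fewer than two pixels or zero variance).
* **Ncoloc** — the number of such pixels; **%Volume** — $100\cdot$ Ncoloc /
  (pixels analyzed).

For the network analysis, the tracer channel of a cell is binarized and
thinned to a unit-width skeleton; every skeleton pixel is classified by its
8-neighbor count (end-point $\le 1$, slab $= 2$, junction $> 2$); junction
pixels group into 8-connected components ("actual junctions"); branches are
the maximal slab paths between nodes, with Euclidean step lengths (1 or
$\sqrt 2$ per step). Multi-cell fields are normalized per cell by dividing
all counts by the number of cells.

## Worked example

```python
from lipnet import (SceneParams, generate_scene, coloc_report,
                    analyze_network, truth_network_metrics)

params = SceneParams(image_size=256, n_cells=1, network_branch_target=24,
                     tubule_width_px=3, cell_radius_px=100.0, puncta_count=0,
                     aunc_dot_count=0, branch_len_min=20, branch_len_max=36,
                     coloc_fraction=0.0, snr=10.0, seed=3)
image, truth = generate_scene(params)

metrics, graph, classes, skeleton = analyze_network(
    image.channels["clld"], mask=truth.cytoplasm_masks[0],
    smooth_sigma=1.2, min_object_px=9, fill_holes_px=12,
    prune_px=4, junction_merge_px=4)

expected = truth_network_metrics(truth, 0)
print("branches:  measured", metrics.n_branches, "truth", expected.n_branches)
print("junctions: measured", metrics.n_actual_junctions, "truth", expected.n_actual_junctions)
```

prints

```
branches:  measured 24 truth 24
junctions: measured 11 truth 11
```

i.e. the pixel-level measurement recovers the generator's branch graph
exactly on this seed: the cell's lipophilic network had 24 branches meeting
at 11 junction points, and the binarize → skeletonize → classify → graph
census found the same numbers in the rendered, noisy image. The
`examples/` directory contains one short script per capability
(simulation, co-localization, line profiles, IBNA, condition contrast),
each printing the numbers it computes and what they mean.

A thin command-line interface mirrors the library:

```bash
lipnet run --config my_run.yaml          # config-driven end-to-end pipeline
lipnet coloc --image img.tif --channels nucleus,clld,mt1mmp,aunc \
             --ch-a aunc --ch-b clld --out report.json
lipnet ibna  --image img.tif --channels nucleus,clld,mt1mmp,aunc \
             --channel clld --out metrics.json --render skeleton.png
```

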