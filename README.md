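# obcacount

Object-based colocalized cell counting for multiplex fluorescence
microscopy.

Tissue sections stained for a nuclear marker (DAPI) and one or two immune
markers (CD4, CD8, CD20, CD68, IBA1, ...) are routinely quantified by
counting *colocalized cells* — cells co-expressing a nucleus and a marker
that, being nuclear vs. cytoplasmic, need not overlap in space.  Manual
counting is the accepted gold standard but slow and operator-dependent.
`obcacount` implements the two computational alternatives as one tested
library:

* **Automated pipeline** — per channel: polynomial illumination
  correction, global three-class Otsu segmentation (foreground above the
  upper threshold t₂), connected-component labeling, shrink-to-centroid,
  then expansion of every centroid to a disk of radius *r* = 5 px; a
  nucleus is colocalized iff its disk shares a pixel with a marker disk
  (effective centroid-distance criterion ≈ 2*r*).
* **Semi-automated method** — per channel: Gaussian pre-blur (σ =
  `pre_blur_radius`), detection of 2D maxima whose **prominence** (peak
  height minus the highest saddle to any strictly higher region) exceeds
  the `noise_tolerance`, scripted point edits standing in for the
  observer's corrections, then overlay disks of per-category radius
  (default 50 px; 30 px for hard morphologies): points are colocalized iff
  their distance ≤ r₁ + r₂.

Counts are reported per category (1 = nuclear, 2/3 = markers) and for the
combined categories 12 / 123 (a nucleus counts once if it has a partner in
every marker channel).

The package also ships a seeded **synthetic scene generator** (round
"easy" cells and fragmented "hard" macrophage-like markers, controllable
colocalized fraction, Gaussian noise, illumination gradients) with exact
ground truth, and the **method-comparison statistics** used in counting
studies: correlation R², two-sided paired t-tests, and overcounting ratios
(method/reference, 0/0 excluded as undefined).

## Worked example

```python
from obcacount import SceneSpec, generate_scene, run_automated_pipeline, run_semiauto_pipeline
from obcacount.maxima import MaximaConfig

spec = SceneSpec(n_nuclei=50, coloc_fraction=0.5, seed=7)   # 512x512 field
scene = generate_scene(spec)
print("ground truth colocalized cells:", scene.n_coloc_truth)

auto = run_automated_pipeline(scene.channels, field_id="demo", marker="CD4")
print("automated:      cat1 =", auto.n_per_category[1],
      " cat2 =", auto.n_per_category[2], " n_coloc =", auto.n_coloc)

cfg = MaximaConfig(pre_blur_radius=2.0, noise_tolerance=60.0)
semi = run_semiauto_pipeline(scene.channels, [cfg, cfg], field_id="demo", marker="CD4")
print("semi-automated: cat1 =", semi.n_per_category[1],
      " cat2 =", semi.n_per_category[2], " n_coloc =", semi.n_coloc)
```

prints

```
ground truth colocalized cells: 25
automated:      cat1 = 50  cat2 = 50  n_coloc = 25
semi-automated: cat1 = 50  cat2 = 50  n_coloc = 50
```

Both methods detect all 50 nuclei and all 50 marker objects (25 true
co-expressions within 3 px of their nucleus plus 25 decoys placed > 15 px
from every nucleus).  The automated criterion (disk overlap within 2x5 px)
counts exactly the 25 true pairs.  The semi-automated count of 50 is the
honest consequence of the default 50 px overlay radius: overlays reach
r₁ + r₂ = 100 px, so decoy markers near (but not on) a nucleus also
overlap — in practice the observer removes such detections (pass an edit
list), shrinks the radii (`ColocConfig(mode="overlay",
overlay_radius={1: 10.0, 2: 10.0})` gives n_coloc = 27 here), or relies on
the automated criterion for tight colocalization.

On a noisy variant (`scene.with_noise(25.0, seed=1)`) the semi-automated
count is unchanged (50) while the automated pipeline, which by design runs
on unprocessed images, explodes to 464 from noise specks — restored to 25
with `SegmentationConfig(min_area=5)`.  That asymmetry (semi-automated
counts stable under noise, automated counts inflated without filtering) is
the expected behavior for these two method families.

The same runs are available from a shell:

```sh
obcacount synth --n-nuclei 50 --coloc-fraction 0.5 --seed 7 --out-dir scene/
obcacount auto --nuclear scene/nuclear.tif --marker scene/marker.tif --out counts.csv
obcacount semi --nuclear scene/nuclear.tif --marker scene/marker.tif \
    --pre-blur 2 --noise-tolerance 60 --out counts.csv
```

## Layout

```
src/obcacount/
  containers.py    ChannelImage, CompositeImage, LabelMap, PointSet, ColocResult
  image_io.py      TIFF/PNG channels, 16-bit conversion, contrast, count tables
  preprocess.py    quadratic illumination surface fit and correction
  segmentation.py  multi-class Otsu thresholds, object labeling, centroids
  maxima.py        pre-blur, prominence maxima, point editing
  colocalize.py    both colocalization criteria + the two pipelines
  synth.py         seeded scene generator and the degraded-image panel
  stats.py         R², paired t, overcounting ratios, evaluation harness
  cli.py           `obcacount` command-line interface
```

See `docs/methods.md` for the model conventions, parameter defaults and
known limitations.
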