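# fcmgwo — nucleus segmentation by fuzzy c-means with grey-wolf refinement

Delineating cell nuclei in stained cytology smears is a prerequisite for
computer-aided cancer diagnosis: most morphological signs of malignancy live
in the nucleus, yet in grayscale the nucleus competes with other dark objects
(cytoplasm edges, red blood cells) for the same intensity band.  `fcmgwo`
segments such images by unsupervised intensity clustering, for image-analysis
practitioners and biostatisticians who need a ground-truth-free pipeline that
is reproducible end to end.

## Method

Pixels are clustered with **fuzzy c-means (FCM)**, which minimizes

$$J_m=\sum_{i=1}^{n}\sum_{j=1}^{c} u_{ij}^{\,m}\,\lVert x_i-c_j\rVert^2,\qquad m>1,$$

by alternating the classical closed-form membership and center updates.  FCM
is sensitive to initialization and can stall in local optima of $J_m$, so a
**grey wolf optimizer (GWO)** then refines the centers: one wolf is placed
exactly at the FCM solution, the rest uniformly in the search box
$[0,225]^c$, and the pack moves toward its three best members (alpha, beta,
delta) through the stochastic encircling equations
$\vec D=\lvert\vec C\circ\vec X_{p}-\vec X\rvert$,
$\vec X(t{+}1)=\vec X_p-\vec A\circ\vec D$ with
$\vec A = 2a\vec r_1-a$, $\vec C=2\vec r_2$ and $a$ decaying linearly from 2
to 0.  The fitness of a candidate center set is $J_m$ with memberships
re-derived optimally, so GWO minimizes exactly the quantity FCM does; because
the FCM solution seeds the pack and leaders are elitist, the hybrid objective
is **never worse than plain FCM's**.

For three clusters the darkest center is called *nucleus*, the middle
*cytoplasm*, the brightest *background*.  Segmentations are scored with four
cluster-validity indices — partition coefficient $V_{pc}$, partition entropy
$V_{pe}$, Davies–Bouldin and Calinski–Harabasz — and two methods are
compared across images with a paired Student-*t* test per index (after a
Shapiro–Wilk normality check of the paired differences).

Because real smears have no pixel-level ground truth, the package ships a
synthetic generator (dark nucleus disks inside cytoplasm halos on a bright
background, additive Gaussian noise, exact label masks) so every stage is
testable with known answers.

## Worked example

```python
import numpy as np
from fcmgwo import (FcmConfig, GwoConfig, SegmentationConfig, SyntheticSpec,
                    generate_cell_image, run_fcmgwo, labels_from_memberships,
                    segmentation_accuracy, assign_tissue_classes)

img, truth = generate_cell_image(SyntheticSpec(seed=0))   # 400x300, 3 levels
cfg = SegmentationConfig(fcm=FcmConfig(seed=0), gwo=GwoConfig(seed=0))
res = run_fcmgwo(img.reshape(-1, 1).astype(float), cfg)

print("FCM objective:    %.1f" % res.fcm_result.objective)
print("Hybrid objective: %.1f" % res.objective)
print("Centers:", np.round(np.sort(res.centers.ravel()), 2))
print("Tissue map:", assign_tissue_classes(res.centers))
labels = labels_from_memberships(res.memberships).reshape(img.shape)
print("Accuracy: %.4f" % segmentation_accuracy(labels, truth))
```

prints

```
FCM objective:    7700039.7
Hybrid objective: 7700039.7
Centers: [ 40.21 129.95 219.99]
Tissue map: {0: 'nucleus', 1: 'cytoplasm', 2: 'background'}
Accuracy: 1.0000
```

The generator paints class mean intensities 40 / 130 / 220 with noise
σ = 8; the recovered centers land within 0.25 of those means, every pixel is
assigned to its true class, and the hybrid objective matches FCM's here
because FCM already reached the global optimum — the guarantee is that the
hybrid can only improve on it.

There is also a CLI:

```sh
fcmgwo synth --seed 3 --out-image img.png --out-mask mask.png
fcmgwo segment --input img.png --method fcmgwo --seed 1 \
       --out-labels labels.png --out-overlay overlay.png --report report.json
fcmgwo compare --images imgdir/ --report table.json
```

`segment` writes the per-pixel labels, an overlay with nuclei in red and
cytoplasm in yellow, and a JSON report (objective, centers, pixel counts,
validity indices).  `compare` emits the per-index paired-*t* table (t, df,
p) for FCM vs FCM-GWO over a directory of images.

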