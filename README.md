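# measurenet

A self-contained toolkit for **image-based digital anthropometry**: it
studies whether a person's body circumferences — and the waist-to-hip ratio
(WHR), one of the strongest shape biomarkers for cardiometabolic risk — can
be recovered from a few segmented body images plus height, weight and sex.
Everything is synthetic and license-free: the package generates its own 3D
bodies, measures them with a virtual tape measure, renders multi-view
segmentation images, trains a convolutional multi-task regressor, and
evaluates accuracy, repeatability and agreement with the statistics used in
clinical measurement studies.

It is aimed at researchers prototyping anthropometric estimation pipelines
who do not have access to licensed statistical body models, laser-scan
libraries or participant data.

## What is inside

| Stage | Module | Idea |
|---|---|---|
| Body model | `measurenet.body_model` | Generalized-cylinder bodies whose six named circumferences (hip, waist, chest, thigh, calf, bicep) are analytic: `shape_from_measurements` inverts Ramanujan's ellipse-perimeter formula, `build_mesh` realizes them as closed labeled meshes within ~0.1% |
| Population | `measurenet.body_model` | Sex-specific marginals + Gaussian copula; cohorts via mixture fit (BIC-selected k) and self-normalized importance sampling toward a target population |
| Tape measure | `measurenet.tape_measure` | Plane slicing + 2D convex-hull perimeter (a taut tape bridges concavities); six named planes and a 112-ring dense profile; WHR = waist/hip |
| Capture | `measurenet.render` | Pinhole cameras in a ±15° orientation box with head-to-knees validity, z-buffered rasterization of part labels (23 classes) |
| Regressor | `measurenet.network` | Per-view residual backbones with squeeze-excitation and Swish, body-centric cropping, a width-profile pooling branch, residual trunk + self-attention, heads for dense rings, named circumferences, WHR regression + classification; uncertainty-weighted multi-task loss `Σ L_i/w_i + log(1+w_i)` with learned `w_i`; WHR ensemble = mean(regression, class-expectation, waist/hip) |
| Statistics | `measurenet.evaluation` | MAE, MAPE, P90, session repeatability, symmetrized-difference noise σ with Gaussian fit, Bland–Altman limits of agreement |

The trainer runs on a compact numpy reverse-mode autodiff engine
(`measurenet.autodiff`) that is finite-difference-checked in the test suite;
no GPU or deep-learning framework is required.

## Worked example

```python
import numpy as np
from measurenet import (default_population, sample_cohort, build_mesh,
                        named_measurements)

# one synthetic subject from the default male population
subject = sample_cohort(default_population("male"), n=1, seed=7)[0]
mesh = build_mesh(subject.params)
ms = named_measurements(mesh, dense=True)
print({k: round(v, 1) for k, v in ms.named.items()}, round(ms.whr, 3))
```

prints (seed 7):

```
{'hip': 984.8, 'waist': 942.3, 'chest': 997.6, 'thigh': 512.2,
 'calf': 386.4, 'bicep': 284.7} 0.957
```

— the tape-measured circumferences (mm) of the generated mesh and its WHR,
which match the requested measurement vector to within 0.1% and serve as
exact ground truth for training. The full experiment (generate → train →
evaluate) is available from the shell:

```bash
measurenet generate -n 10 --seed 7 --sex male --save-meshes --out data/demo
measurenet train --seed 7 --sex male --out runs/demo        # ~10 min
measurenet evaluate --checkpoint runs/demo/male --n-test 50 \
    --sessions 8 --out runs/demo/eval
measurenet measure data/demo/male/subject_00000/body.obj    # standalone tape
```

`evaluate` writes a report with per-measurement MAE/MAPE/P90, session
repeatability and Bland–Altman limits; on a desk-scale training run the
held-out WHR MAE is roughly a third of the cohort's WHR spread.

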