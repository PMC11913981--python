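# spinesynth

Synthesize sagittal **T1w FSE** and **STIR** spine MRI volumes from a
sagittal **T2w FSE** plus a low-resolution axial **Dixon** fat/water pair.

Population imaging studies of the spine usually stop at T2w FSE + axial
Dixon: fast to acquire, but missing the sequences that separate fat from
free water in vertebral marrow (Modic type 1 vs 2 change, edema,
hemangioma).  `spinesynth` fills the gap with two chained 3D paired-GAN
translation networks — network 1 produces a synthetic T1w FSE from
(T2w, Dixon fat, Dixon water); network 2 produces a STIR from
(T2w, synthetic T1w) — together with everything around them:

- **Stitching** of vertically chunked whole-spine scans on a global
  bounding box, with distance-weighted overlap blending
  (`w_x = 1 − d_x/Σ d_i`) and translation-only NCC registration,
- **Preprocessing**: RIP reorientation, 1.1 mm in-plane resampling,
  [−1, 1] intensity rescaling, padding to divisible-by-8, color jitter,
- **Model**: 3D residual U-Net (conv → group norm 8 → SiLU, addition
  skips, positional-embedding channels) trained with
  `L = 10·L1 + 10·(1 − SSIM) + LSGAN`, on a small numpy autodiff engine —
  no GPU framework required at desk scale,
- **Phantom**: a deterministic multi-contrast digital spine phantom with
  controllable fat/water lesions, the shared test bed for every stage,
- **Evaluation**: per-case L1/MSE/PSNR/SSIM, cohort tables, Wilcoxon
  signed-rank comparisons,
- **Reader study**: misclassification rates, Fleiss' kappa with 99% CI and
  interpretation bands, standardized 150×150 presentation images.

See `docs/methods.md` for the model, the phantom's forward rule, and every
numerical convention.

## Worked example

Train both networks on a synthetic cohort and chain them on a held-out
subject carrying a water-rich (Modic 1) lesion:

```python
import dataclasses
from spinesynth.workflows import (make_phantom_cohort, desk_train_config,
                                  desk_generator_config, lesion_mask, DESK_PHANTOM)
from spinesynth.phantom import LesionSpec, render_study
from spinesynth.volume import rescale_intensity
from spinesynth.model import train, two_stage_infer

studies, _ = make_phantom_cohort(10, seed=1)
names = sorted(studies)
tr = {n: studies[n] for n in names[:8]}
val = {n: studies[n] for n in names[8:]}

nets = {}
for task in ("t1w", "stir"):
    nets[task] = train(tr, task, desk_train_config(task, seed=1),
                       gen_cfg=desk_generator_config(task), val_studies=val)
    h = nets[task].history
    print(task, "val L1: %.3f -> %.3f" % (h["val_l1_initial"], h["val_l1"][-1]))

spec = dataclasses.replace(DESK_PHANTOM,
                           lesions=[LesionSpec("modic1", (10, 12, 30), 3.0)], seed=99)
study = {m: rescale_intensity(v) for m, v in render_study(spec).items()}
t1w_synth, stir_synth = two_stage_infer(nets["t1w"], nets["stir"], study)
lesion, vertebra = lesion_mask(spec)
print("synthetic STIR: lesion %.2f vs vertebra %.2f"
      % (stir_synth.data[lesion].mean(), stir_synth.data[vertebra & ~lesion].mean()))
```

Output from this exact run (a few minutes on one CPU core):

```
t1w val L1: 0.637 -> 0.101
stir val L1: 0.676 -> 0.079
synthetic STIR: lesion 0.31 vs vertebra -0.31
```

Validation L1 falls an order of magnitude below its untrained value (and
below the constant-mean 0.25/0.53 and T2w-copy 0.36/0.11 baselines), and the
chained STIR renders the water-rich lesion bright against dark vertebral
marrow — the sign behaviour the whole pipeline exists to reproduce.

The same stages are scriptable from the shell:

```bash
spinesynth phantom --n 10 --out data/ --seed 7
spinesynth preprocess --in data/ --out prep/ --orientation RIP --inplane 1.1
spinesynth stitch --chunks a.nii.gz --chunks b.nii.gz --out fused.nii.gz
spinesynth train --task t1w --data data/ --out g1.npz
spinesynth chain --ckpt1 g1.npz --ckpt2 g2.npz --subject sub01/ --out synth/
spinesynth evaluate --real real/ --gen synth/ --out metrics.csv
spinesynth reader-study --ratings ratings.csv --out report/
```

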