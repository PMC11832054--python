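# mp3rage

Quantitative T1 mapping for MP2RAGE and MP3RAGE brain MRI, with
Monte-Carlo maximum-a-posteriori (MAP) estimation and uncertainty maps,
two-pool selective-inversion-recovery (SIR) reference fitting, and a
patch-based neural calibration that maps MP2RAGE-derived T1 values onto
multi-TI inversion-recovery T1 values.

## The problem

MP2RAGE acquires two (MP3RAGE: three) gradient-echo readouts per
inversion cycle and combines pairs into a "uniform" T1-weighted image

    S_ij = Re(conj(GRE_i) GRE_j) / (|GRE_i|^2 + |GRE_j|^2)  in  [-0.5, 0.5],

which is insensitive to T2*, B0 and receive sensitivity and maps
monotonically to T1 through the sequence's steady-state signal equations,
making fast high-resolution T1 mapping possible. Two practical problems
remain. First, inverting one S value per voxel gives no uncertainty and
does not generalize to three readouts, where S_12 and S_13 may disagree.
This package builds the discrete posterior

    P(T1 | S) = P(S | T1) P(T1) / P(S)

by Monte-Carlo simulation of the forward model under complex Gaussian
noise (uniform T1 prior on [0, 5] s, 100 signal bins, per-voxel B1+
correction), and reports the MAP estimate and the posterior standard
deviation sigma-T1 per voxel — for MP2RAGE (pair mode) and MP3RAGE
(joint 2-D binning). Second, MP2RAGE-derived T1 is systematically lower
than multi-TI IR T1 in brain tissue (magnetization-transfer effects the
monoexponential MP2RAGE model cannot capture): roughly 83 % of the IR
value in white matter, 89 % in subcortical and 95 % in cortical gray
matter. A small residual CNN regressor, trained on co-registered patches
with leave-one-out cross-validation over subjects, learns this
tissue-dependent correction. The IR reference itself is fit voxelwise
with a two-pool SIR model (free water + macromolecular pool, equal
relaxation rates, biexponential recovery with eigen-rates R1 and
R1 + kmf(1+psr)), reporting T1 = 1/R1f.

A seeded digital phantom (concentric tissue shells, smooth B1+ field,
simulated GREs and SIR volumes, injected tissue bias) makes every stage
testable end-to-end with no scan data. See `docs/methods.md` for the
model details, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from mp3rage import (PhantomSpec, MonteCarloConfig, mp3rage_7t_protocol,
                     map_t1_volume, relative_value_by_tissue)
from mp3rage.phantom import synth_subjects

spec = PhantomSpec(seed=1)                      # 4 subjects, 48 x 48 x 5
mc = MonteCarloConfig(n_trials=1_000_000, noise_sigma=0.005, seed=1)
subjects = synth_subjects(spec, 4, mc_cfg=mc)   # phantom -> GREs -> MAP T1
s = subjects[0]
rel = relative_value_by_tissue(s.mp2rage_biased, s.ir_truth, s.labels)
print({k: round(v, 1) for k, v in rel.items()})
```

prints

```
{'wm': 82.9, 'sgm': 89.8, 'cgm': 95.1}
```

— the per-tissue value of the (bias-injected) MAP MP2RAGE T1 map relative
to the IR ground truth for this subject: white matter is underestimated
by ~17 %, cortical gray matter by ~4 %, the discrepancy the calibration
network is trained to remove. After one fold of calibration training
(2,000 steps) the white-matter RMSE against the IR reference drops from
0.36 s to 0.11 s and the relative values return to within a few percent
of 100 %.

The same stages are scriptable from the shell:

```bash
mp3rage simulate-phantom --subjects 4 --seed 1 --out phantom/
mp3rage fit-map --gre phantom/sub-00_gre1 --gre phantom/sub-00_gre2 \
    --gre phantom/sub-00_gre3 --b1 phantom/sub-00_b1.nii.gz \
    --trials 1000000 --seed 1 --out sub00
mp3rage fit-sir --volumes phantom/sub-00_sir.nii.gz --out sub00_sir
mp3rage calibrate-cv --subjects 4 --seed 1 --out cv.json
```

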