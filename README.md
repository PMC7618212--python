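# mcslr — motion-compensated structured low-rank reconstruction for multi-shot EPI

Multi-shot 3D EPI acquires k-space over many excitations, which makes it
vulnerable to two kinds of shot-to-shot inconsistency: physiologically
induced **phase variations** (respiration-driven B0 fluctuation) and bulk
**rigid head motion**. Structured low-rank (SLR) reconstruction handles the
first by reconstructing one image per *shot group* and coupling the groups
through a low-rank constraint on the block-Hankel matrix built from their
k-space — different groups share a magnitude and differ only by smooth
phase, so the lifted matrix

```
M = [ H(F x_1) | H(F x_2) | ... | H(F x_n) ]
```

is low rank. Rigid motion breaks exactly that magnitude consistency. mcSLR
restores it by folding a hierarchical rigid-motion model into the SENSE
forward model,

```
y_ij = A_ij F S T_intra,ij T_inter,i x_i ,
```

and estimating the motion from the data itself: the joint problem

```
min_{X,T}  || A F S T X - Y ||_2^2  +  lambda * sum_l || H_2D F X_l ||_*
```

is solved by alternating (1) an ADMM structured low-rank solve for the
group images `X`, (2) rigid registration of the group images to the first
group for the inter-group motion `T_inter`, and (3) a Levenberg–Marquardt
solve of the per-subdivision data-consistency residual for the intra-group
motion `T_intra`. Rigid transforms are implemented with Fourier phase
ramps and the three-pass shear decomposition, so rotation needs no
regridding and every transform is exactly unitary.

The package is aimed at researchers studying motion/phase robustness of
segmented EPI: it ships the reconstruction methods (`sense`, `mcsense`,
`slr`, `mcslr`), a seg-CAIPI acquisition simulator (synthetic phantom,
coil maps, phase states, motion traces), and evaluation tools (tSNR,
motion RMSE, NRMSE), so the whole simulation study runs without any data
download.

## Worked example

```python
import numpy as np
from mcslr import SimulationSpec, ReconConfig, reconstruct
from mcslr.simulator import simulate
from mcslr.evaluation import nrmse

spec = SimulationSpec(image_shape=(64, 64), n_coils=8, n_shots=16,
                      n_groups=4, shots_per_subdivision=4, n_volumes=1,
                      rot_range_deg=0.0, trans_range_mm=0.0, snr_db=30, seed=9)
run = simulate(spec)
cfg = ReconConfig(admm_iters=2, cg_iters=8, outer_iters_max=8, mcsense_iters_max=4)

X, trace, sos, diag = reconstruct("slr", run.kspace[0], run.sens, run.scheme, cfg)
err = np.mean([nrmse(X[i], run.truth_images[0][i], run.support())
               for i in range(4)])
print(f"mean group-image NRMSE (SLR): {err:.3f}")
```

This prints `mean group-image NRMSE (SLR): 0.319` — the structured
low-rank solve fuses the four mutually undersampled shot groups well below
the independent per-group CG-SENSE error (`0.469` on the same data): the
Hankel coupling is doing the work that coil sensitivities alone cannot do
at the per-group undersampling.

The command line mirrors the library:

```bash
mcslr simulate --config sim.yaml --seed 1 --out run.h5
mcslr recon --method mcslr --in run.h5 --out recon/
mcslr evaluate --truth run.h5 --recon recon/ --report report.json
mcslr plot-sampling --in run.h5 --out masks.png
```

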