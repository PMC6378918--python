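# ecgikit

Electrocardiographic imaging (ECGI) on a synthetic heart–torso phantom:
simulate epicardial potentials with a transmural ischemic lesion, compute
body-surface potentials (BSPs) with a boundary-element forward model, sample
limited electrode grids, and reconstruct the epicardial map by regularised
inversion — then score how well the ischemic lesion can be detected.

The package is aimed at researchers studying the bioelectric inverse problem
of electrocardiography: how many body-surface electrodes are needed, which
Tikhonov regularisation order works best, and how noise, lesion size,
location and detection threshold affect ischemia localisation — all on a
fully synthetic, reproducible phantom.

## The model

**Forward problem.** The torso is a homogeneous volume conductor bounded by
the insulated torso surface and the epicardial surface. Boundary-element
collocation of Green's representation yields a geometry-only transfer matrix
*A* with

&nbsp;&nbsp;&nbsp;&nbsp;*k*ₜ = *A* *r*ₜ,

mapping epicardial node potentials *r*ₜ to torso potentials *k*ₜ at each
timestep. A constant epicardial potential transfers exactly (rows of *A* sum
to 1).

**Inverse problem.** Reconstruction minimises the Tikhonov functional

&nbsp;&nbsp;&nbsp;&nbsp;‖*A r*ₜ − *k*ₜ‖² + λ² ‖*L r*ₜ‖²,

with *L* = I (order 0), the surface gradient (order 1) or the surface
Laplacian (order 2). λ is placed at the corner of the L-curve
(log residual vs log seminorm), located by an iterative Menger-curvature
golden-section search; either one global λ for the time-stacked system or one
λ per timestep.

**Sources.** Epicardial action potentials are phenomenological: a smoothstep
upstroke, drooping plateau and sigmoidal repolarisation, with APD₉₀ = 274 ms
and resting potential −85 mV in healthy tissue. A circular transmural lesion
has a central zone (inner 80 % of the radius) with APD 150 ms and resting
potential depolarised by 18 mV, and a boundary zone in which the remodelling
ramps linearly to zero — a border-zone node shows ≈228 ms / −75 mV.
Activation spreads from a pacing site at fixed conduction velocity; Gaussian
measurement noise is added at a prescribed SNR.

**Metrics.** Reconstruction error is the relative difference measure star
(RDMS): the distance between unit-normalised true and reconstructed
patterns, in [0, 2]. Lesion detection thresholds the map at
*w*ₜₕᵣ = *w̄* − Q(*w̄* − *w*ₘᵢₙ) (default Q = 0.4) and reports traffic-light
areas as a percentage of the true lesion area: correctly ischemic (CI),
incorrectly healthy (IH, missed) and incorrectly ischemic (II, false
detections; can exceed 100 %).

## Worked example

```python
import numpy as np
from ecgikit import (
    EpicardialMapModel, LesionSpec, activation_map, assemble_transfer,
    electrode_grid, epicardial_field, forward_bsp, interpolate_full_bsp,
    real_lesion_mask, sample_leads, score_detection, torso_ventricle_phantom,
)
from ecgikit.study import detection_window, lesion_sites

# phantom: 642-node ellipsoidal ventricle inside a 2562-node torso
heart, torso = torso_ventricle_phantom(resolution=3)
A = assemble_transfer(torso, heart)

# 27 mm transmural lesion on the wall facing the torso surface
lesion = LesionSpec(lesion_sites()["rv_lat"], radius=27.0)
act = activation_map(heart, pacing_nodes=[int(np.argmin(heart.vertices[:, 2]))])
truth = epicardial_field(heart, lesion, act, timeline=(0.0, 2.0, 200))
bsp = forward_bsp(A, truth)

# record 256 leads, interpolate the full BSP, invert with order-2 Tikhonov
layout = electrode_grid(torso, 256)
K = interpolate_full_bsp(sample_leads(bsp, layout), layout, torso, dt=bsp.dt)
res = EpicardialMapModel(A, K, heart, order=2).fit()
print(res.summary())

print(f"mean spatial RDMS vs truth: {res.rdms(truth).mean:.3f}")
report = res.detect(q=0.4, window=detection_window(act))
score_detection(report, real_lesion_mask(heart, lesion), heart)
print(f"CI={report.ci_pct:.1f}%  IH={report.ih_pct:.1f}%  II={report.ii_pct:.1f}%")
```

prints

```
Epicardial Map Reconstruction Results
=====================================
Tikhonov order:     2
lambda mode:        global
lambda:             0.292437
residual norm:      150.109
solution seminorm:  398.642
heart nodes:        642
timesteps:          200
corner converged:   True
mean spatial RDMS vs truth: 0.254
CI=100.0%  IH=0.0%  II=76.4%
```

With 256 electrodes and second-order regularisation the whole lesion is
detected (CI 100 %), at the cost of 76 % of a lesion-area of
over-detection; the mean RDMS of 0.25 quantifies the overall pattern error.
Raising the lead count tightens the detection (II drops into single digits
at 1024 leads) and order 0 performs markedly worse throughout — the
factorial sweep in `ecgikit.study` quantifies these trends.

A command-line interface mirrors the pipeline stage by stage
(`ecgi phantom | simulate | forward | sample | interpolate | invert |
detect | study`); all intermediate artefacts are delimited text.

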