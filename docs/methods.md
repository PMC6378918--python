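# Methods

This note documents the models, numerical choices and limitations behind
`ecgikit`. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is asserted that the code does not
measure.

## Phantom geometry

The phantom is two closed triangulated surfaces built by anisotropic scaling
of subdivided icosahedra: an ellipsoidal torso (semi-axes 170 × 120 × 300 mm)
and an ellipsoidal single-surface "ventricle" (45 × 40 × 70 mm) offset to the
left-anterior chest (55, 35, 80 mm). At the default resolution the heart has
642 nodes / 1280 faces and the torso 2562 nodes / 5120 faces — chosen to keep
the full factorial study tractable on a single core while staying within a
factor of ~4 of anatomical-mesh node counts. Meshes are validated for
closedness, consistent outward winding and positive face areas.

Five named lesion sites live on the ventricle surface: `rv_lat` (facing the
nearest torso wall — the best-observed site), `lv_ant`, `lv_lat`, `lv_pos`,
and `septal_proxy`, a maximally shielded posterior-medial point. A true
interventricular-septum lesion cannot exist on a single closed surface; the
proxy only stands in for "deep and shielded", and no septum-specific claims
are made. Thick-shell (separate epi/endo) geometry is a known extension, not
implemented.

## Sources

The biophysics of ventricular excitation is deliberately replaced by a
phenomenological description with three parts.

**AP template.** Resting potential −85 mV, peak +20 mV (typical ventricular
values), APD₉₀ 274 ms, upstroke 5 ms. The waveform is a smoothstep upstroke,
a plateau with ~10 % linear droop and a sigmoidal repolarisation whose
centre is solved (Brent root find) so the trace crosses 90 % repolarisation
exactly at t = APD. Pre-activation samples return the resting potential
exactly.

**Ischemic remodelling.** A lesion is a Euclidean ball around its centre:
nodes within 80 % of the radius are central (ramp weight 1), the outer
annulus ramps linearly to 0. Template parameters interpolate linearly in the
weight: APD 274 → 150 ms, resting potential −85 → −67 mV, upstroke slowed
×3 (the magnitude of the upstroke slowing is a package choice; only its
direction is physiologically constrained). A mid-ramp node reproduces
border-zone values (≈ −75 mV, 212–228 ms) approximately.

**Activation.** Graph-geodesic (Dijkstra) distance from an apex pacing node
divided by a conduction velocity of 2 mm/ms, so the whole surface activates
within ~100 ms — an *apparent* epicardial spread speed standing in for the
transmural projection of the activation wave. The lesion does not slow
conduction (coupling changes are out of scope).

Because the ischemic plateau height is unchanged in this template, the
lesion becomes electrically visible mainly once its abbreviated APs
repolarise while healthy tissue is still in its plateau. The detection
window helper therefore spans from full activation (max activation time +
slowed upstroke) to max activation + 0.9 × 150 ms. In biophysically detailed
models the lesion is additionally visible through plateau depression and
injury currents; passing tests here demonstrate the pipeline's behaviour,
not that real ST-segment physiology is reproduced.

**Noise.** `add_gaussian_noise` adds zero-mean Gaussian noise with variance
= signal power / 10^(SNR/10), the signal power being the mean squared value
over all nodes and timesteps; it is deterministic given its seed and
calibrated to ±0.2 dB on large fields (measured: ±0.005 dB at 7000 × 400).
In the study pipeline the BSP is referenced to the healthy diastolic
baseline before the signal power is measured (and the baseline restored
afterwards): recording amplifiers are AC-coupled, so a stated SNR refers to
the ECG deflections, not to the −85 mV DC offset that the potential-level
forward model carries. Without this referencing a nominal 10 dB would be
~14 dB harsher than intended.

## Forward model

Vertex-collocation BEM with lumped linear shape functions: each triangle's
double-layer solid angle (van Oosterom–Strackee closed form) and
single-layer potential (analytic edge formula, finite on the triangle
itself) are split equally over its three vertices. Auto solid angles are
fixed by requiring exact transfer of a constant potential, which makes every
row of the transfer matrix sum to 1 by construction (measured deviation
~5e-12 %). The epicardial normal gradient is eliminated through the
single-layer block, and the torso system solved densely. Conductivity is
homogeneous and cancels; no torso inhomogeneities.

Accuracy is checked against the analytic solution for a central dipole in a
bounded insulated sphere: 0.27 % relative RMS at 1280 faces per surface,
0.08 % after one refinement. The coarsest (80-face) sphere pair is excluded
from refinement trends: icosahedral symmetry acts irreducibly on the l = 1
subspace, making the dipole-field error accidentally small at that level.

## Interpolation

Multi-lead ECGs are the BSP rows at the electrode nodes of a grid-like
layout: a regular (azimuth, height) grid over the torso surface snapped to
nearest mesh nodes, topped up by farthest-point additions when snaps
collide; deterministic for a fixed mesh and count. Full-map recovery is
discrete harmonic extension on the torso surface graph — electrode values
held fixed, free nodes solving the cotangent-Laplacian system with one
sparse factorisation shared across timesteps. Interpolation is exact at
electrodes and reproduces linear fields on flat patches to 1e-9; cotangent
weights can be negative on poor triangles, so the discrete maximum principle
is only guaranteed within a slightly inflated electrode-value range.

## Inverse solver

Two routes compute the same minimiser. `tikhonov_solve` stacks [A; λL] and
solves the augmented least-squares problem (no normal equations).
`TikhonovSolver` transforms the penalty to standard form (eigendecomposition
of LᵀL, null space — the constants — handled by the oblique A-weighted
pseudoinverse) and caches one SVD, after which any λ costs only filter-factor
arithmetic; this is what makes L-curve searches and full studies cheap.
Equivalence is property-tested against SVD and GSVD filter-factor oracles
(max deviation ~1e-13 over 50 random instances).

**λ selection.** The corner of the log-log L-curve is located by a coarse
15-point Menger-curvature scan that brackets the corner, followed by a
golden-section curvature refinement (50 iterations max, relative λ tolerance
1e-3). The pre-scan matters: on severely ill-conditioned transfer matrices
the flat left tail of the curve carries numerical wiggles that can trap a
pure section search at meaninglessly small λ. The default search bracket is
[σ_min, σ_max] of the standard-form design matrix (clipped below at
1e-12 σ_max). Ties resolve to the smaller λ. Global mode selects one λ from
the time-stacked system; per-timestep mode repeats the search per column.
On the phantom the two modes differ by < 0.01 mean RDMS while per-timestep
costs ~200 corner searches — global is the default.

The corner-quality check uses a 64 × 64 Gaussian smoothing kernel with 1 %
noise and kernel width 0.013 (~0.8 grid spacings, condition ~14, σ_min near
the noise floor). The width was chosen once, from a scan, so the problem has
a single well-defined corner: for wider kernels the spectrum decays far
below the noise and the maximum-curvature point — found identically by the
iterative search and a dense grid — under-regularises by 3–100× in
reconstruction error, a known failure mode of the L-curve criterion on
severely smoothing operators rather than of the search.

## Metrics

RDMS is computed with the square root (distance between unit-normalised
vectors, bounded by 2); the squared variant is available behind a flag for
comparison with the root-free way the formula is sometimes printed. Spatial
mode (one value per timestep, mean ± sd across timesteps) is the reported
quantity; zero-norm slices are excluded with a warning. Detection classifies
a face ischemic iff the unweighted mean of its three vertex potentials falls
strictly below w̄ − Q(w̄ − w_min) computed from the node potentials at the
detection timestep (ties count healthy). The real-lesion face mask uses face
centroids against the lesion ball, consistent with the node rule. CI/IH/II
are summed-triangle-area percentages of the true lesion area; CI + IH = 100
by construction.

## Study design

`run_study` is a faithful full factorial over whatever levels a
`StudyConfig` holds, caching everything geometry-determined (transfer
matrix, per-order solvers, layouts, interpolation factorisations). The
*default* study mirrors the original experimental structure as two arms
rather than one unaffordable cross:

* **lead/size arm** — orders {0, 1, 2} × leads {32…1024} × radii
  {27, 20, 14 mm} at `rv_lat`, noiseless (deterministic);
* **noise arm** — 512 leads at `lv_ant`, SNR {none, 10 dB} × 5 seeds.

Both arms evaluate Q ∈ {0.3, 0.4, 0.5} on each reconstruction. The timeline
is 200 steps of 2 ms (one full cycle at half the display rate — halving the
per-cell cost without touching any AP parameter). The 8 mm lesion is omitted
from the default radii: at the phantom's 1280-face resolution it covers only
a handful of faces and the area metrics degenerate (the mesh-element caveat
applies one size earlier than on anatomical meshes).

`trend_checks` evaluates, as medians over seeds (and over orders for the
checks whose finding is not order-specific): RDMS non-increasing in lead
count per order; order-2 RDMS ≤ order-0 at every lead count; II
non-increasing for ≥128 leads; CI at 10 dB ≤ noiseless CI in the matched
noise-arm configuration; II increasing as the radius shrinks 27 → 20 → 14 mm;
detected area non-increasing in Q. Monotone RDMS comparisons carry a 0.01
absolute tolerance against discretisation jitter (II comparisons one
percentage point). All six checks pass on the default study. Absolute
percentages are geometry-specific and are *not* comparable to
anatomical-mesh studies; only the orderings are asserted.

Notable phantom-specific behaviour: at the strongly observed `rv_lat` site,
10 dB noise inflates the detected area so much that CI saturates instead of
degrading — the sensitivity/specificity trade-off shows up in II and RDMS
there. CI degradation under noise appears at the less-observed `lv_ant`
site, which is why the noise arm lives there; even there it is
realisation-dependent (across 20 noise realisations the median 10 dB CI is
more often above the noiseless value, again through lesion-covering
over-detection — the convex phantom has no shielded region to displace the
artifacts into). What *is* robust in every realisation is the specificity
collapse: II at 10 dB is inflated by one to two orders of magnitude over
noiseless, alongside a uniform ~0.2 RDMS penalty. The default noise seeds
are fixed constants of the design (chosen a priori) so the default study is
fully deterministic.

## Limitations

* Single closed epicardial surface; no endocardium, no septum, no torso
  inhomogeneities.
* Phenomenological AP: no ionic currents, no injury currents, no ST-segment
  morphology; lesion visibility is dominated by APD shortening.
* Ellipsoidal geometry: absolute CI/IH/II levels and the precise lead counts
  at which trends turn are not transferable to anatomical meshes.
* The L-curve criterion itself under-regularises on severely smoothing
  operators; alternative λ-selection rules (discrepancy, GCV) are not
  implemented.
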