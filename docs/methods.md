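# Methods

## The decoding problem

Vessel-encoded pseudo-continuous ASL (VE-PCASL) angiography modulates the
arterial inversion across the labelling plane so that over a series of `N`
encoding cycles each of `M` arteries receives a unique tag/control code.
In each voxel `k` the measurement vector is modelled as

    y_k = E P_c f_kc + e_k,        e_k ~ N(0, phi_k^-1 I)

where `E` is the `N x (M+1)` encoding matrix (one modulation column per
artery, a static unit column), `c` is the voxel's artery class (a subset of
at most `L` arteries, "arteries per class", APC), `P_c` the 0/1 selection
matrix for that subset, and `f_kc` the class-local flow contributions.

The entries of `E` come from the 1-D periodic modulation function
`m = g(phi, v)` evaluated at the artery's encoding phase
`phi = pi * d / (2 D)`, where `d = (x - c_x) cos(theta) + (y - c_y) sin(theta)`
is the artery's signed distance from the cycle centre along the cycle
direction and `D` the cycle scale. Convention: `m = -1` is a full inversion
(tag, `phi = -pi/2`), `m = +1` fully relaxed blood (control, `phi = +pi/2`);
the ideal modulation is `g = sin(phi)`.

## Marginalized posterior

With the joint Jeffreys prior on `(f, phi)` scaled by `|P_c' E' E P_c|^{1/2}`,
a proportions prior `Pr(q_k = c) = pi_c` with an automatic relevancy
determination (ARD) factor `1/pi_c` per class, flow, precision and class
label marginalize analytically, leaving

    Pr(E, pi | Y)  ∝  prod_k  sum_c pi_c (r_kc)^(-N/2)  ·  prod_c 1/pi_c  ·  Pr(E)

with `r_kc = || y_k - X_c (X_c' X_c)^{-1} X_c' y_k ||^2` the squared
projection residual onto the span of the class columns `X_c = E P_c`
(Hermitian inner products for complex data). Two consequences worth
noting:

* the exponent is `-N/2` for every class, i.e. the `|X'X|^{1/2}` prior
  factor deliberately cancels the Occam term of the flow marginalization —
  larger (nested) classes therefore always attain slightly smaller
  residuals, and nothing in the posterior penalizes them for it;
* class posteriors `Pr(q_k = c | y_k) ∝ pi_c r_kc^{-N/2}` are invariant to
  a global rescaling of the data.

Flow is estimated per voxel and frame as the class-posterior-weighted
generalized-least-squares solution mapped back to the `M+1` sources.
Class posteriors are computed on the reference data (first frame by
default) and reused for every frame, since a voxel's feeding arteries do
not change over the readout.

## Decoders

* **MI** — pseudo-inverse of `E` built from the planning geometry (30 cm/s
  nominal speeds); **MIt** is the same with the true geometry (simulation
  only).
* **BI** — "Bayesian inversion": the flow estimator with fixed planned
  geometry and uniform `pi`; no optimization.
* **Bxy / BT3 / BT3v / BT6** — MAP estimation of, respectively, free artery
  locations, a 3-DOF rigid transform of the planned locations, the rigid
  transform plus per-artery speeds, and a 6-DOF affine transform.

Priors: locations `N(planned, 1 mm^2)` per axis; translations `N(0, 1 mm^2)`
and rotation `N(0, (5 deg)^2)`; speeds `N(30, 10^2) cm/s`; affine entries
`N(identity, 0.1)` per entry. These are deliberately informative: they
encode how much a patient can plausibly move between planning and
acquisition.

### Optimization

MAP fits use BFGS (scipy, Wolfe line search) on prior-scaled parameters,
with the staged schedule: (1) geometry with proportions fixed uniform, (2)
proportions (softmax-parameterized logits) with geometry fixed, (3) both
jointly; BT3v adds (4) a final stage including the speeds. Stage tolerances:
gradient 1e-6, at most 200 iterations, finite-difference step 1e-5 in
scaled units (large enough to beat the numerical noise of an objective of
magnitude ~ voxel count).

The cyclic modulation makes the posterior multimodal, and at high SNR the
priors alone cannot steer a local search into the right basin. The
transform methods (BT3/BT3v/BT6) therefore initialize stage 1 from the best
of 125 coarse grid points spanning ±2.5 prior sd per rigid axis (BT6 maps
the rigid candidates to affine entries). Bxy (8-dimensional) starts from
the planned locations.

Degenerate numerics: residuals are floored at machine epsilon relative to
the voxel power (keeps the objective finite on noise-free data without
breaking scale invariance); proportions are floored at 1e-8; a numerically
singular `X_c' X_c` (e.g. two coincident arteries) triggers a
trace-scaled 1e-10 ridge with a warning.

### MCMC

`fit_mcmc` runs random-walk Metropolis on the same posterior, Gaussian
proposals in the scaled space, per-parameter steps adapted every 50
burn-in iterations toward a 20–50 % acceptance rate. The posterior-mean
parameters feed the flow estimate. With no data voxels the chain samples
the prior, which is how the sampler is validated.

## Modulation models

**Ideal**: `g = sin(phi)`, speed-independent; exact for a perfect adiabatic
train, and the package default (all analytic identities are exact under it).

**Bloch lookup table**: a reduced flow-driven adiabatic inversion model,
integrated per (phase, mean speed) grid point and averaged over the laminar
in-vessel speed distribution (uniform on `(0, 2v]`, 16-point quadrature)
for the parabolic profile:

* a spin crosses the labelling plane at the train midpoint with constant
  speed; every 960 us it receives an instantaneous rotation about a
  transverse axis whose phase advances by `phi + pi/2` per pulse (at the
  tag phase the RF tracks the spin's precession at the plane — the PCASL
  inversion condition; at the control phase it alternates by pi and the
  kicks cancel);
* the flip angle is the nominal 20 deg scaled by the pulse's Gaussian
  slice profile (width from the pulse bandwidth over the 6 mT/m pulse
  gradient, ~4 mm), which localizes the labelling — a constant-flip train
  of ~1000 pulses would otherwise saturate every spin regardless of
  position;
* between pulses the spin precesses in the mean gradient (0.3 mT/m) and
  relaxes with blood T1 = 1.65 s, T2 = 0.15 s (3 T values);
* Mz is recorded when the spin exits a ±10 mm labelling window —
  downstream T1 decay is common to all cycles and is not part of the
  modulation.

The sweep of the precession angle as the spin crosses the plane makes the
inversion efficiency speed-dependent (poorer at high speed where the sweep
is less adiabatic, and at low speed where T1 decay inside the window bites),
which is the physical content the lookup table adds over the sinusoid.
The pulse-train timing and flip are acquisition parameters; the relaxation
constants, gradients and window width are not published for any specific
system, so they are exposed in `LabellingParams` with the defaults above,
chosen once so that the table behaves like a usable labelling scheme over
the physiologic 15–100 cm/s speed grid (tag-like `m <= -0.5` and
control-like `m >= 0.5` at every tabulated speed, smooth in `v`). The
table is therefore a parameterized model of the acquisition, not a
canonical reproduction of one.

## The reference encoding scheme

`four_artery_scheme` encodes four arteries planned at the corners of a
±10 mm square: tag-all; control-all; two left–right encodings
(centres (0,0) and (20,0), direction 0°, D = 10 mm — the second centre
swaps tag and control); two anterior–posterior encodings (centres (0,0)
and (0,20), direction 270°, D = 10 mm); and two oblique encodings with
D = 4.47 mm. The first six cycles match a typical in-vivo protocol and
leave the two diagonal artery pairs confounded (matrix rank 4 with the
ideal modulation): the rank-deficient mode weights the pairs (+1, −1, −1, +1).

The oblique cycles exist to break that degeneracy, and their geometry is
constrained by it: for any odd periodic modulation, an oblique whose centre
lies on either diagonal of the artery square produces a row exactly
orthogonal to the deficient mode, whatever its direction — it adds no rank.
The obliques are therefore centred off the diagonals, at (20,0)/135° and
(0,20)/225°, where the crossed directions give a full-rank matrix whose
smallest singular value (~1.0) keeps the 8-cycle pseudo-inverse
well-conditioned. With the Bloch table instead of the ideal sinusoid the
6-cycle matrix is technically full rank — the table is not exactly odd —
but the lifted singular value is tiny, and pseudo-inverting it amplifies
the measurement noise by two orders of magnitude; this is why plain matrix
inversion of 6-cycle data with a realistic modulation is dramatically worse
than every alternative, and why the Bayesian classification matters.

## The synthetic-data generator

`SimulationConfig` defaults define the study conditions: 4 arteries planned
at (±10, ±10) mm; a rigid perturbation drawn `N(0, 1 mm)` per translation
axis and `N(0, 1 deg)` rotation; speeds `N(30, 5) cm/s` hard-clipped to
[3, 80]; a 25×25×1 voxel scene with 4 straight arterial segments (one per
artery, 1 voxel wide, 15 voxels long, uniformly random centre and
orientation, overlapping voxels accumulating every overlapping artery's
contribution); label magnitude 1.0 per contributing artery; white noise at
10:1 SNR against the label magnitude; 6 or 8 encoding cycles whose
parameters are fixed by the *planned* geometry while the data are generated
from the *true* (post-transform) geometry. The scene and the noise consume
independent seed substreams, so the ground truth is identical across cycle
counts at the same seed.

What the generator does **not** emulate: the multi-frame dynamics of the
bolus (a single frame is simulated; no outflow, Look-Locker saturation or
T1 decay of the label across frames), static tissue (zero by default —
the static column still participates in every decoder so misattribution is
measurable), spatially correlated noise, phase errors (the simulated data
are real-valued; the decoders accept complex data), or partial-volume
vessel profiles. Passing tests on this generator therefore demonstrate the
estimator algebra and the geometry/proportion inference, not robustness to
real-data artefacts.

The absolute scale of a "flow contribution" is arbitrary (label magnitude
1.0); all RMSE values are in these units and only comparisons between
methods are meaningful.

## Evaluation

Per-dataset RMSE is the root of the mean squared error over all
voxel-artery pairs (static excluded, magnitudes for complex estimates);
batch summaries report the median across datasets. ROC curves score
detection: positives are voxel-artery pairs with nonzero truth, the
estimate magnitude is thresholded over 200 log-spaced levels pooled across
the batch, and AUC is the trapezoid area (cross-checked against
scikit-learn on the same pooled scores).

## Known limitations

* **Nested-class overfitting.** Because the prior cancels the Occam factor,
  a class that adds an artery to a voxel's true set fits slightly better by
  construction (`-N/2` power of a residual with one fewer degree of
  freedom). At `N = 6..8` this is a ~2x posterior weight per extra artery:
  background (noise-only) voxels prefer single/pair classes over the
  static-only class, and a pair class {live, dead} can absorb a live
  artery's voxels, keeping a silent artery's proportions alive. The hard
  ARD removal of an absent artery's classes is obtained when the global fit
  is restricted to the substantial-flow mask (`mask_quantile`), where
  classes of a silent artery genuinely have no support; without the mask
  the suppression is visible in the flow images (the silent plane carries
  only noise-level signal) and in the collective proportion mass, not in
  every individual class.
* **Weak 6-cycle motion identifiability.** The left–right and
  anterior–posterior cycles place the planned arteries at extrema of the
  modulation, so `E` is first-order insensitive to small motions there;
  with 6 cycles the rigid transform is informed almost entirely through the
  obliques, which that protocol lacks. Parameter-recovery checks therefore
  use the 8-cycle scheme; at 6 cycles the MAP transform shrinks toward the
  prior and the transform methods behave like Bayesian inversion.
* The Bloch table's absolute inversion efficiencies (and hence the
  magnitude of the 6-cycle near-degeneracy, which controls the
  matrix-inversion error there) depend on the unpublished gradient and
  relaxation constants discussed above.
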