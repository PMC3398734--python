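# veasl — Bayesian decoding of vessel-encoded ASL dynamic angiography

Vessel-encoded arterial spin labelling (VE-ASL) magnetically inverts blood
in the neck with a spatial modulation so that, over a series of encoding
cycles, each feeding artery (internal carotids, vertebrals) carries a
unique tag/control code. Decoding the resulting angiographic image series
into per-artery blood-flow images is a source-separation problem: in each
voxel `k`,

    y_k = E P_c f_kc + e_k,

where `E` is the `N x (M+1)` encoding matrix (one modulation column per
artery plus a static column), `c` a voxel class selecting at most `L`
arteries ("arteries per class"), and `e_k` white noise of precision
`phi_k`. Marginalizing flow, precision and class label analytically gives a
posterior over only the global quantities — the encoding-matrix geometry
and the class proportions `pi`:

    Pr(E, pi | Y) ∝ prod_k sum_c pi_c (r_kc)^(-N/2) · prod_c 1/pi_c · Pr(E)

with `r_kc` the projection residual of `y_k` onto the class's encoding
columns, and an automatic-relevancy (ARD) factor per class proportion.

`veasl` implements this framework for clinical dynamic angiography, for
researchers developing or applying vessel-selective ASL:

* six decoders: plain matrix (pseudo-)inversion (`MI`), fixed-geometry
  Bayesian inversion (`BI`), and staged MAP inference of free artery
  locations (`Bxy`), a 3-DOF rigid motion transform (`BT3`), rigid motion
  plus flow speeds (`BT3v`), or a 6-DOF affine transform (`BT6`) — plus a
  random-walk Metropolis sampler over the same posterior;
* an ideal (sinusoidal) and a Bloch-equation-simulated, speed-dependent
  model of the labelling modulation function;
* a synthetic-data generator reproducing the standard four-artery
  simulation study (random rigid motion, random arterial segments, 10:1
  SNR), and an RMSE/ROC evaluation harness for method comparison;
* NIfTI/CSV I/O and a `veasl` command line (`blochsim`, `simulate`,
  `decode`, `evaluate`).

## Worked example

Simulate one 8-cycle acquisition of four neck arteries that moved between
planning and acquisition, then decode it with the rigid-motion MAP method:

```python
from veasl import (SimulationConfig, simulate_dataset, VEASLModel,
                   ArteryGeometry, rmse_flow)

cfg = SimulationConfig(n_cycles=8)
ds = simulate_dataset(cfg, seed=42)
planning = ArteryGeometry(names=list(ds.arteries.names),
                          planned=ds.arteries.planned.copy())
model = VEASLModel(ds.data, cfg.scheme(), planning, apc=2)
result = model.fit("BT3")
print(result.summary())
```

```
VE-ASL decode summary
======================================================
method:            BT3
arteries:          RICA, RVA, LICA, LVA
cycles / frames:   8 / 1
arteries per class:2 (11 classes)
modulation:        ideal
rigid transform:   dx=+0.26 mm, dy=-1.02 mm, theta=+2.51 deg
artery locations (mm) and speeds (cm/s):
  RICA       ( +10.69,   +8.53)     30.0
  RVA        (  +9.81,  -11.45)     30.0
  LICA       (  -9.29,   +9.41)     30.0
  LVA        ( -10.17,  -10.57)     30.0
largest class proportions: RVA+LVA:0.246, RVA+LICA:0.243, RICA+LICA:0.187, RICA+RVA:0.170, RICA+LVA:0.154
-log posterior:    -8544.889
```

The fitted rigid transform (dx = +0.26 mm, dy = −1.02 mm) recovers the
translation actually drawn by the simulator (+0.30 mm, −1.04 mm; the
rotation, +0.75°, is the most weakly identified parameter and lands at
+2.51° on this dataset). `result.flow` holds the per-artery (+ static)
flow images, `result.class_posteriors` the voxelwise artery-set
probabilities. Scoring against the simulator's ground truth,

```python
mi = model.fit("MI")
print(rmse_flow(mi.artery_flow(0), ds.truth_flow))       # 0.0653
print(rmse_flow(result.artery_flow(0), ds.truth_flow))   # 0.0296
```

the Bayesian decode halves the flow-image error of plain matrix inversion
(in units of the labelled-blood signal magnitude, here 1.0).

The same pipeline runs from the shell:

```
veasl simulate --n 25 --cycles 6 --seed 1 --out sim/
veasl decode --method BT3 --data sim/dataset_000/data.nii.gz \
      --scheme sim/scheme.csv --arteries sim/arteries_planned.csv --out out/
veasl evaluate --batch sim/ --methods MI,BI,BT3 --apc 1,2 --out report/
```

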