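# mwstroke

Differential microwave head imaging and stroke-type classification for a
10-port, 1 GHz antenna-ring system.

Microwave imaging is a candidate technology for fast pre-hospital stroke
diagnosis: ischemic tissue (a clot, lower water content) has a *lower*
complex permittivity than average brain, while a hemorrhage (pooled blood)
has a *higher* one, so a stroke perturbs the scattering matrix measured by an
antenna array around the head. This package implements, end to end and on
synthetic data, the analysis chain of such a system:

1. **Scenario model** — a lossy liquid head medium (εr = 41.40,
   σ = 1.04 S/m at 1 GHz) in a 220 × 180 mm oval container with a single ring
   of 10 antennas, and spherical lesions of 20/30/40 mm diameter with
   ischemic (31.72, 0.92) or hemorrhagic (52.73, 2.85) dielectrics.
2. **Born forward model** — the differential scattering problem is linear in
   the dielectric contrast δO(r) = (ε_c − ε_c,bg)/ε_c,bg:

   ΔS_mn = L_e · δO,  with  L\[(m,n), v] = c₀ k_b² G(r_m, r_v) G(r_n, r_v) ΔV,

   where G(R) = e^(−jk_bR)/(4πR) is the scalar point-source field in the
   lossy background and k_b = (2πf/c)√ε_c,bg (e^{+jωt} convention,
   Im k_b ≤ 0). A reciprocal 10×10 S-matrix has 55 independent channels;
   the operator also accepts externally simulated field maps.
3. **TSVD imaging** — truncated-SVD regularized inversion
   δO = Σ_{n≤nT} (u_nᴴ ΔS / σ_n) v_n with truncation index nT = 50,
   magnitude images |δO|, a normalized 3×3 box blur, and peak localization.
4. **Classification** — 110 features (real + imaginary parts of the 55
   channels), per-feature standardization, PCA to 20 components, and a
   Gaussian-kernel one-vs-one SVM over {iStroke, hStroke, noStroke}, with
   kernel scale and box constraint chosen by seeded 5-fold cross-validated
   grid search. Evaluation reports the confusion matrix, accuracy, per-class
   recall, and Cohen's kappa.
5. **Synthetic datasets** — a training set of 20 fixed lesion positions ×
   3 diameters × 2 stroke types + 40 stroke-free replicates (160 S-matrices)
   and a test set of 30 uniformly random positions (220 S-matrices), with
   complex Gaussian measurement noise at 1% of the differential-signal RMS.

## Worked example

```python
import mwstroke as mw
from mwstroke import imaging, pipeline

grid = mw.make_grid(spacing=5.0)                      # XY slice at the antenna ring
array = mw.default_array()                            # 10 antennas, 1 GHz
operator = mw.assemble_operator(array, grid, mw.HEAD)
model = imaging.TSVDBorn(operator)                    # offline stage: SVD

scenario = mw.stroke_scenario("iStroke", (20, 30), 40)   # 40 mm lesion at (20, 30) mm
dS = mw.forward_dS(operator, mw.true_contrast(scenario, grid))
result = model.fit(dS, nt=50)                         # online stage: TSVD inversion
print(result.summary())
```

```
TSVD Born reconstruction
  truncation index nT : 50 / rank 55
  grid                : 1252 voxels @ 5.0 mm
  residual ||L x - b||: 4.6879e-05
  solution norm ||x|| : 8.9816e-01
  peak |deltaO|       : 9.9011e-02 at (22.5, 32.5, 100.0) mm
```

The reconstruction peaks one voxel diagonal (3.5 mm) from the true lesion
center — the localization error of the noiseless inverse crime. Peak |δO| is
in relative-contrast units (c₀ = 1, uncalibrated).

The full classification study:

```python
cfg = pipeline.RunConfig(master_seed=1000)
m1, m2 = pipeline.simulate(cfg)                  # 160 train + 220 test S-matrices
results, report = pipeline.train_and_evaluate(cfg, m1, m2)
print(results.summary())
print(report.summary())
```

```
PCA + Gaussian-SVM stroke classifier
  training samples   : 160
  PCA components     : 20 (explained variance 86.3%)
  kernel scale       : 20.99
  box constraint C   : 316.2
  5-fold CV accuracy : 86.2%
Stroke classification evaluation

          iStroke  hStroke  noStroke
iStroke        70        3        17
hStroke         1       86         3
noStroke        3        1        36

  overall accuracy : 87.3%
  recall iStroke   : 77.8%
  recall hStroke   : 95.6%
  recall noStroke  : 90.0%
  Cohen's kappa    : 0.804
```

Hemorrhagic lesions (large, high-contrast signals) are recognized almost
perfectly; the errors concentrate in small, deep ischemic lesions whose
differential signal sits at the synthetic noise floor and which are then
called stroke-free — see `docs/methods.md` for the quantitative analysis.

## Command line

```sh
mwstroke simulate --seed 1000 --out runs/demo          # M1/M2 HDF5 (+ .s10p export)
mwstroke run-all  --seed 1000 --out runs/demo          # full pipeline + report + images
mwstroke image    --dataset runs/demo/m1.h5 --sample-id 3 --nt 50 --out img.png
mwstroke sweep-nt --out sweep.csv                      # L-curve truncation table
```

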