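# Methods

This note documents the models behind `mwstroke`, the choices that were
genuinely open, and what the synthetic experiments do and do not show.

## Physical model and conventions

All media are non-magnetic and homogeneous at the single operating frequency
of 1 GHz. The complex relative permittivity is ε_c = ε′ − jσ/(ωε₀) under the
time convention e^{+jωt}; consequently the background wavenumber
k_b = (2πf/c)√ε_c is taken on the branch Re k_b > 0, Im k_b ≤ 0, so that
forward-propagating waves decay. For the head liquid (εr 41.40,
σ 1.04 S/m), k_b ≈ 138.09 − j29.73 rad/m: the in-medium wavelength is
≈ 45 mm and the amplitude attenuation ≈ 0.26 dB/mm.

Coordinates are in mm, origin at the container's XY center, z = 0 at the
container bottom, antenna ring at z = 100 mm. The 10 antennas sit at angles
θ_i = 2πi/10 + π/10 on the ellipse (110 cos θ, 90 sin θ) — the wall centers
of a decagonal 220 × 180 mm oval. The exact wall layout of a physical
container is configurable through `AntennaArray`.

## Born operator

The differential scattering of a weak contrast is linearized: the field
inside the perturbation is approximated by the unperturbed background field,
making ΔS linear in the object function δO(r) = (ε_c(r) − ε_c,bg)/ε_c,bg.
The operator entry for channel (m, n) and voxel v is

    L[(m,n), v] = c₀ · k_b² · G(r_m, r_v) · G(r_n, r_v) · ΔV,

with G(R) = e^{−j k_b R}/(4πR) (R in metres, ΔV in m³). Reciprocity is
built in: only the 55 channels m ≤ n (row-major, 1-based) are represented,
and the (m, n) row is symmetric in the two fields by construction. This
analytic point-source surrogate replaces full-wave simulated total fields;
`assemble_operator(field_maps=...)` accepts an externally computed
(10 × N_voxels) complex field map so simulated or measured fields can be
dropped in without touching the rest of the chain.

Two deliberate simplifications, and their visible consequences:

* **Scalar point sources.** Real antennas have bounded near fields; the
  1/(4πR) form grows without limit near an antenna, so voxels (and lesions)
  close to the wall couple far more strongly than in a real system. The
  differential-signal norms across the admissible lesion positions span
  roughly three orders of magnitude (see "Detectability floor" below).
* **Uncalibrated amplitude.** The proportionality constant between ΔS and
  contrast is not identifiable without a calibration measurement; c₀ = 1 and
  all reconstructions are in relative-contrast units.

A consequence worth noting: because the in-medium wavelength (≈45 mm) is
comparable to the larger lesions, the coherent voxel sum partially cancels
and the signal norm grows sub-linearly with lesion volume — the 40 mm/20 mm
norm ratio is ≈3.8 rather than the volume ratio 8. The signal is still
strictly monotone in diameter.

## TSVD inversion

The operator is decomposed once (economy SVD, `numpy.linalg.svd`); the
online stage inverts a measured ΔS by the truncated pseudo-inverse

    δO = Σ_{n=1..nT} (u_nᴴ ΔS / σ_n) v_n.

`nT` defaults to 50 of the 55 channels and is exposed everywhere, together
with a truncation-sweep utility producing the (nT, residual, solution-norm)
L-curve table, since the right truncation depends on the operator and the
noise level. Images are the per-voxel |δO|; the optional noise-suppression
blur is a 3 × 3 ones kernel normalized by 9 (so amplitudes remain comparable
before/after), reflect-padded, applied per XY slice. Localization takes the
argmax of the blurred magnitude image with ties broken toward the lowest
voxel index (C order), deterministically; an identically zero image is
flagged "no detection" instead of returning a coordinate.

The default imaging grid uses 5 mm isotropic voxels masked to the oval:
a single XY slice at z = 100 mm for in-plane studies (1252 voxels), or a
3-D slab z ∈ [40, 160] mm for out-of-plane studies (31 300 voxels). The
slab is symmetric about the ring plane, which makes the single-ring
z-ambiguity exact: operator columns for mirrored voxels are identical, so
every reconstruction is mirror-symmetric about z = 100 to machine precision
— the "hourglass" artifact of one-ring systems appears as a theorem of the
surrogate operator, and the package reproduces it in tests.

## Synthetic datasets

The generator emulates a liquid-phantom measurement campaign:

* **Training set (M1 analog)**: 20 fixed XY positions × 3 diameters
  (20/30/40 mm) × 2 stroke types + 40 stroke-free replicates = 160 samples.
  The exact fixed layout of the physical campaign is not published; the
  default places an outer ring of 10 points at 92% and an inner ring of 8
  points at 55% of the admissible-region half-axes, plus the two documented
  positions (20, 30) and (10, 10). Even coverage out to the admissible
  boundary matters because the test positions are uniform over that whole
  region; among candidate layouts the rings were selected by training-side
  cross-validation only.
* **Test set (M2 analog)**: 30 positions drawn uniformly (rejection
  sampling) over the oval shrunk by the largest lesion radius (20 mm), each
  reused for all three diameters, + 40 stroke-free replicates = 220 samples.
* **Noise**: i.i.d. complex Gaussian per independent channel, symmetrized to
  preserve reciprocity exactly, with per-entry std equal to
  `noise_level × RMS(|ΔS|)` over the canonical fixed-position stroke set
  (default noise_level 0.01). The noise floor is a property of the
  instrument, so the same std is used for every dataset built on the same
  operator. Stroke-free samples are the reference S-matrix plus noise only.
* All randomness flows from one master seed through a counter-based
  derivation (`SeedSequence(master, spawn_key=(stage,))`), so adding a stage
  never changes earlier stages' draws and dataset builds are bit-identical
  under the same seed.

What the generator does *not* emulate: instrument drift, temperature,
cable movement, antenna coupling, multiple scattering (the forward model is
first-order Born), or inter-session phantom variation. Passing tests
therefore validate the algorithmic chain, not hardware robustness.

## Classifier

Features are the raw S-matrix channels (real parts then imaginary parts,
110 values); a `differential=True` flag switches to reference-subtracted
features for ablation (after centering the two are equivalent). The
pipeline is: per-feature standardization → PCA to 20 components (sign of
each loading fixed by making its largest-magnitude coordinate positive, so
fits are deterministic) → Gaussian-kernel one-vs-one SVM. Standardization
is on by default: the channel variances span more than two decades, and a
single kernel bandwidth on unstandardized features is dominated by the few
strongest channels (centering-only PCA + SVM reaches only ≈55% accuracy on
the default datasets; the flag `standardize=False` retains that variant).
Kernel scale s (gamma = 1/s²) and box constraint C are selected by seeded
stratified 5-fold cross-validated grid search over C ∈ 10^{−1..5} and
gamma ∈ g₀·10^{−2..2} (13 × 13 log-spaced, g₀ the 1/(d·var) heuristic);
the selected pair and CV score are stored with the model. Train/test
separation is structural: evaluation applies the stored scaler/PCA/SVM and
cannot update them.

Cohen's kappa is computed from the confusion matrix as
κ = (p_o − p_e)/(1 − p_e) with p_e from the row/column marginals; the
degenerate case p_e = 1 is defined as 0 with a warning.

## Detectability floor and expected performance

Under the default conditions the per-entry noise std is 1% of the
differential-signal RMS, which is dominated by the strongly coupled
near-boundary samples. A fraction of small ischemic lesions (low contrast
|δO| ≈ 0.22, small volume) then falls *below the noise floor*: about a
quarter of the 20 mm and an eighth of the 30 mm ischemic test samples have
‖ΔS‖ smaller than the expected total noise norm, and these are
indistinguishable from stroke-free measurements in principle. The observed
performance is accordingly ≈86–90% overall accuracy, κ ≈ 0.78–0.84,
hemorrhagic recall ≈92–100%, ischemic recall ≈74–83% across seeds, with the
errors concentrated in weak ischemic lesions misread as stroke-free — the
same "signal below the noise level" failure mode physical single-ring
systems show for out-of-plane lesions, here triggered in-plane by the
surrogate's larger near-field dynamic range.

## Numerical choices

* Voxel centers are offset by half a voxel from the axes so none coincides
  with an antenna or the oval boundary; a coincident voxel would be zeroed
  with a logged warning rather than aborting assembly.
* SVD reconstruction identity is verified to 1e−8 relative Frobenius error;
  full-truncation TSVD matches the dense pseudo-inverse to 1e−6.
* Touchstone files are written in RI format with 17 significant digits, so
  the decimal round trip is bit-exact for float64.
* HDF5 dataset files carry a format version and the channel-ordering string
  ("upper-triangle-row-major-1based-v1"); loading fails loudly on either
  mismatch.
* Problem sizes: the default study (operator assembly on the 31 300-voxel
  slab, 380 forward solves, 169-point hyperparameter search with 5-fold CV)
  completes in a few seconds on one CPU.

## Known limitations

* The Born linearization is quantitatively wrong for the hemorrhagic
  contrast (|δO| ≈ 0.76 is not weak); the pipeline treats it as the
  generative truth, so synthetic results overstate forward-model fidelity.
* Single-frequency, scalar, single-ring: no z-resolution (exact mirror
  ambiguity), no multi-frequency regularization, no vector-field effects.
* Reconstructed amplitudes are relative; no absolute permittivity
  calibration is attempted.
* Out-of-plane lesions are imaged (with the hourglass ambiguity) but not
  classified; the classifier is trained and evaluated on in-plane lesions
  only.
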