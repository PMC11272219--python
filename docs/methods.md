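# Methods

## Scattering model

Atoms are point scatterers with a constant per-element electron count z and
an isotropic Debye-Waller factor, so the structure factor of a model is the
direct summation

    F(hkl) = sum_j occ_j z_j exp(-B_j s^2/4) exp(+2 pi i h.x_j),   s = 1/d.

No Cromer-Mann form factors, anisotropic displacement, or bulk-solvent
scaling enter the calculated amplitudes (a flat-solvent term exists only
inside the omit-map operation, where it gives the Polder exclusion something
to exclude).  This keeps every amplitude reproducible in closed form while
preserving the structure of the appraisal problem: amplitudes, phases,
occupancies and B-factors interact exactly as in the full crystallographic
case.  All toy systems live in P1; the appraisal operations are
symmetry-agnostic once data are merged.  Phases follow the +2πi h·x
convention, are stored in radians and printed in degrees; the Friedel
half-sphere is h > 0, or h = 0 ∧ k > 0, or h = k = 0 ∧ l > 0.

Two-state systems carry conformer tags "A" (reference, resting) and "B"
(activated), with complementary occupancies 1−f and f.  Coherent mixing
F = (1−f)·F_dark + f·F_light is the ground truth that both partial-occupancy
refinement and amplitude extrapolation approximate.

## Synthetic study conditions

The built-in generator defines the conditions every test runs under, chosen
once as a desk-scale analogue of a membrane-protein TR-SFX study:

* Cell 18 × 20 × 22 Å, P1; 16 protein-like atoms (C/N/O/S, half named CA*)
  plus two ordered waters and one transient water; B-factors 10–30 Å².
* Activated state: 4 of 16 protein atoms move, mean shift 0.4 Å (lognormal,
  20% spread), with zero net translation.  The moving fraction is kept small
  deliberately: difference Fourier and extrapolation formalisms assume
  small, localized changes, and a toy that moves half its atoms sits outside
  the regime the methods are defined for.
* Data to d_min = 2.5 Å (3.0 Å in the heavier resampling studies),
  occupancy f_true = 0.27, thirteen log-spaced delays from 16 ns to
  1.725 ms; the transient water is ordered only in a middle window of the
  series.
* Frames: each observes a Bernoulli(0.3) subset of reflections with
  I_p = s·p·I_true + ε, frame scale s ~ LogNormal(0, 0.3), partiality
  p ~ U(0.1, 1), ε Gaussian with sd = 10% of the median true intensity.
  Sigmas record that sd (zero in the noise-free limit — the one documented
  deviation from the "sigma > 0" observation invariant).  Negative
  observations are kept.  Per-frame randomness derives from
  SeedSequence((master_seed, frame_id)), so any subset of frames reproduces
  independently of iteration order.

What the generator does **not** emulate: detector geometry, spot-profile and
partiality modeling, indexing ambiguity, per-frame scaling refinement,
non-isomorphism, radiation damage, and the ~10⁵-atom scale of a real
structure.  Passing tests therefore demonstrate the statistical machinery
(resampling, merging, map algebra, refinement geometry, error calibration),
not photophysics or data-reduction fidelity.

## Resampling and merging

Bootstrap replicates are fixed-size multisets of frame indices drawn with
replacement; the resampling unit is always the frame (one pattern, one
crystal), never the individual observation.  With m replicates of size k
from n frames each frame is selected m·k/n times on average.  Merging is an
unweighted Monte-Carlo mean per reflection, counting a frame drawn twice
twice; reflections with fewer than `min_measurements` (default 3)
observations are dropped and counted.  Amplitudes use the clip-at-zero
square root F = √max(I, 0) with σ_F = sem/(2F); French-Wilson conversion is
a possible future adapter, but the pipeline's comparisons are
self-consistent under the simple policy, and negative-intensity fractions
are always reported.

## Extrapolation

F_ext = (1/f)·F_light + (1 − 1/f)·F_dark on amplitudes, with F_ext ≤ 0
rejected and logged (rejection grows as f falls — the 1/f amplification of
noise is the known cost of the approach).  σ propagation assumes independent
errors.  The operation is exactly invertible on retained reflections
(`remix`), which the tests exploit as an algebraic identity.

## Refinement

The engine minimizes T = Σ_work (F_obs − k|F_calc|)² over the coordinates
and isotropic B-factors of the free atoms, with the scale refit in closed
form (k = ΣF_obs|F_calc| / Σ|F_calc|²) at every evaluation, analytic
gradients, and bounded L-BFGS inside up to `max_cycles` cycles (default 5),
stopping when a cycle no longer decreases the target.  No geometric
restraints are used — the toys are sparse point models.  The R-free set is a
deterministic hash of (h, k, l, seed), default 5%, independent of reflection
order.

**Gauge fixing.**  Amplitude-only refinement of a free conformer against a
fixed partner has a rigid-translation mode that is exactly null in
extrapolated mode (a uniform shift of all atoms leaves every |F| unchanged —
the floating P1 origin) and nearly null in partial-occupancy mode, where a
shift merely decorrelates the two conformers and can genuinely lower the
amplitude residual while dragging every atom off site.  In full
macromolecular refinement this mode is pinned by restraints and the sheer
number of fixed interactions; here the displacement field is parameterized
with its net translation projected out (`fix_net_translation`, default on),
and the synthetic conformational change is generated with zero net
translation so the constraint is compatible with exact recovery.

With exact data the engine is a fixed point at the generating truth, and
from a resting-state start it recovers the activated model to ≲0.001 Å in
partial-occupancy mode.  Extrapolated-mode recovery carries the intrinsic
approximation error of amplitude extrapolation (≈0.01–0.03 Å under the study
conditions), which is a property of the method, not of the optimizer.

## Occupancy scans and the 1/f law

One refinement per grid occupancy (default grid 1–99%); per-f displacement
profiles against the fixed reference; a least-squares line of mean
displacement vs 1/f over f ≥ 0.25 (the domain where the linear law holds);
and occupancy selection as the argmax of the Pearson correlation between
each profile and the grid-mean profile, with ties within 10⁻³ reported as a
range and broken toward the smallest f.  On noise-free coherent-mixture data
the refined mean displacement tracks (f_true/f) times the true displacement;
the deviation grows quadratically with displacement amplitude, so the
pointwise law is exact only in the small-displacement limit while the linear
fit stays excellent (R² > 0.99) under the study conditions.

## Maps

Syntheses are inverse FFTs of half-sphere coefficients with Friedel
completion; F(000) is excluded, so maps have exactly zero mean.  The default
grid spacing is d_min/3 with even dimensions.  Difference maps use
(F_act − F_ref)·exp(iΦ_ref) with no figure-of-merit weighting.  σ-scaling
divides by the rms density.  Omit maps scale F_calc to F_obs by the
closed-form k before synthesis; the optional flat solvent places constant
density k_sol in voxels beyond r_probe of every remaining atom, minus a
Polder exclusion sphere around the omitted atoms (without a solvent term the
exclusion radius is a documented no-op).

SVD stacks are voxels × maps; the principal map is u₁·S₁/√m with its sign
fixed by positive correlation with the voxel-wise mean map.  Sphere
quantification integrates by voxel-center inclusion (no partial-voxel
weighting) after zeroing values below the pedestal (default 2.0σ for
difference maps, 0.1σ for omit maps, each map's own σ, applied per map
before integration); replicate maps are σ-scaled individually before
quantification, so series values are in σ-scaled density units.

## Error estimation

Coordinate spread is the per-atom rmsd from the mean position over replicate
models, computed with minimum-image unwrapping; it scales as N^(−1/2) in the
resample size and is insensitive to the replicate count beyond its own
estimation noise.  The closed-form σ_free uses
0.65·(N_a/N_o)·R_free²·d_min²·C^e with e = −3/2 by default; published
renderings of this formula are typographically ambiguous about the sign of
the completeness exponent, and a positive exponent would make the error
shrink as completeness falls, so the negative sign is the default and the
exponent is exposed as a parameter rather than silently resolved.
B = 8π²⟨u²⟩ converts B-factors to rms displacement amplitudes.

## Problem sizes

The shipped tests and the acceptance script run the full workflow at desk
scale: ~600–1100 reflections, 60–800 frames per dataset, 100 bootstrap
replicates of 14 synthetic datasets (1400 resampled datasets), 8–20
replicate refinements per route, and 20-trial repetitions of the SVD
denoising study.  These sizes were chosen so a complete run stays in the
minutes range on a single CPU while every statistical claim is still
resolved; all of them scale up linearly through configuration.

## Known limitations

* Merging has no per-frame scale refinement; systematic scale error folds
  into the bootstrap spread rather than being removed.
* Extrapolation is implemented on amplitudes only (the printed form); the
  intensity-based variants are out of scope.
* The refinement engine is reciprocal-space only — no real-space cycles, no
  restraint libraries, no TLS/anisotropy — so its R-factors are not
  comparable to full-pipeline values on real data.
* Minimum-image distances assume displacements below half a cell edge,
  adequate for the near-orthogonal toy cells.
* Polder behavior is parity with the stated definition (solvent exclusion
  zone), not with any particular production implementation's mask details.
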