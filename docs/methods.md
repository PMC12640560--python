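# Methods

This note documents the models behind `dbscompare`, the defaults and why
they were chosen, what the synthetic cohort does and does not emulate, and
the numerical choices a maintainer would want to know.

## Volume conductor

The quasi-static potential around a placed lead solves
∇·(σ∇φ) = −I on a regular grid with a 7-point finite-difference stencil and
harmonic averaging of face conductivities (units mm / mA / S/m / V
throughout; the mm–m factors cancel in φ = I_mA / 4πσr_mm).  Two
conductivity conventions are built:

* **DF branch** — homogeneous isotropic bulk at σ_tissue = 0.2 S/m with a
  0.5 mm encapsulation (scar) shell at σ_scar = 0.07 S/m hugging the lead
  surface.
* **VTA branch** — tissue classes: 0.33 S/m inside the supplied gray-matter
  mask, 0.14 S/m elsewhere (white matter), with the electrode removed from
  the conducting domain.

**Electrode model.**  Contact metal is a high-conductivity inclusion
(10³ S/m) and the shaft an insulator (10⁻⁴ S/m) in the conductivity map
itself.  This realizes the floating-potential condition for every passive
contact — equipotential surface, zero net current — through the physics of
the discretized operator, rather than by an outer iteration.  Two benefits
drive this choice: the operator stays linear, so superposition across
contacts is *exact* (a bipolar solution is literally the difference of two
monopolar unit solutions, and one assembled matrix serves all per-contact
right-hand sides), and the floating contract becomes a testable property
(measured passive-contact potential spread is ~10⁻⁵ of the active scale;
net current through a passive contact is zero to solver tolerance).
Rasterization shrinks each contact's axial band by half a voxel and
resolves any residual face-adjacency between contacts so metal of different
contacts can never touch (which would short them).

**Open boundary.**  The truncated outer boundary carries Dirichlet values
from the monopole approximation I_net/4πσr about the active contact.  For
charge-balanced (bipolar) superpositions these terms cancel.  Against the
closed-form point source the solver is within 2% (max, relative) over
radii 2–8 mm at the default 0.5 mm spacing, and the error falls with grid
refinement.

**Grids.**  The DF branch solves once per lead model in the lead frame
(0.5 mm spacing — never coarser than the scar — with an 8 mm tissue
padding); because its conductivity is lead-centric the unit solutions are
cached and shared across subjects and spaces.  The VTA branch depends on
the subject's gray-matter geometry and is solved per subject and space on
an axis-aligned world grid; unit-test accuracy checks run at 0.5/0.25 mm,
while cohort-scale runs use 1.0 mm spacing with 7 mm padding — activation
metrics at that resolution are coarse but monotone and fast enough to
evaluate hundreds of subject-variant pairs.  The linear systems are solved
with Jacobi-preconditioned conjugate gradients (rtol 10⁻⁸).

**Temporal scaling.**  The waveform enters separably: the static field is
multiplied by the voltage-drop factor of a 1-D equivalent circuit (series
access resistance 500 Ω, tissue 1000 Ω, double-layer capacitance 3.3 µF),
exp(−PW/τ) ≈ 0.99 at a 60 µs pulse.  Component values are package
defaults, exposed in configuration; only the factor's separability and
monotone decrease with pulse width matter downstream.

## Activation predictors

**VTA.**  |E| = |∇φ| is thresholded at 0.2 V/mm; of the suprathreshold
voxels only the 26-connected component(s) touching the active contacts are
kept, so disconnected suprathreshold islands never count.  The VTA branch
deliberately ignores pulse width and frequency.  Metrics: percent of
structure voxels covered (normative-space convention), percent of surface
mesh vertices inside the mask (native-space convention; marching cubes at
the 0.5 level; a vertex on a voxel face belongs to the higher voxel —
floor convention), and percent of streamlines with at least one resampled
point inside the mask (any-point inclusion, resampling step = grid
spacing).

**Driving force.**  Nodes of Ranvier are placed along each fiber's arc at
the internodal spacing L = 100 × diameter (4 µm → 0.4 mm for the
hyperdirect analog, 12 µm → 1.2 mm for the corticospinal analog).  The
activating function is the second difference of the (signed,
cathodic-negative) potential; the node phase is scanned (5 offsets) and the
depolarization-maximizing alignment kept — the conservative, most-excitable
case.  The per-fiber threshold uses a strength–duration surrogate

    threshold(mA) = k0 · (1 + τ_c / PW) / peak unit drive,

with k0 = 0.024 V and τ_c = 100 µs.  **This surrogate is a stand-in for a
full multicompartment cable model**: it preserves the properties the
comparison relies on — reciprocity in peak drive, monotone
strength–duration behavior, and diameter selectivity through node spacing —
but its constants are not physiological measurements.  k0 was fixed from
the point-source closed form so that 4 µm fibers at the near-bundle offset
(~1.6 mm) are recruited mid-range (~2 mA) and 12 µm fibers at the capsule
offset (~4.5 mm) are recruited only near 4–5 mA, i.e. the side-effect
pathway is a high-amplitude phenomenon, as the evoked-potential construct
requires.

## Spaces

"Normative" space is emulated operationally: a smooth random displacement
field (Gaussian-filtered white noise, 6 mm correlation length, normalized
to a configurable mean magnitude, default 1.0 mm, optional global scaling
> 1 for the oversized-template effect) is applied to all geometry.  Masks
are pulled back through the numerically inverted field with
nearest-neighbor sampling so they stay binary; the inverse is a fixed-point
iteration and round-trips points to < 0.1 mm at default magnitude.  The
warped lead is re-straightened by a total-least-squares line fit to the
warped tip and per-level contact centroids, with the rigid contact spacing
restored along the fitted axis — and the electric field is then recomputed
around this idealized straight lead.  That mechanism (geometry warps, the
field does not) is exactly how normative-space error enters the real
pipelines being compared.  The roll angle is carried through the warp
unchanged (a pure-rotation effect the displacement field cannot express).

Since the deformation scales linearly with the magnitude parameter for a
fixed seed, warp-magnitude sweeps perturb the same field shape, which makes
degradation-vs-magnitude comparisons well posed.

## Synthetic cohort

The generator emulates the experimental construct at desk scale:

* **Bookkeeping.**  Lead models, the 8/3 standard/steerable split, the
  per-subject monopolar/bipolar setting counts (360 total, range 15–49) and
  the bottom-contact coordinates mirror the shipped experiment table; the
  settings menu is the configuration × amplitude (1–5 mA, 60 µs) product
  truncated to the tabulated counts, with pseudo-ring (all segments of one
  level) classified non-directional.
* **Anatomy** is geometric-primitive based, not atlas-realistic: an
  STN-like gray ellipsoid straddling the distal contacts, an internal
  capsule slab centered 4.5 mm from the lead axis, a thin-fiber bundle
  (closest approach 1.6 ± 0.7 mm) terminating in the ellipsoid, and a
  coherent large-fiber bundle inside the slab (4.5 ± 0.6 mm, never closer
  than 3 mm).  100 fibers per bundle by default.
* **Ground truth is a designated model variant** (default
  DF-Native-Pathway), not an independent physiological simulator.  This
  circularity is intentional and stated plainly: it makes ranking recovery
  a well-posed test of the comparison machinery.  Passing it shows the
  pipeline identifies the data-generating model; it says nothing about
  which method is right for real brains.
* **Evoked potentials.**  EP1 = gain·HDP% + Gaussian noise (gain 1 µV/%,
  σ = 5 µV ≈ 5% of full scale — arbitrary, since only correlations consume
  amplitudes).  EP0 = gain·CSBT% + noise with a 2 µV detection floor
  applied to the *true* response (a response below the recording floor is
  never detected, so an all-zero-truth subject reads all-zero EP0) and
  zero-inflation P(drop) = z·exp(−CSBT%/15).  z = 0.85 was calibrated by a
  Monte-Carlo sweep to the reported zero-inflation level (≈77% zeros per
  subject on average, per-subject range ≈ 0.5–0.9 at defaults).

Everything is deterministic under the cohort seed (per-subject seed
sequences are spawned from it); regenerated cohort directories are
byte-identical.

What the cohort does **not** emulate: raw electrophysiology and latency
structure, atlas-realistic anatomy, tissue anisotropy/heterogeneity,
registration artifacts, lead localization error.  Tests passing on this
cohort therefore validate the machinery and its internal consistency, not
clinical accuracy.

## Statistics

* **R²** is the squared Pearson correlation between per-setting prediction
  and evoked-potential amplitude (HDP ↔ EP1, CSBT ↔ EP0), per subject;
  constant series are reported as excluded, never silently dropped.
* **Wilcoxon signed-rank** (two-sided, α = 0.05, no multiple-testing
  correction — matching the comparison design being reproduced): zero
  differences dropped, midranks for ties, exact distribution by dynamic
  programming over sign assignments for n ≤ 25, tie- and
  continuity-corrected normal approximation beyond.  The exact tail is
  verified against full 2ⁿ enumeration and scipy in tests.
* **F-score** on presence/absence (strict > 0 binarization, configurable),
  for the side-effect pathway only; subjects with all-zero observed EP0 are
  excluded and listed.
* Medians/IQRs use linear-interpolation quantiles.
* The default contrast table pairs every variant with the reference
  (DF-Native-Pathway) plus all single-factor pairs — 10 paired tests.
* Directional vs non-directional grouping filters settings by whether a
  single segmented sector is active (pseudo rings count as
  non-directional).

## Problem sizes used in tests and the acceptance script

Cohort-scale checks run 11-subject cohorts with the tabulated setting
counts at 1.0 mm VTA-grid spacing: ranking recovery over ten cohorts
(report: the median over each variant's pooled per-subject R², both
pathways), the warp sweep over three cohorts pooled per magnitude
{0, 1, 2} mm, and all-zero far-bundle series counts over the ranking
cohorts.  Pooling across pathways/cohorts is the reported statistic because
per-pathway, per-cohort medians of near-duplicate variants differ by less
than the zero-inflated EP0 noise floor.  Solver-accuracy checks use
0.5/0.25 mm grids against the closed form.

## Known limitations

* The DF threshold surrogate is calibrated, not mechanistic (see above);
  absolute thresholds in mA should not be quoted, only comparisons.
* Isotropic conductivity only; no dispersion; no explicit cable model.
* The binary VTA inherits all limitations of a fixed E-field isolevel —
  which is part of what the comparison is designed to expose.
* Mask warping is nearest-neighbor and can alias thin structures at large
  warp magnitudes.
* The 2-D axisymmetric shortcut some pipelines use for ring leads is not
  implemented; all solves are 3-D (ring-contact fields are verified
  radially symmetric to solver tolerance instead).
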