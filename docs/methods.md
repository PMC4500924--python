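# Methods

`dbsim` models extracellular activation of brainstem fiber pathways during
deep brain stimulation (DBS) with an 8-contact lead. The chain has four
stages: a synthetic diffusion-tensor phantom, a diffusion-to-conductivity
mapping, a quasi-static anisotropic volume conductor, and populations of
double-cable myelinated axon models whose activation thresholds are swept
over stimulus amplitude, fiber diameter, conductivity scaling, and lead
position. This note records the model assumptions, the parameters that
matter, the numerical choices, and what the synthetic phantom does and
does not establish about real subject data.

## Synthetic brainstem phantom

Real inputs would be a subject's diffusion-tensor volume (1 mm isotropic
voxels) and tract geometries reconstructed from imaging. The phantom
replaces both with controllable ground truth:

- **Background**: isotropic tensors with mean diffusivity
  3.5545e-4 mm^2/s, calibrated so that the conductivity mapping (below)
  returns exactly 0.3 S/m — the conventional isotropic brain conductivity
  — making the isotropic and anisotropic models directly comparable.
- **Tracts**: cylindrical tubes around polyline centerlines. In-tube
  tensors are prolate (axially symmetric) with the principal eigenvector
  along the local centerline tangent (finite differences of the
  polyline). For a target fractional anisotropy FA and mean diffusivity
  m, the eigenvalues are `lam_par = m (1 + 2a)`, `lam_perp = m (1 - a)`
  with `a = FA / sqrt(3 - 2 FA^2)` — the closed-form inversion of the
  Pierpaoli formula for this family — so tract FA is exact to machine
  precision. Real brainstem voxels mix fiber populations; prolate tensors
  are a deliberate idealization that makes orientation and FA exactly
  specifiable. Overlapping tracts resolve in list order (later wins).
- **Default geometry**: a 40 mm cube at 1 mm voxels with three tracts
  chosen to mirror the brainstem statistics reported for this region:
  an oculomotor-nerve-like tract (FA 0.6, characteristic fiber diameter
  8.7 um) running rostro-caudally 2 mm medial of the lead, a superior-
  cerebellar-peduncle-like tract (FA 0.5, 5.7 um) crossing it at 90
  degrees, and a central-tegmental-tract-like bundle (FA 0.4, 2 um)
  orthogonal to both — neighboring bundles thus differ by >= 45 degrees
  in principal orientation, FA spans the sub-0.1 (background) to 0.6
  range, and the principal-axis conductivity mean lands in the observed
  0.30-0.45 S/m band. Tract diffusivities sit 15% above background.
  The lead is oblique (30 degrees off vertical) so no tract is
  grid-aligned with it.
- **Axon seeding**: each axon trajectory is the centerline displaced by a
  constant cross-sectional offset drawn uniformly from the disc of the
  tract radius and parallel-transported along the centerline, so
  trajectories never leave the tube. The cross-sectional distribution of
  fibers in the source tracts is not known; uniform-disc is our choice
  and is exercised by a distributional test (r^2 uniform). All sampling
  is seeded; a fixed seed reproduces every trajectory bit-for-bit.

What passing phantom tests shows: the pipeline treats anisotropy,
geometry, and sampling correctly under known ground truth. What they do
not show: fidelity to any particular subject's anatomy, partial-volume
mixing, DWI noise, or tractography error — none of which are modelled.

## Diffusion-to-conductivity mapping

Conductivity shares eigenvectors with water diffusion and scales linearly
with it: `sigma = s * D` (the effective-medium estimate), with
`s = 0.844 S*s/mm^3` by default (the center of the reported empirical
range 0.844 +/- 0.0545; the sensitivity sweep uses 0.79 / 0.844 / 0.89).
With `D` in mm^2/s the product is S/mm and is reported in S/m. The map is
linear, so it preserves eigenvectors and FA; this is tested. Conductivity
eigenvalues are floored at 1e-6 S/m so numerical noise can never make the
discrete operator indefinite. Fractional anisotropy uses the Pierpaoli
normalized eigenvalue dispersion; an all-zero tensor is defined as FA = 0
with a warning.

## Volume conductor

The quasi-static potential solves `div(sigma grad V) = -I delta(x-x_c)`
with a point current source at the geometric center of the active
contact. Geometry: a 2F lead (0.333 mm radius) with eight 0.5 mm annular
contacts at 0.75 mm pitch, contact 0 distal to contact 7 proximal; a
250 um encapsulation shell at 0.18 S/m; an insulating shaft (1e-6 S/m)
with conductive metal bands (1e3 S/m) at the contacts so source current
enters the tissue through the contact surface; a 20 mm-radius tissue
sphere.

**Return path.** The reference configuration grounds a cranial-chamber
surface whose geometry is not specified; we ground a 5 mm-radius
spherical-cap patch where the lead trajectory exits the tissue sphere,
with the rest of the sphere surface no-flux. This is a declared
convention (same topology: a remote, localized return) and all thresholds
are reported under it. The patch adds a common-mode spreading-resistance
offset (~0.17 V/mA) to the potentials; axonal activation depends on the
spatial variation of the field along fibers, not this offset.

**Discretization.** Trilinear hexahedral finite elements with 2x2x2 Gauss
quadrature on a tensor-product grid: 0.25 mm spacing within 3 mm of the
lead (resolving the encapsulation shell), geometrically graded (factor
1.4) to 1 mm toward the domain box. Element conductivity is sampled by
nearest-neighbor lookup from the 1 mm tensor grid, with the geometric
overrides above. A two-point-flux finite-volume stencil cannot represent
full-tensor cross terms consistently, which is why the discretization is
Galerkin FEM; the operator is symmetric positive definite, annihilates
constants, and is exact for linear potentials in uniform media (all
tested). Outside the tissue sphere sigma = 0: exterior nodes drop out of
the system and the staircase sphere surface becomes a natural no-flux
boundary.

**Solver.** Jacobi-preconditioned conjugate gradients to a 1e-10 relative
tolerance (reported residuals ~1e-10, limit 1e-8); on the production grid
(~390k nodes) a solve takes seconds. The solve is deterministic, so
fixed inputs give bit-identical potentials.

**Verification.** Against closed forms in homogeneous media:
`V = I/(4 pi sigma r)` (isotropic) and
`V = I/(4 pi sqrt(det S) sqrt(x^T S^-1 x))` (anisotropic), with the
analytic values imposed as Dirichlet data on the boundary shell so the
free-space solution is the exact reference in the interior. A grounded
sphere would otherwise differ from the free-space form by a large
boundary term (~50% at r = 10 mm), which would test the boundary
condition rather than the operator. Agreement is within 5% for
r in [1.5, 10] mm; the integrated flux of `-sigma grad V` through boxes
enclosing the source recovers the injected current within 2%; potential
magnitude decays monotonically with distance; anisotropic isosurface
radii scale as sqrt(sigma_axis).

## Axon model

Fibers are double-cable myelinated axons in the McIntyre-Richardson-Grill
(MRG) tradition: 21 nodes of Ranvier joined by internodes with the
repeating sequence node - MYSA - FLUT - 6 x STIN - FLUT - MYSA, with a
periaxonal space under the myelin sheath. Geometry per fiber diameter
comes from the published MRG table (5.7-16 um), linearly interpolated
between entries; the 2 um entry follows the small-fiber convention of
prior brainstem modelling work (axon diameter 1.6 um, node 1.4 um,
200 um internodes, 10 um FLUT, 30 lamellae). Nodes carry fast Na+
(3.0 S/cm^2), persistent Na+ (0.01), slow K+ (0.08) and leak
(0.007 S/cm^2) with the MRG rate equations at 36 C; paranodes (MYSA and
FLUT) carry a slow K+ current — the variant adopted here — at
2e-4 S/cm^2, a density commensurate with the paranodal leak (the source
models do not print one); internodes are passive. Membrane capacitance is
2 uF/cm^2 and axoplasmic (and periaxonal) resistivity 70 Ohm*cm; myelin
is passive with 0.001 S/cm^2 and 0.1 uF/cm^2 per membrane, divided by
2 x lamella count.

**Resting state.** The leak reversal is solved per compartment type so
that -80 mV is an exact equilibrium with gates at steady state (the
nominal -90 mV leak reversal would rest slightly depolarized of -80 mV).
The rest is then a true fixed point: 500 ms of unstimulated integration
drifts < 1e-10 mV.

**Integration.** Crank-Nicolson for the coupled (intracellular,
periaxonal) voltages with Rush-Larsen gating on a staggered half-step
grid — the gate conductances drive the voltage midpoint — giving
second-order accuracy in dt (threshold shift < 1% when halving dt from
10 us to 5 us). The node's myelin short (an algebraic constraint with no
capacitance) is kept fully implicit to avoid an undamped mode. The time
grid is piecewise: 5 us during each pulse and for 1 ms after it, 25 us
until 5 ms past the onset, 100 us through the remaining inter-pulse
relaxation (the slowest gate time constant, ~30 ms, is comfortably
resolved). The linear system is pentadiagonal under interleaved ordering
and solved by banded elimination in a compiled kernel.

**Stimulus coupling and activation.** The volume-conductor potential per
unit current, sampled at each compartment center, enters the outer layer
of the double cable scaled by the pulse waveform (monophasic rectangular,
cathodic by default; 90 us at 20 Hz). Activation requires a propagated
action potential — an upward -20 mV crossing at a node at least 5
internodes from the stimulus focus, 1 ms refractory merge — within the
protocol's latency window after a pulse onset, for at least 8 of 10
pulses. The criterion's canonical window is the closed interval
[1, 3] ms. Over phantom-scale conduction distances a just-suprathreshold
spike arrives 0.2-0.5 ms after the pulse (initiation plus a few mm of
conduction), so the phantom study configuration uses (0, 3] ms: the 3 ms
upper bound is retained and the artifact-exclusion lower bound — which
presumes subject-scale path lengths — is dropped. This is the package's
own convention, set per protocol.

**Threshold search.** The behavioral ramp: amplitudes 0.1 to 3.5 mA in
0.1 mA steps. Because the field is linear in current, one volume-conductor
solve serves all amplitudes. The model is deterministic and 20 Hz pulses
are nearly independent, so the default search probes a single pulse per
amplitude (bisection over the grid, assuming monotone activation) and
then confirms the full 10-pulse 8-of-10 criterion at the found threshold
and one step below, adjusting if they disagree; a full-train search mode
exists and agrees with the fast mode within one grid step on test
populations. If the amplitude cap itself fails to activate, a low
amplitude is probed before declaring the fiber inactive, because very
close fibers can block conduction at high amplitude; a detected
non-monotone bracket falls back to an ascending scan with a warning.
Optional bisection refines thresholds between grid points (used by the
convergence and scaling tests). Fibers silent at the cap carry a NaN
sentinel and count in activation-curve denominators.

## Population pipeline and sweeps

Percent activation at amplitude a is `100 * |{threshold <= a}| / n`.
Populations default to 100 axons per tract (1000 by configuration; at
n = 100 the percent-activation resolution is 1%); each axon is centered
at its trajectory's closest approach to the active source and uses the
tract's characteristic diameter, a fixed diameter, or a seeded uniform
2-8.7 um mixture. Sweeps cover fiber diameter {2, 5.7, 8.7} um, scaling
factor s {0.79, 0.844, 0.89} (re-solving the conductivity), and rigid
0.5 mm lead shifts (medial/lateral toward/away from the
oculomotor-nerve-like tract, anterior/posterior orthogonal; re-solving
the geometry). Field solutions are cached in memory and optionally on
disk (HDF5 keyed by a configuration hash) so only geometry or
conductivity changes trigger re-solves. On a homogeneous phantom the
potentials scale exactly as 1/s, so thresholds scale proportionally to s
— the mechanism behind the observed insensitivity of predictions to the
empirical s range.

## Behavioural comparison

Given a monopolar-review table of side-effect thresholds per contact, the
report compares the model's percent activation at each behavioural
amplitude, the amplitude predicted to activate 5% of the tract, and the
error `100 * |experimental - predicted| / predicted`. The denominator is
the model prediction: it is the unique simple normalization consistent
with published comparison values (a 1.4 mA behavioural threshold against
a 0.1 mA-grid prediction of 1.5 mA gives 6.67%), and is switchable in
principle since the source description ("the difference between") does
not fix it. The 5-15% consistency band is treated as a closed interval.
A closed-loop harness generates a synthetic behavioural table from a
reference run's own 5%-activation amplitudes and verifies zero error —
the parameter-recovery analogue of the zero-error rows in such
comparisons.

## Test scale and determinism

The test suite runs the same code paths at reduced scale: 0.5 mm
near-lead grid spacing (the resolution floor that still resolves the
encapsulation by element membership), 12-100 axons per population, and
two contacts for the closed loop. The production defaults (0.25 mm,
n = 100 or 1000) are unchanged by tests. Every stochastic step (phantom
seeding, mixed diameters) flows from a single integer seed through
`numpy` seed sequences; end-to-end runs are bit-reproducible, which is
itself a tested property.

## Known limitations

- No capacitive or dispersive tissue properties, no electrode-tissue
  interface impedance: purely resistive, current-controlled quasi-statics.
- Point-source contacts (not equipotential metal surfaces); the metal
  band conductivity makes the contact region nearly equipotential but the
  source remains a point.
- The ground-patch return is a convention, not a reconstructed chamber;
  absolute potentials carry a return-path offset.
- Axon trajectories may pass arbitrarily close to (even inside) the
  encapsulation; real tracts are displaced by the lead.
- Prolate single-population tract tensors; no partial-volume mixing.
- Sealed fiber ends sit only ~5 mm from the source on a 21-node fiber;
  under anodic stimulation the depolarized ends can fire before the
  virtual-cathode flanks, so polarity comparisons use 41-node fibers
  whose ends are ~10 mm out.
- No synapses, cell bodies, network effects, or stochastic channels;
  thresholds are deterministic.
- The direction of the anisotropy effect on thresholds (lower or higher
  than isotropic) depends on fiber orientation relative to the
  conductivity eigenbasis and the lead; the package records magnitude
  and direction rather than asserting a universal sign.
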