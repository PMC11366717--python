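# Methods

## Membrane model and SAC current

Membrane kinetics use the 2006 formulation of the ten Tusscher human
ventricular model (epicardial variant by default; endo/mid selectable).
State: Vm plus 18 variables (11 voltage gates, the Ca-subspace gate
fCass, the ryanodine-receptor adaptation variable, and five
concentrations). Voltage gates are advanced by the Rush–Larsen
exponential update, exact for rates frozen over one step; fCass and the
RyR variable use the same exact exponential form with their
Ca-dependent coefficients frozen; concentrations use forward Euler.
The default reaction step is dt = 0.02 ms (the model's customary
stable step; halving it changes tissue Vm by well under 0.5 mV).

The SAC current `I_SAC = g_SAC (Vm − E_SAC)` is added to the ionic
current sum for every cell of the stretch region, with one conductance
drive broadcast to the whole region. The drive relaxes exponentially
toward a target (tau = 1.8 ms, target 0.1 mS/uF on activation, 0 again
once |g − 0.1| < 1e-13). The conductance update is the exact
exponential solution, so the trajectory is step-size independent; the
switch-off check runs once per solver step, which places the realized
switch within one step of the analytic time tau·ln(g_target/eps)
≈ 49.74 ms (reported as the 50 ms pulse). Drive and stimulus timing are
scheduled on integer solver steps so that a run restarted from a
checkpoint replays bit-identically.

### APD calibration

The tissue model anchors its APD gradient at APD90 = 290 ms for the
IKs-scale-1 cell after 50 prepacing beats at BCL 500 ms. The stock
epicardial variant gives 283.3 ms under that protocol, so a single
multiplicative adjustment of the rapid delayed rectifier conductance,
`GKR_ADJUST = 0.822`, is calibrated once by bisection against the
290 ms reference and frozen
(`sacsim.cell.calibration.calibrate_gkr_adjust` reproduces it). APDs at
other IKs scalings are then predictions: the calibrated model yields
205.2 ms at scale 4 and 213.2 ms at scale 3.5 (reference values 206 and
214 ms). Upstrokes and secondary APs are detected as upward crossings
of −20 mV; APD90 uses the pre-stimulus Vm of the measured beat as its
baseline.

## Synthetic geometries

Patient anatomy is replaced by structured-grid stand-ins that keep the
mechanistically relevant structure:

* **rod** — 1D cable (default 10 cm at 530 um) used for all
  conduction-velocity calibration; fibers axial or transverse.
* **sheet** — 2D wall analog: x is the apicobasal coordinate (apex at
  x = 0), y the transmural coordinate (endocardium at y = 0).
* **slab** — 3D wall: x apicobasal, y lateral, z transmural.

Element-centered coordinates, positions in mm, half-open shell binning.
The transmural coordinate is the min–max-normalized Laplace solution
between the endo- and epicardial faces (a 1D tridiagonal solve on the
box geometry, exactly the linear depth fraction). Fibers rotate
linearly from +60° at the endocardium to −60° at the epicardium in the
wall-tangent plane; the sheet-normal vector is the in-plane unit vector
perpendicular to the fiber (fiber, sheet-normal, and the transmural
axis form the orthonormal triad). A 1 mm endocardial layer is
isotropic and fast (2 m/s) to emulate Purkinje-mediated activation;
four spherical root points (1 mm radius) on the endocardial face, three
simultaneous and one delayed by 5 ms, deliver the sinus stimulus
(100 uA/uF for 1 ms per element; the stimulus is interpreted
per-capacitance because a volume source in absolute uA is dimensionally
ambiguous on a grid).

The SAC region is a sphere (disc in 2D) of configurable radius
(7–10 mm studied), centered one third of the apicobasal distance from
the apical end and mid-wall transmurally, partitioned into 1 mm
concentric shells tagged 1 (outermost) to K (innermost).

## Heterogeneity, conductivities, fibrosis

The IKs scaling field is the product of two linear ramps (1→2
apicobasally from base to apex, 1→2 transmurally from endo to epi),
giving scale 1 at the basal endocardium and 4 at the apical epicardium.

Monodomain conductivities are not taken from the literature but
calibrated: on the standard rod, sigma is bisected (initial bracket
from the cable-theory proportionality CV ∝ √sigma) until the measured
planar-wave CV — the inverted least-squares slope of activation time
vs distance over the central half of the rod — is within 0.5 % of
target (0.56 m/s longitudinal, 0.21 m/s transverse, 2 m/s endocardial
layer). At 530 um this gives sigma_l = 0.217, sigma_t = 0.0629,
sigma_endo = 2.03 S/m with chi = 1400 /cm and Cm = 1 uF/cm² (these two
constants are absorbed by the calibration; only the CV targets
matter). Conduction slowing by a fraction f (20/40/60 % studied)
re-runs the same calibration against (1−f)·CV — CV does not scale
linearly with sigma — and stores the resulting sigma ratios as region
scaling factors, applied globally or to the SAC region only.

Fibrotic microstructure: every interior face between two SAC-region
elements is made non-conducting with independent probability
`p = a |cos(theta)|`, where theta is the angle between the face normal
and the local sheet-normal direction and `a` rises linearly from 0.1
in the outermost shell to 1.0 in the innermost (using the deeper
adjacent element's shell). On the finite-volume grid "facet
duplication" is exactly equivalent to zeroing the face conductance, so
cleft insertion is local and exact. Elements left with no conducting
face are removed from the active tissue. Sampling is reproducible from
(geometry, seed); the seed is the only stochastic input in the whole
package.

## Tissue solver

Two-point finite-volume discretization on the structured grid: each
face's transmissibility is the harmonic mean of the adjacent elements'
fiber-projected diffusivities `D_nn = D_t + (D_l − D_t)(f·n)²`. The
two-point flux ignores the tensor's cross-terms; for fibers aligned
with or moderately rotated against the grid this under-resolves
off-axis anisotropy slightly, which is acceptable here because all CV
calibration and measurement run along grid axes. Time stepping is
first-order operator splitting: n reaction substeps (dt = 0.02 ms, with
tabulated gate steady states and exponentials on a 0.01 mV grid for
tissue-scale speed; the exact formula path remains available and the
two agree to well below the discretization error) followed by one
diffusion step (dt = 0.1 ms), implicit backward Euler with a
prefactorized sparse LU by default; an explicit option carries a CFL
guard. Boundaries are no-flux. Upstroke events (crossings of −20 mV)
are detected every diffusion step.

The remote extracellular potential uses infinite-volume-conductor
dipole-source recovery, `phi_e = −1/(4 pi sigma_b) Σ_e (sigma_i grad
Vm)_e · grad(1/r) dV`, precomputed as a lead-field vector (sigma_i is
taken as a configurable fraction, default 0.5, of the effective sigma;
only the shape/timing of deflections is meaningful, never absolute
amplitude). Gradients use central differences with one-sided stencils
at boundaries so a uniform field contributes exactly zero. Note that a
*compact* Vm blob has zero net current dipole (∫grad Vm dV = 0); the
1/r² dipole falloff applies to wavefronts (dipole layers), which is how
the φe oracle is constructed. The default electrode sits 20 cm from
the domain center along the outward (epicardial) normal, standing in
for a shoulder electrode.

## Protocols and outcome classification

Tissue runs start from a single-cell limit cycle (50 beats at the run's
BCL; scale-1 reference cell for the 206–290 ms gradient, scale 3.5 for
shortened-gradient variants) broadcast to the tissue, followed by three
sinus prepacing beats. The SAC onset is then varied relative to the
last sinus beat — exhaustively in 1 ms steps, or with a bracketing
search that expands from a seed onset until both window edges are found
and then verifies 5 ms beyond each edge.

The source protocol's visually-determined "global reactivation" is
operationalized as a decision tree on upstroke events (thresholds in
`ClassifierConfig`):

1. events after the sinus beat has completed (activation span + 30 ms)
   are re-excitations; none → **none**;
2. activity that never escapes the SAC region → **none**;
3. if the region was repolarized at pulse onset (mean Vm < −55 mV) and
   re-excitation starts inside the region during the pulse (+25 ms),
   that is the direct SAC-triggered ectopic beat; reentry then requires
   a *second* re-excitation of ≥ 75 % of active elements, otherwise the
   run is **ectopy_only**;
4. without a direct trigger (pulse on depolarized tissue, which SAC
   cannot excite) a single re-excitation wave covering ≥ 75 % of
   elements is **reentry** (the early-repolarization mechanism:
   surrounding tissue propagates back into the early-repolarized region
   and escapes);
5. any activity ≥ 1000 ms after the last sinus activation upgrades
   reentry to **sustained**. Runs that end before that horizon raise an
   error unless sustained assessment is explicitly waived.

Mechanism tags use the SAC-region mean Vm at pulse onset:
"depolarization" below −60 mV, "early_repolarization" above −20 mV.
The 75 % / −55 / −60 / −20 mV values are declared conventions for the
reduced geometry, exposed in configuration, not literature values.

## Desk-scale study conditions

The reduced tissue experiments (test suite) run on a 30 × 20 mm sheet
at 1.0 mm spacing: full APD gradient, CVs re-calibrated at that
spacing (sigma_l = 0.336, sigma_t = 0.122, sigma_endo = 2.22 S/m),
10 mm SAC disc, BCL 500 ms, three prepacing beats, sinus activation
completing in ≈ 67 ms. On this sheet the repolarizing channel
(E_SAC = −70 mV) reproduces early-repolarization reentry with a single
contiguous vulnerability window (56–63 ms, at the end of the sinus
activation); the depolarizing channel (−10 mV) produces propagating
ectopic beats only when the region has repolarized, and with fibrotic
clefts (seed 12345) the trapped, tortuous intra-region propagation
converts an ectopy-only onset into a full reentrant reactivation.

What the sheet does *not* emulate: ventricular anatomy and size (the
healthy-tissue wavelength CV·APD ≈ 115 mm exceeds the sheet, so the
depolarization-mechanism reentry of the full-scale setting appears here
only with clefts), the torso volume conductor, patient-scale window
positions and sustained-reentry fractions. Passing tests therefore
certify the mechanisms and their parameter dependence at desk scale,
not patient-scale numbers. Geometry sizes, onset grids and resample
counts were chosen as the smallest configurations that keep every
mechanism expressed.

## Numerical and design choices

* Cell variant for the baseline gradient: epicardial, with the
  calibrated IKr adjustment carrying the APD anchor (the printed APD
  calibration, not the variant, is the ground truth).
* Gate lookup tables are tied to one dt and interpolated linearly in
  Vm (0.01 mV grid; interpolation error ~1e-9 in the gate values).
* Stimulus sites of 1 mm radius rely on the fast endocardial layer for
  capture; on coarse 3D slabs without that layer, 2 mm sites are used
  because tiny clusters face a 3D source–sink mismatch.
* Degenerate inputs: empty cleft sets reproduce the non-fibrotic
  solution bit-for-bit; zero prepace beats return the broadcast initial
  state; a SAC sphere missing the grid warns rather than errors.
* Determinism: cleft sampling is the only randomness; fixed seeds make
  sweeps bit-reproducible, and checkpoint restarts replay exactly.

## Limitations

No mechanical deformation or strain-dependent SAC gating; no bidomain
or torso forward model; no explicit papillary-muscle geometry; no
alternative ionic models; anisotropy cross-terms neglected by the
two-point flux; patient-scale quantitative results are out of reach of
the synthetic geometries by design.
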