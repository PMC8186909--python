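# Methods

This note documents the models, conventions, numerical choices and
limitations behind each analysis stage. Units: coordinates in Å, times in
ps, forces in pN, mechanical lengths in nm (converted at module boundaries;
1 kJ mol⁻¹ nm⁻¹ = 1.66054 pN for MD-engine force records).

## Structures, trajectories, selections

PDB parsing/writing is delegated to biotite. Altloc records resolve to the
highest-occupancy variant (tie: first encountered); a blank element column
is inferred from the atom name; element masses come from biotite's element
table. Trajectories are ordered frames over a fixed atom list with strictly
increasing times; multi-model PDB carries no time stamps, so frames are
assigned `t0 + i·dt` with a caller-chosen dt. The internal frame store is a
documented columnar `.npz` (times, float32 coordinate blocks, optional box)
— float32 bounds the round-trip error at ~10⁻³ Å, well below any analysis
resolution here. Domain definitions are user configuration (YAML mapping
region name → chain/residue-range entries, `backbone_only` restricting to
N/CA/C/O, chain `*` matching all chains): domain boundaries are a modelling
choice tied to a specific deposition's numbering, and hard-coding them would
silently misaddress other models.

## Pore-radius profiles

The profiler computes, per axial position z, the radius of the largest
sphere centered in that plane touching no van der Waals surface:
r(z) = max_c min_i (|p_i − c| − vdw_i) over atoms i in a slab of half-width
equal to the grid step (overlapping slabs avoid empty-slab artifacts;
default step 0.5 Å). The in-plane maximization is a gradient-free compass
search (step halving down to 0.05 Å, i.e. 0.1 Å resolution) seeded on the
axis at the first slice and at the previous slice's center afterwards —
adequate for near-axial channel pores and far simpler than simulated
annealing; the trade-off is that strongly off-axis or branched pores are out
of scope. Negative clearances clamp to 0 and flag the slice occluded;
slices with no atoms near the axis are flagged unbounded (radius ∞), not
errors. Default vdW radii come from biotite's single-atom table
(config-overridable); hydrogens count when present. The pore axis is
assumed on z: orient the structure (e.g. superpose the channel's symmetry
axis onto z) before profiling. Backbone-only profiles use strictly fewer
atoms and are therefore never narrower — comparing them with all-atom
profiles separates backbone dilation from side-chain motion.

## Collective motion

Superposition is Kabsch via SVD with the proper-rotation determinant fix, so
chirality is never inverted (a mirror-image pair keeps a positive residual
RMSD). PCA runs on superposed coordinates (the intended selection is the
Cα set of the pore-forming region, the standard essential-dynamics choice);
eigenpairs come from the SVD of the centered coordinate matrix, which is the
covariance eigendecomposition without forming the 3N×3N covariance.
Components are orthonormal, eigenvalues (Å²) non-increasing, and the mean
projects to zero. When push/pull labels exist, a component's sign can be
fixed so the pushing group projects positively ("larger score = more
dilated"); otherwise signs are arbitrary, as in any PCA.

The sharp-change filter implements "discard after the distance changes
sharply": baseline mean/SD from the first 10% of frames (configurable), the
cut at the first frame deviating more than 5 SD for at least 3 consecutive
frames, retaining everything strictly before it. A zero-SD baseline falls
back to an absolute threshold with a warning. The filter is idempotent on
its own output.

Domain angles: the domain axis is the dominant principal axis of the
selection's coordinates, sign-fixed against a reference direction so it is
stable across contiguous frames. Tilt is the change of the axis–z angle
versus the initial conformation; rotation is the signed angle between the XY
projections of the axis and its reference, positive for clockwise viewed
from the intracellular side (−z), i.e. right-handed about +z. The same sign
convention defines positive torque in the mechanics layer, so "torque
drives the opening rotation" is a single consistent statement. An axis
parallel to z leaves rotation undefined (NaN, not an error). Frames are
globally superposed on an immobile selection (e.g. the TM core) first.

## Spring mechanics

Reaction forces of a harmonically restrained head domain equal minus the
force the rest of the system exerts on it, which is what makes restrained
heads force sensors. Summaries are windowed time averages per chain and
summed. The in-plane torque about z uses mean planar forces at mean
application points (lever arms in nm): τ_z = Σ (r × F̄)·ẑ. Optional C4
symmetrization rotates each chain's contribution into a common quadrant and
averages — τ_z itself is invariant under that operation (cross-product z
components are rotation-invariant about z), but the reported per-chain
forces become exactly C4-symmetric and the net planar force of a symmetric
system vanishes.

Stiffness is Hooke's law, k = F/Δz: Δz is the difference of equilibrated
mean lengths between a force-free and a forced run, each averaged over the
last half after a stationarity check, with block-average uncertainties. A
response below 0.05 nm (default) is rejected as unresolvable rather than
reported as a huge k. The stationarity check accepts a window whose
split-half mean drift is below 0.5× its SD, or whose drift is statistically
insignificant at 4 SE, with the SE built from the integrated autocorrelation
time (Sokal windowing) of the linearly detrended window. The significance
rescue exists because the plain SD rule false-trips with probability O(1) on
strongly autocorrelated but perfectly stationary series (the slow collective
mode of a long spring relaxes in ~100 ps); detrending first keeps a genuine
ramp from inflating its own noise estimate and hiding.

Bundle stiffness of parallel springs is the sum of per-chain constants; the
elastic-range scan fits k at each force and calls the response elastic when
the relative spread stays below 25% (default). Force-transfer onset is the
first time the free and perturbed force traces deviate beyond 3 baseline SDs
for 5 consecutive samples (defaults; the underlying criterion in such
analyses is visual, so both knobs are exposed), and the transfer speed is
v = L/t̄ with the SD propagated from the onset spread.

## Ion permeation

A crossing is a complete traversal: the ion passes from beyond one bounding
plane to beyond the other while its radial distance stays inside the
cylinder for all intermediate frames — entries that retreat, and re-entries
without completion, never count. This is the strictest convention; it is the
right one when the scientific claim rests on full permeation events.
Periodic boxes are handled through the stored box: a per-frame z jump larger
than half the box is an image change that teleports the ion without
traversing the interior; the same jump without box information is rejected
as an error rather than guessed. Events convert to I = Δq/Δt over the full
analyzed duration and C = I/U (SI units internally; pA/pS in displays).

## Synthetic systems

Every generator is a pure function of its arguments including the seed.

**Bead-spring bundle.** Four chains of 29 beads (one per ankyrin repeat)
plus a restrained head bead per chain, on a supercoiled helix of radius
2 nm, rise 15/29 nm per bead (relaxed length exactly 15 nm) and one
superhelical turn over the 29 repeats. Bonds are harmonic in the bond
*vector* relative to the relaxed geometry rather than in bond length alone:
a freely-jointed chain of length-only springs buckles under any compressive
load, which the solid ankyrin stack does not do, and the vector springs keep
the network linear with an end-to-end axial stiffness of exactly
k_chain = k_bond/n_beads. Defaults encode the studied conditions: k_chain
3 pN/nm, head restraint and flat-bottom lateral confinement (3 nm radius on
the force-bearing terminal bead) both at 100 kJ mol⁻¹ nm⁻² ≈ 166 pN/nm,
forces of 1–5 pN per chain applied along z. Dynamics are overdamped
(Euler–Maruyama Brownian updates): only steady-state and propagation
observables matter here, so inertial detail would add parameters the
emulated system does not constrain. The friction coefficient (10 pN·ps/nm
per bead) and time step (0.02 ps, well inside the stability bound
2γ/λ_max ≈ 0.06 ps) are config constants; the slowest collective mode then
relaxes in ~100 ps, and default runs of 200k steps (4 ns) leave a last-half
analysis window of ~20 relaxation times. Because the network is linear,
running the free and forced simulations with the same seed (common random
numbers) cancels the thermal noise exactly in their difference; stiffness
recovery is then limited by equilibration rather than by noise, which is how
the parameter-recovery tests achieve percent-level agreement at 300 K
within desk-scale run lengths. Per-chain heads are restrained separately;
for the observables used here (common compression under equal per-chain
loads) this is equivalent to a shared rigid head, and bundle stiffness is
measured as total force over common compression.

**Force-transfer fixtures** impose a finite signal speed explicitly (the
perturbed trace departs from baseline after L/v): a bead-spring's emergent
signal speed depends on friction/mass constants the emulated system does not
specify, so the fixture encodes the delay itself and the tests validate the
detector, not a sound-speed prediction.

**Pore cylinders** place atom rings at `profile(z) + vdw`, so the accessible
radius equals the requested profile by construction. **Ion drift**
trajectories integrate drift-diffusion along z in a periodic box with the
ground-truth crossing log computed from the continuous (unwrapped) paths
during generation — the detector, operating on wrapped coordinates plus box,
must reproduce it exactly. **Rigid rotation** fixtures tilt a selection away
from z in the axis–z plane and rotate about z, so the angle readers must
invert them to machine precision. **H-bond toys** solve the donor–H–acceptor
triangle for an exact requested distance and angle.

**Synthetic channel model** (`make_channel_model`, labelled synthetic): a
programmatically built C4 tetramer encoding the structure-derived facts the
geometric analyses are tested against — an hourglass pore narrowing to
0.5 Å at the gate residue ILE 1554 with a wider backbone shell, a 29-repeat
AR spring of 15 nm COM-to-COM extent, and interface residues placed so the
closed-state hydrogen-bond census holds by construction (the 1572–1421
backbone bond, 1244–1571 and 1236–1581 present; 1253–1577 beyond the
criterion; the two AR29–LH pairs present). It contains no hydrogens, like a
typical cryo-EM deposition. Tests on it validate the machinery end to end
(selection → profiling → census) against known truth; they do not re-measure
a deposited structure, and none of the generators emulate solvent, lipids,
electrostatics or force-field detail — passing tests demonstrate correctness
of the analyses, not fidelity of any particular MD system.

## Hydrogen bonds

Criterion: donor–acceptor heavy-atom distance ≤ 3.5 Å and, when the donor
hydrogen is present, D–H–A angle ≥ 120° (both inclusive; the common
geometric standard, config-exposed and recorded in outputs). Donors are N/O
with an attached hydrogen (same residue, ≤ 1.25 Å); acceptors are N/O. The
heavy-atom fallback (distance only) applies structure-wide, only when the
model carries no hydrogens at all — in a protonated model a hydrogen-less
oxygen is an acceptor, never a distance-only donor. Residue-level pairs use
the any-combination rule over both donor→acceptor directions, because
interface bonds are reported at residue granularity; whether the bonded atoms
are backbone is reported, which distinguishes backbone-mediated contacts
(robust to side-chain mutation) from side-chain ones. Occupancy is the
fraction of frames bonded; "stable" means occupancy ≥ 0.7 (default), and
raising the threshold can only remove bonds.

## Degenerate inputs and tie-breaks

Collinear selections reject superposition; PCA requires ≥ 2 frames;
extreme-structure and minimum-radius ties resolve to the earlier frame /
smaller z; empty selections are errors except the gate-water count (warn,
0); zero voltage, zero applied force, empty onset lists and out-of-grid
windows are errors naming the violated precondition.

## Problem sizes

Default test/validation sizes: 120k–200k integrator steps per toy run
(2.4–4 ns), 300–800 frame ion trajectories with 5–20 ions, 31-ring pore
fixtures, 50-geometry H-bond sweeps, 950-frame PCA accounting. These sizes
put every estimator deep in its converged regime for the linear toy systems
while keeping the whole suite interactive.

## Known limitations

- The pore profiler assumes a near-axial pore on z; it does not trace
  curved channels and computes no solvent-excluded surface or electrostatics.
- The bead-spring toy is linear by design: it validates estimators, not
  anharmonic ankyrin mechanics; its torque under pure axial load is zero
  because vector springs decouple compression from twist, so torque analysis
  is exercised on constructed force traces instead.
- Conductance is validated on fixtures and closed-form arithmetic; absolute
  conductance of a real channel requires the original simulations' ion
  trajectories.
- H-bond detection is geometric only — no energetic scoring, no
  water-mediated bridges.
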