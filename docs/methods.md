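# Methods

`nanosorb` is a desk-scale re-implementation of the computational machinery
used to estimate adsorption free energies of small biomolecules at ZnS
nanosurfaces: structure construction, a bonded crystal force field,
metadynamics along the surface separation distance with PMFs from
mean-force integration, the adsorption free-energy functional, and
hydration-shell structure analysis. Production-scale solvated simulations
(microseconds of atomistic MD with mesh Ewald electrostatics) are out of
scope; every estimator here is validated instead on synthetic systems whose
answers are known analytically.

## Structures

Zinc-blende ZnS: the conventional cubic cell carries 4 Zn on the fcc sites
and 4 S on the tetrahedral interstices; the Zn-S bond length is
a·√3/4. The lattice constant is not a fitted quantity here; the default is
the standard ZnS value a = 5.41 Å and it is configurable everywhere.

The (110) cleavage is the stable nonpolar surface. The slab builder works
in a rotated frame (x ∥ [001], y ∥ [1̄10], z ∥ [110]): the surface cell is
a × a√2, layers are stoichiometric (2 Zn + 2 S per surface cell) and spaced
a/(2√2), so a slab holds exactly 4·n_x·n_y·n_layers atoms and is always
charge-neutral. With 8×6 surface cells and 14 layers this reproduces the
published 2688-atom (1344 Zn + 1344 S) slab exactly. The published slab
*depth* (3.32 nm) is not consistent with 14 layers at any standard lattice
constant; the atom counts are taken as authoritative.

Nanoparticles are spheres carved from the replicated crystal about a
configurable fractional center, followed by removal of singly-coordinated
surface atoms. Pruning is a single pass by default (one removal step;
atoms that become under-coordinated only through their neighbours' removal
survive), with a fixpoint mode behind a flag; coordination counts
heteroatomic (Zn-S) contacts within a cutoff of 2.9 Å, chosen between the
first (2.34 Å) and second (3.83 Å) neighbour shells. A sphere about a
cation site is generally not charge-neutral; `scan_nanoparticle_centers`
searches high-symmetry centers (atom sites, bond midpoint, tetrahedral
hole) for neutral stoichiometric cuts — the shipped 2-nm fixture uses the
bond-midpoint center (98 Zn + 98 S, charge 0). The published 5-nm particle
composition (1800 + 1800 atoms) exceeds the zinc-blende density at
a = 5.41 Å and is not reproducible by any spherical cut; the builder
reports its own deterministic counts instead (≈1600 + 1600 after pruning,
final radius ≈ 2.5 nm).

Topology derivation bonds all heteroatomic pairs within the cutoff
(minimum image on periodic axes) and emits all bonded triples as angles;
a cutoff reaching the homoatomic second shell is rejected as ambiguous.
Atoms with coordination < 4 are flagged as surface.

## Force field

The crystal model replaces the original Buckingham + Coulomb pair
interaction and three-body term by harmonic bonds and angles, with formal
charges (+2e Zn, −2e S), Lennard-Jones sites, Lorentz-Berthelot mixing and
special surface-pair overrides (Zn-OC, S-OC) for carbonyl oxygens of a
polymer coating. Electrostatic and LJ interactions are excluded between
bonded atoms; a 1-3 (angle-end) exclusion mode exists behind a flag.
"Surface" atoms for the special pairs are those with coordination < 4.
The packaged `OC` species entry (q −0.5 e, σ 2.96 Å, ε 0.879 kJ/mol) is a
representative carbonyl-oxygen parameter set for toy use; real
coating/sorbate parameters are user inputs.

**Units of the published bond constant.** The source table prints the Zn-S
bond parameters as k_b = 92,000 "kJ/mol" with r_0 = 1.6 Å, and r_0 lies
far below the crystal bond length of 2.34 Å. Both readings of the k_b unit
were tested against the model's own published behaviour (crystal RMSD
within 0.4 Å at 300 K):

- read per Å², the bond force at the crystal geometry is ≈ 6.8·10⁴
  kJ·mol⁻¹·Å⁻¹ per bond and a slab collapses within a single 1-fs step;
- read per nm² (the GROMACS convention for bond constants, i.e. 920
  kJ·mol⁻¹·Å⁻²), a reduced (110) slab holds RMSD ≈ 0.1–0.2 Å over 20 ps
  at 300 K.

The package therefore defaults to the nm⁻² reading
(`zns_table1_forcefield(kb_unit="per-nm2")`), with the literal Å⁻² reading
available. Under this reading the printed r_0 = 1.6 Å is physically
sensible: bonded pairs feel no Coulomb attraction (excluded), while the
non-bonded second shells are like-charged and repulsive, so the bond
minimum must undershoot the crystal distance for the lattice to balance —
the fit window 2.0–2.5 Å extrapolates to a minimum at 1.6 Å.

Harmonic fits use dense-grid least squares (512 uniform points) of
½k(x−x₀)² + c over a user window, with the constant reported and
discarded; a non-convex window (e.g. the attractive Coulomb branch) is
rejected rather than silently fitted. Angle fits operate on any tabulated
energy-vs-angle curve (the three-body functional form of the source model
is not public), fit in radians, and report θ₀ in degrees.

Electrostatics at desk scale use shifted-force Coulomb truncation at the
short-range cutoff (default 1.4 nm) instead of mesh Ewald: energies and
forces go continuously to zero at the cutoff, which keeps NVE dynamics
stable; a direct all-pairs sum is available for non-periodic toys. This is
a documented deviation from the production protocol. For the reduced
stability slab the cutoff is lowered to 0.9 nm so it stays below half the
lateral box.

## Dynamics

Velocity-Verlet integration with either a velocity-rescaling thermostat
(Berendsen-style scaling with coupling time, default 1 ps) or BAOAB
Langevin dynamics; no barostat (the production NpT pre-equilibration is
out of scope). Default timestep 1 fs; neighbour lists are rebuilt every
10 steps with a 2 Å skin. Energy minimization is steepest descent with an
adaptive trust-radius step, guaranteeing a non-increasing energy sequence.
Frozen-atom selections let toy sorbate-over-rigid-surface systems run
fast. Identical seeds and configurations give bit-identical trajectories.
Masses are in amu, energies kJ/mol, lengths Å, times ps (1 kJ/mol =
1 amu·nm²·ps⁻²).

The scaled-down crystal-stability check uses a 4×3-cell, 8-layer slab
(384 atoms), 300 steepest-descent steps, then 20 ps at 300 K with
velocity rescaling; the heavy-atom RMSD from the ideal crystal stays at
0.1–0.2 Å (bound 0.4 Å). These conditions are this package's choice of a
desk-scale stand-in for the published stability test.

## Metadynamics and mean-force integration

The collective variable is the surface separation distance (SSD): the
minimum distance from the sorbate center of mass to the nearest surface
atom. Dynamics use a soft minimum, s = −(1/β) ln Σ exp(−β d_k) with
β = 200 nm⁻¹, for continuous forces (the soft value is within 10⁻³ nm of
the hard minimum on the shipped fixtures); hard-min is used in post-hoc
analysis.

Standard (not well-tempered) metadynamics deposits Gaussians of height
ω = 0.01 kJ/mol and width σ_G = 0.05 nm every τ = 1 ps. The source
protocol prints the width once as 0.05 Å and once as 0.05 nm; 0.05 nm is
the physically sensible CV-scale value and is the default. A one-sided
quartic wall U = κ(s−a)⁴ (a = 1.5 nm, κ = 40 kJ·mol⁻¹·Å⁻⁴, active for
s > a only — the printed form is two-sided but it is described as an upper
wall; a two-sided mode exists behind a flag) keeps the sorbate out of the
bulk. For per-step efficiency the accumulated bias is rasterized on a grid
of spacing σ_G/5 with linear interpolation; the hills list is also kept
exactly and round-trips through a `#! FIELDS`-headed hills file.

The PMF is estimated by force integration, not by bias reconstruction:
each step records the instantaneous systematic force projected on the CV,
F_s = (∇s·F)/|∇s|², with bias and wall forces excluded. For the CVs used
here (COM height, site height — both linear in the coordinates with
|∇s| = 1) this projection has no metric correction. Samples are binned
(bin width σ_G/2 by default) after discarding the first 1/6 of the run as
burn-in (mirroring the production protocol's relative burn-in), and
W(s) = ∫_s^{s_n}⟨F⟩ds′ by trapezoid, zeroed at the largest occupied bin.
Interior gaps of ≤ 2 empty bins are linearly bridged and flagged; larger
gaps raise an unconverged-sampling error. The binning resolution and the
instantaneous-force estimator are this package's choices; the source
protocol does not state its own.

## Adsorption free energy

From a bulk-zeroed PMF:

- r_c is the smallest s with a defined PMF value;
- the layer ends at the first point beyond the *last* PMF minimum where
  |W| falls within `zero_tol` (default 0.1 kJ/mol; the source gives no
  tolerance) and stays there toward the bulk edge — oscillations about
  zero inside the bound region do not terminate the layer. This
  "last minimum, then first sustained crossing" rule is this package's
  resolution of PMFs with multiple zero crossings;
- ΔG_ads = −k_BT ln[(1/δ)∫ exp(−W/k_BT) ds] by trapezoid on the stored
  grid (nodes only, interpolated endpoints);
- binding mode: direct if the global minimum sits below 0.4 nm,
  water-mediated in 0.4–0.7 nm, none if no minimum is deeper than the
  tolerance;
- the result is an excess free energy; `standard_state_shift` adds
  k_BT ln(c/c_st) for a concentration reference.

Statistical errors come from block averaging: the post-burn-in force
series is cut into contiguous blocks (5 by default, mirroring the 50-ns
blocks of the production protocol at desk scale), each block yields its
own PMF and ΔG over the full-run binding region, and the error is the
spread of block estimates over √n_blocks.

k_B = 8.314462618×10⁻³ kJ·mol⁻¹·K⁻¹ throughout.

## Synthetic study systems

The toy surface system is a 1–2-site sorbate over an implicit planar
surface at z = 0; its only s-dependent energy is a prescribed potential
acting on the COM height, so the exact PMF along the COM CV is the
potential itself. Potentials: smooth square well (stiff harmonic core —
the sharp wall is what makes it "square"; thermal penetration is ~0.01 nm
at 300 K), harmonic, quartic double well, and a 9-3 wall. Two-site
sorbates carry a stiff harmonic bond (k = 2·10⁴ kJ·mol⁻¹·nm⁻²,
0.1 nm rest length) and rotate freely, making the site-height CV
genuinely different from the COM CV while ΔG should be invariant.

What these toys do *not* emulate: explicit water (no hydration-shell
barriers in the toy PMFs), sorbate conformational flexibility, and real
surface corrugation; passing the toy-recovery tests therefore validates
the estimators, not the force field's realism.

Orientation ensembles are uniform on the sphere or concentrated about a
polar angle (spread 1/√concentration rad); layered fluids place ideal
particles by inverse-transform sampling of a target ρ(z). One global seed
fans out to independent per-generator streams, so adding a generator never
perturbs existing fixtures. In-repo fixtures: a 2×2×4-layer mini slab, a
2-nm bond-midpoint-centered nanoparticle, and a two-site toy sorbate, all
as XYZ plus plain-text topology.

## Hydration analysis

Density profiles are planar (slab normal), radial (spherical shells) or
nearest-surface-atom distance; each profile carries its bin volumes so
Σρ·V recovers the mean selected-particle count per frame exactly (the
nearest-surface mode is a per-length density, since no unique volume
normalization exists for it). Water orientation uses the geometric dipole
(O → HH midpoint bisector; no charge weighting is needed for 3-site water
with symmetric hydrogens): θ against the surface normal or radial
direction, α for each OH bond. Raw angle histograms of an isotropic fluid
follow sin θ; because that baseline is not flat, a sin-corrected mode is
provided and both are reported explicitly — published orientation figures
often leave the convention unstated, so no peak-angle values are asserted.
RDFs use ideal-gas normalization in the frame box, with a sorbent-COM mode
for molecule-to-polymer distributions; for periodic boxes r_max must stay
below half the smallest box length. First solvation shells are the first
local minimum after the first maximum of the relevant profile after 3-bin
smoothing.

## Numerical scales used in validation

Chosen for one CPU core at desk scale, as the package's own study
conditions: double-well recovery uses 2 ns of BAOAB dynamics (4·10⁵ steps
of 5 fs, friction 10 ps⁻¹); the CV-independence comparison 6 ns per CV;
the reduced-slab stability run 20 ps at 1 fs. The 1-D toys have
deterministic systematic forces along s, so the mean-force profile
converges rapidly; the two-site system carries genuine force noise, and
its site-CV PMF uses a wider zero tolerance (0.5 kJ/mol) in the layer
search so the bound-region detection does not latch onto statistical
wiggles.

## Known limitations

- Shifted-force Coulomb is not Ewald; absolute crystal energies differ
  from the production model even where structures agree.
- The Eq.-2 ΔG with the W = 0-crossing layer rule is only approximately
  invariant under the CV choice (the invariant object is the integral of
  e^{−W/kT}−1); the comparison is made at matched sampling with block
  errors for this reason.
- The mini MD engine has no constraints, rigid water, or barostat, and is
  not intended for solvated production runs.
- The binding-mode thresholds (0.4 / 0.4–0.7 nm) are conventions from the
  adsorption literature for this system class and are configurable.
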