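# Model and methods

`avidmc` simulates the equilibrium adhesion of a single ligand-coated
nanoparticle (NP) to a receptor-bearing, thermally fluctuating membrane
patch, and decomposes the resulting binding free energy into enthalpic and
configurational-entropy contributions.  This note records the model, its
assumptions, the numerical choices, and what the desk-scale tests do and do
not establish.

## Energy model

All energies are in units of k_BT at T = 298 K; lengths in nm.  Mechanical
stiffnesses quoted in N/m convert via 1 N/m·nm² = 243.06 k_BT.

**Membrane.**  A fixed-connectivity triangulated patch, periodic in the
plane, carries the discrete Helfrich energy

    E = (κ/2) Σ_v (2H_v)² A_v + E_area(A),

with the vertex mean curvature discretized by cotangent weights and
barycentric dual areas.  The discretization is certified by its convergence
to the closed-form sphere energy 8πκ (monotone over three icosphere
refinements, final error < 0.5 %).  The default bending rigidity is
κ = 20 k_BT.  Excess area A_ex = (A − A_p)/A (the inverse proxy for
tension; studied range 6–20 %) is imposed by the builder, which shapes the
patch with a bending-dominated undulation spectrum and bisects its
amplitude to the target (±0.5 percentage points), and is maintained during
sampling by a stiff harmonic restraint on the total curvilinear area
(`area_mode="clamp"`, stiffness 10⁶ k_BT per unit relative deviation,
giving ~0.1 % area fluctuation).  A plain frame-tension mode
σ·(A − A_p) is available via the same switch.  Vertex moves are
out-of-plane displacements on the fixed in-plane lattice.  This Monge-style
restriction is what makes the patch self-intersection-free by construction
and receptor point-location O(1); at the studied A_ex ≤ 20 % the neglected
overhangs are irrelevant.  Link flips are not used: lateral fluidity is
carried by the mobile receptors.

**Nanoparticle classes.**  Rigid (RG): a 50 nm sphere with 162 ligands
grafted radially (quasi-uniform spherical-Fibonacci placement); no internal
degrees of freedom.  Semirigid (SRG): the same rigid core with each ligand
tip tethered to its surface anchor by a harmonic spring (stiffness
3.3×10⁻⁴ N/m, rest length 15 nm).  Deformable core–shell (LSt/HSt): a
bead–spring star of f = 25 arms × 4 beads (bead radius 6.8 nm, spring
stiffness 1.74×10⁻⁴ N/m) on a 16 nm core (chosen as the smallest core for
which the rest geometry is free of bead–bead overlap); ligand tips tether
to the outer-shell beads.  The high-stiffness variant adds crosslink
springs between same-shell nearest-neighbor beads of different arms
(`crosslink_fraction` of all such candidate pairs; 0 = LSt, 1 = HSt), with
rest lengths frozen at the build geometry.  An affine uniaxial-compression
probe (`estimate_elastic_modulus`) documents that crosslinking stiffens the
particle; only the LSt < HSt ordering is asserted, since the probe's
absolute scale (no internal relaxation) is not comparable to the
experimental kPa moduli of the physical particles.

The ligand tips are explicit coordinates tethered to their parent (bead
center for core–shell, surface anchor for SRG) with rest length
a_bead + L_l and an entropic-spring stiffness derived from the shell
polymer's own parameters: treating the 15 nm ligand linker as a Gaussian
chain of Kuhn segments b_k = 0.44 nm gives k = 3k_BT/(N_k b_k²) ≈
0.46 k_BT/nm².  Rigid-particle tips are fixed to the body.

**Receptors.**  N_r mobile anchors on the membrane surface (counts quoted
per 0.25 µm² reference patch, rescaled to smaller patches at fixed areal
density), each a rigid rod of length L_ant = 19 nm with flexural rigidity
k_f = 7000 pN·nm².  The rod orientation is not an explicit degree of
freedom: unbound rods are free (orientation integrated out), and a bound
rod points along its bond, paying the harmonic tilt energy
(k_f/L_ant)θ²/2 against the local surface normal.  Receptor mass
(1.5×10⁻²² kg, an ~90 kDa adhesion receptor) enters only logarithmically
via the thermal wavelength and cancels in entropy differences.

**Bonds.**  A ligand tip and a receptor anchor at separation d carry the
Bell-type bond energy ΔG₀ + (k_b/2)(d − d₀)², with rest length
d₀ = L_ant (tip–tip contact of the pivoting rod) and the three studied
binder systems (ΔG₀, k_b) = (−19.1 k_BT, 1 N/m), (−11.45, 0.38), (−1.76,
0.56) for strong, intermediate and weak binding.  Bonds are one-to-one and
exist only within a capture window |d − d₀| ≤ δ with (k_b/2)δ² = 5 k_BT.

Because ΔG₀ is a solution binding free energy (1 M standard state), the
statistical weight of a formed bond is mapped onto the tethered geometry as
K_A·ρ_tip, with K_A = v₀·exp(−ΔG₀) and ρ_tip the spatial density of the
free rod's tip at the ligand position.  Written as an energy this adds a
constant anchoring cost per bond,

    + ln( 2π L_ant d σ_d √(2π) / v₀ ),      σ_d = k_b^{-1/2},

about 5.4–5.9 k_BT for the studied binders.  Omitting it would let stiff
bonds overbind (the intermediate binder would then bind rigid particles,
contrary to the monovalent-regime boundary the model must reproduce);
adding the rod orientation as a further explicit degree of freedom would
double-count phase space already contained in the measured ΔG₀.

**Couplings.**  Soft-core repulsion (2 k_BT/nm²) between membrane vertices
(contact radius 5 nm, half the lattice spacing) and the particle core and
beads; a soft penalty (10 k_BT/nm²) for ligand tips dipping below the local
surface; and a hard wall confining the particle center to the simulation
box height (620 nm at the full 500 nm patch, scaled proportionally).

## Sampling

Metropolis Monte Carlo over five elementary move classes (one attempted
move = one MC step): vertex height moves, receptor hops (with an exact
surface re-interpolation of the anchor), rigid-body particle moves, single
bead/tip moves plus whole-arm pivots about the core (25 % of bead moves;
the large-scale flattening mode of star polymers), and bond moves.  Move
amplitudes auto-tune to a 30–50 % acceptance band during equilibration and
are frozen for production.  Default move mix: vertex 0.35, hop 0.25, rigid
0.10, bead 0.15, bond 0.15.  The random stream is NumPy's PCG64 with one
seed per replica (default four replicas; replica SDs are the quoted
errors).  Energy components are updated incrementally per move, with
periodic from-scratch resynchronization; the incremental bookkeeping is
itself tested against full recomputation.

Two sampling problems dominate this system and shape the bond-move design.
First, a stiff bond (σ_d ≈ 0.06 nm for the strong binder) makes blind
formation proposals hopeless.  Bond moves therefore mix four exact
schemes, each satisfying detailed balance on its own:

* *in-place* Rosenbluth formation among capture-window candidates
  (acceptance min(1, W/(B+1)) against uniform breakage min(1, B/W'));
* *anchor regrowth*: formation relocates a free receptor's anchor into the
  capture disk/ring of a free ligand tip (mixture proposal whose density is
  cancelled exactly in the acceptance), balanced by breakage that scatters
  the freed anchor uniformly;
* *ligand regrowth*: the tip itself is drawn directly from the bond's own
  Boltzmann shape around a receptor (separation ~N(d₀, σ_d), tilt from the
  flexural Rayleigh distribution), with regrowth into the tether cloud as
  the exact reverse — this is what decouples bond formation from the
  instantaneous tip presentation height;
* *heat-bath partner resampling*: one receptor's bond state is redrawn
  from its exact conditional (unbound, or any capture-range ligand),
  letting quasi-irreversible strong bonds exchange partners without full
  dissociation.

Second, once a stiff bond exists it pins its tip: naive rigid-body moves
would drag the tip and be rejected at the 100 k_BT/nm scale, freezing the
particle.  Rigid and arm-pivot moves therefore hold bound tips in place
and let the soft tether stretch (its energy change enters the acceptance),
which reflects the physical coupling — the bond holds tip to receptor, the
body couples through the linker — and restores particle mobility.

All four schemes and the pinned-tip convention are verified against exact
partition-function enumeration on frozen two- and three-state toys (3σ
agreement at ~10⁶ steps).

**Initialization.**  The particle is placed with its lowest ligand tip one
rod length above the local surface; receptors are uniform over the patch.
One favorable bond is pre-formed between a low tip and a receptor
relocated beneath it (for mobile-tip particles the tip is regrown onto the
perfect bond geometry over the best tether-reachable spot).  This encodes
the near-membrane initialization: it skips only the first-contact waiting
time, and unfavorable bonds dissolve during equilibration — the
intermediate-binder rigid case still equilibrates to ⟨m⟩ ≈ 0.  During
equilibration a soft z-restraint (0.02 k_BT/nm²) additionally holds the
particle near its initial height (the nucleation scaffold); it is removed
before production, so sampled statistics are unbiased.

## Thermodynamic analysis

ΔH is the bound-minus-unbound difference of mean total energy under
identical schedules; the unbound reference displaces the particle beyond
interaction range, disables bond moves, and holds it with a soft
z-restraint so its internal and rotational fluctuations are sampled under
comparable conditions.

ΔS has three configurational terms, each bound-minus-unbound:

* **Particle**: classical quasiharmonic entropy from the eigenvalues μ of
  the mass-weighted covariance of bead+tip positions after Kabsch removal
  of rigid-body motion; per mode S/k_B = 1 + ln(√(k_BT·μ)/ħ).  Modes below
  10⁻¹⁰ of the leading eigenvalue (or below an absolute numerical floor)
  are discarded as constraint/noise modes.  The classical form is valid
  here (k_BT/ħω ~ 10⁵ for all modes).
* **Membrane**: the same covariance-spectrum construction applied to the
  out-of-plane vertex displacements with the vertex mass.
* **Receptors**: the two-dimensional Sackur–Tetrode entropy
  S/k_B = N[ln(A/(NΛ²)) + 2].  Convention for the bound state: the mobile
  remainder explores the patch area minus the adhesion footprint
  (convex hull of the bound anchors), and each bound receptor keeps the
  translational entropy of its own bond well, of in-plane area
  2π d₀ σ_d.  Deleting bound receptors from the count instead would
  charge the full absolute single-particle entropy (~22 k_B) per bond —
  confinement that the bond free energy already carries — and drives the
  decomposition inconsistent with the sampled occupancies.

Both quasiharmonic estimators reproduce closed-form Gaussian-oscillator
entropies to 1 % at 10⁴ samples.  ΔF = ΔH − TΔS holds identically in every
emitted result; per-bond quantities divide by ⟨m⟩ and are undefined when
nothing binds.

**Multivalency statistics.**  P(m) is the normalized histogram of sampled
bond counts on [0, min(N_r, N_l)]; modes are local maxima of a
Gaussian-smoothed copy (σ = 1.5, minimum prominence 0.02, support
endpoints included so saturation peaks are not missed).  Peak locations,
not heights, are the tested observable — coexisting adhesion modes
exchange too rarely for relative weights to converge.  Coverage
θ = ⟨m⟩/N_l; the selectivity index α = d lnθ/d lnN_r uses central log-log
finite differences (one-sided at edges), reported only inside
0.1 ≤ θ ≤ 0.9, with α ≥ 1 flagging superselectivity.  Excess-area row
contrasts of ΔF use Welch's test with Satterthwaite degrees of freedom and
Benjamini–Hochberg control across all contrasts of a diagram (stars at
q < 0.05).

## Problem sizes

Full-scale presets mirror the studied system: 500×500 nm² patch (52×52
lattice, 2704 vertices — the closest periodic triangulation to the nominal
count; a closed periodic surface fixes N_links = 3N_v), 162 ligands,
receptor counts {50, 125, 250, 500, 1000} per 0.25 µm², with the nominal
5×10⁸/10⁹-step schedule.  The shipped analyses and tests run desk-scale
systems chosen to keep each run in minutes on one CPU while preserving the
statistical structure (per-receptor ligand multiplicity, areal receptor
densities, κ, binder parameters): patches of 120–250 nm with proportional
vertex counts, the full 162-ligand rigid particle (its contact-zone
physics is patch-size independent), and 10–24-ligand deformable/semirigid
particles.  The rigid-particle sweep behind the reproduction targets uses
a 250 nm patch, receptor counts rescaled at fixed density, and
6×10⁴/1.2×10⁵ steps per density.

## What the desk-scale tests show — and what they do not

The generator emulates single-NP adhesion to a bare elastic membrane with
idealized, identical receptors.  Desk-scale runs reproduce the structural
phenotypes: rigid particles cap at a few per cent of ligand capacity under
strong binding and do not bind under intermediate binding; deformable
particles saturate receptor-limited (P(m) mode at N_r) or ligand-limited
(mode at N_l); semirigid particles sit in between.  They do not establish
quantitative free-energy surfaces at the full experimental scale, membrane
wrapping of large rigid cores (desk patches are too stiff at these sizes),
kinetic rates, or any effect of lipid/protein heterogeneity, receptor
polydispersity or inter-particle competition, none of which are modeled.

## Known limitations

* The standard-state anchoring constant is the one quantity the study's
  public description does not pin down; the v₀ = 1 M convention adopted
  here reproduces the published monovalent-regime boundary (strong binders
  saturate deformable particles; intermediate binders cannot nucleate
  adhesion of rigid ones), but per-bond free energies shift rigidly with
  ln v₀ under a different convention.
* Membrane-mediated wrapping of the semirigid particle (curvature
  recruitment) is underrepresented at desk scale, where the patch is small
  and the area clamp stiff.
* The affine compression probe orders particle stiffness but does not
  reproduce experimental moduli.
* Bond formation/breakage is equilibrium sampling; no kinetic rates can be
  read off the move statistics.
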