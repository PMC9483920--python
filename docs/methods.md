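# Methods

## Interaction model and confinement

Particles are hard spheres of diameter σ with a square-well-linear SALR
tail: an attractive well of depth ε on σ ≤ r < λσ and a linear repulsive
ramp εζ(κ − r/σ) on λσ ≤ r < κσ, continuous at the outer cutoff κσ and
discontinuous at the well edge.  Defaults ζ = 0.05, λ = 1.5, κ = 4.0 are
the constants of the studied system; the API accepts any ζ ≥ 0,
1 < λ < κ.  Everything is in reduced units (σ = ε = 1).

Confinement is a hard-walled spherical shell R_inn ≤ |r| ≤ R_out with the
walls inclusive: particle centers may sit exactly on either wall.  Two
volumes appear and must not be confused:

* the **configurational volume** V = (4π/3)(R_out³ − R_inn³), the space
  available to particle centers — this is the V used in the grand-canonical
  acceptance rules, paired with the uniform insertion proposal;
* the **reporting volume** V_acc = (4π/3)[(R_out + σ/2)³ − (R_inn − σ/2)³],
  padded by half a diameter on each side to account for the hard cores —
  the convention behind the quoted number density ρ\* = Nσ³/V_acc.

Below R_inn ≈ 1.5σ particles on opposite sides of the inner sphere are
within the repulsive range of each other and ordered structures are
short-lived; constructing such a shell emits a warning.

## Grand-canonical Monte Carlo

One MC step is one trial move: a displacement with probability 0.95,
otherwise an insertion or deletion (equal odds).  Displacements are
uniform in a cube of half-width δ = 0.5σ; δ is fixed during production (an
optional equilibration-phase tuner targets 30–50% acceptance, then
freezes, preserving detailed balance where averages are taken).  The
de Broglie wavelength is set to σ, so the activity is z = exp(μ\*/T\*)σ⁻³
and printed chemical potentials are directly usable.  Acceptance rules are
the standard Metropolis forms

* insertion: min(1, zV/(N+1) · e^(−βΔU)), position uniform in the shell
  (radius by inverse CDF of r², direction isotropic) or in the box;
* deletion: min(1, N/(zV) · e^(+βΔU_particle));
* displacement: min(1, e^(−βΔU)), with moves through a wall rejected.

Energies are tracked incrementally with a linked-cell list (cubic cells of
edge ≥ κσ; a single-cell brute-force path serves domains too small for
three cells per side).  The incremental total is checked against a full
O(N²) recomputation in the tests (drift ≤ 10⁻⁸·N ε over 10⁶ moves).  All
randomness flows through one seeded generator inside the compiled kernel,
so trajectories are bit-reproducible for a given seed.

Validation limits: with interactions disabled the shell holds an ideal
gas — ⟨N⟩ = zV and the particle number is Poisson (chi-square p > 0.01);
with ζ = 0, λ → 1 a pure hard-sphere box at low activity reproduces the
second-virial density inversion within 5%.

A minimal periodic cubic box mode (minimum-image convention) exists for
bulk reference runs; it shares the kernel and all analysis code.

## Density field and iso-surfaces

The bounding cube of the shell (padded outer radius) is divided into cubic
cells of edge σ/2.  Sampled configurations increment one cell per
particle; the mean local density integrates exactly to the average
particle number over the accumulated samples (asserted to 10⁻¹⁰ relative).
Iso-density surfaces at ρ_iso = 0.4σ⁻³ are extracted by marching cubes
with cell values taken at cell centers, and exported as OBJ or legacy
ASCII VTK.  The full cube is gridded; cells outside the shell are simply
zero.

A note on the sphere-area oracle used in the tests: marching cubes over a
*binary* indicator of a ball inflates the area by ~10% (surface-normal
quantization).  The accumulated density of a uniformly filled ball
converges instead to the fractional cell coverage, for which the extracted
area is within 5% of 4πR²; the synthetic test field is built accordingly.

## Cluster identification and classification

Particles at distance ≤ r_bond are bonded; clusters are connected
components of the bond graph.  The default r_bond = λσ = 1.5σ bonds
exactly the pairs inside each other's attractive well.

Shape classification works on a one-dimensional skeleton:

1. geodesic (bond-graph) distances from an extremal particle give the
   cluster's *extent*;
2. for elongated clusters a **cut test** decides the topology: a thin slab
   perpendicular to the local tube axis (the gradient direction of the
   distance field), bounded to the geodesic neighborhood of the cut point,
   is removed — a loop stays in one piece, an open tube falls in two.
   Several cut locations are tried, since a slab through a sparse section
   may fail to sever;
3. the (possibly cut-open) tube is coarse-grained Reeb-style: the distance
   from one end — a cut face for loops, the extremal particle for open
   tubes — is binned in slabs one bond length wide, each slab splits into
   its bond-connected pieces, and piece centroids become skeleton nodes.
   Slab width = r_bond guarantees a bond can only connect the same or
   adjacent slabs.  Small degree-1 side nodes (below ~¾ of the median node
   population) are fringe artifacts of slab-boundary jitter and are
   absorbed into their neighbor; genuine tube ends carry a full
   cross-section of particles.
4. a skeleton that is a clean cycle is a **closed tube**; a clean path is
   an **open tube** (two free ends) unless its extent is ≤ 1.5 × the tube
   diameter, in which case the cluster is a compact blob (**spherical**);
   clusters smaller than five particles are spherical by default.  Any
   branching skeleton is reported as **irregular** with diagnostics —
   never silently forced into a class.

Measuring from a *point* source on a loop produces a cross-section stub
(the particles "behind" the source) that fakes a branch; measuring from a
cut face removes the artifact.  This cut-based construction replaced an
earlier mid-sphere-projection design: it needs no assumption about the
embedding geometry, so the same code classifies confined shells and
unwrapped bulk clusters.

The **tube radius** estimator reports 3/2 × the mean perpendicular
distance of member particles from the (smoothed) skeleton polyline: a
uniform disk of radius R has mean axis distance 2R/3, so a uniformly
filled tube of radius R reads R (verified to ±0.12 on a random uniform
filling).  A hollow tube wall at radius a reads 1.5a under this
calibration.  Lattice-filled fixtures (below) read ~10% low because the
discrete lattice misrepresents the continuum radial moment.  The skeleton
nodes are smoothed with a window-3 moving average; residual node wobble
biases nearest-axis **spacing** estimates a few percent low (measured
−0.1 to −0.25σ on straight parallel tubes 6σ apart), which the test
tolerances reflect.

Cluster spacing is the mean over skeleton nodes of the distance to the
nearest skeleton segment of a different cluster — or of the same cluster
beyond a fold cutoff (default 8σ) along the skeleton, so a single coil
measures the distance between its own folds.  Handedness is the sign of
the summed discrete torsion of the skeleton; both chiralities occur and
are treated identically.

In the periodic box, clusters are identified with minimum-image bonds,
unwrapped by breadth-first minimum-image walking, and classified with the
same machinery; only tube-like clusters contribute to the bulk radius
statistic (a straight-axis PCA fit misreads bent or merged clusters and
was discarded).

## Packing model

The generating packing of k tori and l polar spheres (tube diameter = the
shell width W) crosses the cut plane in n = 2k + l points on the mid-shell
circle of radius R_c = R_inn + W/2, spaced by the chord 2R_c·sin(π/n).
Close packing of n tube cross-sections of diameter D gives
R_inn = D/(2 sin(π/n)) − W/2.  Two conventions for D coexist: the pure
geometric model uses D = W; for matching simulations the effective
spacing d\* stands in for D, because the soft long-range repulsion — not
hard contact — sets the distance between cluster centers.  The default
d\* = 5.6σ reproduces the packings of all four simulated shells
(n = 6, 8, 9, 11); a brute-force scan shows any d\* in (5.53, 5.91) does,
and the scan is frozen as a test.

Connectivity of a derived structure is computed on the n meridian
positions: each hemisphere contributes a perfect matching (every
half-torus joins mirror positions about that hemisphere's polar axis) with
caps at its sphere positions; tracking angles in half-quanta θ/2, a
rotation by m half-quanta is a pure rotation for even m and a hybrid
(hemispheres from the two degenerate packings of an even-n shell) for odd
m.  Components of the union of the two matchings are the clusters:
alternating cycles are closed tubes, alternating paths open tubes ending
at caps, and a doubly-capped position is a spherical cluster.  The trace
is verified exhaustively for n ≤ 31 against an independent
graph-components oracle, and the bookkeeping identity
(open ends) + 2·(spheres) = l_A + l_B holds for every structure.  Center
lines are emitted as half-circle polylines on the mid-shell sphere; the
construction is an isometry, so the total arc length is invariant under
the rotation — a frozen test — and ±m rotations give mirror-image
(opposite-handed) structures.

Sphere placement: one polar sphere sits at a pole; two sit at both poles;
with l = 0 the position grid is offset by θ/2 so no position is polar.

## Synthetic fixtures

`fixtures.decorate` fills the tube volume around each center line (and the
balls of spherical components) with particles at 0.9 per σ³ — above the
iso level 0.4 so surfaces are well formed, below jamming, and near the
interior density of clusters in this regime.  Filling uses an FCC lattice
(nearest-neighbor distance 1.16σ at that density) clipped to the tube,
with a uniform ball jitter of radius 0.1σ to break lattice artifacts;
jitters that violate the hard core are re-drawn deterministically.
Random sequential insertion cannot reach 0.9σ⁻³ (hard-sphere RSA
saturates near 0.73σ⁻³), which is why a lattice is used.  Tube radius
defaults to the equilibrium cluster radius r₀ = 1.5σ.

Fixtures are geometric stand-ins, not thermodynamic microstates: they have
no density fluctuations, no inter-cluster vapor, lattice-discretized
radial profiles, and exact menu connectivity by construction.  Passing the
recovery tests therefore shows that the analysis chain inverts the
generative geometry exactly — it does not by itself validate the
simulation, which is tested separately against closed-form limits and the
scaled-down self-assembly runs.

## Scaled-down run design

The original campaign used 2×10¹⁰ trial moves per state point; the runs
here are sized to converge on one desktop CPU in minutes, chosen before
freezing the tests:

* **Bulk reference** (lattice constant and tube radius): periodic box
  L = 12σ — commensurate with two rows of the hexagonal phase — at
  T\* = 0.35, μ\* = −2.30 (inside the stated stability window), 3×10⁷
  moves from empty.  The inter-axis spacing is read from the pair-
  correlation peak between 4 and 6σ (5.9σ observed); tube radii from the
  skeleton estimator on unwrapped clusters (1.6–1.9σ across seeds).  At
  μ\* = −2.17 the desk-scale box forms a single percolating labyrinth
  whose radius is not measurable, so the lower-μ point in the same phase
  is used.
* **Small-shell menu** (shell (3, 8), μ\* = −2.17): five independent
  5×10⁷-move runs; the final configuration's cluster signature is compared
  against the six-crossing menu.  At this scale only a minority of seeds
  anneals into a menu structure (one seed forms a clean closed loop); the
  remaining runs are trapped in branching defected states whose healing
  requires deleting well-bonded particles, an exponentially slow process.
  The corresponding test states the majority criterion and currently
  fails at desk scale; runs 2–4× longer were checked and remain trapped.
* **Largest-shell plateau** (shell (7.5, 12.5), μ\* = −2.17): growth from
  an empty shell in 10⁶-move windows until the window mean of N changes by
  less than 1% over two consecutive windows (minimum ten windows).  Seed 1
  plateaus at ⟨N⟩ ≈ 1.6×10³ after 2.6×10⁷ moves (ρ\* ≈ 0.21) — within the
  reported 1000–2200 particle range; a desk-scale plateau may undershoot
  the fully equilibrated value slightly.

## Known limitations

* Snapshot-based cluster classification is stricter than visual inspection
  of time-averaged iso-density surfaces: instantaneous bridges between
  folds read as irregular even when the averaged density would separate
  cleanly.
* The spacing estimator carries a small negative bias from skeleton-node
  wobble (documented above); the tube-radius calibration assumes a
  uniformly filled tube.
* Hybrid structures are enumerated only for shells whose even-n packing
  admits both degenerate decompositions; the packing model asserts, but
  does not prove, optimality of the generating packings.
* No cluster moves or parallel tempering: deep quenches anneal slowly, so
  desk-scale self-assembly runs can stay in defected states (see above).
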