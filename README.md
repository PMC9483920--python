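# salrshell

Self-assembly of colloids with competing interactions (short-range
attraction, long-range repulsion — SALR) confined in narrow spherical
shells.  The package provides:

* a grand-canonical Monte Carlo (GCMC) engine for the square-well-linear
  SALR fluid between hard concentric spheres (plus a minimal periodic-box
  mode for bulk reference runs),
* the analysis chain used to identify the self-assembled structures:
  three-dimensional local density accumulation, iso-density surfaces
  (marching cubes), and bond-graph cluster analysis with shape/topology
  classification (spherical blob, closed tube, open coiled tube),
* the geometric packing model that predicts and enumerates those
  structures: optimal packings of tori and spheres in a shell, the
  hemisphere-rotation construction that derives coiled structures from
  them, and hybrid structures combining two degenerate packings,
* a fixtures module that decorates predicted structures with ideal
  particle configurations, so every analysis stage is testable without
  long simulations.

## Model

Monodisperse spheres of diameter σ interact through the
square-well-linear potential

```
           ∞                      r < σ
u(r) =    −ε                      σ ≤ r < λσ
           εζ(κ − r/σ)            λσ ≤ r < κσ
           0                      r ≥ κσ
```

with ζ = 0.05, λ = 1.5, κ = 4.0 (reduced units: σ = ε = 1).  The fluid is
confined between hard walls at radii `R_inn` and `R_out` with
`W = R_out − R_inn = 5σ`, and simulated in the (μ, V, T) ensemble at
T\* = k·T/ε = 0.35, where the bulk phase is a hexagonal arrangement of
cylindrical clusters with lattice constant l₀ ≈ 6σ and cluster radius
r₀ ≈ 1.5σ.

In a shell of width W the cylinders reorganize into stacks of tori and
polar spheres.  A *generating* packing of k tori and l ∈ {0, 1, 2} polar
spheres crosses a meridian plane in n = 2k + l equally spaced points;
cutting the shell along that plane and rotating one hemisphere by a
multiple of θ = 2π/(2k + l) reconnects the tube ends into *derived*
structures — single or double helices, closed loops, and mixtures — whose
connectivity the package computes combinatorially and verifies against
simulation.

## Worked example

Predict the structure menu for the shell R_inn = 6σ, R_out = 11σ:

```
$ salrshell predict --r-inn 6 --r-out 11
shell (6.0, 11.0): mid radius 8.5, n = 9, theta = 0.698132 rad
  generating packing: 4 tori + 1 spheres
  m/2=0: rotation 0*theta: 4 closed + 0 open + 1 sphere
  m/2=2: rotation 1*theta: 0 closed + 1 open + 0 sphere
  m/2=4: rotation 2*theta: 0 closed + 1 open + 0 sphere
  m/2=6: rotation 3*theta: 1 closed + 1 open + 0 sphere
  m/2=8: rotation 4*theta: 0 closed + 1 open + 0 sphere
```

The selected packing has nine meridian crossings (four tori plus one polar
sphere, θ = 2π/9 ≈ 0.70 rad).  The generating structure contains five
clusters; rotating one hemisphere by θ, 2θ or 4θ coils everything into a
single open tube, while 3θ yields one open and one closed cluster — the
same menu the simulations produce for this shell.

The same machinery from Python, with a synthetic configuration:

```python
from salrshell import (
    ShellGeometry, derived_connectivity, FixtureSpec, decorate,
    build_clusters,
)

shell = ShellGeometry(6.0, 11.0)
structure = derived_connectivity(9, 1, 1, 6)      # rotation by 3*theta
cfg = decorate(FixtureSpec(structure=structure, seed=3), shell)
clusters = build_clusters(cfg, r_bond=1.5)
print(cfg.n, clusters.summary())                  # -> 994 (1, 1, 0)
```

994 particles decorate the structure; the cluster analysis recovers one
closed and one open tube, matching the combinatorial prediction.

A short simulation from the shell command line:

```
salrshell simulate --r-inn 6 --r-out 11 --mu -2.17 --steps 1000000 \
    --equilibration 1000000 --seed 1 --out run/
salrshell analyze --trajectory run/trajectory.xyz --out analysis/
```

writes observables (step, N, U, u\*, ρ\*), an extended-XYZ trajectory, the
averaged density grid, the ρ_iso = 0.4 iso-surface (OBJ/VTK) and a cluster
report.

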