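# Methods

This note records the model, the numerical choices, and the limits of what
the test fixtures can establish.

## Physical model

**Smooth dielectric.** The solute is not bounded by a molecular surface.
Each atom carries a Gaussian density `g_i(r) = exp(−|r−r_i|²/(σ²R_i²))`
with R_i its van der Waals radius; atom densities combine through the
complement product `g = 1 − Π(1−g_i)` so overlapping atoms saturate toward
1 rather than double-count. The permittivity is the pointwise convex blend
`ε = g·ε_in + (1−g)·ε_w`. Consequences the tests rely on: ε is continuous,
bounded by [ε_in, ε_w], equals ε_in exactly at an atom center, and reaches
ε_w to better than 1e-6·(ε_w−ε_in) beyond 6σR of every atom.

**Mobile ions.** Mobile salt species are Boltzmann-distributed in the
potential, with a Born desolvation penalty added to the exponent:
`n_i(r) = c_bulk·exp(−(z_i φ + ΔG_solv,i(r))/RT)`, where
`ΔG_solv = (N_A z²e²/8πε₀r₀)(1/ε_r − 1/ε_w)`. Because ε_r → ε_in inside
the solute body, the accessibility factor `λ = exp(−ΔG_solv/RT)` falls to
~1e-30 there and mobile charge is excluded smoothly — this is the
mechanism that replaces the Stern/ion-exclusion layer of sharp-boundary
solvers. The penalty's sign convention (added to the exponent's energy, so
it *reduces* local ion density) is fixed by the requirement that the same
expression, `G(s) = q_ion Φ(s) + ΔG_solv`, is the site score in which
negative values are favorable.

**Site score and filters.** Every interior grid node strictly outside all
vdW spheres is scored with G(s); Φ(s) is the raw node value (no
interpolation) and ε_r(s) the arithmetic mean of the six adjacent
edge-midpoint permittivities. Only negative scores are retained, in a
binary min-heap. Popping in order of increasing G, a site is discarded if
any atom is closer than R_ion + R_atom (strict inequality discards) or any
already-accepted site is within 6 Å (strict inequality accepts). Survivors
receive ranks 1, 2, … up to the user's maximum.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| grid scale | 2 | grids/Å | resolution/speed tradeoff of the production method |
| perfil (box fill) | 70 | % | solute occupies 70% of the cube side, radius-inclusive |
| σ (relative variance) | 0.93 | — | conventional value for the Gaussian dielectric lineage; the method description leaves it unstated, so it is exposed as a knob |
| ε_in / ε_w | 2 / 80 | — | reported optimum for the internal reference; bulk water |
| salt | 0.5 | mol/L | reported optimum (0.1–0.5 M studied) |
| ion r₀ = R_ion | 2.0 | Å | single effective radius for cations and anions |
| T | 298.15 | K | not stated by the method; standard lab temperature |
| solver tolerance | 1e-4 | kT/e | max per-sweep update |
| mode | linear | — | the ranking consumes φ only; nonlinear mode provided |

## Numerics

* **Grid.** Vertex-centered cubic lattice, node count forced odd so a
  central node exists, minimum 5. Side = (largest radius-inclusive extent)
  / (perfil/100), rounded up to whole spacings. The box is centered on the
  midpoint of the radius-inclusive bounding box, which guarantees the
  margin bound and exact translation covariance.
* **Discretization.** Flux-conservative 7-point stencil with ε on edge
  midpoints (three staggered arrays); charges assigned to the 8
  surrounding nodes by trilinear weights (total charge preserved to
  1e-12); Dirichlet boundary from the Debye–Hückel superposition
  `Σ q_a exp(−κd)/(ε_w d)` with κ from first principles (κ=0 at zero
  salt).
* **Relaxation.** Red–black Gauss–Seidel with over-relaxation
  ω = 2/(1+sin(π/n)) by default (user-overridable in [1,2)). Convergence =
  max |Δφ| per sweep ≤ tolerance; non-convergence returns a flagged,
  warned result, never a silent one; NaNs raise. In nonlinear mode the
  Boltzmann source is Picard-iterated with its linearization treated
  implicitly (the `exp(−zφ)−1+zφ` remainder is lagged), which is stable
  for the |φ| ranges the fixtures produce.
* **Internal units.** φ in kT/e, energies in kcal/mol, lengths in Å,
  charges in e. The only constants used are N_A e²/(4πε₀) =
  332.0637 kcal·Å/mol and k_B N_A = 0.0019872 kcal/(mol·K), both derived
  from CODATA 2018 exact values.
* **Determinism.** Ties in G(s) (and in the baseline's node energies)
  break by lexicographic grid index; all outputs are byte-reproducible for
  identical inputs. For that reason the run manifest carries a wall-clock
  timestamp only on request (`--timestamp`).

## Design choices where the method description was open

* *Arithmetic* mean for the six-midpoint local ε ("averaged" is otherwise
  unspecified); harmonic averaging would bias ε_r low near the surface and
  enlarge the penalty.
* R_ion (clash) defaults to r₀ (Born) = 2.0 Å; both are configurable per
  species.
* Candidate enumeration scans *all* exterior nodes, not a surface shell.
* The Coulomb baseline's "protein surface" is the vdW surface (distance to
  nearest atom center minus its radius); its uniform dielectric defaults
  to 80; it builds a padded box (standoff + 4 Å each side) because a
  70%-fill box leaves no nodes beyond the 6 Å standoff for small solutes.
* Linearized PBE is the default production path; nonlinear mode exists and
  is held to agreement with the linear solution in the small-|φ| regime.
* PQR parsing takes the last five whitespace-separated numeric tokens of
  each ATOM/HETATM record as x, y, z, q, R, with the chain ID detected by
  token count — the only convention that survives the format's dialects.

## What the synthetic fixtures do and do not establish

The generators produce: a single Born ion (analytic Coulomb/Debye/Born
limits), a dipole, a lattice cluster with a charged face (known attraction
direction), a part-buried charged pocket, and seeded random clusters. The
pocket deserves explanation: at the 2 Å-ion clash standoff, walls made of
ordinary 2 Å atoms present Gaussian densities of only ~0.01 per atom, so
no *accessible* node ever sees a low ε. The pocket therefore uses
residue-scale beads (R = 4.5 Å, ring radius 6.5 Å) around a −0.6 e partial
charge; accessible nodes at the cup bottom then sit at ε ≈ 18, where the
Ca²⁺ Born penalty (≈ +14 kcal/mol) outweighs the Coulomb attraction
(≈ −12 kcal/mol) and visibly relocates rank-1 out of the pocket — the
qualitative behavior that distinguishes this treatment from a plain
Coulomb placer. That contrast experiment runs at 0.1 M salt (within the
studied 0.1–0.5 M range) so that remote surface sites remain bound.

Green tests on these fixtures establish the correctness of the numerics
and the algorithm's contracts. They do **not** establish predictive
accuracy on real proteins: the fixtures have no backbone geometry, no
heterogeneous charge distributions at protein density, and grid sizes far
below production runs. Benchmarking against experimentally determined ion
positions requires real PQR structures, which this package reads but does
not ship.

## Known limitations

* Single cubic grid; no focusing, multigrid, or periodic boundaries.
* Equal bulk concentration for all mobile species (electroneutral valence
  set required); no mixed-concentration electrolytes.
* One σ for all atoms; no atom-type-specific Gaussian widths.
* Candidate positions are grid nodes; no sub-grid refinement, so reported
  coordinates carry O(h/2) quantization.
* The desolvation-modified accessibility uses the node-averaged ε, which
  lags the midpoint field by half a spacing at worst.
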