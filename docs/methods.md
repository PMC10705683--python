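# Methods

`tacsim` simulates the reciprocal mechanical interplay between an
off-lattice colony of tumor cells and a grid-based extracellular matrix
(ECM), and quantifies the resulting fibril arrangements as tumor-associated
collagen signatures: TACS-1 (unorganized far-field fibrils), TACS-2
(fibrils parallel to the colony boundary) and TACS-3 (fibrils radial to the
boundary at invasion sites).

## Model

**Cells.** Each cell is a circular agent with nucleus position `X_i`,
age `A_i`, maturation age `A_i^mat`, constant radius `R` and a behavioral
state (proliferative / growth-arrested / migrating).  A mature,
non-overcrowded, proliferative cell divides into daughters at
`X ± 0.5·R·(cos θ, sin θ)` (uniform θ), so the daughter pair is born one
radius apart and overlapping.  Daughter ages are zero; maturation ages are
`base·(1 + τ)` with independent `τ ~ U(−0.15, 0.15)` about the *lineage
base* (20 h), so fluctuations do not compound across generations.
Overcrowding — more than 12 cells within two cell diameters (4R) — blocks
division without changing state.

**Forces.** Overlapping cells (`d < 2R`) repel with the Hookean force
`F_rep·(2R − d)` along the center line; cells with at most five neighbors
within 4R adhere to neighbors in the band `R_adh < d < 2R_adh` with force
`F_adh·(R_adh − d)`.  `R_adh` is set to one cell diameter (16 µm) so
adhesion engages immediately outside contact with no dead zone.  A
migrating cell adds a motility force of fixed magnitude `G` along
`G̃ = α·Ĝ* + (1−α)·⟨h⟩`, the competition between its persistent direction
`Ĝ*` (weight α) and the mean fibril orientation within `R + 2Δx` of its
center (fibrils sign-aligned to `Ĝ*` first; fibrils are axial).  Motion is
overdamped forward Euler: `X ← X + (Δt/ν)(F + G)`, positions clipped to the
domain rectangle (equivalent to zeroing the outward velocity component).

**ECM.** The matrix is a regular grid (spacing Δx = 4 µm, one node per
fibril bundle) of unit orientation vectors `h(x,y)` and stiffness values
`ξ(x,y)` in units of σ (1σ = 100 Pa).  The initial state is isotropic
(`h = (ε_x, ε_y)/‖·‖`, ε uniform on [−1,1]) at uniform `ξ0 = 1σ` — the
TACS-1 normal-tissue condition.

**Remodeling.**  Cells remodel the matrix two ways, both scaled by the
fibril compliance β ∈ [0, 1]:

* *Orientation mixing.*  Each affected node becomes the normalisation of
  `(1−β)·h + β·Σ g`, where a **pusher** (a non-migrating cell currently
  being displaced by an overlap force) contributes the unit vector
  perpendicular to the force moving it over a disk of radius `R + 2Δx`,
  and a **puller** (a migrating cell) contributes its unit motility
  direction over a disk of radius `R + Δx`.  Every contribution is first
  flipped into the half-plane of the node's current orientation (nematic
  convention) so antiparallel contributions reinforce rather than cancel;
  an exactly cancelling sum leaves the node unchanged.  Contributions are
  direction-only: the mixed vector is renormalised anyway, so β is the
  sole mixing weight.
* *Stiffening.*  A puller raises stiffness by `β·Δξ·w` with annulus
  weights w = 3 (under the cell body), 2 and 1 over rings of width Δx/2
  out to `R + Δx`.  A pusher raises the rings `(R, R+Δx/2]`,
  `(R+Δx/2, R+Δx]`, `(R+Δx, R+3Δx/2]` with weights 3/2/1, and additionally
  *displaces* the fibrils its body covers: the total stiffness on enclosed
  nodes (d ≤ R) is moved onto the weighted ring, one share `Δζ = Σξ/Σw`
  per unit weight, and the enclosed nodes drop to zero.  This
  redistribution conserves total stiffness exactly (tested), is idempotent
  for a stationary cell, and is the dominant stiffness-transport process:
  as a colony expands over virgin matrix it sweeps tens of σ onto its rim,
  which is what drives the threshold crossings on a timescale of days —
  the per-step seasoning `Δξ = 4·10⁻⁵ σ` alone would take weeks.
  Stiffness is capped at `ξ_max = 500σ` after every update.

A consequence of displacement is that *per-node* stiffness is not monotone
(a captured node drops to 0); the monotonicity the model does guarantee,
and the tests assert, is that the field total never decreases and nodes
outside every cell body never soften.

**Stiffness sensing and the state machine.**  Each step every cell senses
the cumulative stiffness Ξ of the nodes within its sensing disk and maps it
through two thresholds: `Ξ ≤ Ξ_div` → proliferative, `Ξ_div < Ξ ≤ Ξ_mot` →
growth-arrested, `Ξ > Ξ_mot` → migrating.  Migration is absorbing (no
reversion is modeled); arrest is re-evaluated every step, but since local
stiffness never decays an arrested cell in practice either stays arrested
or starts migrating.

## Numerical and design choices

* **Sensing radius.**  The engine's default sensing disk is `R + Δx`
  (12 µm).  On the 4-µm grid this disk holds exactly 29 nodes, so
  unremodeled tissue at 1σ per node sums to 29σ — just below the
  calibrated arrest threshold `Ξ_div = 30σ`.  This is the unique geometry
  in which a newborn colony proliferates, then arrests as remodeling
  accumulates, then invades past `Ξ_mot = 50σ`.  A disk of `R + 2Δx`
  (49 nodes) would put every cell past the arrest threshold at birth and
  freeze the simulation; the standalone `sense_stiffness` operation
  nevertheless defaults to `R + 2Δx`, the full contact-guidance
  neighborhood (the same disk the motility term and push remodeling use),
  and the engine radius is config-exposed (`sense_radius`).
* **Pusher trigger.**  Growth-type remodeling applies only to cells with
  an actual overlap (beyond a 10⁻⁹-µm tolerance that absorbs
  floating-point noise at exact contact spacing).  Treating any nonzero
  force — e.g. the ever-present weak adhesion in a packed colony — as
  "pushing" would stiffen the matrix continuously and arrest every colony
  within minutes of simulated time.
* **Tie-breaks.**  Coincident cell centers repel along a deterministic
  pseudo-random direction hashed from the unordered id pair (antisymmetric
  by construction).  Daughter ids are `2i+1, 2i+2` — a binary lineage code
  that is collision-free and reproducible.
* **Update order** per step: lifecycle (age → sense → state → divide),
  force assembly, position update, remodeling driven by this step's forces
  and movements.  One seeded generator per run consumes draws in a fixed
  documented order (field nodes, initial maturation ages, initial ages,
  then per-division θ, τ₁, τ₂ in cell-index order), making runs bitwise
  reproducible; equal seeds give identical snapshot digests.
* **Boundaries.**  The domain is a fixed (non-periodic) rectangle; cells
  clip to it; remodeling annuli truncate at the grid edge with no
  re-weighting.
* **Fast mode.**  `stiffen_batch = k` applies stiffening every k steps
  with `k·Δξ`, guarded by a Δx/4 displacement limit; it is off (k = 1) in
  every reference and acceptance run.

## TACS quantification

The colony boundary is a concave hull of cell centers dilated by R
(shapely `concave_hull`, ratio 0.5; a circle of radius R for fewer than
three cells).  For classification the engine builds this boundary from the
*non-migrating* cells — migrating cohorts are invasion fronts radiating
from the colony, and including them would push the measured shell outside
the tangential ring that encircles the core (a hull of widely scattered
runners also lays boundary edges obliquely alongside radial corridors and
misreads them as boundary-parallel).  When fewer than three resident cells
remain there is no polygonal colony left, and the shell is referenced to
the footprint of the colony of origin (a circle covering the initial cell
positions), which is the cluster the corridors actually emanate from.

Over the peritumoral shell (nodes within 3Δx outside the boundary) we
measure the tangential index (mean |cos φ| to the local boundary tangent),
the radial index (mean |cos ψ| to the outward normal) and the nematic
order `S = |⟨e^{2iθ}⟩| = 2⟨cos²(θ−θ̄)⟩ − 1`.  The shell is split into 12
angular sectors; a sector is TACS-2 if its tangential index exceeds 0.75,
TACS-3 if its radial index does, else TACS-1 — and an alignment call
additionally requires the sector's nematic order to exceed both 0.5 and
the Rayleigh significance bound `√(−ln α / n)` (α = 10⁻³), which holds the
false-positive rate on isotropic fibrils to ~0.1% per sector.  All indices
are invariant to fibril sign flips and rigid rotations (tested).  The 0.75
threshold, shell width, sector count and α are artifact choices
(histology classifies these patterns by eye); all are config-exposed and
reported alongside the labels.  For a uniformly random field the expected
|cos| against any fixed direction is 2/π ≈ 0.64, which is the baseline the
permutation checks compare against.

## Scenarios and study conditions

Calibrated constants used everywhere: R = 8 µm, maturation 20 h ± 15%,
F_rep = 50 and F_adh = 5 µg/(µm·s²), ν = 250 µg/(µm·s), G = 0.08 µg·µm/s²
(free persistent speed G/ν = 0.00032 µm/s), Δx = 4 µm, ξ0 = 1σ,
Δξ = 4·10⁻⁵σ per step, ξ_max = 500σ, Δt = 2.5 s.

Named scenarios: `single_cell` (one permanently migrating cell, α = 1,
β = 0.75, headed for the top-left corner), `tacs1` (cell-free isotropic
field), `tacs2` (growing colony, thresholds disabled, β = 0.5), `tacs3`
(invading cohort, α = 1, β = 0.75, fixed leftward Ĝ*), `transition`
(Ξ_div = 30σ, Ξ_mot = 50σ, β = 0.5, α = 1, persistent direction radially
outward from the domain center, single centered initial cell).

**Scaled regimes.**  The threshold-plane behavior is exercised at desk
scale on a 200×200-µm domain for 2 simulated days (69,120 steps of 2.5 s),
starting from a 19-cell hexagonally packed colony at exact contact spacing
(a force-free equilibrium, so a fully arrested colony stays bitwise
static) with ages staggered uniformly over one maturation period:

| regime     | Ξ_div | Ξ_mot | expected outcome |
|------------|-------|-------|------------------|
| suppressed | 10σ   | 10⁹σ  | arrest at birth (baseline 29σ > 10σ): no divisions, untouched field, TACS-1 only |
| colony     | 200σ  | 10⁹σ  | unchecked growth, tangential (TACS-2) shell, no migration |
| invasive   | 200σ  | 25σ   | migration at birth (29σ > 25σ): radial corridors, TACS-3 |
| coexist    | 30σ   | 50σ   | growth → arrest → invasion; all three signatures in the final snapshot |

These runs reproduce the full-scale 6-day phenomenology qualitatively
only: the colony is smaller, the shell thinner and the label counts
coarser than in a full-domain run.  Individual realizations vary — in the
compressed 2-day window the coexist regime's tangential remnant can be
overrun if nearly every resident cell invades, so the per-seed label set
is a property of the realization, not only of the thresholds.  What the passing checks do show is the
causal chain (pushing → tangential alignment and rim stiffening; sensed
stiffness → arrest, then migration; pulling → radial corridors); what they
do not show is quantitative agreement with any imaging data — the
synthetic initial field has no spatial correlation, fibril density and
cross-linking are folded into the single stiffness scalar, and no
degradation, elastic recoil, or stromal cells are modeled.

## Known limitations

* Remodeled orientation and stiffness persist indefinitely (no elastic
  recoil or proteolytic decay) — deliberately, as in the underlying model.
* The sensed-stiffness dynamics are dominated by fibril displacement
  (capture/redistribution); its rate scales with division activity, so
  threshold-crossing times scale with colony growth rather than with Δξ.
* Force assembly is O(n²); fine for the few hundred cells these domains
  hold, not for tissue-scale runs.
* The TACS labels depend on the artifact classification constants above;
  they are reported with the labels so downstream comparisons can
  recompute them under different choices.
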