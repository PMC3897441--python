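# Methods

`conemosaic` couples a two-dimensional vertex model of the retinal cone
epithelium to a quantitative image-analysis pipeline, with synthetic-data
generators standing in for micrographs. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not emulate.

## The vertex model

Cells are polygons meeting at vertices; vertex positions evolve to
balance three energies,

```
E = Σ_cells K/2 (A − A0)²  +  Σ_edges Λ_eff L  +  Σ_cells Γ/2 P²,
```

area elasticity, interfacial line tension, and perimeter contractility.
Each interface additionally carries planar-cell-polarity (PCP) protein
*amounts*, one per flanking cell; the total concentration
`c = (a_α + a_β)/L` lowers the effective tension linearly,

```
Λ_eff = Λ · m · max(0, 1 − χ c),
```

where `m` is a tension multiplier (three on the edges of a UV cone being
eliminated, one otherwise). Protein-rich interfaces therefore pull less —
the mechanical face of polarized Crumbs-complex adhesion. Lengths are
normalized so the mean cell area is one (`l² = Lx·Ly/N`), tensions by the
reference tension Λ.

Forces treat the concentration field as frozen: the tension entering the
vertex force is `Λ_eff` at the current concentrations, while the PCP
*amounts* are the conserved quantities. Each damped-gradient-descent step
performs an Armijo line search on the fixed-concentration energy and
additionally requires the true functional not to increase, so the
recorded energy trace is non-increasing. An early design used the exact
gradient of the amount-fixed energy instead; its marginal tension is a
step function (`Λ` above the slack length `χ·a`, zero below) which makes
protein-rich edges an absorbing, perfectly protected state — eliminations
then never break columns on any timescale, contradicting the phenomenon
being modeled, so the graded frozen-concentration force was adopted.

The box is periodic along y (parallel to the retinal margin). In x it has
either rigid walls (central retina at x = 0, the precursor reservoir at
x = Lx; wall vertices slide along the wall) or periodic boundaries, used
for ground-state tests. Anisotropic compression perpendicular to the
margin enters as a reduced column spacing at construction (parameter ε).

### T1 transitions

An edge shorter than the threshold collapses to a fourfold vertex. Both
resolutions — the original pairing of the four outer edges and the
neighbor exchange — are scored by the net opening force: the magnitude of
the difference of the two pair forces (`F_P = T_i û_i + T_j û_j`, with
effective tensions at current concentrations) minus twice the tension of
the prospective new edge. The larger positive score wins; the new edge
opens parallel to the pair-force difference at length `1.01 ×` threshold
to prevent immediate re-collapse; a one-sweep refractory period prevents
flip-flopping. Protein on the new edge is allotted per flanking cell as a
σ-blend of that cell's concentrations on its two edges meeting the new
vertices (evaluated at the pre-transition state): `(1−σ)` times the
length-weighted mean plus `σ` times the plain mean. Amounts on surviving
edges are rescaled so every cell's total is conserved exactly; the two
cells losing the edge redistribute the lost amount over their remaining
edges.

### PCP dynamics

Within each cell, protein flows from edges longer than the cell's mean
edge length toward shorter ones at rate
`mobility · (L_e − ⟨L⟩) · total/perimeter` — the minimal intracellular
law under which adhesion complexes accumulate on short, compressed
interfaces. The forward-Euler step is flux-limited per edge (donors give
at most what they hold; recipients are scaled to the realized outflow),
which conserves each cell's total to machine precision and keeps amounts
nonnegative without global step-size coupling. There is no intercellular
transport and no cytoplasmic pool, so a cell's polarity direction is
defined only up to sign; the tissue order parameter Φ is accordingly the
nematic (doubled-angle) mean resultant of the per-cell polarity axes,
`p = Σ_e a_e n̂_e` with outward normals `n̂`.

New cone columns receive random protein: per-edge *concentrations* drawn
i.i.d. uniform, amounts `c·L` normalized to the per-cell budget P0 = 1.
Sampling concentrations rather than amounts keeps the initial tension
modulation unbiased with respect to edge length; with amount sampling the
anisotropy-shortened within-column edges start at roughly double
concentration and the fast-elimination limit loses its arbitrary
edge-loss order. Established columns start polarized (80% of the budget
on within-column interfaces).

## Growth and UV elimination

The front converts one precursor column per cycle. In the first
differentiated column every sixth cell is marked as a presumptive UV cone
(five cones between marks, seeded random offset); in later columns, for
each consecutive pair of the previous column's UV marks the cell nearest
the pair's midpoint is marked. Mark positions are recorded at marking
time, since in the mutant scenario the marked cells are eliminated before
the next column appears. Spectral types are assigned by distance to the
nearest UV mark (green, red, blue at distances 1, 2, ≥3), which keeps
every UV flanked by green cones even when gaps drift from five.

Elimination follows the extrusion protocol: edge tensions of the UV cell
are tripled; every τ sweeps (fast) or 10τ sweeps (slow) its preferred
area is multiplied by ρ = 0.4 and its protein total is rescaled
proportionally to its perimeter so concentrations stay finite; edges are
lost by T1 transitions as the cell shrinks; at the cutoff area
(0.02 ⟨A0⟩) the remaining triangle is deleted, its protein discarded and
each neighbor's interface protein redistributed within that neighbor.
Two protocol-level rules keep the quasi-static integration faithful to a
continuously shrinking cell: when an interval produces less than 10% area
decrease while the cell still has more than three edges, the currently
shortest edge is forced through a T1 (tension and protein act on this
choice through the lengths they produce); and a three-sided cell jammed
near the cutoff for three consecutive intervals is deleted outright (its
edges are protein-slack and tension-free, so the pressure balance alone
cannot push it below an arbitrary cutoff).

The outcome is classified at the instant of removal: `column_intact`
exactly when the two along-column neighbors share an edge, otherwise
`column_broken` — cleanly so when a precursor bridges both neighbors, and
flagged ambiguous when something else (usually a cone of the adjacent
column, an immediate column merge) fills the vacancy. A merge interrupts
the single-cell-wide column, hence counts as a break; merged events are
reported separately via the ambiguous flag and included in the
denominator.

### Timescales

The fast/slow dichotomy exists only if protein redistribution is slower
than a fast elimination and faster than a slow one. With the defaults
(mobility 0.02 per sweep, τ = 5) a fast elimination spans ~50–80 sweeps
and a slow one ~500–800, while column polarization develops over a few
hundred sweeps of growth — the required ordering. The T1 threshold (0.17
in units of the reference length, safely below the bulk minimum edge
length ≈ 0.42) was set so that the fast limit reproduces the arbitrary
edge-loss order it is defined by: the fraction of eliminations in which
both along-column neighbors survive to the final triangle matches the
uniform-random benchmark (3 survivors of 6 neighbors → 20%; measured 19%
at 0.17, versus 34% at 0.15 and 3% at 0.20). With these settings slow
eliminations leave columns essentially always intact and fast
eliminations break them in roughly two thirds of events.

## Synthetic data

`generate_ideal_mosaic` builds the crystalline wild-type lattice from the
12-cone motif: columns repeat the pentamer green-red-blue-red-green
separated by single UV cones, adjacent columns offset by half a motif so
cones of the same type are never lateral neighbors; rods sit at column
interfaces. `generate_fragmented_mosaic` emulates the mutant pattern:
single-cell-wide chains with geometric (or fixed) lengths and bounded
random-walk curvature, surrounded by rods; no quantitative
fragment-length distribution is available for the mutant, so these are
free parameters
recorded with every output.

`render_stack` turns a lattice into a two-channel z-stack at 0.1 µm/px:
cell profiles are discs capped by the radius-weighted Voronoi partition
of (optionally jittered) centers, rods at 0.55× the cone diameter;
junction lines ~0.3 µm thick at the boundary peak; interiors dim (0.12);
the interstitium at 0.55 of peak, emulating the unresolved mesh of tiny
junction profiles that fills the space between photoreceptors at the
outer limiting membrane (real flat-mounts have no dark acellular space
there, and a dark background would segment as phantom cells); per-cell z
profiles peak at that cell's OLM slice; rods and any precursor cells are
filled in the reporter channel; optional Poisson (400-photon) plus
Gaussian noise.

`render_packing` rasterizes a simulated packing the same way and inserts
rod profiles along every cone–cone interface whose total PCP
concentration falls below 0.6 — rods populate exactly the interfaces
lacking polarized adhesion, the tissue's own rule for rod placement. The
threshold sits at the geometric mean of the unpolarized baseline (~0.36)
and the polarized level (~1.0 and above); the flanking cones are pushed
back along the whole rod-bearing interface so non-partners end up
separated by more than twice the closing radius. Chains read out by the
pipeline are therefore protein-bonded chains, which in the mutant
legitimately cross cohort boundaries (column merges).

What the synthetic data do **not** emulate: point-spread blur, chromatic
shifts, dorsoventral profile-size gradients, Müller-glia morphology
(glia exclusion is exercised only through the roundness filter), and
empirically calibrated noise. Tests passing on these renders show the
measurement chain is correct on its stated geometry, not that it would
segment arbitrary real micrographs.

## Image pipeline

Maximum projection of the junction channel → Otsu threshold → bright
boundary mask → 8-connected components of the complement are cell
profiles (minimum area 20 px; border-touching components flagged;
components brighter than midway between the dimmest component and the
threshold are interstitium, not cells). Per cell, the OLM slice is the z
maximizing mean junction intensity in a 2-px annulus; the mean reporter
intensity inside the cell at that slice feeds a seeded two-cluster
k-means (10 restarts) whose brighter cluster is rods; profiles with
roundness 4πA/P² < 0.45 are excluded as glia. For every candidate cone
pair (centroid prefilter 40 px by default — scale it with the rendering),
the union mask is closed with a 10-px disc; the between-region (closed
minus union, components touching both cells) is measured by its second
moments: thickness is the principal radius of gyration `√(I_min/area)`
in px — the raw moment compared to a 10-px threshold is dimensionally a
length only after this normalization; raw moments are recorded too —
and elongation is `I_max/I_min`. A pair is adjacent when thickness ≤ 10 px
and elongation ≥ 2.0 (low threshold) or ≥ 2.5 (high threshold); an empty
between-region is adjacent only for directly abutting cells. The high
graph is a subgraph of the low graph by construction. Planimetric
densities use the two-of-four-sides rule: boundary-crossing profiles
count only if every window side they touch is a designated inclusion side
(left and top by default).

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| Λ (reference_tension) | 0.12 | Λ-units | line tension; the classic soft-network value for K=1, A0=1 |
| K (area_stiffness) | 1.0 | 1/area² | area elasticity |
| Γ (contractility) | 0.04 | 1/length² | perimeter contractility |
| χ (pcp_tension_coupling) | 0.5 | 1/concentration | tension reduction per unit concentration |
| pcp_mobility | 0.02 | 1/sweep | intracellular redistribution rate |
| P0 (pcp_total) | 1.0 | amount | per-cell protein budget |
| ε (anisotropy) | 0.15 | — | compression perpendicular to the margin |
| t1_threshold | 0.17 | l | edge length triggering a T1 |
| σ (sigma_blend) | 0.5 | — | T1 protein reallocation blend |
| ρ (shrink_factor) | 0.4 | — | preferred-area factor per interval |
| τ (shrink_interval) | 5 | sweeps | sweeps between shrinks (fast); 10τ slow |
| A_min (cutoff_area) | 0.02 | ⟨A0⟩ | deletion cutoff |
| uv_tension_factor | 3.0 | — | edge-tension multiplier of shrinking UV cones |

Problem sizes: the default growth experiment uses 12 cells per column
and a handful of columns; the break-prevalence statistic is accumulated
over ≥100 elimination events across several seeded runs (8 columns × 12
cells per run), the scale at which the binomial standard error is ~4
percentage points. Column height matters beyond statistics: the vacated
area of an eliminated cell is absorbed by global redistribution along
the whole column, so taller columns relax it more slowly per sweep and
drift toward the slow-elimination (protected) regime. The 12-cell
column is the size at which the fast protocol actually sits in the
arbitrary-loss-order regime it is defined by (both-neighbor survival at
the benchmark 20%); at 18–24 cells the survival rises to 40–60%.

## Known limitations

Rigid x-walls mildly distort the first and last columns; rendered
periodic columns are truncated at the image border (the "interior"
qualifiers in tests exclude both). The redistribution law has no
saturation, so on frozen geometry all protein eventually pools on each
cell's below-mean edges. Outcome classification at the instant of removal
ignores later rearrangements, which is the intended reading but not the
only one. The published values of K, Γ, χ, ε, τ, A_min, σ and the exact
T1 protein-allocation formula are not recoverable from the source text;
the defaults above are this package's own choices and every one is
overridable in `Parameters`.
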