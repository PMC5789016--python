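# Methods

This note documents the models, estimators and design choices behind
cgleaflet, in the order data flows through the pipeline.

## Coordinate conventions

Coordinates are in nm throughout; z is the membrane normal; the xy
plane is periodic with the box. All binning uses half-open cells
(`[i·c, (i+1)·c)`) with periodic wrapping, and all bond vectors use the
minimum-image convention, so molecules split across a boundary are
handled without pre-wrapping. GRO files are read and written through
MDAnalysis (Å↔nm conversion at the boundary); round-trip precision is
the format's 3 decimals (5·10⁻⁴ nm) plus float32 representation error.

## Leaflet assignment

A lipid belongs to the upper leaflet iff its reference phosphate sits
above the midplane, taken as the mean z of all reference phosphates.
This is a deliberate simplification valid for planar bilayers only;
curved or vesicular membranes need orientation- or graph-based methods.
Interdigitated *tails* do not influence assignment — lipids are
assigned by headgroup position alone. Cardiolipin carries two phosphate
moieties; the registry designates its central glycerol linker as the
single reference bead (configurable), preserving the
one-bead-per-lipid rule used by every map.

## Order parameter and maps

Per lipid: P2 = ½(3 cos²θ − 1) per tail bond vs z, averaged over all
bonds of all tails. Averaging is per-lipid first, then per cell — each
lipid carries equal weight regardless of tail count, which matters when
one leaflet's species has six tails and the other's two. Whether to
weight per bond instead is a genuine free choice; per-lipid was chosen
and is the contract the tests pin down.

Maps locate each lipid by its reference phosphate (consistent with the
density rule), not by tail center of mass. Grid resolution defaults to
1 × 1 nm cells, adjusted so the grid spans the box exactly. Cells with
no samples are NaN, never 0 — zero is a legal value for every mapped
quantity. Density maps are the exception to the missing-cell rule:
every cell is observed every frame, so zero density is a value and the
count array holds frames averaged.

## Partial density profiles and interdigitation

The profile selects beads with xy strictly inside the patch (beads
exactly on a bound are excluded), re-evaluated every frame, and
histograms z relative to that frame's membrane center of mass (unit
bead masses by default; a mass table is accepted, default 72 amu per CG
bead for the mass-density variant). The z range spans a full box length
either side of the COM so no bead ever falls off the histogram —
integral of count density × bin volume equals the mean bead count of
the group, exactly. Default bin width 0.1 nm; default window the last
1/8 of frames (structural maps use the last 1/2), both exposed as
fractions.

Interdigitation is read off the profile: the midplane is the z where
upper- and lower-phosphate densities are equal (center of the
equal-density plateau between the peaks; fallback: the COM itself), and
a leaflet's penetration depth is the distance past the midplane at
which its tail density falls below 5% of its own peak. The 5% threshold
is this package's operationalisation of a property usually described
only qualitatively; it is a parameter. Asymmetry = lower-into-upper −
upper-into-lower; the overlap integral ∫ min(ρ_up, ρ_lo) dz is reported
in beads/nm².

## Protein insertion

The concave hull is formalised as the alpha shape: the union of
Delaunay triangles with circumradius ≤ α, hole-filled (for clash
removal, "inside the hull" must include the barrel lumen). α defaults
to 0.6 nm, roughly one CG bead diameter above bead spacing; as α → ∞
the shape converges to the convex hull, and a disconnected shape raises
rather than silently picking a component. A lipid overlaps if *any* of
its beads projects into the hull (xy, periodic images included) or lies
within 0.1 nm (3D, periodic) of any protein bead — any-bead triggering
is the safer clash-removal rule. Placement samples uniformly in a 3 nm
disk by rejection sampling until the maximum per-species mole-fraction
change, measured over the whole membrane in percentage points, is below
0.20 (per-leaflet scope available; whichever is chosen, the bound's
scope is ambiguous in qualitative descriptions of such procedures, so
it is explicit here). Everything is deterministic for a fixed seed.

## Coupling statistics

Pearson r over cells occupied in both maps (≥ 10 required), against a
null of random non-zero toroidal shifts of the second map — values and
occupancy shifted together, co-occupancy re-derived per shift. Cyclic
shifts preserve each map's autocorrelation, so the null is valid for
smooth fields where an i.i.d. shuffle would wildly overstate
significance. The p-value uses the add-one estimator
p = (1 + #extreme)/(1 + n_perm) and is never exactly zero; default
n_perm = 999, two-sided unless a direction is pre-registered in the
run config. Void/cardiolipin co-localization is the same statistic
applied to (−1 × LPS order map) vs the cardiolipin density map,
one-sided positive.

## The synthetic generator

The generator is a geometric model, not a force field: its purpose is
exact planted truth, and several choices follow from that.

* **Order planting.** Every tail bond is tilted at
  θ = arccos √((2 P2 + 1)/3) from z with uniform random azimuth, so the
  bond's P2 equals the target *identically*, not just in expectation.
  Order fields are constants or callables evaluated at each lipid's
  current position every frame.
* **Tails.** Each tail runs from its glycerol attachment to a terminal
  bead anchored at the planted interdigitation depth past the midplane.
  The bond *direction* carries the exact tilt; the bead spacing
  stretches to bridge attachment and tip (a geometric membrane can
  afford non-physical bond lengths; nothing downstream measures them).
  For nearly flat tilts the vertical reach is capped, shortening the
  realised penetration rather than producing unbounded horizontal
  chains.
* **Composition.** Species counts realise mole fractions by
  largest-remainder rounding (ties broken by species name), so realised
  fractions never deviate by a full lipid. 90/5/5 over 400 lipids gives
  exactly 360/20/20.
* **Voids.** Candidate lattice sites inside void regions are
  down-weighted (default 70% depletion; the candidate lattice carries
  ~1.6× surplus sites so depletion can bite), and the membrane is
  locally thinned near voids, symmetrically in both leaflets.
* **Clusters and dynamics.** The enrichment factor is defined as the
  *stationary* density ratio of the generated dynamics: a deterministic
  number of cluster lipids (largest-remainder over weight strata,
  solving ratio = enrichment given a uniform free background) is pinned
  to anchors inside the regions, while all other lipids random-walk
  with their leaflet's per-frame mobility sigma. Pinned-vs-free is the
  physical picture being emulated — cation-cross-linked or void-trapped
  lipids barely move while the phospholipid background diffuses an
  order of magnitude faster — and it keeps planted clusters persistent
  through the analysis window while the background ergodicises.
  Defaults: σ = 0.8 nm/frame (phospholipid leaflet) vs 0.08 (LPS-like
  leaflet), consistent with CG lipid diffusion at tens-of-ns frame
  spacing and the reported 10:1 leaflet asymmetry.
* **Solvent and ions.** Water slabs flank the membrane with
  round(2% × water count) antifreeze beads by default; Ca²⁺ pairs
  neutralise LPS and Na⁺ the remaining anionic lipids, placed uniformly
  in the slabs.
* **Barrel presets.** Synthetic β-barrels are bead columns on a circle
  (8 columns, 2.2 × 5.6 nm for the OmpA-like preset; 16 columns,
  3.3 × 5.1 nm for the OmpF-monomer-like preset) with a small per-row
  twist (β-barrel shear) and a sparse lumen fill standing in for pore
  loops. The lumen fill also makes the alpha shape well posed: a bare
  ring of cocircular points has no triangle with a small circumradius.
* **Determinism.** All randomness flows from one seed through named
  SeedSequence substreams; identical config + seed is bit-identical.

### The outer-membrane preset

Mirrors the asymmetric study system: LPS-like upper leaflet (6 tails, 8
sugar beads; both configurable since CG LPS models vary), 90/5/5
POPE/POPG/cardiolipin lower leaflet, 23 × 23 × 15 nm box, 1024 lipids
per leaflet, 48 frames. The planted upper-leaflet order field digs
Gaussian disordered nano-domains (width 1.4 nm) at 7 irregular,
seed-derived centers into an ordered background, spanning ≈ 0.20–0.65 —
inside the 0.15–0.70 range reported for LPS phases. Irregular centers
are deliberate: a periodic planted pattern is invariant under some
toroidal shifts and degrades the permutation null by symmetry, besides
being unlike real nano-domains. The lower leaflet raises its order at
the same centers (planted anti-correlation); LPS headgroup depletion
and 3× cardiolipin enrichment sit at the same centers; interdigitation
is 1.0 nm (lower) vs 0.3 nm (upper). The mixed-phospholipid control
uses orthogonal Fourier modes for the two leaflets (true field
correlation zero), no voids or clusters, and symmetric interdigitation.

## What the synthetic data does and does not show

Passing recovery tests demonstrates that the estimators measure what
they claim on data whose truth is known exactly: gridded means equal
brute-force loops to 1e-12, planted fields are recovered with r > 0.9,
planted couplings are detected and absent couplings are rejected at the
nominal rate. It does **not** demonstrate force-field realism: the
generator has no energetics, no entropic tail disorder (order is
deterministic given position), no headgroup chemistry, no membrane
undulations, and confined-plus-free dynamics rather than true
diffusion. Conclusions about real membranes still require real
trajectories; the package reads those through the same interfaces.

## Numerical choices and degenerate inputs

Map cells with zero samples are NaN and excluded from all statistics;
difference maps are missing wherever either input is. The correlation
statistic refuses < 10 co-occupied cells or constant maps rather than
returning NaN. Toroidal shifts that leave < 3 co-occupied cells or a
constant overlap are redrawn (with a hard cap). The alpha shape raises
on collinear input, on empty triangle sets and on disconnection.
Insertion failure after the attempt budget raises an error carrying the
best attempt found. Analysis windows are trailing fractions of the
frame list (defaults: 1/2 for maps, 1/8 for profiles), mirroring the
practice of analysing only the converged tail of a production run.

## Problem sizes

Defaults were chosen so a full two-system analysis runs in seconds to
minutes on one CPU: 1024 lipids per leaflet (≈ 48 000 lipid beads for
the outer membrane), 48 frames, 999 permutations. The acceptance
script's 100-seed insertion sweep uses a single frame of the same
membrane. These sizes are the package's study conditions, fixed in the
presets; anything larger is a matter of passing bigger numbers.
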