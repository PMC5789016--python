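# cgleaflet

Leaflet-resolved analysis of coarse-grained (CG) membrane simulations,
built for the asymmetric Gram-negative outer membrane: a
lipopolysaccharide (LPS) upper leaflet over a 90/5/5
POPE/POPG/cardiolipin phospholipid lower leaflet, with or without an
embedded β-barrel protein (OmpA- or OmpF-like). It is aimed at
simulators who want to go beyond eyeballing 2D maps: every qualitative
claim about leaflet structure — "tail disorder up here matches tail
order down there", "cardiolipin clusters under LPS packing voids" —
becomes a number with a calibrated significance test, and every
estimator can be validated against synthetic membranes with planted,
exactly known structure.

## What it computes

* **Per-lipid tail order.** The second-rank order parameter of tail
  bond vectors against the membrane normal z,

  P2 = ½ (3 ⟨cos²θ⟩ − 1),

  averaged over all bonds of all tails of a lipid (so a six-tailed LPS
  counts once, like a two-tailed POPE). P2 = 1 means tails parallel to
  the normal, 0 isotropic, −0.5 in-plane.
* **Leaflet-resolved 2D maps** of order, per-species phosphate density
  (one reference bead per lipid, normalised by leaflet lipid count) and
  phosphate-to-phosphate thickness, on a periodic grid (default 1 nm
  cells), plus cellwise difference maps and protein-centered frames.
* **Partial density profiles** of a dynamic subset: beads inside an xy
  patch (default 6 < x < 9, 16 < y < 19 nm; membership re-evaluated
  every frame) histogrammed along z relative to the per-frame membrane
  center of mass. From the profile, **interdigitation metrics**: how far
  each leaflet's tails reach past the midplane, their overlap integral,
  and the asymmetry between leaflets.
* **Protein insertion.** A transmembrane barrel is placed stochastically
  in a 2D disk (default radius 3 nm); lipids are removed if any bead
  falls inside the protein's concave hull (alpha shape, default
  α = 0.6 nm) or within 0.1 nm of a protein bead; placements are
  retried until the lipid composition changes by less than 0.20
  percentage points.
* **Interleaflet coupling statistics.** Pearson correlation between two
  maps over co-occupied cells, tested against a toroidal-shift
  permutation null (cyclic 2D shifts preserve each map's spatial
  autocorrelation, so smooth fields do not fake significance).
* **Synthetic membranes with planted truth.** A geometric generator
  plants order fields (realised *exactly* via the analytic tilt
  θ = arccos √((2 P2 + 1)/3)), headgroup voids, cardiolipin clusters,
  interdigitation depths and a 10:1 leaflet mobility asymmetry, so every
  analysis above has a ground truth to recover.

## Worked example

```sh
python analysis/01_run_outer_membrane.py    # asymmetric outer membrane
python analysis/02_run_mixed_control.py     # symmetric 90/5/5 control
python analysis/03_compare_systems.py       # side-by-side table
```

The first script generates the outer-membrane preset (1024 lipids per
leaflet in a 23 × 23 × 15 nm box, 48 frames), inserts an OmpA-like
barrel and runs every analysis stage. It prints:

```
outer membrane run complete -> results/outer_membrane
  lipids removed by insertion : 50
  insertion composition change: 0.0501 pp (< 0.20 required)
  leaflet order coupling      : r = -0.986, p = 0.0010
  void/cardiolipin coupling   : r = +0.240, p = 0.0010
  interdigitation             : lower-into-upper 1.00 nm, upper-into-lower 0.30 nm (asymmetry +0.70 nm)
```

Reading: inserting the barrel removed 50 lipids but shifted the overall
composition by only 0.05 percentage points. The LPS-leaflet order map
is strongly anti-correlated with the lower-leaflet order map
(r = −0.99; none of 999 toroidal shifts produced so negative a
correlation, hence p = 1/1000), cardiolipin density is significantly
co-localised with LPS tail disorder, and the lower leaflet's tails
penetrate 0.70 nm further past the midplane than the upper leaflet's —
all three being the structure the generator planted. The symmetric
control shows r ≈ 0 (not significant) and zero asymmetry.

A `cgleaflet` CLI exposes the same stages (`generate`, `insert`,
`couple`, `run`, `compare`) for ad-hoc use on GRO files; `cgleaflet run
--config run.yaml` drives the whole pipeline from a YAML config with a
single seed, and reruns are byte-identical.

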