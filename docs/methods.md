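# Methods

## Analysis lattice and areas

All rasters live on the global 1° × 1° geographic lattice (180 × 360,
half-open cells, row 0 = [−90, −89), column 0 = [−180, −179); the single
point lat = 90 joins the top band; longitudes wrap modulo 360). Surface
accounting uses the exact spherical-zone formula per latitude band,
A = R² · Δλ · (sin φ₂ − sin φ₁) with R = 6371 km, rather than projecting
rasters to an equal-area projection: the two are mathematically equivalent
for area sums, and the analytic route avoids resampling error entirely.
Cell areas telescope to 4πR² over the globe to ~1e−15 relative error, so
any partition of the grid (sectors, bathymetry classes, EEZs) sums exactly
to the global area. Mollweide is implemented (Newton iteration on
2θ + sin 2θ = π sin φ) for rendering only; drawing a map never alters a
stored raster.

Conventions chosen once and used everywhere: half-open bins with boundary
values in the higher bin (a 200 m seafloor is in the 200–1000 m class);
the five latitudinal sectors are assigned by cell-center latitude to
[−90,−60), [−60,−30), [−30,30), [30,60), [60,90]; the dive-depth strata
are the one deliberate exception, right-closed ((0,200] epipelagic …)
so that a species with a 200 m maximum dive is counted as able to profile
the epipelagic zone.

## Gap classification

For each calendar year, profile positions are binned to cells (raw counts;
an area-normalized density switch exists but is not the default, since the
classification is a within-year quantile on a fixed grid and is invariant
to a common scale). A cell-year is a gap if

* un-sampled: count = 0, or
* under-sampled: 0 < count < T, where T is the q = 0.20 empirical quantile
  (linear interpolation) of the strictly positive counts over ocean cells
  of that year.

Zero-count cells never enter the quantile — they are a separate category,
not the low tail of the density distribution — and the comparison is
strict, so a year in which all positive counts are equal has only its
zero-count cells flagged. The quantile is taken per year, not pooled
across years: the per-year reading keeps the classification stationary
under fleet growth, and persistence is meant to aggregate independent
annual assessments.

Persistence is the fraction of analysed years a cell was a gap, with the
number of analysed years (12 for 2005–2016) as the fixed denominator, so
values are exact multiples of 1/12 and a cell missing data behaves exactly
like an un-sampled cell.

## Coldspots

Cells with persistence ≥ 0.8 are binarized and labelled as connected
components under 8-connectivity with longitude wrap-around (column 0 is
adjacent to column 359; no connectivity across the poles, where the
lattice degenerates). Components with fewer than 25 cells are dropped —
a 1° cell subtends exactly one square degree, so "larger than 25 square
degrees" is implemented as n_cells ≥ 25, inclusive, with the threshold,
connectivity and wrap all exposed as parameters. Surviving components are
relabelled 1..K in decreasing area order. Labelling is implemented with
`scipy.ndimage.label` plus a union–find merge across the seam; the test
suite holds it to a breadth-first flood-fill oracle.

Summaries report total coldspot surface, its fraction of the ocean
surface, fractions by sector and bathymetry class ([0,200), [200,1000),
[1000,2000), ≥2000 m), the fraction poleward of 60° (Antarctic + Arctic
sectors), the fraction inside any EEZ, and a per-EEZ area ranking.

## Species layers

EOO polygons are rasterized inclusively: a cell is present iff the
geometry intersects the cell rectangle with positive area (a shared edge
does not count), then presence is clipped to the ocean mask. The
positive-area rule, rather than centroid-in-polygon, matches the nature of
EOO maps as outer envelopes of occurrence. Self-intersecting polygons are
repaired (`shapely.make_valid`); empty or unrepairable geometry raises an
error naming the species.

Per-taxon richness is the cell-wise count of present species, rescaled by
the taxon's global maximum to [0, 1] (an all-zero taxon stays zero — no
division). The composite is the unweighted cell-wise mean over all eight
taxa, zeros included; averaging only over locally present taxa is offered
as an option but is not the default, because the composite is meant to
compare cells on a common scale.

Dive-depth strata fractions are computed over species with known maximum
dive depth only; species with missing depth are reported in an `unknown`
row and excluded from the denominator.

## Overlap indices

For a species range and the coldspot set, S = area(range ∩ coldspots),
C = area(coldspots), R = area(range), and OV_coldspot = S/C,
OV_range = S/R. Indices are computed on km² areas, not cell counts (cell
areas vary ~115-fold between the equator and the polar band); a cell-count
mode exists for debugging. Per-sector records clip S, C and R all to the
sector, so sector S values add up exactly to the global S. A region with
no coldspot surface (C = 0) or no range surface (R = 0) yields an
*undefined* (NaN) index, never 0 — absence of a gap is not absence of
overlap — and undefined records are excluded from summary counts. Summary
thresholds (<10 %, >50 %) are strict inequalities.

## Telemetry

Locations are binned per taxon; presence requires ≥ 1 location by default
(a minimum-count threshold exists). A great-circle speed filter
(iteratively dropping points faster than v_max from the last retained
point) is provided but disabled by default: public telemetry compilations
are typically pre-quality-controlled, and silent filtering hurts
reproducibility. Coldspot cells are classified into telemetry + EOO,
EOO only, or neither; the three class areas partition the coldspot surface
exactly. Telemetry outside the EOO envelope is retained and logged, since
EOO maps can be incomplete.

## Synthetic worlds

The generator's defaults state the world the tests assume:

* **Profiles** — inhomogeneous Poisson sampling at 3.5 profiles per ocean
  cell-year with a linear latitudinal tilt of +20 % at the north pole,
  −20 % at the south (the real array is mildly north-heavy). On a ~70 %
  ocean world over 12 years this yields ≈ 1.9 million profiles from a pool
  of 13,000 platform ids, the scale of the real 2005–2016 archive
  (>1.5 M profiles, >13,000 instruments).
* **World** — ocean mask from smoothed Gaussian noise thresholded at the
  ocean-fraction quantile (default 0.70); bathymetry deepening with
  distance from the synthetic coasts; an EEZ mosaic assigning coastal
  cells (≤ 4 cells from land) to the nearest of 20 seeds.
* **Planted coldspots** — rectangular cell blocks whose Poisson rate is
  zeroed in the first round(f · n_years) analysis years for gap fraction
  f (deterministic, so f is realized exactly). Blocks must be connected
  and pairwise non-adjacent; they are forced to ocean.
* **Species** — 23 species per taxon (184 ≈ the 183-species compilation),
  geodesic-cap ranges with log-uniform radii of 2°–90° (closed-form cap
  area 2πR²(1 − cos θ) anchors the tests), per-taxon log-uniform dive
  depths, and exactly the real compilation's missing-depth rate (61/183).
* **Tracks** — correlated random walks (exponential step length, scale
  50 km; von Mises turning, κ = 4; hourly fixes, 100 per animal) confined
  to the species' cap by reflecting the heading toward the cap center,
  holding position if even the reflected step exits. 70 animals per
  pinniped/turtle species gives > 3,000 animals, the scale of the public
  compilations.

One integer seed determines everything; each generator draws from its own
`default_rng([seed, stream])` substream.

What the generator does **not** emulate: ocean circulation, the spatial
correlation of real float drift (counts are independent across cell-years,
so real coldspots driven by advection or ice cover have no synthetic
analogue), coastline geometry, real EOO shapes (caps are convex), or
behavioural movement (haul-outs, central-place foraging). A green
planted-truth test therefore establishes the correctness of the
classification, labelling and overlap arithmetic — not that the pipeline
would reproduce any particular real-world coldspot map.

## Numerical and degenerate-input choices

Quantiles use linear interpolation (`numpy.quantile` default). An empty
ocean mask, an empty region mask, mixed taxa in a richness stack, a
missing taxon in the composite, non-monotone bathymetry breaks, negative
dive depths and out-of-range latitudes all raise `ValueError`; an empty
zonal mask reports zero areas and zero fractions without dividing.
Component ties in area are broken by first-encountered label, making
labelling deterministic. netCDF3 (scipy engine) carries no booleans, so
boolean rasters round-trip as int8 with a marker attribute.

## Scale choices in the test suite

Unit and pipeline tests run reduced worlds (lower Poisson intensity, 2
species per taxon, short tracks) purely for speed; scale is a scenario
parameter, never a separate code path. The acceptance tests run the
full-scale planted-truth scenario once with a fixed seed.

## Known limitations

* No geodesy beyond the sphere; no sub-degree grids.
* GeoTIFF and ESRI Shapefile interfaces are not provided (no raster/vector
  GIS libraries in the supported environment); NetCDF and GeoJSON are.
* Caps touching a pole have no polygon boundary representation and are
  carried as rasters only.
* Analyses of the real Argo archive, EOO compilations and telemetry
  databases require the licensed inputs, which are not bundled; readers
  for their file dialects are provided.
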