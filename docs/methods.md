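# Methods

## The feedback model

The package models the net vertical movement of a mangrove forest floor
relative to the contemporaneous mean sea level. The elevation-change rate
is an empirical exponential decay in relative elevation,

    ΔE(E) = a · e^(−b·E)   [mm yr⁻¹],   a > 0,

capturing the ecogeomorphic feedback that lower ground is inundated longer
and accretes faster. Under an SLR rate *S* (mm yr⁻¹) the relative
elevation of a site is stepped annually,

    E ← E + ΔE(E)/10 − S/10   [cm],

with accretion evaluated at the start-of-year elevation and the year's SLR
subtracted in the same step; the 2020–2100 horizon is 80 steps. Because
b·ΔE(E)/10 ≪ 2 everywhere in the parameter range of interest, the map is a
contraction: trajectories are monotone, never oscillate, and relax toward
the equilibrium E* = ln(a/S)/b (undefined for b = 0). The yearly step was
checked against a dt = 0.01 yr forward integration of the same vector
field: the two stay within 0.1 cm of each other over the whole scenario
grid, far inside the 1.5-cm band the tests enforce.

**Relative vs absolute frame.** All outputs are elevations relative to the
*current* year's sea level. Absolute elevation always rises (ΔE > 0); it
is only in the relative frame that sites can sink, zones narrow, and the
regime boundaries have meaning.

**Extrapolation.** The law is evaluated outside the surveyed −15…150 cm
band without modification whenever a trajectory leaves it. This is a
deliberate choice: the dynamic model needs a rate everywhere it goes, and
the exponential form stays positive and bounded on any finite range.

## Calibration routes

1. **Field chain.** RSET pin readings are reduced per occasion to the mean
   of 36 (baseline − current) pin distances and regressed on decimal years
   (365.25 d) for a rate in mm yr⁻¹; marker-horizon burial depths (mean of
   three cores) are regressed the same way for accretion rates. An OLS
   line of elevation-change on accretion at the benchmarks converts
   accretion measured at unmonumented transect stations into
   elevation-change rates, and `a, b` are fitted to (elevation, rate)
   pairs by nonlinear least squares started from the exact log-linear
   solution (which makes the fit a no-op on exactly exponential data).
   Occasions with fewer than 36 pin readings are dropped with a warning;
   non-positive rates cannot be represented by the law and are excluded
   with a warning.
2. **Threshold anchors.** Given two (elevation, rate) anchors the closed
   form b = ln(s₂/s₁)/(e₁−e₂), a = s₁·e^(b·e₁) reproduces them exactly;
   the default anchors (4.57 mm yr⁻¹ at 150 cm, 8.14 mm yr⁻¹ at −15 cm)
   give a = 7.7238 mm yr⁻¹, b = 3.4986×10⁻³ cm⁻¹.
3. **Endpoint root-finding.** One rate anchor plus one known simulated
   endpoint pins b by bisection (Brent) on the 80-step map; used as a
   cross-check of the two-anchor calibration.

## Zone geometry

Elevation is linearly interpolated between adjacent sites along distance;
the mangrove zone is the union of segments at or above the survival floor
(−15 cm), summed over disjoint pieces (a non-monotone profile can split
the zone). The 2020 reference width runs from the seaward forest edge
(x = 0, extending the first site's elevation seaward) to the landward-most
site; simulated widths sum the between-site segments only. Ratios of the
two give the zone-width fraction.

## Zonation statistics

Species densities are pooled across seasons and quadrats: total count over
total sampled area per (assemblage, elevation), with effort taken from the
full quadrat table so zero-count quadrats still contribute area.
Standardised profiles (proportions summing to 1) give density-weighted
means, variances and type-1 percentiles on the discrete elevation grid.

For rank tests, individuals are reconstructed by assigning each counted
individual its site's elevation; the resulting heavy ties make the
tie-corrected Kruskal–Wallis H mandatory (scipy's implementation, checked
in the tests against an explicit rank-formula oracle). Post-hoc grouping
uses pairwise two-sided Dunn z tests with the tie-corrected pooled rank
variance and Holm adjustment at α = 0.05, followed by a sliding-window
compact-letter display over species sorted by mean rank: every maximal run
of consecutive, mutually non-significant species shares a letter. This is
an open, documented equivalent of the proprietary "stepwise step-down"
procedure of commercial statistics packages, which is not published in
algorithmic form; results may differ in borderline cases.

The variance–mean relationship across species is fitted by OLS on raw
(uncentred) linear and quadratic terms; the reported p is the overall-F
p-value and the vertex −β₁/(2β₂) locates the elevation of maximum niche
spread. One-sample t tests (two-sided) compare rate samples against an
external reference rate, e.g. a ²¹⁰Pb-derived accretion rate.

## Abundance projection

Each species' 2020 density–elevation relationship is frozen as a
piecewise-linear curve with knots at the sampled elevations. Outside the
knot range the boundary density is clamped (not zeroed — simulated
elevations above the top knot would otherwise annihilate high-shore
species that in fact benefit from low SLR; not extrapolated — lines can go
negative). Abundance is the trapezoid integral of density over the
transect in units of individuals per 1-m-wide strip; only ratios are
reported, so the strip width cancels. Under a scenario, site densities are
read off the *static* curve at the simulated 2100 elevations (no lag, no
dispersal limitation). Segments straddling the −15 cm floor are truncated
at the linearly interpolated crossing point, the cut end evaluated at the
floor elevation, which makes the integral exactly equal to the 2020
abundance when nothing moves and continuous in the elevations as segments
cross the floor. Density knots live on the elevation grid, not per site:
two sites sharing an elevation share a density but keep independent
trajectories.

Degenerate ratios are flagged rather than forced: a species absent in 2020
but present in 2100 is a "colonization", both-zero is "undefined".

## Synthetic data

The generators emulate the field campaign so the pipeline can be exercised
end to end from a single integer seed (per-table streams are derived
deterministically from it):

* **Transect** — sites on the 25-cm elevation lattice −15…150 cm (seven
  levels; the 135-cm level is unsampled, mirroring a gap in the real
  forest), ascending with an optional interior dip, random positive
  spacing (~80 m mean).
* **Quadrat counts** — Gaussian elevation niches per species
  (peak · e^(−(E−mode)²/2w²)); expected count = niche density × quadrat
  area; Poisson noise, with a negative-binomial option behind one
  dispersion knob. The sampling design is 4 seasons × (3 × 25 m² arboreal,
  5 × 1 m² epifaunal, 5 × 0.0625 m² infaunal) quadrats per site.
  Default species: four per assemblage, modes evenly spanning −15…150 cm,
  widths 25–40 cm (one to two grid steps, matching compact observed
  zones), peak densities 3/20/40 ind. m⁻² for arboreal/epifaunal/infaunal.
* **RSET readings** — latent surfaces rise at a·e^(−b·E); 36 pin distances
  per occasion shrink accordingly around per-pin baseline offsets, with
  2.0 mm reading noise (typical pin reproducibility), 8 occasions over
  3.5 years.
* **Marker depths** — accretion at elevation E is
  (a·e^(−b·E) − intercept)/slope, the exact inverse of the accretion
  regression, so the full calibration chain recovers (a, b) to machine
  precision on noiseless output. Three cores per occasion with 1.5 mm
  noise on each recorded depth (each is already the mean of three ruler
  readings), 6 occasions over 2 years. Marker stations sit at 36
  elevations distributed like the real survey's sites — calibration
  leverage matches the emulated study, with 9 RSET benchmarks along the
  simulated transect.

True parameters default to the threshold-calibrated field scale
(a = 7.72 mm yr⁻¹, b = 3.5×10⁻³ cm⁻¹) with an accretion regression of
slope 0.30 and intercept 2.5 mm yr⁻¹, consistent with elevation change of
roughly 5–10 mm yr⁻¹ against accretion of roughly 7–25 mm yr⁻¹. Under
these defaults the full noisy calibration chain recovers (a, b) within
10 % in 92 % of 200 fixed-seed replicates (b's error SD ≈ 3.5 %).

What the generators do **not** emulate: spatial autocorrelation within
sites, tidal cycles, seasonal zonation shifts, storm-driven erosion
events, and density-dependent biology. Passing tests therefore demonstrate
the correctness of the estimators and the simulator under the model's own
assumptions, not the adequacy of those assumptions for any particular
shore.

## Numerical choices and degenerate inputs

* Units: elevations cm, vertical rates mm yr⁻¹; the single mm→cm
  conversion (÷10) lives in `io.mm_to_cm`.
* Dates are ISO-8601; elapsed time uses 365.25-day years.
* Equal anchor rates give b = 0 exactly (flat law, no equilibrium).
* An all-zero density profile raises an explicit empty-niche error instead
  of propagating NaN.
* Zero-variance t-test samples: (0, 1) on the null, signed infinity with a
  warning off it.
* A single marker occasion is accepted only with an explicit deployment
  date anchoring (t₀, 0 mm); alone it is an error.
* The scenario grid defaults to 2.00–16.00 mm yr⁻¹ in 0.25 steps
  (57 scenarios).

## Problem sizes

The shipped tests and the acceptance script run the 9-site published
transect for 80 annual steps per scenario, up to 57 scenarios per sweep,
and 200 seeded replicates of the noisy calibration chain (each: 9
benchmarks × 8 RSET occasions × 36 pins, 45 marker stations × 6
occasions × 3 cores); these sizes match the emulated study design, and the
whole suite completes in well under a minute.

## Known limitations

* The feedback law is purely empirical; it carries no sediment-supply,
  hydrodynamic or subsidence terms, and extrapolates beyond the surveyed
  elevation band.
* The abundance projection assumes instantaneous tracking of the static
  2020 density–elevation curve — no dispersal limits, lags, competition or
  predation.
* The compact-letter post hoc is an open reimplementation of an
  unpublished proprietary procedure; borderline letterings may differ.
* The closed-form threshold calibration inherits the rounding of its two
  printed anchor rates.
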