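# intertidal

Dynamic surface-elevation modelling and molluscan zonation projection for
mangrove shores under sea-level rise (SLR).

Mangrove forests hemmed in by seawalls cannot migrate landward as the sea
rises; whether they — and the molluscan assemblages zoned along their
elevation gradient — persist depends on an ecogeomorphic feedback: lower
ground is inundated longer, traps more sediment, and therefore rises
faster. This package implements that feedback as a calibrated dynamic
model and chains it to quadrat-based zonation statistics to project how
mollusc abundance along a shore-normal transect changes by 2100 under SLR
scenarios from 2 to 16 mm yr⁻¹. It is written for coastal ecologists and
ecogeomorphologists working with RSET–MH (rod surface elevation table /
marker horizon) monitoring data and quadrat counts.

## The model

The rate of surface-elevation change at relative elevation *E* (cm above
contemporaneous mean sea level) is an exponential decay,

    ΔE(E) = a · e^(−b·E)        [mm yr⁻¹],

and a site's relative elevation evolves in annual steps

    E_{t+1} = E_t + ΔE(E_t)/10 − S/10        [cm],

where *S* is the SLR rate (mm yr⁻¹). Each site relaxes monotonically
toward the equilibrium *E\** = ln(*a*/*S*)/*b*; a site holds its position
exactly when *S* equals its **critical SLR rate** ΔE(E₀).

The law is calibrated either

* from field tables — RSET pin-reading trends (elevation change) and
  marker-horizon burial depths (accretion) at benchmarks, linked by linear
  regression, then an exponential fit of converted rates over the transect
  sites (`SurfaceElevationModel.from_field_data(...).fit()`), or
* from two published anchor rates via the closed form
  `calibrate_from_thresholds(e1, s1, e2, s2)`.

Downstream, per-species density–elevation curves (piecewise linear through
the sampled elevations, clamped outside them) are integrated along the
deformed transect with the trapezoid rule, truncating segments at the
mangrove survival floor (−15 cm), to give each species' 2100 abundance as
a percentage of its 2020 abundance.

A seeded synthetic-data module generates all four input tables (transect,
quadrats, RSET readings, marker depths) with the statistical structure the
analysis assumes, so the whole pipeline is testable without field data.

## Worked example

```python
import intertidal as it

law = it.calibrate_from_thresholds(150.0, 4.57, -15.0, 8.14)
print(law.summary())

sj = it.load_transect("SJ")                      # published 9-site transect
final = law.simulate_profile(sj, 16.0)           # SLR 16 mm/yr, 2020-2100
for sid, e0, e1 in zip(sj.site_ids, sj.elevations_cm, final.elevations_cm):
    print(f"{sid:5s} {e0:7.0f} -> {e1:7.2f} cm"
          f"   critical SLR {float(law.critical_slr(e0)):.2f} mm/yr")
print("2100 zone width:", round(100 * it.zone_width_fraction(sj, final), 2), "%")
```

prints

```
Surface elevation feedback model  rate(E) = a*exp(-b*E)
  calibration: thresholds   n = 2
  a =     7.7238 mm/yr
  b =   0.003499 1/cm
  rate at 150 cm: 4.57 mm/yr; rate at -15 cm: 8.14 mm/yr
SJ-1      -15 ->  -70.87 cm   critical SLR 8.14 mm/yr
SJ-2       10 ->  -51.27 cm   critical SLR 7.46 mm/yr
SJ-3       35 ->  -31.30 cm   critical SLR 6.83 mm/yr
SJ-4       60 ->  -10.99 cm   critical SLR 6.26 mm/yr
SJ-5       35 ->  -31.30 cm   critical SLR 6.83 mm/yr
SJ-6       60 ->  -10.99 cm   critical SLR 6.26 mm/yr
SJ-7       85 ->    9.64 cm   critical SLR 5.74 mm/yr
SJ-8      110 ->   30.58 cm   critical SLR 5.26 mm/yr
SJ-9      150 ->   64.68 cm   critical SLR 4.57 mm/yr
2100 zone width: 29.85 %
```

Reading it: under the extreme scenario every site loses relative
elevation; the seaward half of the transect sinks below the −15 cm
survival floor, the landward-most site drops from 150 to about 65 cm, and
the mangrove zone narrows to roughly 30 % of its 2020 width — a coastal
squeeze against the landward seawall.

A full pipeline run (synthetic data → zonation → simulation → abundance
projection) is one command:

```sh
intertidal gen --seed 1 --out synthetic/
intertidal run-all --config config.yaml
```

with a YAML config such as

```yaml
synthetic: true
seed: 1
out_dir: results/
slr_min: 2.0
slr_max: 16.0
slr_step: 0.25
```

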