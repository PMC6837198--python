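# driftorient

Orientation analysis for individual animals observed in a drifting,
freely rotating circular arena, with the moon (or sun) as a candidate
orientation cue.

The package covers the full analysis chain:

* **`driftorient.circstats`** — circular statistics from formulas: mean
  direction and mean resultant length, Rayleigh uniformity test with the
  second-order series-corrected p-value, first- and second-order (one
  mean per individual) variants, 95% confidence arcs (large-sample
  circular dispersion with a bootstrap fallback), angular arithmetic,
  von Mises concentration inversion, and a two-sided Wilcoxon rank-sum
  test with an exact enumeration branch for small samples.
* **`driftorient.ephemeris`** — self-contained low-precision astronomy:
  moon and sun azimuth/altitude at a site and instant (truncated
  trigonometric series, parallax-in-altitude for the moon), illuminated
  fraction, lunar phase labels from elongation windows, horizon flags,
  and a gravitational-pull utility. Valid 1950–2050; accuracy ~0.1° for
  the moon and ~0.01° for the sun against an authoritative ephemeris.
* **`driftorient.tracks`** — IO for per-second trajectory
  (`t_s,x_px,y_px`), compass (`t_s,heading_deg`) and YAML metadata
  files; rotating-frame bearing extraction (camera angle + compass
  heading), acclimation trimming, gap handling and swimming speed.
* **`driftorient.synthetic`** — ground-truthed deployment and campaign
  simulation (von Mises individuals, wrapped-normal chamber rotation,
  lognormal speed scale). Extraction is an exact inverse of generation,
  so the whole pipeline is testable without any field data.
* **`driftorient.pipeline`** — per-individual inference, significance
  filtering, condition classification (moon phase / tide / horizon),
  moon- and sun-relative transformation, second-order group tests,
  above/below-horizon speed contrast, and deterministic TSV/JSON
  reports.

## Command line

```sh
# moon or sun position at a site and instant
driftorient ephemeris --utc 2015-04-19T12:00:00 --lat 60.09 --lon 5.28 --body moon

# write a ground-truthed synthetic campaign
driftorient simulate --out data/ --n-deployments 20 --seed 1 --kappa-within 0.63

# analyse a deployment manifest and write report tables
driftorient analyze --manifest data/manifest.csv --out results/ --pool-new-moon

# regenerate group tables from cached per-individual results
driftorient report --results results/ --out results2/
```

`analyze` accepts `--declination` (magnetic declination, east positive),
`--alpha`, `--pool-new-moon` (adds a pooled row across tide/horizon
strata) and `--sun-frame` (repeats the group analysis against the sun
azimuth as a control).

## Conventions

Angles are degrees in [0, 360), clockwise from north. A bearing is the
angular position of the animal's head relative to the chamber centre,
referenced to magnetic north via the recorded compass heading. The
cue-relative angle is `wrap(bearing − cue azimuth)`: 0° = toward the
cue, 180° = away. Altitude exactly 0 counts as below the horizon. Tide
phase is always supplied as metadata, never computed.
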