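# trunksway

Variability and complexity analysis of seated trunk sway from chest-worn
smartphone sensors.

Office workers sit for hours; how their trunk sways while they do carries
information about motor control, and chronic spinal pain is hypothesized to
change both the *amount* of sway (linear variability) and its *temporal
structure* (complexity). `trunksway` implements the full analysis chain for
such studies, for movement scientists and biosignal engineers:

1. **Ingest & synchronize** raw accelerometer / rotation-vector /
   magnetometer streams (nanosecond timestamps, irregular rates), crop them
   to the common interval and resample to a uniform 100 Hz.
2. **Preprocess & segment**: 10 Hz low-pass, gravity removal, detrending,
   moving-average smoothing; non-seated intervals removed where the
   acceleration magnitude |a| = sqrt(ax^2 + ay^2 + az^2) exceeds 2 m/s^2
   (a threshold derived both from reference walking accelerations and from
   the MET regression MET = 5.289 |a| - 8.5548 at 3 METs); sessions tiled
   into 15-minute windows labelled AM1.., Lunch, PM1...
3. **COP projection**: quaternions -> z-y'-x'' Euler angles -> median-
   centered -> cop = lever * tan(angle), clipped to a 25 x 18 mm admissible
   sway ellipse, yielding anterior-posterior (AP) and medial-lateral (ML)
   displacement series in mm.
4. **Measures**: per-window linear features (SD, RMS, IQR, sway area, path,
   velocity, ...) and nonlinear ones — multifractal detrended fluctuation
   analysis H(q) for q in [-5, 5] with the singularity-spectrum widths, and
   sample entropy (m = 4, r = 0.2 SD) — validated per window against 100
   IAAFT surrogates at the 95% level.
5. **Group statistics**: a 2 (group) x 6 (day x period) mixed ANOVA with
   Mauchly sphericity testing, Greenhouse-Geisser correction and partial eta
   squared (np^2 = SS_effect / (SS_effect + SS_error)), categorized
   small / medium / large at 0.06 / 0.14.

Because no raw recordings of the original protocol are public, the package
includes a first-class synthetic cohort generator (exact-covariance
fractional Gaussian noise via circulant embedding, binomial multiplicative
cascades, walking bursts with known ground-truth indices, battery-throttled
timestamps) so every stage is testable end to end. See `docs/methods.md` for
the full model documentation.

## Worked example

```python
from trunksway.config import RunConfig
from trunksway.synthetic import CohortSpec, generate_cohort
from trunksway.pipeline import analyze_cohort

win = 1024 / 100.0  # 10.24 s windows: reduced-size study conditions
cfg = RunConfig(window_minutes=win / 60, session_minutes=9 * win / 60,
                acc_smooth_samples=15, min_window_samples=256, seed=7)
spec = CohortSpec(session_minutes=cfg.session_minutes,
                  window_minutes=cfg.window_minutes, seed=7)
res = analyze_cohort(generate_cohort(spec), cfg)

cells, aov = res["cells"], res["anova"]
for f in ["sd", "hq_0"]:
    sub = cells[(cells.feature == f) & (cells.direction == "AP")]
    gm = sub.groupby("group").value.mean()
    row = aov[(aov.feature == f) & (aov.direction == "AP")
              & (aov.effect == "group")].iloc[0]
    print(f"{f}: PG={gm['PG']:.3f} CSPG={gm['CSPG']:.3f} "
          f"F({row.df1:.0f},{row.df2:.0f})={row.F:.2f} "
          f"p={row.p:.4f} np2={row.np2:.3f} {row.category}")
```

prints

```
sd: PG=2.896 CSPG=4.306 F(1,14)=17.93 p=0.0008 np2=0.562 large
hq_0: PG=1.682 CSPG=1.823 F(1,14)=99.44 p=0.0000 np2=0.877 large
```

Read: in this simulated 6 + 10 cohort the chronic-pain group sways with a
larger AP standard deviation (4.3 vs 2.9 mm at the default 500 mm lever arm)
and a more persistent fractal structure (H(q=0) of 1.82 vs 1.68), and the
mixed ANOVA flags both group effects as significant with large effect sizes
— the direction of contrast the generator injected.

There is also a CLI:

```bash
trunksway demo --out demo_run --seed 0     # reduced-size end-to-end run
trunksway simulate --out raw --seed 1      # write raw sensor CSVs
trunksway run --config cfg.yaml            # full pipeline from a config file
```

Each run directory contains `features.csv` (tidy window-level features),
`windows.csv`, `cells.csv`, `anova.csv`/`.json`, `normality.csv`, the
serialized `config.yaml`, and `manifest.json` with a config hash and
per-stage sample counts; reruns with the same config are bit-identical.

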