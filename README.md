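# stemscan

Benchmarking terrestrial LiDAR devices for forest inventory, end to end
and in silico: synthetic scenes, device-specific scan simulation, stem
diameter and tree height extraction, and the error statistics that
compare devices.

Forest inventories need two numbers per tree: **DBH**, the stem diameter
1.3 m above ground, and **TH**, the tree height.  Point clouds from a
survey-grade tripod scanner, a handheld mobile scanner, a low-cost
rosette-pattern prototype and a phone-integrated depth sensor all promise
those numbers at very different price points — but with different point
densities, noise levels, fields of view and range limits.  `stemscan`
implements the full measurement chain for all four device classes so that
their error budgets can be studied, reproduced and stress-tested without
hardware:

- **Scenes** — a laboratory arrangement of 12 reference tubes
  (diameters 2.6–50.5 cm) and plantation plots at 4 × 4 m spacing with
  lognormal DBH and allometric heights.
- **Scanner simulation** — ray-cast scans with per-device beam patterns
  (including a non-repetitive two-frequency rosette whose coverage grows
  with dwell time), Gaussian ranging noise, range limits, detection
  censoring of thin targets, and per-scan registration jitter for
  SLAM-based devices.
- **DBH** — a 5 cm slice at breast height ([1.30, 1.35) m), Taubin
  circle fit, polar unwrap, truncated-Fourier contour model, the width
  of the central 95% residual interval as a per-section noise figure
  (mm), and diameter from the perimeter of a polygon outlining the outer
  contour: DBH = perimeter / π.
- **TH** — DTM (per-cell minimum), DSM (per-cell maximum),
  nDSM = DSM − DTM, sampled at each stem position; tube lengths from the
  vertical extent of opposed surface strips.
- **Evaluation** — err = est − ref, RMSE = √(Σe²/n), bias, rRMSE/rBias,
  R², detection rate; paired t-tests, one-way ANOVA and Tukey HSD (exact
  studentized-range quantiles) for device comparison.  The published
  laboratory benchmark tables ship with the package and are reproduced
  exactly.

## Worked example

```python
import stemscan as ss

# published lab benchmark: per-device accuracy from the packaged table
table = ss.lab_reference_diameters()
for dev in table.devices:
    s = ss.error_stats(table, dev)
    print(f"{dev:8s} RMSE {s.rmse:5.2f} cm  bias {s.bias:5.2f} cm  "
          f"TDR {s.tdr:5.1f} %  (n={s.n})")

# simulate a plot survey with the low-cost rosette prototype
scene = ss.make_plantation_scene(3, 3, seed=1)
cloud = ss.scan_scene(scene, ss.DEFAULT_PROFILES["lca_tls"], seed=1)
est = ss.measure_plantation_dbh(cloud, scene).set_index("id")
ref = {t.id: t.dbh for t in scene.objects}
err = [est.loc[k, "est"] - v for k, v in ref.items() if est.loc[k, "detected"]]
print(f"simulated plot: DBH RMSE {ss.rmse(err):.2f} cm, bias {ss.bias(err):+.2f} cm")
```

prints

```
iphone   RMSE  1.76 cm  bias  1.17 cm  TDR  83.3 %  (n=10)
lca_tls  RMSE  1.23 cm  bias  1.03 cm  TDR 100.0 %  (n=12)
riegl    RMSE  0.61 cm  bias  0.60 cm  TDR 100.0 %  (n=12)
stonex   RMSE  1.47 cm  bias  1.28 cm  TDR 100.0 %  (n=12)
simulated plot: DBH RMSE 0.77 cm, bias +0.71 cm
```

The first block is the laboratory benchmark: the phone misses the two
2.6 cm tubes (detection rate 83.3%) and the tripod scanner is the most
accurate.  The second block scans a synthetic 9-tree plot with the
rosette prototype and recovers DBH to well under a centimetre — its
2 cm @ 20 m ranging noise shrinks to a few millimetres at plot ranges.

A command-line interface mirrors the library:
`stemscan simulate`, `convert`, `dbh`, `noiseband`, `height`, `compare`
(see `stemscan --help`).

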