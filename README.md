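# kfiber

Quantification of kinetochore-fiber (k-fiber) length, dynamics, and
poleward flux in mammalian mitotic spindles.

K-fibers are the microtubule bundles that connect each chromosome's
kinetochore to a spindle pole. A central question in spindle biology is
whether their length is set globally — by pole-focusing forces
integrating information at the pole — or locally, by each fiber's own
end dynamics. Comparing normal ("focused") spindles with spindles whose
poles have been unfocused by dynein inhibition turns this into a
measurement problem: fiber lengths in 3D, their variability across
space and time, the kinetics of length recovery after acute shortening,
and the rate of poleward tubulin flux. This package implements that
measurement pipeline end to end, together with a synthetic-spindle
generator that provides ground truth for every stage.

## What it computes

- **3D fiber length** from a traced planar path plus its z-slice span:
  an interpolating Catmull–Rom spline gives the planar arc length *s*,
  the slice span gives *dz*, and *L* = √(*s*² + *dz*²). For fibers
  ending at a focused pole, the centrosome radius *r* (the half-width
  at half-max of the pole's intensity peak, default 0.97 µm) is
  subtracted.
- **Spindle morphometry**: Otsu threshold → largest connected component
  → major/minor axes of the ellipse with the same normalized second
  central moments.
- **Spatial coordination**: metaphase-plate axis as the principal
  direction of the kinetochore cloud; inner (≤ 2 µm) / outer (≥ 3 µm)
  zones; signed alignment scores; interkinetochore distances;
  length–position correlations.
- **Temporal statistics**: minute binning, time-averaged length,
  coefficient of variation CV = 100·σ/µ, sister-sum conservation, and
  the length autocorrelation
  ρ(h) = Σᵢ₌₁ⁿ⁻ʰ (xᵢ−x̄)(xᵢ₊ₕ−x̄) / Σᵢ₌₁ⁿ (xᵢ−x̄)²
  with a per-lag Welch comparison between conditions.
- **Regrowth kinetics** after laser ablation or drug washout: per-minute
  group binning, OLS growth rate over the first 5 min, fraction of
  length recovered vs unablated neighbours.
- **Poleward flux**: rigid registration, 5-pixel-box kymographs,
  photomark/minus-end tracking, and flux as −(OLS slope) of the
  mark-to-minus-end distance over time.
- **Anaphase**: sister-chromatid separation velocity and chromosome-mass
  partitioning among daughter-cell outlines.

Group comparisons use the two-tailed Welch *t*-test throughout.

## Worked example

```python
from kfiber.synthgen import simulate_kymograph
from kfiber.kymo import track_features, flux_rate

kymo, truth = simulate_kymograph(
    flux_um_min=0.55, plus_growth_um_min=0.55, fiber_len_um=10.0,
    mark_offset_um=2.0, duration_min=8.0, dt_min=0.2,
    pixel_size_um=0.105, noise_sd=0.02, seed=1)
tracks = track_features(kymo, "auto")
print(flux_rate(tracks))
```

prints

```
{'flux_um_min': 0.5506001390969203, 'stderr': 0.0014033040493588965, 'n': 41}
```

— a photobleach mark planted to approach the fiber's minus-end at
0.55 µm/min is auto-tracked through the rendered kymograph and the
regression recovers the planted flux to 0.1%. The numbered scripts in
`analysis/` run the same kind of recovery for every stage (lengths,
spatial zones, dynamics, ablation regrowth, flux, anaphase) and write
their tables under `results/`:

```sh
python analysis/01_simulate_scenes.py
python analysis/02_fiber_lengths.py
...
python analysis/07_anaphase.py
```

A `kfiber` command-line entry point exposes the same stages over a YAML
config (`kfiber run -c config.yaml`, or per-stage subcommands such as
`kfiber simulate`).

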