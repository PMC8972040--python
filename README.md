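# myoturnover

Quantification of myosin replacement in skeletal-muscle thick filaments
from two-channel fluorescence imaging, together with a stochastic
simulator that generates every input synthetically.

A sarcomeric thick filament is a bipolar assembly of roughly 300 myosin
molecules, about 1.6 µm long, centred on the M-line. Although the
structure is stable, its myosins turn over continuously: a molecule is
released and a molecule from the cytosolic pool takes its place. Two
imaging experiments quantify this exchange:

* **Photoconversion (FRAP-style)** — a green→red photoconvertible tag on
  myosin is flipped by UV in a region of myofibrils; the green signal of
  the converted region then reports myosin *insertion* (recovery from 0)
  and the red signal reports myosin *release* (decay from 1).
* **Pulse-chase** — pre-existing myosin is labeled green, newly
  synthesized myosin red; per-sarcomere line scans show *where* along
  the filament new myosin inserts.

This package implements the full analysis: trace normalization
(photobleaching reference correction for green; the 500–600 min linear
drift "correction value" for red), the single-exponential recovery fit

```
FI(t) = Mf · (1 − e^(−b·t)) + c,      t½ = ln 2 / b
```

(Mf, the mobile fraction, is the maximum change of normalized
fluorescence; t½ its half-life), sarcomere waveform extraction
(polynomial smoothing, Z-bands as the turning points of the green curve,
baseline removal, normalization to an x-axis with the M-line at 0 and
Z-bands at ±1 so the filament tips land at ±0.8), red−green difference
maps, an eight-category red-peak pattern classifier (both sides,
predominantly right/left, right/left side, center, random fashion, no
incorporation), and red-peak-to-center distance statistics.

Because the underlying microscopy data are not public, the
`simulate` module generates them: per-site Poisson exchange on the
filament (uniform, biphasic two-pool, or spatially tip-biased rates),
two-channel trace and line-scan rendering with realistic artifacts
(photobleaching, red drift, PSF, noise), with ground truth retained for
every output.

## Worked example

```bash
python analysis/01_frap_recovery.py --seed 1 --out-dir results
```

prints

```
Per-channel recovery (mean over traces):
  green: Mf = 56.06% ± 0.51% (SE), t_1/2 = 2.66 ± 0.06 h (n = 7)
  red  : Mf = 63.63% ± 4.65% (SE), t_1/2 = 1.25 ± 0.14 h (n = 7)
  green vs red mf: t = -1.62, p = 0.132
  green vs red t_half: t = +8.97, p = 0.000
```

Seven noisy synthetic traces per channel were normalized and fitted; the
means recover the generative presets (green 55.24% / 2.55 h, red 66.98%
/ 1.38 h) within sampling error, the red channel being noisier because
its drift correction is estimated from an 11-sample window. The other
drivers follow the same pattern:

* `analysis/02_biphasic_calibration.py` — solves the two-pool
  replacement curve through the anchors 20% @ 10 min, 30% @ 60 min,
  70% @ 10 h (fast pool A₁ = 0.179 at 30 h⁻¹, slow pool A₂ = 0.575 at
  0.236 h⁻¹, 24.6% immobile).
* `analysis/03_photoconversion_map.py` — builds the red−green difference
  map over 200 min; it is positive in the filament middle and negative
  at |x| ≈ 0.75, the signature of faster exchange at the tips.
* `analysis/04_pulse_chase_patterns.py` — classifies 150-sarcomere
  populations at 7/15/30 min of chase; side-group patterns stay near
  80% while the center pattern rises to ~20% by 30 min and
  no-incorporation fades.

All tables land as CSV under `--out-dir`, with figures alongside. The
same stages are scriptable through the `myoturnover` CLI
(`simulate`, `frap-fit`, `scan`, `classify`, `report`, `run`), e.g.

```bash
myoturnover run --config configs/demo.yaml --out results/demo
```

## Layout

```
src/myoturnover/   library (geometry, kinetics, simulate, frap,
                   waveform, classify, io, pipeline, cli)
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance script
docs/methods.md    models, parameters, numerical choices, limitations
```
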