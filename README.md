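# lungdfi

Simulation and analysis of **grating-based tri-modal lung radiography** in a
murine single-left-lung transplantation cohort.

A Talbot-Lau interferometer placed between an X-ray source and detector
turns one exposure series into three co-registered images: conventional
**absorption**, **dark-field** (small-angle scattering — high in healthy,
aerated lung because of its myriad air–tissue interfaces) and
**differential phase contrast** (edge enhancement at interfaces such as the
air-filled bronchi).  After a left lung transplant, large-airway
complications at the bronchial anastomosis (stenosis, truncation) starve the
graft of ventilation: the dark-field signal collapses, absorption rises, and
the phase image shows the narrowed or truncated bronchial lumen directly.

`lungdfi` is a synthetic-data pipeline for this setting, for researchers in
phase-contrast / dark-field imaging who need a controlled, fully calibrated
test bed:

* **`lungdfi.phantom`** — digital mouse-thorax projection phantoms (lungs,
  ribs, spine, bronchi, anastomotic cuff; stenosis / truncation /
  pneumothorax pathologies) and a calibrated transplant-cohort sampler,
* **`lungdfi.forward`** — the phase-stepping forward model
  `I_k = a0(1 + V cos(2πk/M + φ))` with Poisson counting noise,
* **`lungdfi.retrieval`** — per-pixel Fourier retrieval of
  `A = −ln(a0_s/a0_r)`, `D = −ln((a1_s/a0_s)/(a1_r/a0_r))` and the wrapped
  phase difference,
* **`lungdfi.roi`** — lung ROI masks, automatic rib/spine exclusion by
  thresholding + morphological opening, pneumothorax screening, per-lung
  mean signals,
* **`lungdfi.bronchus`** — tracing of the left main bronchus along its
  bipolar phase-edge signature, sub-pixel lumen diameter metrology, and the
  normal / stenosis / truncation call relative to the cuff,
* **`lungdfi.stats`** — exclusions, paired Student t-tests, cohort report,
* **`lungdfi.dataset` / `lungdfi.cli`** — a staged on-disk pipeline
  (multi-page TIFF stacks, CSV/JSON tables) behind a thin `lungdfi` CLI.

## Worked example

`examples/` contains one short script per capability.  Measuring the lumen
of two tube phantoms at the scanner's 29 µm effective pixel
(`python examples/04_bronchus_metrology.py`):

```
tube rendered at 1.5 mm -> measured 1.5037 mm (error 3.7 um, one pixel = 29 um)
tube rendered at 1.1 mm -> measured 1.1010 mm (error 1.0 um, one pixel = 29 um)
Both calibres are resolved well within one effective pixel.
```

A ten-animal cohort end-to-end (`python examples/03_cohort_statistics.py`)
prints the per-animal ROI table, the bronchus calls and the paired
comparison:

```
darkfield  transplanted 0.768±0.129 vs control 1.487±0.125  t=-12.38, p=1.69e-06 (n=9 pairs)
absorption transplanted 0.952±0.078 vs control 0.737±0.045  t=+6.38, p=2.13e-04 (n=9 pairs)
counts: {'n_recipients': 10, 'analysed': 9, 'excluded_pneumothorax': 1, ...}
```

The transplanted lungs have lost dark-field signal and gained absorption
relative to each animal's own control lung — the quantitative signature of
impaired graft ventilation — while the classifier recovers the seeded airway
pathologies.

The same flow is available from the shell:

```bash
lungdfi simulate --seed 1 --out run/
lungdfi retrieve --out run/
lungdfi quantify --out run/
lungdfi classify --out run/
lungdfi report   --out run/
```

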