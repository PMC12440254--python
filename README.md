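# pulsegrip

Simulation and analysis of pulsatile gripping-force signals for tactile
blood-vessel identification in minimally invasive surgery.

Laparoscopic graspers give surgeons almost no force feedback, so pulsating
vessels hidden under tissue are easy to injure.  One proposed remedy is a
grasper with a fiber Bragg grating (FBG) force sensor in its jaw: while the
instrument steadily clamps tissue, each arterial pressure pulse adds a
small transient to the gripping force.  The height of those transients
above the static clamp force — the **peak clamping force fluctuation
(PCFF)** — depends on the vessel's wall hardness and on the thickness and
hardness of covering tissue, and the spacing of the peaks gives the pulse
rate.  Group-mean PCFF separates vessel conditions statistically, and a
dual-path CNN-LSTM can classify conditions from the raw waveforms.

This package implements that entire analysis chain on synthetic data,
since the underlying force recordings are not public:

* `pulsegrip.synthetic` — seeded generator of pulsatile grip trials
  (`f(t) = baseline + a·pulse(t) + noise`) with presets for six vessel
  models whose group-mean amplitudes equal the published condition means
  (e.g. porcine abdominal artery 0.047 N vs vein 0.022 N);
* `pulsegrip.fbg` — the FBG photonic model: Bragg wavelength
  `λ_B = 2·n_eff·Λ`, linear force-to-wavelength-shift conversion at the
  0.082 nm/N calibration, and an interrogator;
* `pulsegrip.preprocess` — wavelet soft-threshold denoising, Z-score
  normalization, width-3 moving average, stratified 6:2:2 splits;
* `pulsegrip.pcff` — peak detection, PCFF and pulse-frequency extraction,
  and the t-test / Mann-Whitney / Kruskal-Wallis comparison battery;
* `pulsegrip.network` / `training` — a dual-path CNN-LSTM (bottleneck
  residual CNN path + two-layer LSTM path, concatenated into a fully
  connected classifier) implemented in NumPy with hand-written
  backpropagation, trained with Nesterov SGD under a cosine-annealing
  schedule with doubling restarts and binary cross-entropy;
* `pulsegrip.evaluation` / `pipeline` / `cli` — confusion matrices and
  macro precision, the end-to-end reproducible pipeline, and a
  command-line interface.

See `docs/methods.md` for the models, defaults and design rationale.

## Worked example

Generate 80 trials for each condition of the porcine "adipose vs muscle
cover" model, extract PCFF, and compare the groups:

```python
import pulsegrip as pg
from pulsegrip.pcff import dataset_pcff, compare_groups

ds = pg.generate_dataset("porcine_III", 80, 100, 42)
stats = dataset_pcff(ds)
for name, s in stats.items():
    print(f"{name:8s} n={s['n']}  mean PCFF = {s['mean_pcff']:.3f} N  "
          f"pulse rate = {s['mean_pulse_rate_bpm']:.1f}/min")
res = compare_groups([stats["adipose"]["pcff"], stats["muscle"]["pcff"]])
print(f"{res.test_name} test: statistic = {res.statistic:.2f}, "
      f"p = {res.p_value:.2e}, significant = {res.significant}")
```

prints

```
adipose  n=80  mean PCFF = 0.060 N  pulse rate = 90.2/min
muscle   n=80  mean PCFF = 0.032 N  pulse rate = 90.7/min
mann_whitney test: statistic = 6400.00, p = 9.39e-28, significant = True
```

The recovered group means match the generator presets (0.059 N and
0.032 N) to within sampling error, the pulse rate reads the pump's
90 pulses/min, and the contrast is highly significant — the synthetic
analogue of the published group comparison.

The full pipeline (simulate → interrogate → PCFF report → preprocess →
train → evaluate) runs from the command line:

```sh
pulsegrip run-all --task porcine_I --n-per-condition 80 --seed 7 --outdir run7
```

and leaves `pcff_report.csv`, `history.csv`, `checkpoint.npz` and
`eval.json` (confusion matrix and per-class/macro precision of the trained
CNN-LSTM on the held-out test trials) under `run7/`, all stamped with the
run-config hash.  A second run with the same config reproduces every
number.

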