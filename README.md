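# ohcmobility

Quantitative analysis of membrane-protein lateral mobility in the outer
hair cell (OHC) lateral wall — the question being whether motor proteins
such as prestin (Slc26a5) diffuse freely in the plasma membrane or are
immobilized by the wall's trilaminate cortical architecture, and whether
pharmacological disruption liberates them.

The package implements, as tested reusable components:

* **FRAP normalization and model fitting.** A bleach-spot intensity trace
  is background-subtracted, corrected for acquisition photobleaching by
  the ratio to an unbleached reference region, and normalized as

      f(t) = (I − I_min) / (I_max − I_min) × 100,

  with I_max the mean of the first five pre-bleach scans and I_min the
  first post-bleach value; bleach efficiency is I_min/I_max × 100. The
  recovery is fitted with the Axelrod/Soumpasis uniform-disc diffusion
  model

      f(t) = A e^(−2τ_D/t) [I₀(2τ_D/t) + I₁(2τ_D/t)],

  giving the mobile fraction A and diffusion timescale τ_D = w²/(4D), or
  with a saturating single exponential A(1 − e^(−kt)). A repeated-measures
  decision rule tests a population of cells for significant recovery.
* **Number-and-brightness (σ²/μ) fluctuation mapping.** For a
  photon-counting detector, pixels over fixed fluorophores obey Poisson
  statistics (σ²/μ = 1); molecules diffusing through the detection volume
  add number fluctuations (σ²/μ > 1). Per-pixel temporal variance/mean
  maps and paired cell-vs-background region statistics separate mobile
  from fixed populations without any model fitting.
* **Nonlinear capacitance (NLC).** Voltage–capacitance sweeps are fitted
  with the two-state Boltzmann form C(V) = C_lin + Q_max α b/(1+b)²,
  b = e^(−α(V−V_h)), yielding total mobile charge Q_max and voltage
  sensitivity α; lateral-wall morphometry uses A_lat = πDL.
* **Synthetic-microscopy generators** for all three regimes with explicit
  seeds and ground truth attached, so every stage is testable end-to-end
  without external data.

The fit-shaped cores are sklearn-style estimators (`FrapRecoveryModel`,
`BoltzmannNLCModel`, `FluctuationMapper`) with `fit`/`predict`/`transform`
and trailing-underscore fitted attributes; module-level functions
(`fit_recovery`, `compute_fluctuation_map`, ...) wrap them.

## Worked example

```python
import ohcmobility as m

# simulate a membrane strip: mobile fraction 0.75, D = 0.1 um^2/s,
# 2 um bleach spot (tau_D = w^2/4D = 10 s), imaged every 10 s
series = m.simulate_frap_series(m.FrapSimParams(seed=1))

gt = series.ground_truth  # the simulation suggests its own ROIs
roi = lambda k: m.CircleRoi(tuple(gt[k]["center"]), gt[k]["radius_px"])
rois = m.RoiSet(bleach=roi("roi_bleach"), reference=roi("roi_reference"),
                background=roi("roi_background"))

curve = m.correct_and_normalize(series, rois)
print(f"bleach efficiency {curve.bleach_efficiency_percent:.1f}%")
fit = m.fit_recovery(curve, model="axelrod")
print(f"A = {fit.A:.3f}, tau_D = {fit.tau_d_s:.2f} s")
```

prints

```
bleach efficiency 39.9%
A = 0.753, tau_D = 9.27 s
```

i.e. the spot retained ~40% of its fluorescence after the bleach, and the
fit recovers the simulated mobile fraction (0.75) and diffusion timescale
(10 s) from the noisy stack. The same round trip for electrophysiology:

```python
trace = m.simulate_nlc_trace(m.NlcSimParams(seed=3))   # Qmax 750 fC, alpha 0.035
fit = m.fit_boltzmann_nlc(trace)
# -> Qmax = 751.2 fC, alpha = 0.0351 /mV, Vh = -70.1 mV, Clin = 6.98 pF
print(m.lateral_area(diameter_um=6.0, length_um=20.0))  # 376.99 um^2
```

A `click` CLI exposes the pipeline (`ohcmob simulate-frap`,
`frap-analyze`, `simulate-nandb`, `nandb-analyze`, `nlc-fit`,
`morphometry`), each run writing its outputs plus a provenance record so
results reproduce bit-for-bit from config + seed.

## Acceptance script

`scripts/acceptance.py` regenerates the package's calibration benchmark
from scratch: it simulates a photon-counting background time series
(225 frames, 256×256 pixels, independent Poisson counts at 2 per frame),
computes the per-pixel σ²/μ map, and reports the full-field mean ratio —
the quantity that must equal 1 for a pure shot-noise series.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the models, generator assumptions, numerical
choices, and known limitations.
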