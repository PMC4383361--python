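# cfcsim

Weak-sense-stationary (WSS) stochastic-process models of theta–gamma
phase–amplitude cross-frequency coupling, with an exact covariance-based
simulator and the spectral analyses used to compare coupling variants.

The observation process is `y = theta + gamma + eta`:

* **theta** — slow oscillation, Gaussian spectral peak pair at ±6 Hz
  (2 Hz FWHM by default);
* **eta** — `1/f^alpha` background noise (alpha = 2 by default);
* **gamma** — product of a latent band-limited fast process `x`
  (100–140 Hz by default) with an envelope driven by the lagged theta:
  * *sinusoidal*: `e_t = theta_{t+tau}`
  * *pulsatile*: `e_t = sum_k w_k theta_{t+tau}^k` (one pulse per cycle)
  * *biphasic*: `e_t = sum_k w_k (theta_{t+tau}^2)^k` (two pulses per cycle)

All components are defined by their spectra; autocovariances follow from the
discrete-time Wiener–Khintchine relation. Sample paths are drawn exactly via
the symmetric square root of the Toeplitz covariance (`path = R^{1/2} v`),
with an independent circulant-embedding sampler as cross-check and long-path
workhorse. The second-order theory of gamma (`r^gamma = M_e * r^x`) is
computed exactly by Isserlis/Wick moment calculus.

## Layout

| module | contents |
| --- | --- |
| `cfcsim.spectra` | spectrum builders, `SpectrumSpec`/`AcvSeq`, Wiener–Khintchine transforms, spectral convolution |
| `cfcsim.sampling` | Toeplitz covariance square-root and circulant-embedding samplers, `SamplePath`/`Ensemble` |
| `cfcsim.coupling` | coupling envelopes, gamma construction, Gaussian cross moments, gamma acv theory, preferred phase, harmonic spacing |
| `cfcsim.model` | `ModelConfig`, composite simulation, theoretical `r^y`/`S_y`, ensemble experiment |
| `cfcsim.spectral_estimation` | Hann periodograms, ensemble averaging, peak/centroid/slope/pulse-duration measurements |
| `cfcsim.cli` | YAML config handling and the `cfcsim` command |

## CLI

```sh
cfcsim validate-config config.yaml
cfcsim spectra    --out out/theory
cfcsim simulate   --config config.yaml --out out/sim --seed 1
cfcsim experiment --out out/exp --seed 1 --ensemble-size 500 [--plot]
```

`experiment` runs all three coupling kinds (or one, with `--coupling`),
writes averaged estimated spectra, theoretical spectra, and a JSON report
with the low-band (theta) peak, the high-band (gamma) argmax and power
centroid, and the fitted background slope. Minimal config:

```yaml
delta_s: 0.001
n_samples: 1000
ensemble_size: 500
theta: {center_f_hz: 6.0, peak_width_hz: 2.0, variance: 1.0}
x: {f_lo_hz: 100.0, f_hi_hz: 140.0, variance: null}   # null -> default scaling
eta: {alpha: 2.0, floor_f_hz: 0.5, variance: null}
coupling: {kind: pulsatile, tau_samples: 0}
```

Omitted variances are filled by documented defaults: theta has unit
variance, eta is scaled so its density at the theta frequency is one tenth
of the theta peak, and x is scaled through the envelope moment so the gamma
variance is one tenth of theta's. Every run writes a `manifest.json` with
the config snapshot, base seed, and SHA-256 checksums of all outputs; the
same seed reproduces byte-identical numeric output.

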