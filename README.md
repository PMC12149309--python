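# bcgdenoise

Denoising and validation tools for **ballistocardiogram (BCG)** signals —
the micro-vibrations the body surface picks up from every heartbeat. BCG
sensing mats record cardiac mechanical activity without electrodes, but the
raw signal mixes the cardiac waveform with a large low-frequency respiratory
sway and wideband sensor noise. This package implements:

- **ESVT (Enhanced Singular Value Thresholding)** denoising: the signal
  x(n) is embedded into an L×(N−L+1) Hankel trajectory matrix **X**,
  decomposed as **X = UΣVᵀ**, the singular values are soft-thresholded
  (σᵢ → max(0, σᵢ − τ)), the matrix is reconstructed and re-projected onto
  Hankel structure by anti-diagonal averaging, and the cycle repeats for
  *i* iterations before inverse embedding back to a time series — a
  Cadzow/SSA-style alternating scheme.
- A **synthetic BCG generator** (six cardiac sinusoids at 1.5–9 Hz plus a
  0.2 Hz respiratory sinusoid, Gaussian noise at nominal SNR 0–15 dB,
  100 Hz sampling) used to **grid-search (τ_opt, i_opt)** by output SNR,
  and a conventional **wavelet soft-threshold baseline** for comparison.
- **Heart-rate agreement analysis**: R-peak/J-peak handling, HR
  estimation, and Bland–Altman statistics (Pearson r, RMSE, MAE, bias,
  limits of agreement bias ± 1.96·SD).
- **Dataset I/O** for the published recording layout
  (`hdata<ID><EJ|XJ|ZJ>` folders with `signal.csv`, peak-annotation CSVs,
  subject metadata spreadsheet), with matching writers so everything is
  testable from synthetic fixtures.

Intended users: researchers working on unobtrusive cardiac monitoring who
need a tested, reproducible reference implementation of Hankel-SVD
soft-threshold denoising and its evaluation protocol.

## Worked example

```python
import numpy as np
from bcgdenoise import (SyntheticSpec, simulate, grid_search,
                        esvt_denoise, measure_snr)

spec = SyntheticSpec(nominal_snr_db=0.0)      # 30 s at 100 Hz, heavy noise
gs = grid_search(spec, seed=1)                # tune (tau_opt, i_opt)
sig = simulate(spec, 0)                       # one noisy realization
den = esvt_denoise(sig.noisy, gs.params())
print(f"tau_opt={gs.tau_opt:.1f}  i_opt={gs.i_opt}")
print(f"SNR vs cardiac: {measure_snr(sig.noisy, sig.clean_cardiac):.2f} dB "
      f"-> {measure_snr(den.denoised, sig.clean_cardiac):.2f} dB")
```

Output:

```
tau_opt=424.3  i_opt=2
SNR vs cardiac: -11.08 dB -> 0.00 dB
```

The input SNR is measured against the cardiac component alone, so the
respiratory sinusoid (amplitude 2 vs cardiac amplitudes ≤ 0.6) counts as
interference: the tuned filter removes most of the noise *and* the
respiratory sway, raising the cardiac-referenced SNR by about 11 dB.

The same operations are available from a CLI:

```bash
bcgdenoise simulate --duration 30 --snr 0 --seed 1 --out run/
bcgdenoise tune --seed 1 --out run/
bcgdenoise denoise --input run/some_signal.csv --tau 424.3 --iters 2 --out run/
bcgdenoise benchmark --levels 0,5,10,15 --seeds 10 --out run/
bcgdenoise validate-hr --root /path/to/Data --out run/
bcgdenoise dataset-check --root /path/to/Data
```

Every run writes its resolved configuration as `run_config.json` beside
its outputs; re-running from that file reproduces deterministic outputs
bitwise.

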