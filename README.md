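# spikefit

Model-based analysis of **calcium spikes** in confocal line-scan (x-t)
images of cardiac myocytes.

Calcium spikes — the fluorescence transients produced by calcium release
from single ryanodine-receptor clusters — are fast (milliseconds) and
noisy (signal-to-noise ratios down to ~1-2). Temporal filtering would
distort their kinetics, so spikefit takes the opposite route: it fits each
extracted ΔF/F₀ trace with a kinetic model of the spike time course,

  ΔF(t) = F_M · (1 − e^−(t−t₀)/τ_A) · (α + (1−α) · e^−(t−t₀)/τ_T),  t ≥ t₀,

and accepts a spike only when the five-parameter fit beats a constant fit
in the extra-sum-of-squares F-test, F(4, N−5), at p < 0.05. Accepted fits
are summarized by the latency t₀ and the numeric descriptors A (peak
amplitude), TTP (time to peak) and FDHM (full duration at half-maximum).

The package also corrects a systematic timing error of line-scan imaging:
pixels within a line are acquired sequentially (one pixel integration time
t_p apart), yet image software stamps them all with the line time. At
1000 Hz and 512 pixels/line this mis-times an off-center spike by up to
~262 µs, which propagates directly into the fitted latency. spikefit
evaluates the model at the true per-pixel acquisition times instead
(unidirectional and bidirectional scan modes).

Included besides the fitting core: trace extraction from TIFF x-t images
(background subtraction, F₀ normalization, 7-pixel spatial averaging), a
synthetic-spike simulator (OG-5N- and Fluo-3-like presets, three dataset
designs, Mersenne-twister noise), and a benchmarking harness (algorithm
grid, detectability-vs-SNR logistic, timing-error experiment).

## Worked example

```python
import numpy as np
from spikefit import (SpikeParams, ScanConfig, FitSettings, OG5N,
                      build_pixel_time_map, render_xt_image, extract_trace,
                      fit_spike)

scan = ScanConfig.from_preset(1000, n=96, m=256)      # 1 kHz, 96 x 256 px
truth = SpikeParams(t0=5.0, FM=2.0, alpha=0.05, tauA=2.2, tauT=4.5)
image = render_xt_image([(truth, 48)], scan, baseline=100.0,
                        noise_sd=2.0, stimulus_onset=60.0, seed=1)

timemap = build_pixel_time_map(scan)
trace = extract_trace(image, 48, timemap, correct_times=True, F0=100.0)
fit = fit_spike(trace, FitSettings(init=OG5N.param_means))
d = fit.descriptors
print(f"accepted={fit.accepted} p={fit.p_value:.2e}")
print(f"t0={fit.params.t0:.2f} ms  A={d.A:.3f} dF/F0  "
      f"TTP={d.TTP:.2f} ms  FDHM={d.FDHM:.2f} ms")
```

prints

```
accepted=True p=8.56e-40
t0=4.85 ms  A=0.626 dF/F0  TTP=2.68 ms  FDHM=9.11 ms
```

The spike is accepted with overwhelming significance, and the descriptors
recover the seeded curve (true peak 0.59 dF/F₀ at TTP 2.5 ms, latency
5.0 ms) to within the noise of this single trace. Note that F_M = 2 is
*not* the amplitude: it is the level the spike would reach if release
never terminated — the descriptors, not the raw parameters, are the
physical summary. On noise-free input the corrected times matter directly:
with `correct_times=False` the fitted latency is early by exactly the
position time error of the spike's column (~25 µs at column 48, up to
~262 µs at the image edge).

The same pipeline is scriptable from the shell:

```sh
spikefit simulate --type 3 --indicator og5n --snr 10 --n 100 --seed 1 --out data/
spikefit analyze --config myscan.yaml
spikefit benchmark --experiment detectability --indicator og5n --fast
```

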