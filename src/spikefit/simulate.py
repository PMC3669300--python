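"""Synthetic calcium-spike datasets and x-t image rendering.

Three dataset types drive the validation program:

1. *random-parameter spikes*: model parameters drawn independently from
   normal distributions around the indicator's mean values, plus Gaussian
   white noise of fixed RMS — emulates a population of experimental spikes.
2. *pure noise*: no signal at all — probes false-positive detection.
3. *fixed-parameter spikes*: one spike (the indicator means) combined with
   independent noise instances whose SD is set from the required
   signal-to-noise ratio, ``sigma = A_mean / SNR`` — probes accuracy,
   precision and detectability as a function of SNR.

Noise is normally distributed pseudorandom numbers from the Mersenne
twister generator (``numpy.random.RandomState``).  Traces are sampled at
the corrected acquisition times of the central pixel of the configured
scan, so sequential-sampling effects are representable.

Indicator presets
-----------------
The presets for OG-5N (Oregon Green BAPTA-5N, low affinity, low SNR) and
Fluo-3 (high affinity, high SNR) are *synthetic reconstructions*: the
primary per-parameter tables of the source datasets are not publicly
deposited, so the distributions below were calibrated to the published
aggregate statistics of those datasets — mean peak amplitude, noise RMS,
the SNR distribution (5.39 ± 2.11 for OG-5N, 14.19 ± 5.60 for Fluo-3) and
the detectability curve.  See docs/methods.md for the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .extract import FluoTrace, LineScanImage
from .model import SpikeParams, compute_descriptors, evaluate_spike
from .scantime import ScanConfig, ScanMode, build_pixel_time_map

__all__ = [
    "IndicatorPreset",
    "DatasetSpec",
    "OG5N",
    "FLUO3",
    "PRESETS",
    "draw_spike_params",
    "noise_sd_for_snr",
    "make_dataset",
    "render_xt_image",
    "default_scan_config",
]

_PARAM_NAMES = ("t0", "FM", "alpha", "tauA", "tauT")


@dataclass(frozen=True)
class IndicatorPreset:
    """Spike-parameter distribution and noise model of one indicator."""

    name: str
    param_means: SpikeParams
    param_sds: dict[str, float]
    noise_rms_type1: float
    snr_grid_type3: tuple[float, ...]

    def __post_init__(self):
        missing = set(_PARAM_NAMES) - set(self.param_sds)
        if missing:
            raise ValueError(f"param_sds missing entries for {sorted(missing)}")
        if any(v < 0 for v in self.param_sds.values()):
            raise ValueError("parameter SDs must be non-negative")
        if any(s <= 0 for s in self.snr_grid_type3):
            raise ValueError("SNR grid values must be positive")

    def mean_amplitude(self) -> float:
        """Peak amplitude of the mean-parameter spike (dF/F0)."""
        return compute_descriptors(self.param_means).A


# Synthetic indicator presets (see module docstring): parameter means/SDs
# calibrated against the published aggregate statistics of the original
# OG-5N and Fluo-3 spike datasets, not transcribed from a primary table.
OG5N = IndicatorPreset(
    name="OG5N",
    # mean spike: A ~ 0.81 dF/F0, TTP ~ 2.5 ms, FDHM ~ 7 ms; with the fixed
    # 0.15-RMS noise the population SNR is ~ 5.4 +/- 2.2
    param_means=SpikeParams(t0=4.15, FM=2.02, alpha=0.03, tauA=2.20, tauT=4.50),
    param_sds={"t0": 1.2, "FM": 0.68, "alpha": 0.02, "tauA": 0.55, "tauT": 1.10},
    noise_rms_type1=0.15,
    snr_grid_type3=(1.0, 1.5, 2.0, 3.0, 5.0, 7.0, 10.0),
)

FLUO3 = IndicatorPreset(
    name="Fluo3",
    # mean spike: A ~ 1.3 dF/F0, TTP ~ 3.5 ms, FDHM ~ 10 ms; population SNR
    # ~ 14.2 +/- 5.7 at the matched type-1 noise RMS
    param_means=SpikeParams(t0=4.20, FM=3.17, alpha=0.03, tauA=3.00, tauT=6.50),
    param_sds={"t0": 1.2, "FM": 1.10, "alpha": 0.02, "tauA": 0.70, "tauT": 1.50},
    noise_rms_type1=0.0916,
    snr_grid_type3=(1.0, 1.5, 2.0, 3.0, 5.0, 7.0, 10.0, 15.0, 20.0),
)

PRESETS: dict[str, IndicatorPreset] = {"og5n": OG5N, "fluo3": FLUO3}


def default_scan_config() -> ScanConfig:
    """1000 Hz unidirectional scanning, 512 x 512 pixels."""
    return ScanConfig(mode=ScanMode.UNIDIRECTIONAL, f=1000.0, n=512, m=512, tp=0.515)


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for one synthetic dataset."""

    dataset_type: int
    preset: IndicatorPreset
    n_traces: int = 1000
    snr: Optional[float] = None
    seed: int = 0
    sampling: ScanConfig = field(default_factory=default_scan_config)
    column: int = 255
    stimulus_onset: float = 50.0

    def __post_init__(self):
        if self.dataset_type not in (1, 2, 3):
            raise ValueError("dataset_type must be 1, 2 or 3")
        if self.dataset_type == 3 and (self.snr is None or self.snr <= 0):
            raise ValueError("type-3 datasets require a positive snr")
        if self.n_traces < 1:
            raise ValueError("n_traces must be at least 1")
        if not 0 <= self.column < self.sampling.n:
            raise ValueError("column outside the scanned line")


def noise_sd_for_snr(mean_amplitude: float, snr: float) -> float:
    """Noise SD that realizes a required SNR: ``sigma = A / SNR``."""
    if snr <= 0:
        raise ValueError(f"SNR must be positive, got {snr}")
    return mean_amplitude / snr


def draw_spike_params(
    preset: IndicatorPreset, n: int, seed: int | np.random.RandomState = 0
) -> list[SpikeParams]:
    """Draw ``n`` parameter sets, each component independently normal.

    Draws violating the model's validity constraints (negative time
    constants or amplitude, alpha outside [0, 1], negative latency) are
    rejected and redrawn, so no probability mass piles up at the
    boundaries.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.RandomState) else np.random.RandomState(seed)
    means = preset.param_means
    out = []
    for _ in range(n):
        vals = {}
        for name in _PARAM_NAMES:
            mu, sd = getattr(means, name), preset.param_sds[name]
            for _ in range(10_000):
                v = rng.normal(mu, sd)
                if _param_valid(name, v):
                    break
            else:  # pragma: no cover - only reachable with absurd presets
                raise RuntimeError(f"rejection sampling for {name} did not terminate")
            vals[name] = v
        out.append(SpikeParams(**vals).validate())
    return out


def _param_valid(name: str, v: float) -> bool:
    if name == "alpha":
        return 0.0 <= v <= 1.0
    if name == "t0":
        return v >= 0.0
    return v > 0.0  # FM, tauA, tauT


def make_dataset(spec: DatasetSpec) -> list[tuple[FluoTrace, Optional[SpikeParams]]]:
    """Generate the traces of a dataset (with per-trace ground truth).

    Sample times are the corrected acquisition times of the central pixel
    at ``spec.column``, shifted so t = 0 is the stimulus onset.  The
    trace's ``baseline_sd`` is estimated empirically from the pre-stimulus
    samples, exactly as for extracted experimental traces.
    """
    rng = np.random.RandomState(spec.seed)
    timemap = build_pixel_time_map(spec.sampling)
    times = timemap.times[:, spec.column] - spec.stimulus_onset

    if spec.dataset_type == 1:
        truths: list[Optional[SpikeParams]] = list(
            draw_spike_params(spec.preset, spec.n_traces, rng)
        )
        sigma = spec.preset.noise_rms_type1
    elif spec.dataset_type == 2:
        truths = [None] * spec.n_traces
        sigma = spec.preset.noise_rms_type1
    else:
        truths = [spec.preset.param_means] * spec.n_traces
        sigma = noise_sd_for_snr(spec.preset.mean_amplitude(), spec.snr)

    dataset = []
    for truth in truths:
        signal = evaluate_spike(truth, times) if truth is not None else np.zeros_like(times)
        values = signal + rng.normal(0.0, sigma, size=times.size) if sigma > 0 else signal.copy()
        pre = values[times < 0.0]
        baseline_sd = float(pre.std(ddof=1)) if pre.size >= 2 else float(sigma)
        dataset.append(
            (FluoTrace(times=times, values=values, baseline_sd=baseline_sd,
                       center_column=spec.column, n_avg=1), truth)
        )
    return dataset


def render_xt_image(
    spikes: list[tuple[SpikeParams, int]],
    config: ScanConfig,
    baseline: float = 100.0,
    background: float = 10.0,
    spatial_sd: float = 2.0,
    noise_sd: float = 0.0,
    stimulus_onset: float = 0.0,
    seed: int | np.random.RandomState = 0,
) -> LineScanImage:
    """Render a synthetic x-t image with spikes at given columns.

    Each pixel is evaluated at its *own* acquisition time, so the
    sequential-sampling timing error is physically present in the image::

        pixel(i, j) = background
                      + F0 * (1 + sum_k dF_k(t_ij - stimulus_onset)
                                    * exp(-(j - col_k)^2 / (2 spatial_sd^2)))
                      + noise

    ``spatial_sd`` is the Gaussian spatial profile of a spike in pixels;
    pass ``np.inf`` for a spatially flat signal.
    """
    for _, col in spikes:
        if not 0 <= col < config.n:
            raise ValueError(f"spike column {col} outside the scanned line")
    rng = seed if isinstance(seed, np.random.RandomState) else np.random.RandomState(seed)
    timemap = build_pixel_time_map(config)
    t = timemap.times - stimulus_onset
    j = np.arange(config.n, dtype=float)[None, :]
    dF = np.zeros((config.m, config.n))
    for params, col in spikes:
        if np.isinf(spatial_sd):
            profile = np.ones((1, config.n))
        else:
            profile = np.exp(-((j - col) ** 2) / (2.0 * spatial_sd**2))
        dF += evaluate_spike(params, t.ravel()).reshape(t.shape) * profile
    pixels = background + baseline * (1.0 + dF)
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
    return LineScanImage(
        pixels=pixels,
        config=config,
        stimulus_onset=stimulus_onset,
        provenance={"synthetic": True, "baseline_F0": baseline, "background": background},
    )
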