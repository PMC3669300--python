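"""Phenomenological model of the calcium-spike time course.

A calcium spike is the brief, localized rise of indicator fluorescence
produced by calcium release from a single ryanodine-receptor cluster in a
patch-clamped cardiac myocyte.  Its time course, expressed as a
background-subtracted fluorescence increase normalized to the pre-stimulus
baseline (dF/F0), is described by the product of an exponential activation
and an exponential termination::

    dF(t) = FM * (1 - exp(-(t - t0)/tauA)) * (alpha + (1 - alpha) * exp(-(t - t0)/tauT))

for ``t >= t0`` and zero before the onset ``t0``.  ``FM`` is the maximal
fluorescence increase that would be reached in the absence of release
termination, ``alpha`` is the fraction of the signal contributed by the
calcium concentration build-up (the sustained component that remains after
release terminates), and ``tauA``/``tauT`` are the activation and
termination time constants.

Because the model is phenomenological, fitted spikes are reported through
numeric descriptors derived from the fitted curve: the peak amplitude ``A``,
the time to peak ``TTP`` (interval from onset to peak) and the full duration
at half-maximum ``FDHM``.  All times are in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "SpikeParams",
    "SpikeDescriptors",
    "evaluate_spike",
    "compute_descriptors",
]

# exponent clip keeps exp() finite for wildly invalid trial parameters
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class SpikeParams:
    """The five parameters of the spike time-course model.

    Attributes
    ----------
    t0 : float
        Latency of the spike onset relative to the stimulus, ms.
    FM : float
        Maximal fluorescence increase in the absence of release
        termination, dF/F0 units.
    alpha : float
        Fraction of the signal contributed by calcium build-up, in [0, 1].
    tauA : float
        Activation time constant, ms.
    tauT : float
        Termination time constant, ms.
    """

    t0: float
    FM: float
    alpha: float
    tauA: float
    tauT: float

    def validate(self) -> "SpikeParams":
        if not np.isfinite([self.t0, self.FM, self.alpha, self.tauA, self.tauT]).all():
            raise ValueError("spike parameters must be finite")
        if self.FM <= 0:
            raise ValueError(f"FM must be positive, got {self.FM}")
        if self.tauA <= 0 or self.tauT <= 0:
            raise ValueError(f"time constants must be positive, got tauA={self.tauA}, tauT={self.tauT}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.t0 < 0:
            raise ValueError(f"latency t0 must be non-negative, got {self.t0}")
        return self

    def as_array(self) -> np.ndarray:
        return np.array([self.t0, self.FM, self.alpha, self.tauA, self.tauT], float)

    @classmethod
    def from_array(cls, x) -> "SpikeParams":
        t0, FM, alpha, tauA, tauT = (float(v) for v in x)
        return cls(t0=t0, FM=FM, alpha=alpha, tauA=tauA, tauT=tauT)


@dataclass(frozen=True)
class SpikeDescriptors:
    """Numeric descriptors of a (fitted) spike curve.

    ``FDHM`` is ``None`` when the curve never falls back below half of its
    peak within the analysis window (e.g. ``alpha = 1``, a purely monotone
    build-up).
    """

    A: float
    TTP: float
    FDHM: Optional[float]
    t0: float

    @property
    def fdhm_defined(self) -> bool:
        return self.FDHM is not None


def _evaluate_raw(x: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Evaluate the model without validating parameters.

    Used by unconstrained optimizers that may probe invalid regions; the
    exponents are clipped so the result stays finite.
    """
    t0, FM, alpha, tauA, tauT = x
    u = np.asarray(times, float) - t0
    up = np.where(u > 0.0, u, 0.0)
    ea = np.exp(np.clip(-up / tauA, -_EXP_CLIP, _EXP_CLIP))
    et = np.exp(np.clip(-up / tauT, -_EXP_CLIP, _EXP_CLIP))
    out = FM * (1.0 - ea) * (alpha + (1.0 - alpha) * et)
    return np.where(u > 0.0, out, 0.0)


def _jacobian_raw(x: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the model w.r.t. (t0, FM, alpha, tauA, tauT)."""
    t0, FM, alpha, tauA, tauT = x
    u = np.asarray(times, float) - t0
    mask = u > 0.0
    up = np.where(mask, u, 0.0)
    ea = np.exp(np.clip(-up / tauA, -_EXP_CLIP, _EXP_CLIP))
    et = np.exp(np.clip(-up / tauT, -_EXP_CLIP, _EXP_CLIP))
    g = 1.0 - ea
    h = alpha + (1.0 - alpha) * et
    J = np.zeros((times.size, 5))
    # d/dt0: chain rule through u = t - t0
    J[:, 0] = -FM * (ea / tauA * h - g * (1.0 - alpha) * et / tauT)
    J[:, 1] = g * h
    J[:, 2] = FM * g * (1.0 - et)
    J[:, 3] = -FM * h * ea * up / tauA**2
    J[:, 4] = FM * g * (1.0 - alpha) * et * up / tauT**2
    J[~mask, :] = 0.0
    return J


def evaluate_spike(params: SpikeParams, times) -> np.ndarray:
    """Evaluate the spike model pointwise on an arbitrary time grid.

    Parameters
    ----------
    params : SpikeParams
        Valid model parameters (validated; invalid values raise
        ``ValueError``).
    times : array_like
        Sample times in ms.  The grid may be non-uniform, which is how
        pixel-acquisition-time-corrected traces are evaluated.

    Returns
    -------
    ndarray
        dF/F0 values; exactly zero for ``t <= t0``, continuous and
        non-negative everywhere.
    """
    params.validate()
    times = np.asarray(times, float)
    if not np.isfinite(times).all():
        raise ValueError("times must be finite")
    return _evaluate_raw(params.as_array(), times)


def compute_descriptors(
    params: SpikeParams,
    window: tuple[float, float] = (0.0, 200.0),
    resolution: float = 0.01,
) -> SpikeDescriptors:
    """Derive (A, TTP, FDHM) from the model curve by numeric search.

    The peak is bracketed on a dense grid and refined by bounded scalar
    minimization; the half-maximum crossings are located by bracketed
    root-finding to 1e-4 ms.  ``FDHM`` is reported as undefined (``None``)
    when the descending arm never reaches half-maximum inside the window —
    never as the window length.

    Parameters
    ----------
    params : SpikeParams
    window : (t_start, t_end)
        Analysis window in ms; must contain ``t0``.
    resolution : float
        Grid step for the initial bracketing, ms.
    """
    params.validate()
    t_start, t_end = float(window[0]), float(window[1])
    if not (t_start <= params.t0 <= t_end):
        raise ValueError(f"window {window} must contain the onset t0={params.t0}")
    if resolution <= 0:
        raise ValueError("resolution must be positive")

    x = params.as_array()
    # only t > t0 matters; the curve is identically zero before onset
    grid = np.append(np.arange(max(t_start, params.t0), t_end, resolution), t_end)
    vals = _evaluate_raw(x, grid)
    k = int(np.argmax(vals))

    if 0 < k < grid.size - 1:
        res = minimize_scalar(
            lambda t: -_evaluate_raw(x, np.array([t]))[0],
            bounds=(grid[k - 1], grid[k + 1]),
            method="bounded",
            options={"xatol": 1e-7},
        )
        t_peak, A = float(res.x), float(-res.fun)
        if vals[k] > A:  # guard against refinement losing the grid optimum
            t_peak, A = float(grid[k]), float(vals[k])
    else:
        t_peak, A = float(grid[k]), float(vals[k])

    half = A / 2.0

    def f(t):
        return _evaluate_raw(x, np.array([t]))[0] - half

    # ascending crossing between onset and peak
    if t_peak > params.t0 and f(t_peak) > 0:
        t_up = brentq(f, params.t0, t_peak, xtol=1e-4)
    else:
        t_up = t_peak

    # descending crossing between the peak and the window end, if any
    fdhm: Optional[float] = None
    if f(t_end) < 0:
        # bracket from the grid to stay robust against long flat tails
        tail = grid[grid >= t_peak]
        tail_vals = _evaluate_raw(x, tail) - half
        below = np.nonzero(tail_vals < 0)[0]
        if below.size:
            j = below[0]
            lo = tail[j - 1] if j > 0 else t_peak
            t_down = brentq(f, lo, tail[j], xtol=1e-4)
            fdhm = float(t_down - t_up)

    return SpikeDescriptors(A=A, TTP=float(t_peak - params.t0), FDHM=fdhm, t0=params.t0)
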