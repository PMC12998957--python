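"""Event-level leaky integrate-and-fire simulator with alpha synapses.

Provides Poisson barrage generation, interneuron population recruitment,
trial loops and PSTHs.  Internal units: ms, mV, pA, nS, pF, MOhm.  These are
self-consistent: pA * MOhm = microvolt, so leak current in pA is
``(V - V_l) / R * 1e3``, and pA * ms / pF = mV for the Euler update.

Integration is forward Euler at dt = 0.01 ms; the spike test runs after the
voltage update and the membrane is reset to ``V_l`` in the same step, with
no additional refractory period.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
from scipy.signal import fftconvolve

from .ei_core import NetworkParams, ParameterError

__all__ = [
    "LIFParams",
    "SynapticKernel",
    "SimResult",
    "InhibPopResult",
    "alpha_kernel",
    "kernel_charge",
    "psp_shape",
    "psp_peak",
    "integrate_lif",
    "simulate_lif",
    "generate_sustained_barrage",
    "simulate_inhibitory_population",
    "measure_pI_hat",
    "build_inhibitory_barrage",
    "run_trials",
]


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire constants.

    Defaults: R = 75 MOhm, V_l = -70 mV (rest and reset), tau_m = 10 ms,
    C = 133 pF, threshold V_theta = -55 mV, dt = 0.01 ms.  ``tau_m`` must be
    consistent with R * C to within 1%.
    """

    R: float = 75.0
    V_l: float = -70.0
    tau_m: float = 10.0
    C: float = 133.0
    V_theta: float = -55.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError(f"dt must be > 0, got {self.dt!r}")
        if self.V_theta <= self.V_l:
            raise ParameterError("V_theta must exceed V_l")
        rc = self.R * self.C / 1000.0  # MOhm * pF = us -> ms
        if abs(rc - self.tau_m) > 0.01 * self.tau_m:
            raise ParameterError(
                f"tau_m={self.tau_m} ms inconsistent with R*C={rc:.4g} ms (>1%)"
            )

    @property
    def delta_V(self) -> float:
        """Threshold distance from rest, V_theta - V_l (mV)."""
        return self.V_theta - self.V_l

    def with_(self, **kwargs) -> "LIFParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SynapticKernel:
    """Alpha-function unitary synaptic event.

    ``amplitude`` is the peak value (pA in current mode, nS in conductance
    mode; inhibitory current kernels carry a negative amplitude).  The
    normalized shape is ``(t/tau) * exp(1 - t/tau)``, peaking at 1 for
    t = tau.  ``support`` truncates the sampled kernel; the default 15 ms
    (7.5 tau) reproduces a unitary charge of 0.0557 pC for a 10.3 pA event
    rather than the untruncated 0.0560 pC.
    """

    amplitude: float
    tau: float = 2.0
    mode: str = "current"
    V_rev: float = 0.0
    support: float = 15.0

    def __post_init__(self) -> None:
        if self.mode not in ("current", "conductance"):
            raise ParameterError(f"kernel mode must be current|conductance, got {self.mode!r}")
        if self.tau <= 0 or self.support <= 0:
            raise ParameterError("tau and support must be > 0")
        if self.mode == "conductance" and self.amplitude < 0:
            raise ParameterError("conductance kernels must have amplitude >= 0")

    @classmethod
    def excitatory_current(cls, amplitude: float = 10.3, **kw) -> "SynapticKernel":
        return cls(amplitude=amplitude, mode="current", **kw)

    @classmethod
    def inhibitory_current(cls, amplitude: float = -10.3, **kw) -> "SynapticKernel":
        return cls(amplitude=amplitude, mode="current", **kw)

    @classmethod
    def excitatory_conductance(cls, amplitude: float = 0.147, **kw) -> "SynapticKernel":
        return cls(amplitude=amplitude, mode="conductance", V_rev=0.0, **kw)

    @classmethod
    def inhibitory_conductance(cls, amplitude: float = 1.045, **kw) -> "SynapticKernel":
        return cls(amplitude=amplitude, mode="conductance", V_rev=-80.0, **kw)


def alpha_kernel(kernel: SynapticKernel, dt: float) -> np.ndarray:
    """Sample the scaled alpha kernel on [0, support] at step dt.

    Requires dt <= tau/10 so the peak is resolved; warns if the support
    window is shorter than 5 tau (charge undercounted).
    """
    if dt > kernel.tau / 10.0:
        raise ParameterError(f"dt={dt} too coarse for tau={kernel.tau} (need dt <= tau/10)")
    if kernel.support < 5.0 * kernel.tau:
        warnings.warn(
            f"kernel support {kernel.support} ms < 5*tau: charge will be undercounted",
            stacklevel=2,
        )
    t = np.arange(0.0, kernel.support + 0.5 * dt, dt)
    return kernel.amplitude * (t / kernel.tau) * np.exp(1.0 - t / kernel.tau)


def kernel_charge(kernel: SynapticKernel, dt: float = 0.01) -> float:
    """Integral of the sampled kernel: pC for current kernels, nS*ms otherwise."""
    samples = alpha_kernel(kernel, dt)
    integral = float(np.trapezoid(samples, dx=dt))
    return integral / 1000.0 if kernel.mode == "current" else integral


# -- closed-form membrane response ----------------------------------------

def psp_shape(t, amplitude: float, tau: float, lif: LIFParams) -> np.ndarray:
    """Closed-form PSP: alpha current filtered by the passive membrane (mV).

    Solves ``tau_m dV/dt = -V + R i(t) / 1e3`` for
    ``i(t) = amplitude (t/tau) exp(1 - t/tau)``:

        V(t) = A * exp(-t/tau_m) * (1 - (1 + a t) exp(-a t)) / a^2,
        a = 1/tau - 1/tau_m,   A = amplitude * R * e / (1e3 * tau * tau_m),

    with the degenerate quadratic form when tau == tau_m.
    """
    t = np.asarray(t, dtype=float)
    scale = amplitude * lif.R / 1000.0 * math.e / (tau * lif.tau_m)  # mV / ms^2
    a = 1.0 / tau - 1.0 / lif.tau_m
    decay = np.exp(-t / lif.tau_m)
    if abs(a) < 1e-12:
        out = scale * decay * t * t / 2.0
    else:
        out = scale * decay * (1.0 - (1.0 + a * t) * np.exp(-a * t)) / (a * a)
    return np.where(t >= 0, out, 0.0)


def psp_peak(amplitude: float, tau: float, lif: LIFParams) -> float:
    """Peak depolarization (mV) of the closed-form unitary PSP."""
    t = np.arange(0.0, 10.0 * (tau + lif.tau_m), lif.dt)
    return float(psp_shape(t, amplitude, tau, lif).max())


# -- Euler integration -----------------------------------------------------

def integrate_lif(
    drive,
    lif: LIFParams,
    record_v: bool = False,
):
    """Forward-Euler integration of one or many LIF neurons.

    Parameters
    ----------
    drive
        Either an array of synaptic current (pA) with time on the last axis,
        or a tuple ``(gE, VE, gI, VI)`` of conductance arrays (nS) and
        reversal potentials (mV) for conductance mode.
    lif
        Neuron constants; ``drive`` must be sampled at ``lif.dt``.

    Returns
    -------
    spikes : boolean array, same shape as the drive
    v : voltage traces (only if ``record_v``), reset values at spike bins
    """
    if isinstance(drive, tuple):
        gE, VE, gI, VI = drive
        gE = np.atleast_2d(np.asarray(gE, dtype=float))
        gI = np.atleast_2d(np.asarray(gI, dtype=float))
        if gE.shape != gI.shape:
            raise ParameterError("gE and gI must have the same shape")
        if not (np.isfinite(gE).all() and np.isfinite(gI).all()):
            raise ParameterError("non-finite conductance drive")
        n, T = gE.shape
        conductance = True
    else:
        i_syn = np.atleast_2d(np.asarray(drive, dtype=float))
        if not np.isfinite(i_syn).all():
            raise ParameterError("non-finite current drive")
        n, T = i_syn.shape
        conductance = False

    dt = lif.dt
    V = np.full(n, lif.V_l)
    spikes = np.zeros((n, T), dtype=bool)
    v_out = np.empty((n, T)) if record_v else None
    leak_per_R = 1000.0 / lif.R  # nS; (V - V_l) * leak_per_R is pA
    for k in range(T):
        if conductance:
            i_k = gE[:, k] * (VE - V) + gI[:, k] * (VI - V)
        else:
            i_k = i_syn[:, k]
        V = V + dt / lif.C * (-(V - lif.V_l) * leak_per_R + i_k)
        fired = V >= lif.V_theta
        if fired.any():
            spikes[:, k] = fired
            V = np.where(fired, lif.V_l, V)
        if record_v:
            v_out[:, k] = V
    return (spikes, v_out) if record_v else (spikes, None)


@dataclass
class SimResult:
    """Spike times, PSTH and rate statistics over trials."""

    spike_times: list  # per-trial arrays of spike times (ms)
    dt: float
    duration: float
    psth: Optional[np.ndarray] = None  # per-bin firing probability
    mean_rate: float = 0.0
    rate_sd: float = 0.0
    v: Optional[np.ndarray] = None
    currents: Optional[dict] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.spike_times)


def _spike_times_from_raster(raster: np.ndarray, dt: float) -> list:
    return [np.flatnonzero(row) * dt for row in raster]


def _result_from_raster(raster, dt, duration, v=None, currents=None, meta=None) -> SimResult:
    counts = raster.sum(axis=1)
    rates = counts / duration * 1000.0  # Hz
    psth = raster.mean(axis=0).astype(float)
    return SimResult(
        spike_times=_spike_times_from_raster(raster, dt),
        dt=dt,
        duration=duration,
        psth=psth,
        mean_rate=float(rates.mean()),
        rate_sd=float(rates.std(ddof=1)) if len(rates) > 1 else 0.0,
        v=v,
        currents=currents,
        meta=meta or {},
    )


def simulate_lif(input_drive, lif: LIFParams, record_v: bool = True) -> SimResult:
    """Single-trial simulation; ``input_drive`` as in :func:`integrate_lif`."""
    raster, v = integrate_lif(input_drive, lif, record_v=record_v)
    T = raster.shape[1]
    return _result_from_raster(
        raster, lif.dt, T * lif.dt, v=v[0] if v is not None else None
    )


# -- barrage generation ----------------------------------------------------

def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def poisson_events(rate_per_ms, n_bins: int, dt: float, rng) -> np.ndarray:
    """Per-bin Poisson event counts at instantaneous rate (events/ms).

    Poisson (not Bernoulli) per bin, so several events may share a 0.01 ms
    bin at high aggregate rates.
    """
    mu = np.broadcast_to(np.asarray(rate_per_ms, dtype=float), (n_bins,)) * dt
    return rng.poisson(mu)


def generate_sustained_barrage(
    params: NetworkParams,
    pE_profile,
    duration: float,
    kernel: SynapticKernel,
    rng_seed,
    transmission: Optional[float] = None,
) -> np.ndarray:
    """Inhomogeneous-Poisson synaptic barrage (current in pA, or nS).

    Events are drawn at instantaneous rate ``nE * pE(t) * rE * transmission``
    and convolved with the unitary kernel.  ``transmission`` defaults to
    ``params.pE_to_R``; pass ``params.pE_to_I`` for interneuron drive.
    """
    rng = _as_rng(rng_seed)
    return _barrage(params, pE_profile, duration, kernel, rng, transmission)


def _barrage(params, pE_profile, duration, kernel, rng, transmission=None, dt=None):
    dt = dt if dt is not None else 0.01
    n_bins = int(round(duration / dt))
    profile = np.broadcast_to(np.asarray(pE_profile, dtype=float), (n_bins,))
    if profile.min() < 0 or profile.max() > 1:
        raise ParameterError("pE profile values must lie in [0, 1]")
    ptrans = params.pE_to_R if transmission is None else transmission
    rate_per_ms = params.nE * profile * params.rE * ptrans / 1000.0
    counts = poisson_events(rate_per_ms, n_bins, dt, rng)
    kern = alpha_kernel(kernel, dt)
    return fftconvolve(counts.astype(float), kern)[:n_bins]


@dataclass
class InhibPopResult:
    """Spike output of the simulated interneuron pool."""

    counts: np.ndarray  # (n_cells, n_bins) spike counts
    dt: float
    duration: float
    pI_hat: float  # fraction of interneurons that fired
    rI: float  # mean rate (Hz) of interneurons that fired

    @property
    def spike_times(self) -> list:
        return _spike_times_from_raster(self.counts > 0, self.dt)


def measure_pI_hat(counts: np.ndarray) -> float:
    """Fraction of interneurons with at least one spike."""
    counts = np.atleast_2d(counts)
    return float((counts.sum(axis=1) > 0).mean())


def simulate_inhibitory_population(
    params: NetworkParams,
    pE_profile,
    duration: float,
    rng_seed,
    lif: Optional[LIFParams] = None,
    kernel_E: Optional[SynapticKernel] = None,
    n_cells: Optional[int] = None,
    max_chunk_bins: int = 40_000_000,
) -> InhibPopResult:
    """Simulate a pool of 3 * nI interneurons driven by independent barrages.

    Each interneuron receives its own excitatory barrage scaled by
    ``pE_to_I``.  Returns the pooled spike trains plus the measured firing
    fraction (an estimate of pI_hat) and the mean rate of the cells that
    fired.
    """
    if params.nI < 1:
        raise ParameterError("nI must be >= 1")
    rng = _as_rng(rng_seed)
    lif = lif or LIFParams()
    kernel_E = kernel_E or SynapticKernel.excitatory_current(params.aE)
    n_cells = n_cells if n_cells is not None else 3 * params.nI
    n_bins = int(round(duration / lif.dt))

    chunk = max(1, max_chunk_bins // max(n_bins, 1))
    rasters = []
    for start in range(0, n_cells, chunk):
        stop = min(start + chunk, n_cells)
        drives = np.stack(
            [
                _barrage(params, pE_profile, duration, kernel_E, rng,
                         transmission=params.pE_to_I, dt=lif.dt)
                for _ in range(stop - start)
            ]
        )
        spikes, _ = integrate_lif(drives, lif)
        rasters.append(spikes)
    raster = np.concatenate(rasters, axis=0)
    counts = raster.astype(np.int16)
    per_cell = counts.sum(axis=1)
    fired = per_cell > 0
    pI_hat = float(fired.mean())
    rI = float(per_cell[fired].mean() / duration * 1000.0) if fired.any() else 0.0
    return InhibPopResult(counts=counts, dt=lif.dt, duration=duration, pI_hat=pI_hat, rI=rI)


def build_inhibitory_barrage(
    trains: np.ndarray,
    params: NetworkParams,
    kernel_I: SynapticKernel,
    rng_seed,
    pI: Optional[float] = None,
    dt: float = 0.01,
    n_select: Optional[int] = None,
) -> np.ndarray:
    """Sum a random subset of interneuron trains and convolve with the
    inhibitory kernel.

    The subset size is ``round(pI * nI)`` (half-up) unless ``n_select``
    overrides it; ``pI`` defaults to the parameter set's effective value.
    Selection happens before convolution.
    """
    trains = np.atleast_2d(np.asarray(trains))
    if pI is None:
        pI = params.effective_pI()
    n_sel = int(math.floor(pI * params.nI + 0.5)) if n_select is None else int(n_select)
    if n_sel > trains.shape[0]:
        raise ParameterError(
            f"requested {n_sel} trains (round(pI*nI)) but only {trains.shape[0]} available"
        )
    rng = _as_rng(rng_seed)
    n_bins = trains.shape[1]
    if n_sel == 0:
        return np.zeros(n_bins)
    idx = rng.choice(trains.shape[0], size=n_sel, replace=False)
    summed = trains[idx].sum(axis=0).astype(float)
    kern = alpha_kernel(kernel_I, dt)
    return fftconvolve(summed, kern)[:n_bins]


def run_trials(
    exc_barrage_gen: Callable[[np.random.Generator], np.ndarray],
    inh_barrage_gen: Optional[Callable[[np.random.Generator], np.ndarray]],
    lif: LIFParams,
    n_trials: int,
    rng_seed,
    conductance: Optional[tuple] = None,
    rate_window: Optional[tuple] = None,
    max_chunk_bins: int = 20_000_000,
) -> SimResult:
    """Run independent trials and compile PSTH and rate statistics.

    Each trial draws fresh excitatory / inhibitory barrages from the
    generator callables (called with a per-trial spawned RNG stream, so runs
    are reproducible bit-for-bit from the seed).  In conductance mode pass
    ``conductance=(VE, VI)`` and make the generators return conductance
    arrays (gI positive).

    ``rate_window=(t0, t1)`` restricts the rate statistics to a time window
    (ms); the PSTH always covers the full duration.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    rng = _as_rng(rng_seed)
    streams = rng.spawn(n_trials)

    drives_E = []
    drives_I = []
    for s in streams:
        drives_E.append(np.asarray(exc_barrage_gen(s), dtype=float))
        if inh_barrage_gen is not None:
            drives_I.append(np.asarray(inh_barrage_gen(s), dtype=float))
    n_bins = drives_E[0].shape[-1]
    duration = n_bins * lif.dt

    chunk = max(1, max_chunk_bins // n_bins)
    rasters = []
    for start in range(0, n_trials, chunk):
        stop = min(start + chunk, n_trials)
        gE = np.stack(drives_E[start:stop])
        gI = (
            np.stack(drives_I[start:stop])
            if drives_I
            else np.zeros_like(gE)
        )
        if conductance is not None:
            VE, VI = conductance
            spikes, _ = integrate_lif((gE, VE, gI, VI), lif)
        else:
            spikes, _ = integrate_lif(gE + gI, lif)
        rasters.append(spikes)
    raster = np.concatenate(rasters, axis=0)

    result = _result_from_raster(raster, lif.dt, duration)
    if rate_window is not None:
        k0 = int(round(rate_window[0] / lif.dt))
        k1 = int(round(rate_window[1] / lif.dt))
        counts = raster[:, k0:k1].sum(axis=1)
        rates = counts / ((k1 - k0) * lif.dt) * 1000.0
        result.mean_rate = float(rates.mean())
        result.rate_sd = float(rates.std(ddof=1)) if n_trials > 1 else 0.0
    result.meta["n_trials"] = n_trials
    return result
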