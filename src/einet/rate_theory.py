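"""Analytic input-output theory for the sustained-stimulus regime.

Two firing regimes are combined.  Above rheobase the deterministic LIF
frequency-current relation applies (oscillatory regime); below it, firing is
driven by fluctuations in the number of surviving excitatory inputs within a
membrane integration window, modeled as an exact Poisson tail times the rate
at the oscillatory onset.  The overall prediction is the larger of the two.

The onset rate ``r_rh`` is not pinned down by the reduced model (the pure
LIF rate vanishes at rheobase); the default used here is the oscillatory
rate at 1.05x rheobase, exposed as a parameter.  This is the module's
largest approximation, as is the choice of integration window (tau_m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ei_core import (
    ConstraintError,
    NetworkParams,
    ParameterError,
    ScalingMode,
    compute_effective_pI,
    compute_pnet,
    conductance_correction,
)
from .lif_sim import LIFParams, SynapticKernel, kernel_charge, psp_peak

__all__ = [
    "RatePrediction",
    "rheobase",
    "osc_rate",
    "onset_rate",
    "threshold_count",
    "fluct_rate",
    "resolve_pI_point",
    "predict_io_curve",
    "io_curve_frame",
    "mean_synaptic_conductance",
]


@dataclass(frozen=True)
class RatePrediction:
    """Analytic prediction at one operating point."""

    pE: float
    pI: float
    pnet: float
    i_net: float  # pA (conductance-corrected if requested)
    r_osc: float  # Hz
    r_fluct: float  # Hz
    regime: str  # "oscillatory" | "sub_oscillatory"

    @property
    def r_combined(self) -> float:
        return max(self.r_osc, self.r_fluct)


def rheobase(lif: LIFParams) -> float:
    """Minimum constant current (pA) for sustained firing: (V_theta - V_l)/R."""
    return lif.delta_V / lif.R * 1000.0


def osc_rate(i_net: float, lif: LIFParams) -> float:
    """Deterministic LIF firing rate (Hz) for a constant current drive.

    Zero at or below rheobase; otherwise
    ``1000 / (tau_m * ln(V_inf / (V_inf - delta_V)))`` with
    ``V_inf = i_net * R / 1e3`` the asymptotic depolarization from rest.
    """
    if not math.isfinite(i_net):
        raise ParameterError("i_net must be finite")
    v_inf = i_net * lif.R / 1000.0  # mV above rest
    if v_inf <= lif.delta_V:
        return 0.0
    return 1000.0 / (lif.tau_m * math.log(v_inf / (v_inf - lif.delta_V)))


def onset_rate(lif: LIFParams, margin: float = 1.05) -> float:
    """Default r_rh: oscillatory rate just above rheobase (at margin * irh)."""
    return osc_rate(margin * rheobase(lif), lif)


def threshold_count(lif: LIFParams, epsp_peak_mV: float) -> int:
    """Number of simultaneous unitary EPSPs needed to reach threshold."""
    if epsp_peak_mV <= 0:
        raise ParameterError("EPSP peak must be > 0")
    if epsp_peak_mV >= lif.delta_V:
        raise ParameterError(
            "a single input is suprathreshold; outside the model's assumptions"
        )
    return math.ceil(lif.delta_V / epsp_peak_mV)


def fluct_rate(
    params: NetworkParams,
    lif: LIFParams,
    window: Optional[float] = None,
    r_rh: Optional[float] = None,
    pnet: Optional[float] = None,
    epsp_peak_mV: Optional[float] = None,
    kernel_tau: float = 2.0,
) -> float:
    """Sub-oscillatory rate: ``Pr(X >= n_theta) * r_rh`` (Hz).

    ``X`` is the Poisson count of surviving EPSPs within the integration
    window (default tau_m, the membrane acting as a leaky counter), with
    mean ``nE * pnet * rE * pE_to_R * window / 1000``.  The threshold count
    ``n_theta`` is the number of unitary EPSP peaks spanning the distance to
    threshold.  The exact Poisson tail is used (no normal approximation).
    """
    window = lif.tau_m if window is None else window
    if window <= 0:
        raise ParameterError("window must be > 0")
    r_rh = onset_rate(lif) if r_rh is None else r_rh
    if r_rh < 0:
        raise ParameterError("r_rh must be >= 0")
    if pnet is None:
        pnet = params.pnet()
    if epsp_peak_mV is None:
        epsp_peak_mV = psp_peak(params.aE, kernel_tau, lif)
    n_theta = threshold_count(lif, epsp_peak_mV)
    mu = params.nE * pnet * params.rE * params.pE_to_R * window / 1000.0
    tail = float(stats.poisson.sf(n_theta - 1, mu)) if mu > 0 else 0.0
    return tail * r_rh


def resolve_pI_point(
    pE: float,
    scaling: ScalingMode,
    params: NetworkParams,
    lif: LIFParams,
) -> float:
    """Effective pI at one grid point under a scaling mode (full network
    reading; the recruit mode runs the interneurons' own analytic f-I)."""
    if scaling.mode == "fixed_pI":
        return scaling.pi_fixed
    if scaling.mode == "linear_kc":
        kn = scaling.kc * pE
        return compute_effective_pI(params.pI_hat, kn, params.kq, params.kr, params.kEI)
    # ffwd_recruit: pE_to_I = kp * pE -> interneuron drive follows pE^2
    pE_to_I = min(1.0, scaling.kp * pE)
    drive = pE * pE_to_I * params.nE * params.qE * params.rE
    rI = osc_rate(drive, lif)
    if rI == 0.0:
        return 0.0
    kr = rI / params.rE
    return compute_effective_pI(1.0, params.kn, params.kq, kr, params.kEI)


def mean_synaptic_conductance(
    params: NetworkParams,
    kernel_E: SynapticKernel,
    kernel_I: SynapticKernel,
    pI: Optional[float] = None,
    dt: float = 0.01,
) -> float:
    """Mean total synaptic conductance (nS) of the steady-state barrages.

    Event rate times unitary conductance integral for each pathway;
    excitatory and inhibitory conductances add regardless of sign.
    """
    qg_E = kernel_charge(kernel_E, dt)  # nS*ms
    qg_I = kernel_charge(kernel_I, dt)
    rate_E = params.nE * params.pE * params.pE_to_R * params.rE / 1000.0  # events/ms
    pI = params.effective_pI() if pI is None else pI
    # inhibitory event rate via the pI factorization on the afferent constants
    rate_I = pI * params.pE_to_R * params.nE * params.rE / 1000.0 / max(params.kq, 1e-300) \
        if pI > 0 else 0.0
    return rate_E * qg_E + rate_I * qg_I


def predict_io_curve(
    pE_grid: Sequence[float],
    scaling: ScalingMode,
    params: NetworkParams,
    lif: LIFParams,
    window: Optional[float] = None,
    r_rh: Optional[float] = None,
    conductance_kernels: Optional[tuple] = None,
) -> list:
    """Analytic I-O prediction along a pE grid.

    Per grid point: resolve pI under the scaling mode, form pnet and the
    mean net drive, apply the conductance correction when conductance
    kernels are supplied, and evaluate both regime rates.

    ``conductance_kernels`` is an optional ``(kernel_E, kernel_I)`` pair of
    conductance-mode kernels; the divisive correction then rescales the net
    drive by leak over total conductance, and the EPSP amplitude used for
    the threshold count is the conductance event's driving current at rest.
    """
    out = []
    epsp_amp = params.aE
    if conductance_kernels is not None:
        kE, kI = conductance_kernels
        epsp_amp = kE.amplitude * (kE.V_rev - lif.V_l)
    epsp_mV = psp_peak(epsp_amp, 2.0, lif)
    for pE in np.asarray(pE_grid, dtype=float):
        try:
            pI = resolve_pI_point(pE, scaling, params, lif)
        except ConstraintError as err:
            raise ConstraintError(f"at pE={pE:.4g}: {err}") from err
        pnet = compute_pnet(pE, pI)
        i_net = params.nE * params.qE * params.rE * params.pE_to_R * pnet
        lif_eff = lif
        if conductance_kernels is not None:
            # conductance loading: divisive drive correction together with
            # the conductance-scaled membrane (shorter tau, higher rheobase)
            p_here = params.with_(pE=float(pE))
            g_syn = mean_synaptic_conductance(p_here, kE, kI, pI=pI)
            g_tot = 1000.0 / lif.R + g_syn
            R_eff = 1000.0 / g_tot
            lif_eff = lif.with_(R=R_eff, tau_m=R_eff * lif.C / 1000.0)
            i_net = conductance_correction(i_net, g_syn, lif)
            i_net_for_rate = i_net * g_tot / (1000.0 / lif.R)  # undo divisive part
        else:
            i_net_for_rate = i_net
        r_osc = osc_rate(i_net_for_rate, lif_eff)
        r_fluct = fluct_rate(
            params, lif, window=window, r_rh=r_rh, pnet=pnet, epsp_peak_mV=epsp_mV
        )
        regime = "oscillatory" if r_osc > 0 else "sub_oscillatory"
        out.append(
            RatePrediction(
                pE=float(pE), pI=float(pI), pnet=float(pnet), i_net=float(i_net),
                r_osc=r_osc, r_fluct=r_fluct, regime=regime,
            )
        )
    return out


def io_curve_frame(predictions: Sequence[RatePrediction]) -> pd.DataFrame:
    """Tabulate predictions (CSV-ready)."""
    return pd.DataFrame(
        {
            "pE": [p.pE for p in predictions],
            "pI": [p.pI for p in predictions],
            "pnet": [p.pnet for p in predictions],
            "i_net_pA": [p.i_net for p in predictions],
            "r_osc_Hz": [p.r_osc for p in predictions],
            "r_fluct_Hz": [p.r_fluct for p in predictions],
            "r_combined_Hz": [p.r_combined for p in predictions],
            "regime": [p.regime for p in predictions],
        }
    )
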