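"""Probability algebra of excitatory-inhibitory cancellation in feedforward circuits.

The central quantity is the survival probability of excitation,

    pnet = pE * (1 - pI),

i.e. the probability that an excitatory input both occurs (``pE``) and is not
cancelled by coincident feedforward inhibition (``1 - pI``).  The effective
inhibitory probability ``pI`` folds the relative number, strength, activity
and synaptic reliability of the inhibitory population into a single factor,

    pI = pI_hat * kn * kq * kr * kEI,

so that all mean synaptic currents can be written purely in terms of the
excitatory afferent parameters (``nE``, ``qE``, ``rE``, ``pE_to_R``).

Unit conventions used throughout the package: time in ms, voltage in mV,
current in pA, conductance in nS, capacitance in pF, resistance in MOhm,
charge in pC.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "ConstraintError",
    "NetworkParams",
    "ScalingMode",
    "MeanCurrents",
    "compute_pnet",
    "compute_effective_pI",
    "mean_currents",
    "pnet_curve",
    "conductance_correction",
    "load_network_params",
    "dump_network_params",
]


class ParameterError(ValueError):
    """A parameter is outside its mathematical domain."""


class ConstraintError(ValueError):
    """A derived quantity violates a model constraint (e.g. pI > 1)."""


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must be a probability in [0, 1], got {value!r}")
    return value


def _check_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0.0:
        raise ParameterError(f"{name} must be finite and >= 0, got {value!r}")
    return value


def compute_pnet(pE: float, pI: float) -> float:
    """Survival probability of excitation: ``pE * (1 - pI)``.

    Both arguments must be probabilities; the result is automatically a
    probability, so no rectification is needed here.
    """
    pE = _check_prob("pE", pE)
    pI = _check_prob("pI", pI)
    return pE * (1.0 - pI)


def compute_effective_pI(
    pI_hat: float, kn: float, kq: float, kr: float, kEI: float
) -> float:
    """Effective inhibitory probability ``pI = pI_hat * kn * kq * kr * kEI``.

    Raises
    ------
    ConstraintError
        If the product exceeds 1: the factorization is only interpretable as
        a probability while the product of the ratio constants stays below
        unity.  The offending factors are named in the message.
    """
    pI_hat = _check_prob("pI_hat", pI_hat)
    factors = {"kn": kn, "kq": kq, "kr": kr, "kEI": kEI}
    for name, value in factors.items():
        _check_nonneg(name, value)
    product = pI_hat * kn * kq * kr * kEI
    if product > 1.0:
        big = {k: v for k, v in factors.items() if v > 1.0}
        raise ConstraintError(
            f"effective pI = {product:.6g} exceeds 1; the product "
            f"pI_hat*kn*kq*kr*kEI must stay below unity "
            f"(factors > 1: {big or 'pI_hat-weighted combination'})"
        )
    return product


@dataclass(frozen=True)
class NetworkParams:
    """Feedforward-circuit parameters.

    Field names follow the conventional symbols: ``nE``/``nI`` population
    sizes, ``pE`` afferent activation probability, ``pE_to_R``/``pE_to_I``/
    ``pI_to_R`` synaptic transmission probabilities, ``rE``/``rI`` firing
    rates (Hz), ``aE``/``aI`` unitary PSC peak amplitudes (pA; ``aI <= 0``),
    ``qE``/``qI`` unitary charge transfers (pC; ``qI <= 0``), ``pI_hat``
    the probability that an inhibitory neuron fires during the stimulus.
    """

    nE: int = 250
    nI: int = 50
    pE: float = 0.35
    pE_to_R: float = 1.0
    pE_to_I: float = 1.0
    pI_to_R: float = 1.0
    rE: float = 50.0
    rI: float = 50.0
    aE: float = 10.3
    aI: float = -10.3
    qE: float = 0.0557
    qI: float = -0.0557
    pI_hat: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pE", "pE_to_R", "pE_to_I", "pI_to_R", "pI_hat"):
            _check_prob(name, getattr(self, name))
        for name in ("nE", "nI"):
            value = getattr(self, name)
            if not (isinstance(value, (int, np.integer)) and value >= 1):
                raise ParameterError(f"{name} must be a positive integer, got {value!r}")
        for name in ("rE", "rI"):
            _check_nonneg(name, getattr(self, name))
        if self.qE <= 0:
            raise ParameterError(f"qE must be > 0, got {self.qE!r}")
        if self.aE <= 0:
            raise ParameterError(f"aE must be > 0, got {self.aE!r}")
        if self.aI > 0:
            raise ParameterError(f"aI must be <= 0, got {self.aI!r}")
        if self.qI > 0:
            raise ParameterError(f"qI must be <= 0, got {self.qI!r}")
        if self.pE_to_R > 0:
            # reject parameterizations whose effective pI is not a probability
            self.effective_pI()

    # -- derived ratio constants ------------------------------------------
    @property
    def kn(self) -> float:
        """Inhibitory-to-excitatory input ratio nI/nE."""
        return self.nI / self.nE

    @property
    def kq(self) -> float:
        """Ratio of unitary charge magnitudes |qI/qE|."""
        return abs(self.qI / self.qE)

    @property
    def kr(self) -> float:
        """Inhibitory-to-excitatory rate ratio rI/rE."""
        if self.rE == 0:
            if self.rI == 0:
                return 0.0
            raise ParameterError("kr undefined: rE = 0 while rI > 0")
        return self.rI / self.rE

    @property
    def ka(self) -> float:
        """Ratio of unitary amplitude magnitudes |aI/aE|."""
        return abs(self.aI / self.aE)

    @property
    def kEI(self) -> float:
        """Synaptic efficacy ratio pI_to_R / pE_to_R."""
        if self.pE_to_R == 0:
            raise ParameterError("kEI undefined: pE_to_R = 0")
        return self.pI_to_R / self.pE_to_R

    @property
    def pi_E_to_I(self) -> float:
        """Effective excitatory drive to inhibitory neurons, pE * pE_to_I.

        Stored as a derived quantity, never as independent state.
        """
        return self.pE * self.pE_to_I

    # -- effective probabilities ------------------------------------------
    def effective_pI(self, amplitude_ratio: bool = False) -> float:
        """Effective pI from the ratio product.

        With ``amplitude_ratio=True`` the amplitude ratio ``ka`` replaces the
        charge ratio ``kq`` (appropriate for the transient, single-spike
        regime, where ``kr`` degenerates to 1 unless set otherwise).
        """
        k_strength = self.ka if amplitude_ratio else self.kq
        return compute_effective_pI(self.pI_hat, self.kn, k_strength, self.kr, self.kEI)

    def pnet(self) -> float:
        return compute_pnet(self.pE, self.effective_pI())

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "NetworkParams":
        return cls(**data)

    def with_(self, **kwargs) -> "NetworkParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ScalingMode:
    """How the effective inhibitory probability co-varies with pE.

    Exactly one mode is active:

    - ``fixed_pI``: pI held at ``pi_fixed`` for all pE.
    - ``linear_kc``: inhibition recruited in proportion to excitation.  In
      the reduced (toy) reading pI = kc * pE; in the full network reading the
      input ratio scales as kn = kc * pE and pI follows the ratio product.
    - ``ffwd_recruit``: the afferent-to-interneuron efficacy scales as
      pE_to_I = kp * pE, so interneuron drive (and hence pI) follows the
      interneurons' own input-output curve.
    """

    mode: str = "fixed_pI"
    kc: Optional[float] = None
    kp: Optional[float] = None
    pi_fixed: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_pI", "linear_kc", "ffwd_recruit"):
            raise ParameterError(f"unknown scaling mode {self.mode!r}")
        required = {"fixed_pI": "pi_fixed", "linear_kc": "kc", "ffwd_recruit": "kp"}
        name = required[self.mode]
        if getattr(self, name) is None:
            raise ParameterError(f"mode {self.mode!r} requires {name}")
        others = {"pi_fixed", "kc", "kp"} - {name}
        for other in others:
            if getattr(self, other) is not None:
                raise ParameterError(
                    f"mode {self.mode!r} takes only {name}; {other} must be None"
                )
        if self.mode == "fixed_pI":
            _check_prob("pi_fixed", self.pi_fixed)
        elif self.mode == "linear_kc":
            value = _check_nonneg("kc", self.kc)
            if value > 1.0:
                raise ParameterError(f"kc must lie in [0, 1], got {value!r}")
        else:
            _check_nonneg("kp", self.kp)

    @classmethod
    def fixed(cls, pi_fixed: float) -> "ScalingMode":
        return cls(mode="fixed_pI", pi_fixed=pi_fixed)

    @classmethod
    def linear(cls, kc: float) -> "ScalingMode":
        return cls(mode="linear_kc", kc=kc)

    @classmethod
    def recruit(cls, kp: float) -> "ScalingMode":
        return cls(mode="ffwd_recruit", kp=kp)


@dataclass(frozen=True)
class MeanCurrents:
    """Mean steady-state synaptic currents (pA).

    ``iI_to_R`` is reported as the magnitude of the inhibitory drive;
    ``i_net`` is the conditioned (survival-probability) net drive.
    """

    iE_to_R: float
    iE_to_I: float
    iI_to_R: float
    i_net: float


def mean_currents(params: NetworkParams) -> MeanCurrents:
    """Mean steady-state currents of the feedforward circuit.

    The excitatory drives are rate * charge products; the inhibitory drive
    admits two factorizations (through the inhibitory population, or through
    the effective pI and the excitatory afferent constants) which agree
    exactly by construction of the ratio product.
    """
    p = params
    iE_to_R = p.pE * p.pE_to_R * p.nE * p.qE * p.rE
    iE_to_I = p.pi_E_to_I * p.nE * p.qE * p.rE
    pI = p.effective_pI()
    iI_to_R = p.pI_hat * p.pI_to_R * p.nI * abs(p.qI) * p.rI
    alt = pI * p.pE_to_R * p.nE * p.qE * p.rE
    if not math.isclose(iI_to_R, alt, rel_tol=1e-9, abs_tol=1e-12):
        raise ConstraintError(
            f"inhibitory-current factorizations disagree: {iI_to_R} vs {alt}"
        )
    i_net = p.nE * p.qE * p.rE * p.pE_to_R * compute_pnet(p.pE, pI)
    return MeanCurrents(iE_to_R=iE_to_R, iE_to_I=iE_to_I, iI_to_R=iI_to_R, i_net=i_net)


def resolve_pI(pE: float, scaling: ScalingMode, params: Optional[NetworkParams] = None) -> float:
    """Effective pI at a given pE under a scaling mode.

    Without ``params`` the reduced (toy) reading is used for ``linear_kc``
    (pI = kc * pE).  With ``params`` the full ratio product applies, with
    kn = kc * pE.  ``ffwd_recruit`` needs an interneuron rate model and is
    resolved in :mod:`einet.rate_theory` / :mod:`einet.transient`.
    """
    pE = _check_prob("pE", pE)
    if scaling.mode == "fixed_pI":
        return scaling.pi_fixed
    if scaling.mode == "linear_kc":
        if params is None:
            return scaling.kc * pE
        kn = scaling.kc * pE
        return compute_effective_pI(params.pI_hat, kn, params.kq, params.kr, params.kEI)
    raise ParameterError(
        "ffwd_recruit requires an interneuron rate model; "
        "use rate_theory.predict_io_curve or transient.transient_io_curve"
    )


def pnet_curve(
    pE_grid: Sequence[float],
    scaling: ScalingMode,
    params: Optional[NetworkParams] = None,
) -> np.ndarray:
    """pnet evaluated along a grid of pE values under a scaling mode.

    Fixed mode is linear in pE with slope (1 - pI); linear mode gives
    pE * (1 - kc * pE), which is non-monotonic on [0, 1] iff kc > 0.5 with
    maximum 1/(4 kc) at pE = 1/(2 kc).
    """
    grid = np.asarray(pE_grid, dtype=float)
    if grid.size and (grid.min() < 0 or grid.max() > 1):
        raise ParameterError("pE grid values must lie in [0, 1]")
    return np.array(
        [compute_pnet(pE, resolve_pI(pE, scaling, params)) for pE in grid]
    )


def conductance_correction(
    i_net: float,
    g_syn_mean: float,
    lif,
    strategy: Optional[Callable[[float, float, float], float]] = None,
) -> float:
    """Conductance-dependent adjustment of the mean net drive.

    Default strategy: divisive scaling by the total membrane conductance
    relative to leak, ``i_eff = i_net * g_leak / (g_leak + g_syn_mean)``.
    This is an approximation standing in for the full derivation; an
    alternative form can be supplied via ``strategy(i_net, g_leak, g_syn)``.
    """
    g_syn_mean = float(g_syn_mean)
    if not math.isfinite(g_syn_mean) or g_syn_mean < 0:
        raise ParameterError(f"g_syn_mean must be >= 0, got {g_syn_mean!r}")
    g_leak = 1000.0 / lif.R  # MOhm -> nS
    if strategy is not None:
        return strategy(i_net, g_leak, g_syn_mean)
    return i_net * g_leak / (g_leak + g_syn_mean)


# -- config file round-trip ------------------------------------------------

def dump_network_params(params: NetworkParams, path) -> None:
    """Write parameters as a flat key-value config (JSON or YAML by suffix)."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_network_params(path) -> NetworkParams:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return NetworkParams.from_dict(data)
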