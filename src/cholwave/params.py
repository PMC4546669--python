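"""Parameter containers for the single-cell and synapse models.

All parameters are read from flat key-value config files (YAML); the bundled
default, ``cholwave/data/pyramidal.yaml``, holds the published constants of
the cortical pyramidal-cell model with a slow potassium (M-type) current.
Nothing numerical is hard-coded here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "GateParams",
    "NeuronParams",
    "SynapseParams",
    "load_neuron_params",
    "load_synapse_params",
    "default_config_path",
]

TAU_FLOOR_MS = 0.37  # additive floor of the voltage-dependent time constants


@dataclass(frozen=True)
class GateParams:
    """Constants of one Hodgkin-Huxley gate.

    Steady state is the logistic ``x_inf(V) = 1/(1 + exp((alpha - V)/beta))``.
    The time constant is either fixed (``tau_fixed``, used for the slow
    potassium gate s) or voltage dependent,
    ``tau(V) = 0.37 + D/(1 + exp((gamma + V)/eps))``.
    """

    alpha: float  # half-activation voltage, mV
    beta: float  # slope, mV (negative for inactivation gates)
    gamma: float = 0.0  # mV
    eps: float = 1.0  # mV
    D: float = 0.0  # ms
    tau_fixed: float | None = None  # ms

    def __post_init__(self) -> None:
        if self.beta == 0:
            raise ValueError("gate slope beta must be nonzero")
        if self.D < 0:
            raise ValueError("gate D must be >= 0")
        if self.tau_fixed is not None and self.tau_fixed <= 0:
            raise ValueError("fixed time constant must be positive")

    def steady_state(self, V: float) -> float:
        return 1.0 / (1.0 + math.exp((self.alpha - V) / self.beta))

    def tau(self, V: float) -> float:
        if self.tau_fixed is not None:
            return self.tau_fixed
        return TAU_FLOOR_MS + self.D / (1.0 + math.exp((self.gamma + V) / self.eps))


@dataclass(frozen=True)
class NeuronParams:
    """All single-cell constants of the membrane equation.

    ``gKs_max`` is the cholinergically controlled slow potassium conductance
    (high ACh corresponds to low ``gKs_max``); ``I_tune`` is the direct
    current calibrated so the isolated cell fires at the target rate.
    """

    cm: float  # uF/cm^2
    gNa_max: float  # mS/cm^2
    gKdr_max: float  # mS/cm^2
    gKs_max: float  # mS/cm^2
    gl: float  # mS/cm^2
    ENa: float  # mV
    EK: float  # mV
    El: float  # mV
    I_tune: float  # uA/cm^2
    m: GateParams = field(repr=False, default=None)  # type: ignore[assignment]
    h: GateParams = field(repr=False, default=None)  # type: ignore[assignment]
    n: GateParams = field(repr=False, default=None)  # type: ignore[assignment]
    s: GateParams = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("gNa_max", "gKdr_max", "gKs_max", "gl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.ENa > 0 > self.EK):
            raise ValueError("physiological ordering requires ENa > 0 > EK")
        for g in ("m", "h", "n", "s"):
            if getattr(self, g) is None:
                raise ValueError(f"gate parameters for '{g}' are required")

    def with_gks(self, gKs_max: float, I_tune: float | None = None) -> "NeuronParams":
        """Copy with a new slow-K conductance (and optionally a new I_tune)."""
        return replace(
            self,
            gKs_max=gKs_max,
            I_tune=self.I_tune if I_tune is None else I_tune,
        )

    def with_itune(self, I_tune: float) -> "NeuronParams":
        return replace(self, I_tune=I_tune)


@dataclass(frozen=True)
class SynapseParams:
    """Double-exponential conductance synapse.

    The kernel ``K (exp(-(t - tau_D)/tau_S) - exp(-(t - tau_D)/tau_F))`` is
    zero before the delay ``tau_D`` and normalized by ``K`` so its peak is
    exactly 1: a pulse through a synapse of weight w spans [0, w].
    """

    tau_F: float  # ms, fast (rise) time constant
    tau_S: float  # ms, slow (decay) time constant
    tau_D: float  # ms, axonal/synaptic delay
    E_exc: float  # mV, reversal for excitatory presynaptic cells
    E_inh: float  # mV, reversal for inhibitory presynaptic cells

    def __post_init__(self) -> None:
        if not (self.tau_S > self.tau_F > 0):
            raise ValueError("require tau_S > tau_F > 0")
        if self.tau_D < 0:
            raise ValueError("tau_D must be >= 0")

    @property
    def t_peak(self) -> float:
        """Time after a presynaptic spike at which the kernel peaks (ms)."""
        r = self.tau_S * self.tau_F / (self.tau_S - self.tau_F)
        return self.tau_D + r * math.log(self.tau_S / self.tau_F)

    @property
    def K(self) -> float:
        """Normalization constant giving the kernel a unit peak."""
        tp = self.t_peak - self.tau_D
        return 1.0 / (math.exp(-tp / self.tau_S) - math.exp(-tp / self.tau_F))


def default_config_path() -> Path:
    with resources.as_file(
        resources.files("cholwave").joinpath("data/pyramidal.yaml")
    ) as p:
        return Path(p)


def _read_config(path: str | Path | None) -> dict:
    if path is None:
        text = (
            resources.files("cholwave").joinpath("data/pyramidal.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("parameter config must be a flat mapping")
    return cfg


def load_neuron_params(
    path: str | Path | None = None,
    *,
    gKs_max: float | None = None,
    I_tune: float | None = None,
) -> NeuronParams:
    """Load neuron parameters from a config file (bundled default if None).

    ``gKs_max`` and ``I_tune`` may be overridden, mirroring the command-line
    interface.
    """
    cfg = _read_config(path)
    gates = {
        "m": GateParams(alpha=cfg["alpha_m"], beta=cfg["beta_m"]),
        "h": GateParams(
            alpha=cfg["alpha_h"], beta=cfg["beta_h"],
            gamma=cfg["gamma_h"], eps=cfg["eps_h"], D=cfg["D_h"],
        ),
        "n": GateParams(
            alpha=cfg["alpha_n"], beta=cfg["beta_n"],
            gamma=cfg["gamma_n"], eps=cfg["eps_n"], D=cfg["D_n"],
        ),
        "s": GateParams(alpha=cfg["alpha_s"], beta=cfg["beta_s"], tau_fixed=cfg["tau_s"]),
    }
    return NeuronParams(
        cm=cfg["cm"],
        gNa_max=cfg["gNa_max"],
        gKdr_max=cfg["gKdr_max"],
        gKs_max=cfg["gKs_max"] if gKs_max is None else gKs_max,
        gl=cfg["gl"],
        ENa=cfg["ENa"],
        EK=cfg["EK"],
        El=cfg["El"],
        I_tune=cfg["I_tune"] if I_tune is None else I_tune,
        **gates,
    )


def load_synapse_params(path: str | Path | None = None) -> SynapseParams:
    """Load synapse parameters from a config file (bundled default if None)."""
    cfg = _read_config(path)
    return SynapseParams(
        tau_F=cfg["syn_tau_F"],
        tau_S=cfg["syn_tau_S"],
        tau_D=cfg["syn_tau_D"],
        E_exc=cfg["E_syn_exc"],
        E_inh=cfg["E_syn_inh"],
    )
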