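"""Model parameters.

All neuron, inhibition, plasticity, connectivity and cell-assembly extraction
parameters live here, with the published simulation values as defaults.  Time
constants are denominated in simulation steps; membrane potentials, thresholds
and synaptic weights are in dimensionless model units.  Quantities that the
model family leaves open (stimulus drive, noise bound, inhibition feedback
scales, weight ceiling, connection-kernel densities) are calibration choices
documented in docs/methods.md; they are ordinary config fields like everything
else.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "NeuronParams",
    "GlobalInhibitionParams",
    "PlasticityParams",
    "ConnectivityParams",
    "CAExtractionParams",
    "StimulusParams",
    "ProtocolParams",
    "ExperimentConfig",
    "load_config",
    "save_config",
    "config_hash",
]

#: simulation step length in ms, entering only through the noise amplitude
#: k2 = 2*sqrt(24/dt)
DEFAULT_DT_MS = 0.5


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass
class NeuronParams:
    """Single-cell integration constants (excitatory and inhibitory layers)."""

    tau_exc: float = 2.5        # membrane time constant, excitatory cells [steps]
    tau_inh: float = 5.0        # membrane time constant, inhibitory cells [steps]
    k1: float = 0.01            # total-input rescaling factor
    dt_ms: float = DEFAULT_DT_MS
    thresh: float = 0.18        # spiking threshold
    alpha: float = 7.0          # adaptation strength (threshold elevation)
    tau_adapt: float = 10.0     # adaptation time constant [steps]
    tau_favg: float = 30.0      # firing-rate-estimate time constant [steps]
    noise_bound: float = 0.25   # white noise is uniform on [-noise_bound, +noise_bound]
    local_inhibition_strength: float = 3000.0  # weight of the local inhibitory feedback

    @property
    def k2(self) -> float:
        """Noise amplitude, 2*sqrt(24/dt)."""
        return 2.0 * math.sqrt(24.0 / self.dt_ms)

    def __post_init__(self) -> None:
        for name in ("tau_exc", "tau_inh", "tau_adapt", "tau_favg", "dt_ms", "thresh"):
            _positive(name, getattr(self, name))
        if self.noise_bound < 0 or self.local_inhibition_strength < 0:
            raise ValueError("noise_bound and local_inhibition_strength must be >= 0")


@dataclass
class GlobalInhibitionParams:
    """Area-specific global inhibition (the attention dial)."""

    kG: float = 0.70            # global inhibition strength (0.50 = high attention)
    tau_glob: float = 12.0      # time constant [steps]
    input_scale: float = 12.0   # rescales the per-area spike count fed to the integrator
    baseline_gate_threshold: float = 0.75  # inter-trial readiness level
    gate_areas: tuple[str, ...] = ("V1", "M1_L", "A1", "M1_i", "PF_L", "PB")

    def __post_init__(self) -> None:
        if not 0.0 < self.kG <= 1.0:
            raise ValueError(f"kG must lie in (0, 1], got {self.kG!r}")
        _positive("tau_glob", self.tau_glob)
        _positive("input_scale", self.input_scale)


@dataclass
class PlasticityParams:
    """Discretized Hebbian rule with LTP, homo- and heterosynaptic LTD."""

    theta_pre: float = 0.15     # minimum presynaptic rate for LTP / homosynaptic LTD
    theta_plus: float = 0.15    # upper postsynaptic membrane-potential threshold
    theta_minus: float = 0.14   # lower postsynaptic membrane-potential threshold
    delta: float = 0.0012       # learning increment (+/- Delta)
    w_max: float = 10.0         # weight ceiling [model units]
    learning_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_minus < self.theta_plus:
            raise ValueError("require 0 <= theta_minus < theta_plus")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")
        _positive("w_max", self.w_max)


@dataclass
class ConnectivityParams:
    """Topographic sparse wiring of excitatory synapses and local inhibition.

    Connection probability between cells at Euclidean grid distance d is
    ``p0 * exp(-d^2 / (2 sigma^2))`` inside a square neighborhood window and 0
    outside; the within-area kernel realizes roughly 10% of the candidate
    links, the between-area kernel is denser (assembly ignition across areas
    needs convergence of many afferents).
    """

    within_neighborhood_radius: int = 9   # 19x19 window
    within_gaussian_sigma: float = 4.5
    within_p0: float = 0.28
    between_neighborhood_radius: int = 9  # 19x19 window
    between_gaussian_sigma: float = 9.0
    between_p0: float = 0.85
    inhib_neighborhood_radius: int = 2    # 5x5 pool
    w_init_lo: float = 0.0
    w_init_hi: float = 3.0                # sculpting regime: sizeable random initial weights
    w_max: float = 10.0                   # must match PlasticityParams.w_max

    def __post_init__(self) -> None:
        for name in ("within_p0", "between_p0"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "within_neighborhood_radius",
            "between_neighborhood_radius",
            "inhib_neighborhood_radius",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.w_init_lo <= self.w_init_hi <= self.w_max):
            raise ValueError("require 0 <= w_init_lo <= w_init_hi <= w_max")


@dataclass
class CAExtractionParams:
    """Cell-assembly extraction and word-referent linking criteria."""

    gamma: float = 0.5          # relative firing threshold for CA membership
    probe_steps: int = 16
    linking_fraction: float = 0.10
    noise_off: bool = True      # probes always run noise-free

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        if not 0.0 < self.linking_fraction <= 1.0:
            raise ValueError("linking_fraction must lie in (0, 1]")
        if self.probe_steps < 1:
            raise ValueError("probe_steps must be >= 1")


@dataclass
class StimulusParams:
    """Synthetic input patterns and their drive."""

    pattern_cells: int = 22          # cells per input pattern (~3.5% of 625)
    amplitude: float = 1500.0        # constant supra-threshold drive, V_in units
    static_noise_frac: float = 0.10  # multiplicative jitter, fixed within a trial
    noise_amplitude: float = 200.0   # drive of the variable (uncorrelated) inputs

    def __post_init__(self) -> None:
        if self.pattern_cells < 1:
            raise ValueError("pattern_cells must be >= 1")
        if self.amplitude < 0 or self.noise_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0.0 <= self.static_noise_frac < 1.0:
            raise ValueError("static_noise_frac must lie in [0, 1)")


@dataclass
class ProtocolParams:
    """Trial and experiment bookkeeping."""

    stimulus_steps: int = 16
    relaxation_cap: int = 500        # steps; exceeding it signals runaway activity
    phase1_presentations: int = 3000
    phase2_presentations: int = 100
    n_networks: int = 22             # created; merged networks are excluded later
    n_networks_one_stage: int = 13
    attention_high_kG: float = 0.50
    attention_high_steps: int = 3    # learning steps run at the lowered kG
    one_stage_burn_in: int = 2       # first learning trials excluded from linking

    def __post_init__(self) -> None:
        if self.stimulus_steps < 1 or self.relaxation_cap < 1:
            raise ValueError("stimulus_steps and relaxation_cap must be >= 1")
        if min(self.phase1_presentations, self.phase2_presentations) < 1:
            raise ValueError("presentation counts must be >= 1")
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")


@dataclass
class ExperimentConfig:
    """Aggregate configuration for a full simulated experiment."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    global_inhibition: GlobalInhibitionParams = field(default_factory=GlobalInhibitionParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    ca_extraction: CAExtractionParams = field(default_factory=CAExtractionParams)
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    master_seed: int = 1

    def __post_init__(self) -> None:
        if self.plasticity.w_max != self.connectivity.w_max:
            raise ValueError("plasticity.w_max and connectivity.w_max must agree")

    # -- scale presets ---------------------------------------------------
    def scaled(self, **overrides: Any) -> "ExperimentConfig":
        """Return a copy with protocol-level overrides applied."""
        proto = dataclasses.replace(self.protocol, **overrides)
        return dataclasses.replace(self, protocol=proto)

    @classmethod
    def desk(cls, master_seed: int = 1) -> "ExperimentConfig":
        """Reduced configuration for desk-scale (minutes, not hours) runs."""
        cfg = cls(master_seed=master_seed)
        return cfg.scaled(
            phase1_presentations=300,
            phase2_presentations=50,
            n_networks=2,
            n_networks_one_stage=2,
        )


def _to_dict(cfg: ExperimentConfig) -> dict[str, Any]:
    return dataclasses.asdict(cfg)


def _from_dict(d: dict[str, Any]) -> ExperimentConfig:
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    types = {
        "neuron": NeuronParams,
        "global_inhibition": GlobalInhibitionParams,
        "plasticity": PlasticityParams,
        "connectivity": ConnectivityParams,
        "ca_extraction": CAExtractionParams,
        "stimulus": StimulusParams,
        "protocol": ProtocolParams,
    }
    for key, value in d.items():
        if key in types:
            sub = types[key]
            field_names = {f.name for f in dataclasses.fields(sub)}
            bad = set(value) - field_names
            if bad:
                raise ValueError(f"unknown keys in config section {key!r}: {sorted(bad)}")
            if key == "global_inhibition" and "gate_areas" in value:
                value = dict(value)
                value["gate_areas"] = tuple(value["gate_areas"])
            kwargs[key] = sub(**value)
        else:
            kwargs[key] = value
    return ExperimentConfig(**kwargs)


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    d = _to_dict(cfg)
    d["global_inhibition"]["gate_areas"] = list(d["global_inhibition"]["gate_areas"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_config(path: str | Path) -> ExperimentConfig:
    return _from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(cfg: ExperimentConfig) -> str:
    """Stable short hash identifying a configuration (embedded in outputs)."""
    d = _to_dict(cfg)
    d["global_inhibition"]["gate_areas"] = list(d["global_inhibition"]["gate_areas"])
    blob = json.dumps(d, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
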