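"""Ground-truth compartment decays and pharmacological scenario presets.

The simulator assigns each cellular compartment a multi-exponential NADH
decay: mitochondria carry the (0.5, 2.3) ns lifetime pair, cytoplasm the
(1.0, 3.7) ns pair, lipid droplets a long mono-exponential, and the
background a dim nuisance decay.  Pharmacological scenarios rescale the
compartment amplitudes (concentration / quantum-yield shifts) while leaving
the lifetimes untouched, and declare the direction each derived metric
(MCR, free-to-bound ratio, redox ratio) is expected to move relative to the
untreated control.

Presets ship as YAML data files under ``flim4/synth/presets``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "CompartmentDecay",
    "ScenarioConfig",
    "load_baseline",
    "load_scenario",
    "available_scenarios",
    "apply_scenario",
    "COMPARTMENTS",
]

COMPARTMENTS = ("mitochondria", "cytoplasm", "droplet", "background")
_METRICS = {"MCR", "free_to_bound", "redox"}
_DIRECTIONS = {"up", "down", "flat"}


@dataclass(frozen=True)
class CompartmentDecay:
    """Ground-truth decay of one compartment.

    Amplitudes are pre-IRF photon-rate weights: the steady-state intensity of
    component i is alpha_i * tau_i, so ``brightness`` is the relative photon
    yield of the compartment per unit excitation.
    """

    label: str
    lifetimes_ns: tuple[float, ...]
    amplitudes: tuple[float, ...]

    def __post_init__(self):
        if len(self.lifetimes_ns) != len(self.amplitudes):
            raise ValueError("lifetimes and amplitudes must have equal length")
        if any(t <= 0 for t in self.lifetimes_ns):
            raise ValueError("all lifetimes must be positive")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(self, "lifetimes_ns", tuple(float(t) for t in self.lifetimes_ns))
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))

    @property
    def brightness(self) -> float:
        """Relative steady-state photon yield, sum of alpha_i * tau_i."""
        return sum(a * t for a, t in zip(self.amplitudes, self.lifetimes_ns))

    def scaled(self, factors) -> "CompartmentDecay":
        factors = tuple(float(f) for f in factors)
        if len(factors) != len(self.amplitudes):
            raise ValueError(
                f"scenario must supply one factor per lifetime of '{self.label}' "
                f"(got {len(factors)}, need {len(self.amplitudes)})"
            )
        if any(f <= 0 for f in factors):
            raise ValueError("amplitude factors must be positive")
        return CompartmentDecay(
            label=self.label,
            lifetimes_ns=self.lifetimes_ns,
            amplitudes=tuple(a * f for a, f in zip(self.amplitudes, factors)),
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """A pharmacological perturbation of the baseline decays.

    ``oxidative_activity`` is a declared scalar proxy for the oxygen
    consumption rate of the condition (the simulator makes no attempt to
    model respirometry); it feeds the MCR^-1 trend analysis.
    """

    name: str
    amplitude_factors: dict[str, tuple[float, ...]]
    fad_factor: float = 1.0
    oxidative_activity: float = 1.0
    expected_direction: dict[str, str] = field(default_factory=dict)
    description: str = ""

    def __post_init__(self):
        for metric, direction in self.expected_direction.items():
            if metric not in _METRICS:
                raise ValueError(f"unknown metric '{metric}' in expected_direction")
            if direction not in _DIRECTIONS:
                raise ValueError(f"unknown direction '{direction}' for {metric}")
        if self.fad_factor <= 0:
            raise ValueError("fad_factor must be positive")
        for label, factors in self.amplitude_factors.items():
            if any(f <= 0 for f in factors):
                raise ValueError(f"non-positive factor for compartment '{label}'")


def _preset_path(name: str) -> Path:
    return resources.files("flim4.synth").joinpath("presets", f"{name}.yaml")


def available_scenarios() -> list[str]:
    """Names of the shipped scenario presets."""
    folder = resources.files("flim4.synth").joinpath("presets")
    names = sorted(
        p.name[: -len(".yaml")]
        for p in folder.iterdir()
        if p.name.endswith(".yaml") and p.name != "baseline.yaml"
    )
    return names


def load_baseline(path: str | Path | None = None) -> dict[str, CompartmentDecay]:
    """Load the ground-truth compartment decays (label -> CompartmentDecay)."""
    source = Path(path) if path is not None else _preset_path("baseline")
    data = yaml.safe_load(source.read_text())
    out = {}
    for label, entry in data["compartments"].items():
        out[label] = CompartmentDecay(
            label=label,
            lifetimes_ns=tuple(entry["lifetimes_ns"]),
            amplitudes=tuple(entry["amplitudes"]),
        )
    return out


def load_scenario(name: str | Path) -> ScenarioConfig:
    """Load a scenario preset by name, or from an explicit YAML path."""
    path = Path(name)
    if not path.suffix:
        path = _preset_path(str(name))
    try:
        data = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise KeyError(
            f"unknown scenario '{name}'; available: {available_scenarios()}"
        ) from None
    return ScenarioConfig(
        name=data["name"],
        amplitude_factors={
            label: tuple(factors)
            for label, factors in data["amplitude_factors"].items()
        },
        fad_factor=float(data.get("fad_factor", 1.0)),
        oxidative_activity=float(data.get("oxidative_activity", 1.0)),
        expected_direction=dict(data.get("expected_direction", {})),
        description=data.get("description", ""),
    )


def apply_scenario(baseline, scenario: ScenarioConfig):
    """Rescale baseline compartment amplitudes by the scenario's factors.

    Accepts either a list of :class:`CompartmentDecay` or a label-keyed dict
    and returns the same container type.  Lifetimes are never changed: the
    perturbations model concentration and quantum-yield shifts.
    """
    if isinstance(baseline, dict):
        items = list(baseline.values())
        as_dict = True
    else:
        items = list(baseline)
        as_dict = False
    scaled = []
    for decay in items:
        if decay.label not in scenario.amplitude_factors:
            raise KeyError(
                f"scenario '{scenario.name}' has no factors for "
                f"compartment '{decay.label}'"
            )
        scaled.append(decay.scaled(scenario.amplitude_factors[decay.label]))
    if as_dict:
        return {d.label: d for d in scaled}
    return scaled
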