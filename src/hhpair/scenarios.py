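"""Scenario configuration: parsing, validation, and the built-in registry.

A *scenario* is a complete, serializable description of one experiment:
a neuron parameter block, an initial state, stimulus block(s), an optional
synapse block, a time grid, and (for sweeps) a weight list.  Scenarios are
read from TOML (preferred, comment-friendly) or JSON; unknown keys are
rejected everywhere so typos fail loudly rather than silently falling back
to defaults.

Pair scenarios clone the single ``[neuron]`` block into both the preceding
and posterior roles -- the two-neuron experiments shipped here always use
biophysically identical neurons differing only in stimulus timing.
Heterogeneous pairs remain available programmatically through
:class:`~hhpair.pair_sim.PairConfig`.

The built-in registry embeds the reference experiments: three single-neuron
initial-value cases under a 100 uA/cm^2 x 2 ms pulse, the four synapse-type
comparisons (coupling strength 4, pre pulse at 10 ms, post pulse at 12 ms),
and the coupling-strength sweeps of the simplified synapse.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from .hh_core import NeuronParams, NeuronState, PulseStimulus
from .integrate import TimeGrid
from .pair_sim import PairConfig
from .synapse import SynapseSpec

__all__ = [
    "Scenario",
    "ScenarioError",
    "load_scenario",
    "save_scenario",
    "scenario_from_dict",
    "builtin_fixtures",
    "INITIAL_VALUE_CASES",
]

#: the three reference initial-value cases (V in mV, gates dimensionless)
INITIAL_VALUE_CASES: dict[str, NeuronState] = {
    "case1": NeuronState(-65.0, 0.0, 0.0, 0.0),
    "case2": NeuronState(-65.0, 0.0529, 0.5961, 0.3177),
    "case3": NeuronState(-65.0, 0.1, 0.7, 0.4),
}

#: standard pulse used by every reference experiment
_PULSE = {"amplitude": 100.0, "width": 2.0}


class ScenarioError(ValueError):
    """A scenario file or dict violates the schema."""


@dataclass(frozen=True)
class Scenario:
    """A validated, runnable experiment description."""

    name: str
    kind: str  # "single" | "pair" | "sweep"
    neuron: NeuronParams = field(default_factory=NeuronParams)
    init: NeuronState = field(default_factory=lambda: INITIAL_VALUE_CASES["case2"])
    stimulus: PulseStimulus = field(default_factory=PulseStimulus)
    pre_stimulus: PulseStimulus = field(default_factory=PulseStimulus)
    post_stimulus: PulseStimulus = field(default_factory=PulseStimulus)
    synapse: SynapseSpec = field(default_factory=SynapseSpec)
    grid: TimeGrid = field(default_factory=TimeGrid)
    sweep_weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("single", "pair", "sweep"):
            raise ScenarioError(
                f"scenario kind must be 'single', 'pair' or 'sweep', got {self.kind!r}"
            )
        if self.kind == "sweep" and not self.sweep_weights:
            raise ScenarioError("sweep scenarios need a non-empty 'sweep_weights' list")

    # -- conversion to runnable configurations --------------------------------

    def single_config(self) -> tuple[NeuronParams, NeuronState, PulseStimulus, TimeGrid]:
        if self.kind != "single":
            raise ScenarioError(f"scenario {self.name!r} is not a single-neuron scenario")
        return self.neuron, self.init, self.stimulus, self.grid

    def pair_config(self) -> PairConfig:
        if self.kind not in ("pair", "sweep"):
            raise ScenarioError(f"scenario {self.name!r} is not a pair scenario")
        return PairConfig.identical(
            self.neuron,
            self.init,
            self.pre_stimulus,
            self.post_stimulus,
            self.synapse,
            self.grid,
        )

    def with_grid(self, **kwargs) -> "Scenario":
        return replace(self, grid=replace(self.grid, **kwargs))

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "kind": self.kind,
            "neuron": asdict(self.neuron),
            "init": asdict(self.init),
            "grid": asdict(self.grid),
        }
        if self.kind == "single":
            d["stimulus"] = asdict(self.stimulus)
        else:
            d["pre_stimulus"] = asdict(self.pre_stimulus)
            d["post_stimulus"] = asdict(self.post_stimulus)
            d["synapse"] = asdict(self.synapse)
        if self.kind == "sweep":
            d["sweep_weights"] = list(self.sweep_weights)
        return d


def _build(cls, block: dict, where: str):
    """Construct a dataclass from a dict, rejecting unknown keys."""
    allowed = set(cls.__dataclass_fields__)
    unknown = set(block) - allowed
    if unknown:
        raise ScenarioError(
            f"unknown key(s) {sorted(unknown)} in {where!r}; allowed: {sorted(allowed)}"
        )
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ScenarioError(f"invalid {where!r} block: {exc}") from exc


_TOP_KEYS = {
    "name",
    "kind",
    "neuron",
    "init",
    "stimulus",
    "pre_stimulus",
    "post_stimulus",
    "synapse",
    "grid",
    "sweep_weights",
}


def scenario_from_dict(data: dict, name: str | None = None) -> Scenario:
    """Validate a raw dict (parsed TOML/JSON) into a :class:`Scenario`.

    Missing blocks fall back to the documented defaults (classical neuron
    parameters, case-2 initial state, 50 ms grid at dt = 0.01 ms, zero-delay
    synapse with threshold 0 mV).
    """
    if not isinstance(data, dict) or not data:
        raise ScenarioError("scenario must be a non-empty mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ScenarioError(
            f"unknown top-level key(s) {sorted(unknown)}; allowed: {sorted(_TOP_KEYS)}"
        )
    if "kind" not in data:
        raise ScenarioError("scenario is missing the required 'kind' key")
    kwargs: dict = {
        "name": data.get("name", name or "unnamed"),
        "kind": data["kind"],
    }
    for key, cls in (
        ("neuron", NeuronParams),
        ("init", NeuronState),
        ("stimulus", PulseStimulus),
        ("pre_stimulus", PulseStimulus),
        ("post_stimulus", PulseStimulus),
        ("synapse", SynapseSpec),
        ("grid", TimeGrid),
    ):
        if key in data:
            kwargs[key] = _build(cls, dict(data[key]), key)
    if "sweep_weights" in data:
        try:
            kwargs["sweep_weights"] = tuple(float(w) for w in data["sweep_weights"])
        except (TypeError, ValueError) as exc:
            raise ScenarioError(f"invalid 'sweep_weights': {exc}") from exc
    return Scenario(**kwargs)


def load_scenario(path) -> Scenario:
    """Read a scenario from a ``.toml`` or ``.json`` file."""
    path = Path(path)
    text = path.read_bytes()
    if path.suffix.lower() == ".json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ScenarioError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    else:
        try:
            data = tomllib.loads(text.decode("utf-8"))
        except tomllib.TOMLDecodeError as exc:
            raise ScenarioError(f"{path}: invalid TOML: {exc}") from exc
    if not data:
        raise ScenarioError(f"{path}: empty scenario file")
    return scenario_from_dict(data, name=path.stem)


def save_scenario(scenario: Scenario, path) -> None:
    """Write a scenario as JSON (round-trips through :func:`load_scenario`)."""
    Path(path).write_text(json.dumps(scenario.to_dict(), indent=2) + "\n")


def _single(name: str, case: str, onset: float) -> Scenario:
    return Scenario(
        name=name,
        kind="single",
        init=INITIAL_VALUE_CASES[case],
        stimulus=PulseStimulus(onset=onset, **_PULSE),
    )


def _pair(name: str, synapse: SynapseSpec, kind: str = "pair", weights=()) -> Scenario:
    return Scenario(
        name=name,
        kind=kind,
        init=INITIAL_VALUE_CASES["case2"],
        pre_stimulus=PulseStimulus(onset=10.0, **_PULSE),
        post_stimulus=PulseStimulus(onset=12.0, **_PULSE),
        synapse=synapse,
        sweep_weights=tuple(weights),
    )


def builtin_fixtures() -> dict[str, Scenario]:
    """The named registry of reference experiments.

    Single-neuron runs cover the three initial-value cases (zero gates,
    the self-consistent resting gates, and a deliberately offset set) with
    the pulse at 4 or 15 ms.  Pair runs compare the four coupling kinds at
    strength 4.  The sweep scenarios trace posterior spike timing against
    coupling strength: a fine sweep over [0, 0.8] plus the large weights
    {1, 2, 3} where the posterior response gains a second spike.
    """
    fine = tuple(round(0.05 * i, 2) for i in range(17))  # 0.00 .. 0.80
    reg = {
        "fig3_case1": _single("fig3_case1", "case1", onset=4.0),
        "fig3_case2": _single("fig3_case2", "case2", onset=4.0),
        "table1_case2": _single("table1_case2", "case2", onset=4.0),
        "fig4_case1": _single("fig4_case1", "case1", onset=15.0),
        "fig5_case3": _single("fig5_case3", "case3", onset=15.0),
        "fig6_none": _pair("fig6_none", SynapseSpec("none", 0.0)),
        "fig6_chemical": _pair("fig6_chemical", SynapseSpec("chemical", 4.0)),
        "fig6_electrical": _pair("fig6_electrical", SynapseSpec("electrical", 4.0)),
        "fig6_simplified": _pair("fig6_simplified", SynapseSpec("simplified", 4.0)),
        "fig8_sweep": _pair(
            "fig8_sweep",
            SynapseSpec("simplified", 0.0),
            kind="sweep",
            weights=fine + (1.0, 2.0, 3.0),
        ),
        "fig9_large_weights": _pair(
            "fig9_large_weights",
            SynapseSpec("simplified", 1.0),
            kind="sweep",
            weights=(1.0, 2.0, 3.0),
        ),
    }
    return reg
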