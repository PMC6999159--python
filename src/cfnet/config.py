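"""Run configuration: every tunable constant of the model in one serializable record.

Timing is purely relative; the unit is fixed by normalizing every input rate
vector to an L2 magnitude of one spike per time unit, and all time constants
below are expressed in those units.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

VARIANTS = ("cfn", "no_dopamine", "no_dopamine_homeostasis", "random_weights")

TAU_D_DEFAULT = 200.0 / math.log(2.0)


@dataclass
class RunConfig:
    """All network, plasticity and protocol constants.

    Defaults reproduce the published operating point: tau_mem = 15 time
    units, tau_pre = 200, a 200-unit recognition window closed by five
    output spikes, learning rate 0.01 boosted to 1.0 under dopamine, a
    [0, 0.2] weight cap before L2 normalization, and a dopaminergic unit
    resting at 2.0 with threshold 1.0 whose rise constant 200/ln 2 makes it
    fire exactly 200 time units after a reset when uninhibited.
    """

    variant: str = "cfn"
    n_neurons: int = 32
    input_dim: int = 64

    # LIF output layer
    v_th: float = 13.5
    tau_mem: float = 15.0

    # recognition protocol
    recognize_time: float = 200.0
    recognize_spikes: int = 5
    escalation_factor: float = 1.5
    max_escalation_steps: int = 10

    # STDP
    tau_pre: float = 200.0
    alpha_base: float = 0.01
    alpha_boost: float = 1.0
    w_cap: float = 0.2
    stdp_rule: str = "stabilized"  # or "static_offset"
    static_offset: float = 1.0  # only used by the static-offset rule

    # dopaminergic unit
    tau_d: float = TAU_D_DEFAULT
    dopamine_v_rest: float = 2.0
    dopamine_v_th: float = 1.0
    dopamine_inhibit: float = 2.0
    eta: float = 0.1  # dopaminergic-weight depression fraction per post fire
    kappa: float = 1.0  # stimulation gain multiplier: gain = kappa*v_th/max(d)

    # lateral inhibition
    inhibition: str = "hard"  # "hard" reset-to-zero or "subtractive"
    inhibition_amount: float = 5.0  # subtractive mode only

    # homeostasis baseline
    theta_plus: float = 0.05
    tau_theta: float = 1e5

    # schedule
    scenario: str = "disjoint"
    epochs_per_task: int = 1
    class_order: list[int] | None = None
    seeds: list[int] = field(default_factory=lambda: [0])
    test_fraction: float = 0.2

    # instrumentation
    capture_events: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.scenario not in ("disjoint", "interleaved"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.stdp_rule not in ("stabilized", "static_offset"):
            raise ValueError(f"unknown stdp_rule {self.stdp_rule!r}")
        if self.n_neurons < 1 or self.input_dim < 1:
            raise ValueError("n_neurons and input_dim must be positive")
        for name in ("v_th", "tau_mem", "tau_pre", "tau_d", "recognize_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.dopamine_v_rest > self.dopamine_v_th:
            raise ValueError(
                "dopamine resting potential must exceed its threshold "
                "(self-firing property)"
            )

    @property
    def has_dopamine(self) -> bool:
        return self.variant == "cfn"

    @property
    def has_homeostasis(self) -> bool:
        return self.variant == "no_dopamine_homeostasis"

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)
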