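"""Run configuration: defaults, TOML round trip.

Defaults are the studied state point: SALR constants zeta = 0.05,
lam = 1.5, kappa = 4.0; T* = 0.35; shell width W = 5 sigma (6, 11);
iso level rho_iso = 0.4; bond cutoff r_bond = lam = 1.5.
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .gcmc import MoveMix, RunSchedule
from .model import PotentialParams, ShellGeometry, ThermoState

__all__ = ["AnalysisOptions", "RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class AnalysisOptions:
    cell_edge: float = 0.5
    rho_iso: float = 0.4
    r_bond: float = 1.5


@dataclass
class RunConfig:
    potential: PotentialParams = field(default_factory=PotentialParams)
    shell: ShellGeometry = field(
        default_factory=lambda: ShellGeometry(6.0, 11.0)
    )
    thermo: ThermoState = field(default_factory=ThermoState)
    mix: MoveMix = field(default_factory=MoveMix)
    schedule: RunSchedule = field(default_factory=RunSchedule)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    def to_toml(self) -> str:
        def table(name, obj):
            rows = [f"[{name}]"]
            for k, v in asdict(obj).items():
                if isinstance(v, bool):
                    rows.append(f"{k} = {str(v).lower()}")
                elif isinstance(v, float):
                    rows.append(f"{k} = {v!r}")
                else:
                    rows.append(f"{k} = {v}")
            return "\n".join(rows)

        parts = [
            "# salrshell run configuration; reduced units (sigma, epsilon)",
            table("potential", self.potential),
            table("shell", self.shell),
            table("thermo", self.thermo),
            table("mix", self.mix),
            table("schedule", self.schedule),
            table("analysis", self.analysis),
        ]
        return "\n\n".join(parts) + "\n"


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(config.to_toml())


def load_config(path) -> RunConfig:
    data = tomllib.loads(Path(path).read_text())
    kwargs = {}
    sections = {
        "potential": PotentialParams,
        "shell": ShellGeometry,
        "thermo": ThermoState,
        "mix": MoveMix,
        "schedule": RunSchedule,
        "analysis": AnalysisOptions,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, cls in sections.items():
            if name in data:
                kwargs[name] = cls(**data[name])
    return RunConfig(**kwargs)
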