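"""The serializable unit of work: phantom + array + schedule + configuration."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ectplan.phantom import TissueProperties, default_tissue_table
from ectplan.electrodes import (
    ElectrodeArray,
    NeedleElectrode,
    PulseSchedule,
    ScheduleEntry,
)
from ectplan.solver import SolverConfig


@dataclass
class TreatmentPlan:
    """Electrode array + pulse schedule + tissue/solver configuration.

    The phantom itself is referenced by path (volumes are stored in standard
    image formats, not embedded in the plan file).  All coordinates are
    world mm.
    """

    array: ElectrodeArray
    schedule: PulseSchedule
    tissue_table: dict[int, TissueProperties] = field(default_factory=default_tissue_table)
    solver_config: SolverConfig = field(default_factory=SolverConfig)
    phantom_path: str | None = None
    margin_width_mm: float = 5.0

    def to_dict(self) -> dict:
        return {
            "units": "mm",
            "phantom_path": self.phantom_path,
            "margin_width_mm": float(self.margin_width_mm),
            "insertion_direction": [float(v) for v in self.array.insertion_direction],
            "electrodes": [
                {
                    "id": int(e.id),
                    "entry_mm": list(map(float, e.entry)),
                    "tip_mm": list(map(float, e.tip)),
                    "active_tip_length_mm": float(e.active_tip_length),
                    "radius_mm": float(e.radius),
                }
                for e in self.array
            ],
            "schedule": [
                {
                    "pair": [int(i) for i in s.pair],
                    "voltage_v": float(s.voltage),
                    "n_pulses": int(s.n_pulses),
                    "pulse_duration_us": float(s.pulse_duration_us),
                }
                for s in self.schedule
            ],
            "tissue_table": {
                str(code): asdict(props) for code, props in self.tissue_table.items()
            },
            "solver_config": asdict(self.solver_config),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreatmentPlan":
        array = ElectrodeArray(
            electrodes=[
                NeedleElectrode(
                    id=e["id"],
                    entry=tuple(e["entry_mm"]),
                    tip=tuple(e["tip_mm"]),
                    active_tip_length=e["active_tip_length_mm"],
                    radius=e["radius_mm"],
                )
                for e in d["electrodes"]
            ],
            insertion_direction=tuple(d["insertion_direction"]),
        )
        schedule = PulseSchedule(
            entries=[
                ScheduleEntry(
                    pair=tuple(s["pair"]),
                    voltage=s["voltage_v"],
                    n_pulses=s.get("n_pulses", 8),
                    pulse_duration_us=s.get("pulse_duration_us", 100.0),
                )
                for s in d["schedule"]
            ]
        )
        tissue_table = {
            int(code): TissueProperties(**props)
            for code, props in d.get("tissue_table", {}).items()
        } or default_tissue_table()
        solver_config = SolverConfig(**d.get("solver_config", {}))
        return cls(
            array=array,
            schedule=schedule,
            tissue_table=tissue_table,
            solver_config=solver_config,
            phantom_path=d.get("phantom_path"),
            margin_width_mm=d.get("margin_width_mm", 5.0),
        )

    def save(self, path) -> None:
        """Write the plan as JSON or YAML, by file extension."""
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path) -> "TreatmentPlan":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)
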