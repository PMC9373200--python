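"""Patient-level trial dataset: allocations, stages and outcomes.

Column-oriented container produced by the simulator and consumed by the
analysis engine.  One row per patient; per-randomisation columns hold the
received arm, the allocation mechanism (randomised / not-eligible /
not-consented / scheme-fixed) and, for reduced-eligibility patients, the arm
subset they could have been randomised to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TrialDesign

__all__ = ["TrialData"]


@dataclass
class TrialData:
    design: TrialDesign  # full stage trajectory as realised
    randomisation_ids: list[str]
    patient_id: np.ndarray
    arrival: np.ndarray
    stage: np.ndarray
    assignment: dict[str, np.ndarray]  # rand id -> received arm (object; None possible)
    mechanism: dict[str, np.ndarray]
    eligible_subset: dict[str, list]  # rand id -> per-patient frozenset or None (=all)
    outcome_type: str = "binary"
    event: np.ndarray | None = None  # definitive event indicator
    time_to_event: np.ndarray | None = None  # tte duration (or censoring time)
    outcome_time: np.ndarray | None = None  # calendar time outcome becomes observable
    intermediate: np.ndarray | None = None
    factors: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.patient_id)

    def received(self, arm_id: str) -> np.ndarray:
        """Indicator of receiving an intervention through any mechanism."""
        out = np.zeros(self.n, dtype=bool)
        for rid in self.randomisation_ids:
            out |= self.assignment[rid] == arm_id
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "patient_id": self.patient_id,
            "arrival": self.arrival,
            "stage": self.stage,
        }
        for f, v in self.factors.items():
            cols[f"factor_{f}"] = v
        for rid in self.randomisation_ids:
            cols[f"{rid}_assignment"] = self.assignment[rid]
            cols[f"{rid}_mechanism"] = self.mechanism[rid]
        if self.event is not None:
            cols["event"] = self.event
        if self.time_to_event is not None:
            cols["time_to_event"] = self.time_to_event
        if self.intermediate is not None:
            cols["intermediate"] = self.intermediate
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
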