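"""In-memory containers for one treatment's observations.

A treatment is one (humic-acid level, nominal Cu level) cell of the design:
a 12-h uptake series of tissue concentrations, optionally a depuration
series (clean-water phase), the exposure profile the animals saw, and
optionally replicate survival series from the toxicity test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .toxicokinetics import ExposureProfile

__all__ = ["SurvivalSeries", "TreatmentDataset"]

#: expected columns of a tissue-observation table
TISSUE_COLUMNS = ("time_h", "cint", "replicate")


@dataclass(frozen=True)
class SurvivalSeries:
    """Live counts over time for one replicate container.

    ``times`` are hours from the start of the toxicity test (first entry 0);
    ``n_alive`` the corresponding live counts (first entry = initial number).
    """

    times: np.ndarray
    n_alive: np.ndarray
    replicate: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_alive, dtype=int)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "n_alive", n)
        if len(times) != len(n) or len(times) == 0:
            raise ValueError("times and n_alive must be nonempty, equal length")
        if times[0] != 0:
            raise ValueError("survival series must start at t = 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("survival times must be strictly ascending")
        if np.any(np.diff(n) > 0) or np.any(n < 0):
            raise ValueError("live counts must be nonincreasing and nonnegative")

    @property
    def n0(self) -> int:
        return int(self.n_alive[0])


@dataclass
class TreatmentDataset:
    """All observations for one (HA level, Cu level) treatment.

    ``uptake`` and ``depuration`` are tidy tables with columns
    ``time_h, cint, replicate`` (µg g⁻¹ dry weight, tracer-corrected);
    ``depuration`` may be empty.  Times are hours from exposure start for
    both phases, so depuration observations begin at the exposure end.
    """

    treatment_id: Tuple[float, float]
    uptake: pd.DataFrame
    depuration: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(TISSUE_COLUMNS))
    )
    exposure: ExposureProfile = field(default_factory=lambda: ExposureProfile.constant(0.0))
    survival: List[SurvivalSeries] = field(default_factory=list)
    doc_mg_per_l: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("uptake", "depuration"):
            df = getattr(self, name)
            missing = set(TISSUE_COLUMNS) - set(df.columns)
            if missing:
                raise ValueError(f"{name} table missing columns {sorted(missing)}")
            if len(df) and (df["time_h"] < 0).any():
                raise ValueError(f"{name} observation times must be nonnegative")

    @property
    def ha_level(self) -> float:
        return self.treatment_id[0]

    @property
    def cu_level(self) -> float:
        return self.treatment_id[1]

    @property
    def depuration_start(self) -> float:
        """Hour at which exposure ends (water concentration drops to 0)."""
        bp, vals = self.exposure.breakpoints, self.exposure.values
        for t, v in zip(bp, vals):
            if v == 0.0 and t > 0:
                return t
        if len(self.uptake):
            return float(self.uptake["time_h"].max())
        if len(self.depuration):
            return float(self.depuration["time_h"].min())
        return 0.0

    def pooled_survival(self):
        """Aggregate replicate survival to (times, total_alive, total_n0).

        Replicates must share the observation grid (the design records all
        containers at the same checks).
        """
        if not self.survival:
            raise ValueError("dataset has no survival observations")
        times = self.survival[0].times
        for s in self.survival[1:]:
            if len(s.times) != len(times) or not np.allclose(s.times, times):
                raise ValueError("replicate survival series must share one time grid")
        total = np.sum([s.n_alive for s in self.survival], axis=0)
        n0 = sum(s.n0 for s in self.survival)
        return times, total, n0
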