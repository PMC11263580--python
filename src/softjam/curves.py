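"""Tabular containers for measured or synthetic translocation data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

#: canonical column order of the in-memory table (strict SI)
CURVE_COLUMNS = ("pressure", "concentration", "frequency", "sem", "n_replicates")


@dataclass
class FrequencyCurve:
    """Translocation frequency versus (pressure, concentration).

    Wraps a DataFrame with SI columns ``pressure`` (Pa), ``concentration``
    (1/m^3), ``frequency`` (1/s), ``sem`` (1/s, standard error of the mean)
    and ``n_replicates``.  ``meta`` carries acquisition context: pore
    geometry, side (exit/entry), condition label, and — for synthetic data —
    the generating truth parameters.
    """

    data: pd.DataFrame
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CURVE_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidParameterError(f"FrequencyCurve missing columns: {missing}")
        d = self.data
        if (d["pressure"] <= 0).any():
            raise InvalidParameterError("pressures must be positive")
        if (d["frequency"] < 0).any():
            raise InvalidParameterError("frequencies must be non-negative")
        bad_sem = (d["frequency"] > 0) & ~(d["sem"] > 0)
        if bad_sem.any():
            raise InvalidParameterError(
                "sem must be > 0 wherever frequency > 0 "
                f"(rows {list(d.index[bad_sem])})"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def pressures(self) -> np.ndarray:
        return self.data["pressure"].to_numpy(dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        return self.data["concentration"].to_numpy(dtype=float)

    @property
    def frequencies(self) -> np.ndarray:
        return self.data["frequency"].to_numpy(dtype=float)

    @property
    def sems(self) -> np.ndarray:
        return self.data["sem"].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "FrequencyCurve":
        """Row subset sharing the same metadata."""
        return FrequencyCurve(self.data.loc[mask].reset_index(drop=True), dict(self.meta))

    @classmethod
    def from_arrays(
        cls,
        pressure: np.ndarray,
        concentration: np.ndarray,
        frequency: np.ndarray,
        sem: np.ndarray,
        n_replicates: np.ndarray | int = 1,
        meta: dict[str, Any] | None = None,
    ) -> "FrequencyCurve":
        n = np.broadcast(pressure, concentration, frequency).size
        df = pd.DataFrame(
            {
                "pressure": np.broadcast_to(np.asarray(pressure, float), (n,)),
                "concentration": np.broadcast_to(np.asarray(concentration, float), (n,)),
                "frequency": np.asarray(frequency, float),
                "sem": np.broadcast_to(np.asarray(sem, float), (n,)),
                "n_replicates": np.broadcast_to(np.asarray(n_replicates), (n,)),
            }
        )
        return cls(df, meta or {})
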