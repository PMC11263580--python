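"""CSV reading/writing and structured text fit reports.

Data tables are plain UTF-8 CSV with dot decimals and unit-bearing column
names (``pressure_Pa``, ``concentration_per_mL``, ``frequency_per_s``,
``sem_per_s``, ``n_replicates``), converted to strict SI on read.  Fit
reports are flat, deterministic key-value text with ``[section]`` headers so
they can be parsed back without loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from .curves import FrequencyCurve
from .errors import SchemaError
from .fitting import FitResult
from .units import molar_to_per_m3, per_m3_to_per_ml, per_ml_to_per_m3

#: supported concentration units and their CSV column names
_CONC_COLUMNS = {
    "per_mL": "concentration_per_mL",
    "per_m3": "concentration_per_m3",
    "molar": "concentration_M",
}
_CONC_TO_SI = {
    "per_mL": per_ml_to_per_m3,
    "per_m3": lambda x: x,
    "molar": molar_to_per_m3,
}


def read_frequency_csv(
    path: str | Path, concentration_unit: str = "per_mL"
) -> FrequencyCurve:
    """Read a frequency table into SI, preserving row order.

    Raises :class:`SchemaError` naming any missing column, and a row-level
    error (with line number) for malformed or negative values.
    """
    if concentration_unit not in _CONC_COLUMNS:
        raise SchemaError(
            f"unsupported concentration unit {concentration_unit!r}; "
            f"choose from {sorted(_CONC_COLUMNS)}"
        )
    conc_col = _CONC_COLUMNS[concentration_unit]
    df = pd.read_csv(path)
    required = ["pressure_Pa", conc_col, "frequency_per_s", "sem_per_s", "n_replicates"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    for col in required:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header is line 1
            raise SchemaError(
                f"malformed numeric value {df.loc[df.index[bad][0], col]!r} "
                f"in column {col}, line {row}"
            )
        df[col] = numeric
    neg = df["frequency_per_s"] < 0
    if neg.any():
        row = int(df.index[neg][0]) + 2
        raise SchemaError(f"negative frequency at line {row}")
    si = pd.DataFrame(
        {
            "pressure": df["pressure_Pa"].astype(float),
            "concentration": _CONC_TO_SI[concentration_unit](df[conc_col].astype(float)),
            "frequency": df["frequency_per_s"].astype(float),
            "sem": df["sem_per_s"].astype(float),
            "n_replicates": df["n_replicates"].astype(int),
        }
    )
    meta: dict[str, Any] = {"source": str(path)}
    sidecar = Path(path).with_suffix(Path(path).suffix + ".meta.json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return FrequencyCurve(si, meta)


def write_frequency_csv(
    curve: FrequencyCurve, path: str | Path, sidecar_meta: bool = True
) -> None:
    """Write a curve in the canonical CSV dialect (concentration in /mL).

    Truth parameters and acquisition metadata, when present, go to a JSON
    sidecar next to the CSV.
    """
    out = pd.DataFrame(
        {
            "pressure_Pa": curve.pressures,
            "concentration_per_mL": per_m3_to_per_ml(curve.concentrations),
            "frequency_per_s": curve.frequencies,
            "sem_per_s": curve.sems,
            "n_replicates": curve.data["n_replicates"].to_numpy(),
        }
    )
    # 17 significant digits: float64 round-trips losslessly through text
    out.to_csv(path, index=False, float_format="%.17g")
    if sidecar_meta and curve.meta:
        serialisable = {
            k: v for k, v in curve.meta.items()
            if isinstance(v, (str, int, float, bool, dict, list))
        }
        if serialisable:
            sidecar = Path(path).with_suffix(Path(path).suffix + ".meta.json")
            sidecar.write_text(json.dumps(serialisable, indent=1, sort_keys=True))


def read_clog_csv(path: str | Path) -> pd.DataFrame:
    """Read a clog-transient table with columns ``time_s`` and ``contrast``."""
    df = pd.read_csv(path)
    for col in ("time_s", "contrast"):
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    return df


def _fmt(value: Any) -> str:
    if isinstance(value, float):
        return f"{value:.12e}"
    return str(value)


def write_fit_report(result: FitResult, path: str | Path) -> None:
    """Serialise a fit result as deterministic nested key-value text."""
    lines: list[str] = ["[fit]"]
    lines.append(f"chi2 = {_fmt(result.chi2)}")
    lines.append(f"ndata = {result.ndata}")
    lines.append(f"nvarys = {result.nvarys}")
    lines.append(f"success = {result.success}")
    lines.append(f"seed = {result.seed}")
    if result.tie_break:
        lines.append(f"tie_break = {result.tie_break}")
    for section, mapping in (
        ("estimates", result.estimates),
        ("stderrs", result.stderrs),
        ("fixed", result.fixed),
        ("derived", result.derived),
    ):
        if mapping:
            lines.append(f"[{section}]")
            for key in sorted(mapping):
                lines.append(f"{key} = {_fmt(mapping[key])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fit_report(path: str | Path) -> dict[str, dict[str, Any]]:
    """Parse a fit report back into {section: {key: value}}."""
    sections: dict[str, dict[str, Any]] = {}
    current: dict[str, Any] | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], {})
            continue
        if current is None or "=" not in line:
            raise SchemaError(f"malformed report line: {raw!r}")
        key, _, value = line.partition("=")
        value = value.strip()
        parsed: Any
        try:
            parsed = float(value)
        except ValueError:
            parsed = {"True": True, "False": False, "None": None}.get(value, value)
        current[key.strip()] = parsed
    return sections


@dataclass
class RunConfig:
    """Flat configuration mirroring the CLI flags; CLI values override it."""

    radius_nm: float = 100.0
    length_um: float = 10.0
    viscosity: float = 1.0e-3
    temperature: float = 295.0
    seed: int = 0
    preset: str | None = None
    noise: str = "poisson_counting"
    sigma: float = 0.05
    concentration_unit: str = "per_mL"
    extras: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cfg = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise SchemaError(f"malformed config line: {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if hasattr(cfg, key) and key != "extras":
                current = getattr(cfg, key)
                if isinstance(current, bool):
                    setattr(cfg, key, value.lower() in ("1", "true", "yes"))
                elif isinstance(current, int):
                    setattr(cfg, key, int(value))
                elif isinstance(current, float):
                    setattr(cfg, key, float(value))
                else:
                    setattr(cfg, key, value)
            else:
                cfg.extras[key] = value
        return cfg
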