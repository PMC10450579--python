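"""Tabular and configuration I/O.

CSV dialects (one header line, comma separator, decimal point):

* thermogram:      injection_index, injection_volume_uL, heat_uJ
* titration curve: ligand_total_nM, signal
* synergy grid:    o_nM, a_nM, k_obs  (long format)

Model parameter files are flat key-value YAML documents with the keys
``k_eq, kd_o_active, kd_o_inactive, kd_a_active, kd_a_inactive,
coupling_active, coupling_inactive`` (concentrations in nM, ``inf`` for a
non-binding state).  Column order never matters; unknown keys are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding import ITCThermogram, TitrationCurve
from .linkage import DoubleDrugModel

__all__ = [
    "ParseError",
    "read_thermogram",
    "write_thermogram",
    "read_titration",
    "write_titration",
    "read_model",
    "write_model",
    "write_grid",
    "read_grid",
    "RunConfig",
]


class ParseError(ValueError):
    """A tabular or config file failed validation; the message names the
    offending file, row and column."""


def _load_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing} "
                         f"(found {list(df.columns)})")
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")
    for col in required:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric value in column "
                             f"{col!r}, row {int(bad[0]) + 2}")  # +header+1-based
        df[col] = vals
    return df[list(required)]


def read_thermogram(path, discard_first: bool = True) -> tuple[ITCThermogram, np.ndarray]:
    """Read a thermogram CSV; returns the thermogram and the injection
    volumes (uL), ordered by injection index."""
    df = _load_table(path, ("injection_index", "injection_volume_uL", "heat_uJ"))
    df = df.sort_values("injection_index")
    return (ITCThermogram(df["heat_uJ"].to_numpy(), discard_first=discard_first),
            df["injection_volume_uL"].to_numpy())


def write_thermogram(path, thermogram: ITCThermogram,
                     injection_volumes) -> None:
    pd.DataFrame({
        "injection_index": np.arange(1, len(thermogram) + 1),
        "injection_volume_uL": np.asarray(injection_volumes, dtype=float),
        "heat_uJ": thermogram.heats,
    }).to_csv(path, index=False)


def read_titration(path) -> TitrationCurve:
    df = _load_table(path, ("ligand_total_nM", "signal"))
    x = df["ligand_total_nM"].to_numpy()
    if np.any(np.diff(x) <= 0):
        i = int(np.flatnonzero(np.diff(x) <= 0)[0])
        raise ParseError(f"{path}: ligand_total_nM not strictly increasing "
                         f"at row {i + 3}")
    try:
        return TitrationCurve(x, df["signal"].to_numpy())
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_titration(path, curve: TitrationCurve) -> None:
    pd.DataFrame({"ligand_total_nM": curve.ligand_total,
                  "signal": curve.signal}).to_csv(path, index=False)


def write_grid(path, grid) -> None:
    grid.to_long_frame().to_csv(path, index=False)


def read_grid(path) -> pd.DataFrame:
    return _load_table(path, ("o_nM", "a_nM", "k_obs"))


def read_model(path) -> DoubleDrugModel:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: model file must be a flat key-value document")
    try:
        return DoubleDrugModel.from_dict(doc)
    except (ValueError, KeyError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_model(path, model: DoubleDrugModel) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class RunConfig:
    """Flat declarative run configuration for the CLI.

    Unknown keys are rejected so silent typos cannot change a run; the seed
    is always echoed to the log.
    """

    seed: int = 0
    model_file: str | None = None
    preset: str | None = None
    data_file: str | None = None
    out_dir: str | None = None
    noise_itc_uj: float = 0.0
    noise_fret: float = 0.0
    noise_activity: float = 0.0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        import dataclasses

        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)
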