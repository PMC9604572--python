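"""Domain types, case-file I/O, configuration loading and the packaged reference table.

A *case* is one surgical procedure managed by the closed-loop vasopressor
(CLV) system: systolic and mean arterial pressure (SAP/MAP, mmHg) recorded on
a uniform 20-s grid together with the commanded norepinephrine infusion rate
(µg/min), a pump-active flag and a signal-validity flag.  Case files are plain
CSV with columns ``t_s, sap_mmhg, map_mmhg, rate_ug_min, pump_active, valid``
(booleans stored as 0/1) so that a write → read round trip is bit exact.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Type, TypeVar

import numpy as np
import pandas as pd
import pydantic
import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "CASE_COLUMNS",
    "CaseFormatError",
    "CaseValidationError",
    "ConfigError",
    "TargetBand",
    "ControllerConfig",
    "ScenarioConfig",
    "CaseTimeSeries",
    "band_bounds",
    "read_case",
    "write_case",
    "table2_fixture",
    "load_config",
    "config_sha256",
    "round_half_up",
]

#: Mandatory case-file column order.
CASE_COLUMNS = ["t_s", "sap_mmhg", "map_mmhg", "rate_ug_min", "pump_active", "valid"]

#: Grid tolerance when checking time-stamp uniformity (seconds).
_GRID_ATOL = 1e-6


class CaseFormatError(ValueError):
    """A case file does not conform to the CSV contract (columns, parse)."""


class CaseValidationError(ValueError):
    """A case time series violates a structural invariant (grid, signs)."""


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


def band_bounds(target: float, fraction: float) -> tuple[float, float]:
    """Lower/upper bound of the symmetric percentage target band.

    ``band_bounds(130, 0.10)`` → ``(117.0, 143.0)``: the band used for
    "under / in / above target" classification of SAP samples.

    Parameters
    ----------
    target : float
        Band centre in mmHg, > 0.
    fraction : float
        Half-width as a fraction of target, in (0, 1).
    """
    if target <= 0:
        raise ValueError(f"target must be positive, got {target}")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    return target * (1.0 - fraction), target * (1.0 + fraction)


class TargetBand(BaseModel):
    """SAP target with a ±fraction acceptance band (default 130 mmHg ± 10%)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    target: float = Field(130.0, gt=0.0, description="band centre, mmHg")
    fraction: float = Field(0.10, gt=0.0, lt=1.0, description="half-width fraction")

    @property
    def lower(self) -> float:
        return self.target * (1.0 - self.fraction)

    @property
    def upper(self) -> float:
        return self.target * (1.0 + self.fraction)


class ControllerConfig(BaseModel):
    """Tuning and safety limits of the PID + rules controller.

    The numeric defaults are this package's own tuning (chosen so the closed
    loop adjusts its rate a few times per minute, comparable to clinical
    observation); they are configurable and carry no claim of matching any
    deployed device.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    kp: float = Field(0.1, ge=0.0, description="proportional gain, µg/min per mmHg")
    ki: float = Field(0.01, ge=0.0, description="integral gain, µg/min per mmHg·s")
    kd: float = Field(0.0, ge=0.0, description="derivative gain, µg/min·s per mmHg")
    dt_control: float = Field(10.0, gt=0.0, description="controller cycle, s")
    rate_max: float = Field(80.0, gt=0.0, description="absolute rate ceiling, µg/min")
    step_up_max: float = Field(2.0, gt=0.0, description="max rate increase per cycle, µg/min")
    step_down_max: float = Field(4.0, gt=0.0, description="max rate decrease per cycle, µg/min")
    band: TargetBand = Field(default_factory=TargetBand)
    hold_on_invalid: bool = Field(True, description="freeze rate on invalid signal")
    rate_epsilon: float = Field(0.05, ge=0.0, description="µg/min threshold counting a rate modification")


class ScenarioConfig(BaseModel):
    """A reproducible cohort simulation scenario (YAML-loadable)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    n_cases: int = Field(12, ge=1)
    duration_s: float = Field(14400.0, gt=0.0, description="case length, s (default 4 h)")
    seed: int = Field(0, ge=0)
    disturbance_rate_per_h: float = Field(2.0, ge=0.0, description="Poisson intensity of hypotensive insults")
    controller: ControllerConfig = Field(default_factory=ControllerConfig)


@dataclass(eq=False)
class CaseTimeSeries:
    """Uniformly sampled record of one closed-loop managed case.

    Attributes are parallel numpy arrays on a strictly increasing uniform
    time grid (``dt_record`` seconds apart, t = 0 at controller start).
    ``valid`` marks samples with trustworthy arterial-line signal; metric
    denominators exclude invalid samples but the clock keeps running.
    """

    t: np.ndarray
    sap: np.ndarray
    map: np.ndarray
    rate: np.ndarray
    pump_active: np.ndarray
    valid: np.ndarray
    case_id: str = "case"
    dt_record: float = 20.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.sap = np.asarray(self.sap, dtype=float)
        self.map = np.asarray(self.map, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.pump_active = np.asarray(self.pump_active, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n = len(self.t)
        for name in ("sap", "map", "rate", "pump_active", "valid"):
            if len(getattr(self, name)) != n:
                raise CaseValidationError(f"column '{name}' length mismatch")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise CaseValidationError("time stamps must be strictly increasing")
            if np.any(np.abs(dt - self.dt_record) > _GRID_ATOL):
                raise CaseValidationError(
                    f"time grid not uniform on dt_record={self.dt_record} s"
                )
        if np.any(self.rate < 0):
            raise CaseValidationError("infusion rate must be non-negative")
        v = self.valid
        if np.any(self.sap[v] <= 0) or np.any(self.map[v] <= 0):
            raise CaseValidationError("valid pressures must be positive")
        if np.any(self.map[v] >= self.sap[v]):
            raise CaseValidationError("MAP must be below SAP at valid samples")

    def __len__(self) -> int:
        return len(self.t)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CaseTimeSeries):
            return NotImplemented
        return (
            self.case_id == other.case_id
            and self.dt_record == other.dt_record
            and all(
                np.array_equal(getattr(self, c), getattr(other, c))
                for c in ("t", "sap", "map", "rate", "pump_active", "valid")
            )
        )

    @property
    def duration_s(self) -> float:
        """Case duration: each sample owns one recording interval."""
        return len(self) * self.dt_record

    @property
    def span_s(self) -> float:
        """Elapsed time between first and last sample."""
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    # -- frame conversion ------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "sap_mmhg": self.sap,
                "map_mmhg": self.map,
                "rate_ug_min": self.rate,
                "pump_active": self.pump_active.astype(int),
                "valid": self.valid.astype(int),
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, case_id: str = "case", dt_record: float | None = None
    ) -> "CaseTimeSeries":
        missing = [c for c in CASE_COLUMNS if c not in frame.columns]
        if missing:
            raise CaseFormatError(f"missing required column(s): {', '.join(missing)}")
        t = frame["t_s"].to_numpy(dtype=float)
        if dt_record is None:
            dt_record = float(np.median(np.diff(t))) if len(t) >= 2 else 20.0
        return cls(
            t=t,
            sap=frame["sap_mmhg"].to_numpy(dtype=float),
            map=frame["map_mmhg"].to_numpy(dtype=float),
            rate=frame["rate_ug_min"].to_numpy(dtype=float),
            pump_active=frame["pump_active"].to_numpy().astype(bool),
            valid=frame["valid"].to_numpy().astype(bool),
            case_id=case_id,
            dt_record=dt_record,
        )


def read_case(path: str | Path) -> CaseTimeSeries:
    """Read a case CSV, validating the column set and the uniform time grid."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as err:  # malformed CSV
        raise CaseFormatError(f"cannot parse case file {path}: {err}") from err
    return CaseTimeSeries.from_frame(frame, case_id=path.stem)


def write_case(series: CaseTimeSeries, path: str | Path) -> None:
    """Write a case CSV (full float precision; shortest round-trip repr)."""
    series.validate()
    series.to_frame().to_csv(path, index=False)


def table2_fixture() -> pd.DataFrame:
    """The packaged 12-case clinical performance table.

    One row per case: band-time percentages (under/in/over a 117–143 mmHg SAP
    band), % case time MAP < 65 mmHg, % case time the loop was administering
    vasopressor, rate changes per minute, total norepinephrine dose (µg) and
    mean rate (µg/min), exactly as published for the 12-patient feasibility
    cohort.
    """
    with resources.files("clvsim.data").joinpath("table2.csv").open("r") as fh:
        return pd.read_csv(fh)


M = TypeVar("M", bound=BaseModel)


def load_config(path: str | Path, model: Type[M]) -> M:
    """Load a YAML config file into a pydantic schema.

    Unknown keys are rejected (``extra='forbid'``) and the offending key is
    named in the raised :class:`ConfigError`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return model.model_validate(data)
    except pydantic.ValidationError as err:
        raise ConfigError(f"{path}: {err}") from err


def config_sha256(cfg: BaseModel) -> str:
    """Stable hash of a config snapshot, for run manifests and logs."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero on the decimal grid (presentation only).

    Needed because the published summary rows round 92.35 → 92.4 and
    4.65 → 4.7, which banker's rounding would not reproduce.
    """
    scale = 10.0**ndigits
    return float(np.floor(np.abs(x) * scale + 0.5) / scale * np.sign(x)) if x else 0.0
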