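"""Shared domain types and unit conversions.

Concentrations are carried as %ID/cc (percent of injected dose per cubic
centimetre of tissue, decay-corrected) unless explicitly converted to
µg/mL.  Tissue density is taken as 1 g/cc, the usual small-animal PET
convention, so %ID/cc and %ID/g are interchangeable and influx clearances
in mL/h/g apply directly to per-cc concentrations.

Time is in hours with t = 0 at radioligand injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "Dosing",
    "PlasmaParams",
    "TissueParams",
    "SubjectDataset",
    "BLOOD_TO_PLASMA_RATIO",
    "pid_cc_to_conc",
    "conc_to_pid_cc",
    "blood_to_plasma",
    "read_tac_csv",
    "write_tac_csv",
]

#: Whole-blood to plasma concentration ratio for IgG (antibodies are
#: restricted to the serum; red cells dilute the signal).
BLOOD_TO_PLASMA_RATIO = 0.55


class InvalidDosingError(ValueError):
    """Raised when dosing metadata is non-positive or inconsistent."""


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, non-overlapping PET frame intervals in hours."""

    start: np.ndarray
    end: np.ndarray

    def __init__(self, start: Sequence[float], end: Sequence[float]):
        start = np.asarray(start, dtype=float)
        end = np.asarray(end, dtype=float)
        if start.shape != end.shape or start.ndim != 1:
            raise ValueError("start/end must be 1-D arrays of equal length")
        if not np.all(end > start):
            raise ValueError("every frame must satisfy end > start")
        if not np.all(start[1:] >= end[:-1] - 1e-12):
            raise ValueError("frames must be sorted and non-overlapping")
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)

    def __len__(self) -> int:
        return len(self.start)

    @property
    def mid(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @property
    def duration(self) -> np.ndarray:
        return self.end - self.start


@dataclass(frozen=True)
class TimeActivityCurve:
    """One region's activity-concentration curve in %ID/cc."""

    region: str
    schedule: FrameSchedule
    value: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self):
        value = np.asarray(self.value, dtype=float)
        if value.shape != (len(self.schedule),):
            raise ValueError("value length must match schedule")
        if not np.all(np.isfinite(value)) or np.any(value < 0):
            raise ValueError("values must be finite and non-negative")
        object.__setattr__(self, "value", value)
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            if sd.shape != value.shape or np.any(sd < 0):
                raise ValueError("sd must match value length and be >= 0")
            object.__setattr__(self, "sd", sd)

    def with_values(self, value: np.ndarray) -> "TimeActivityCurve":
        return TimeActivityCurve(self.region, self.schedule, value, self.sd)


@dataclass(frozen=True)
class Dosing:
    """Injected activity and specific activity, with the derived protein dose.

    protein_dose [µg] = injected_activity / specific_activity × molar_mass,
    with molar_mass defaulting to 150 µg/nmol for intact IgG.
    """

    injected_activity: float  # MBq
    specific_activity: float  # MBq/nmol
    molar_mass: float = 150.0  # µg/nmol

    def __post_init__(self):
        if (
            self.injected_activity <= 0
            or self.specific_activity <= 0
            or self.molar_mass <= 0
        ):
            raise InvalidDosingError("dosing quantities must be strictly positive")

    @property
    def protein_dose(self) -> float:
        """Injected protein mass in µg."""
        return self.injected_activity / self.specific_activity * self.molar_mass


@dataclass(frozen=True)
class PlasmaParams:
    """Micro-constants of the bicompartmental plasma model.

    Vc [mL] central volume; k10 [1/h] first-order elimination from the
    central compartment; k12/k21 [1/h] central<->peripheral exchange.
    The hybrid rates alpha >= beta are the roots of
    lambda^2 - (k10+k12+k21) lambda + k10*k21 = 0.
    """

    Vc: float
    k10: float
    k12: float
    k21: float

    def __post_init__(self):
        if self.Vc <= 0 or self.k10 <= 0 or self.k12 < 0 or self.k21 < 0:
            raise ValueError("Vc and k10 must be > 0; k12, k21 >= 0")

    @property
    def hybrid_rates(self) -> tuple[float, float]:
        """(alpha, beta) with alpha >= beta > 0."""
        s = self.k10 + self.k12 + self.k21
        p = self.k10 * self.k21
        disc = max(s * s - 4.0 * p, 0.0)
        root = np.sqrt(disc)
        alpha = 0.5 * (s + root)
        beta = 0.5 * (s - root)
        if beta <= 0.0:  # k21 == 0: monoexponential limit
            beta = 0.0
        return alpha, beta

    @property
    def Vp(self) -> float:
        """Peripheral distribution volume Vc*k12/k21 [mL]."""
        if self.k21 == 0:
            return float("nan")
        return self.Vc * self.k12 / self.k21


@dataclass(frozen=True)
class TissueParams:
    """Parameters of the transient-permeability tissue models.

    While the ultrasound-opened barrier persists (t <= t_FUS) the plasma
    to tissue entry clearance is K_FUS [mL/h/g]; afterwards it is K1.
    k2 [1/h] is tissue-to-plasma efflux, vB the fractional blood volume.
    k3/k4 [1/h] exchange with the specifically bound compartment and are
    zero for the one-tissue model.
    """

    K_FUS: float
    t_FUS: float
    K1: float
    k2: float
    vB: float
    k3: float = 0.0
    k4: float = 0.0

    def __post_init__(self):
        vals = (self.K_FUS, self.t_FUS, self.K1, self.k2, self.vB, self.k3, self.k4)
        if any(v < 0 for v in vals):
            raise ValueError("all tissue parameters must be >= 0")
        if not (0 <= self.vB < 1):
            raise ValueError("vB must lie in [0, 1)")

    @property
    def is_two_tissue(self) -> bool:
        return self.k3 > 0 or self.k4 > 0


@dataclass(frozen=True)
class SubjectDataset:
    """Blood and regional TACs plus dosing metadata for one animal."""

    subject_id: str
    dosing: Dosing
    fus_applied: bool
    blood_tac: TimeActivityCurve
    region_tacs: Mapping[str, TimeActivityCurve]
    fus_to_injection_delay: float = 1.7  # minutes
    true_params: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        for region, tac in self.region_tacs.items():
            if tac.region != region:
                raise ValueError(f"region key {region!r} != TAC label {tac.region!r}")


def pid_cc_to_conc(value, dosing: Dosing):
    """Convert %ID/cc to µg/mL via the injected protein dose (density 1 g/cc)."""
    return np.asarray(value, dtype=float) / 100.0 * dosing.protein_dose


def conc_to_pid_cc(conc, dosing: Dosing):
    """Inverse of :func:`pid_cc_to_conc`."""
    return np.asarray(conc, dtype=float) * 100.0 / dosing.protein_dose


def blood_to_plasma(blood: TimeActivityCurve) -> TimeActivityCurve:
    """Whole-blood curve -> plasma curve (divide by the 0.55 blood:plasma ratio)."""
    plasma = blood.value / BLOOD_TO_PLASMA_RATIO
    sd = None if blood.sd is None else blood.sd / BLOOD_TO_PLASMA_RATIO
    return TimeActivityCurve(blood.region, blood.schedule, plasma, sd)


def read_tac_csv(path) -> dict[str, TimeActivityCurve]:
    """Read TACs from a delimited text table.

    Columns: region, t_start_h, t_end_h, value_pid_cc, optionally sd_pid_cc.
    Returns one TimeActivityCurve per region label.
    """
    df = pd.read_csv(path)
    required = {"region", "t_start_h", "t_end_h", "value_pid_cc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TAC table missing columns: {sorted(missing)}")
    out: dict[str, TimeActivityCurve] = {}
    for region, grp in df.groupby("region", sort=False):
        grp = grp.sort_values("t_start_h")
        sched = FrameSchedule(grp["t_start_h"].to_numpy(), grp["t_end_h"].to_numpy())
        sd = grp["sd_pid_cc"].to_numpy() if "sd_pid_cc" in grp.columns else None
        out[str(region)] = TimeActivityCurve(str(region), sched, grp["value_pid_cc"].to_numpy(), sd)
    return out


def write_tac_csv(path, tacs: Mapping[str, TimeActivityCurve]) -> None:
    rows = []
    for region, tac in tacs.items():
        for i in range(len(tac.schedule)):
            row = {
                "region": region,
                "t_start_h": tac.schedule.start[i],
                "t_end_h": tac.schedule.end[i],
                "value_pid_cc": tac.value[i],
            }
            if tac.sd is not None:
                row["sd_pid_cc"] = tac.sd[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
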