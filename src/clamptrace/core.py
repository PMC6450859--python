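"""Domain model for two-stage hyperinsulinaemic-euglycaemic clamp studies.

The objects here carry a single subject's anthropometry, the infusion
protocol, and the irregularly sampled clamp time series, in the units the
bedside instruments report: plasma glucose in mmol/l, serum insulin in
pmol/l, NEFA in mmol/l, glycerol in umol/l, tracer enrichment as a
dimensionless tracer-to-tracee ratio (TTR), and pump rates in
mg glucose per kg body weight per minute. Turnover outputs downstream are
umol.kg-1.min-1 throughout, except the whole-body M value which stays in
mg.kg-1.min-1 by convention.

Time is measured in minutes relative to the start of the insulin infusion
(t = 0); the tracer equilibration (basal) period begins at t = -120.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Group",
    "Subject",
    "ClampProtocol",
    "GIRProfile",
    "SampleSeries",
    "KineticsResult",
    "UnitContext",
    "compute_bsa",
    "GLUCOSE_MW",
    "GLYCEROL_MW",
    "SAMPLING_SCHEDULE",
    "default_protocol",
]

#: Molecular masses (g/mol) used for all mass <-> mole bridges.
GLUCOSE_MW = 180.16
GLYCEROL_MW = 92.09

#: The study's blood-sampling schedule, minutes relative to insulin start.
SAMPLING_SCHEDULE = (
    -30.0, -20.0, -10.0, 0.0,
    30.0, 60.0, 90.0, 100.0, 110.0, 120.0,
    150.0, 180.0, 210.0, 220.0, 230.0, 240.0,
)


class Group(str, enum.Enum):
    """Study arm: black (West) African men or white European men."""

    BAM = "BAM"
    WEM = "WEM"


def compute_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) by the Mosteller formula.

    BSA = sqrt(height[cm] * weight[kg] / 3600).

    Raises
    ------
    ValueError
        If height or weight is not strictly positive.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError(
            f"height and weight must be positive, got height={height_cm}, "
            f"weight={weight_kg}"
        )
    return math.sqrt(height_cm * weight_kg / 3600.0)


@dataclass(frozen=True)
class Subject:
    """A study participant.

    Optional body-composition covariates (MRI-derived masses, kg) are None
    when missing -- never silently zero, so complete-case statistics can
    find them.
    """

    id: str
    group: Group
    weight_kg: float
    height_cm: float
    vat_kg: float | None = None
    sat_kg: float | None = None
    muscle_kg: float | None = None

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError(f"subject {self.id}: weight must be > 0")
        if self.height_cm <= 0:
            raise ValueError(f"subject {self.id}: height must be > 0")
        if not isinstance(self.group, Group):
            object.__setattr__(self, "group", Group(self.group))

    @property
    def bsa_m2(self) -> float:
        """Mosteller body surface area, m^2 (derived, never stored)."""
        return compute_bsa(self.height_cm, self.weight_kg)


@dataclass(frozen=True)
class ClampProtocol:
    """Infusion protocol constants for the two-stage clamp.

    Defaults are the study protocol: primed (2.0 mg/kg) continuous
    (0.02 mg.kg-1.min-1) D2-glucose and primed (0.12 mg/kg) continuous
    (0.0067 mg.kg-1.min-1) D5-glycerol tracers started at t = -120 min;
    insulin at 10 then 40 mU.m-2(BSA).min-1 for stages 1 (0-120 min) and
    2 (120-240 min); variable 20% dextrose spiked with glucose tracer at
    8 mg tracer per g glucose during stage 1 and 10 mg/g during stage 2
    so the plasma TTR stays near constant; euglycaemic target 5 mmol/l;
    Steele distribution volume 22% of body weight.
    """

    glucose_tracer_prime_mg_kg: float = 2.0
    glucose_tracer_rate_mg_kg_min: float = 0.02
    glycerol_tracer_prime_mg_kg: float = 0.12
    glycerol_tracer_rate_mg_kg_min: float = 0.0067
    insulin_rate_low_mU_m2_min: float = 10.0
    insulin_rate_high_mU_m2_min: float = 40.0
    infusate_enrichment_low_mg_g: float = 8.0
    infusate_enrichment_high_mg_g: float = 10.0
    v_frac: float = 0.22
    glycaemic_target_mmol_l: float = 5.0
    basal_start_min: float = -120.0
    stage1_start_min: float = 0.0
    stage2_start_min: float = 120.0
    clamp_end_min: float = 240.0
    basal_window: tuple[float, float] = (-30.0, 0.0)
    low_window: tuple[float, float] = (90.0, 120.0)
    high_window: tuple[float, float] = (210.0, 240.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.v_frac < 1.0:
            raise ValueError(f"v_frac must lie in (0, 1), got {self.v_frac}")
        windows = {
            "basal_window": (self.basal_window, (self.basal_start_min, self.stage1_start_min)),
            "low_window": (self.low_window, (self.stage1_start_min, self.stage2_start_min)),
            "high_window": (self.high_window, (self.stage2_start_min, self.clamp_end_min)),
        }
        for name, (win, stage) in windows.items():
            a, b = win
            if not (stage[0] <= a < b <= stage[1]):
                raise ValueError(
                    f"{name} {win} must lie inside its stage {stage}"
                )

    def stage_of(self, t: float) -> int:
        """0 = basal, 1 = low-dose stage, 2 = high-dose stage."""
        if t < self.stage1_start_min:
            return 0
        if t < self.stage2_start_min:
            return 1
        return 2

    def infusate_enrichment_at(self, t: float) -> float:
        """Tracer spiking of the dextrose infusate (mg tracer / g glucose) at t."""
        stage = self.stage_of(t)
        if stage == 0:
            return 0.0
        if stage == 1:
            return self.infusate_enrichment_low_mg_g
        return self.infusate_enrichment_high_mg_g


def default_protocol() -> ClampProtocol:
    """The study's protocol with all printed constants."""
    return ClampProtocol()


class UnitContext:
    """Unit bridge for one subject: distribution volume and mass/mole moves.

    The Steele distribution volume V is expressed in ml per kg body weight
    so that V * C (C in mmol/l == umol/ml) lands directly in umol/kg.
    """

    def __init__(self, weight_kg: float, v_frac: float = 0.22) -> None:
        if weight_kg <= 0:
            raise ValueError("weight must be > 0")
        if not 0.0 < v_frac < 1.0:
            raise ValueError("v_frac must lie in (0, 1)")
        self.weight_kg = weight_kg
        self.v_frac = v_frac

    @property
    def v_ml_per_kg(self) -> float:
        """Distribution volume, ml per kg body weight (1 kg BW ~ 1000 ml)."""
        return self.v_frac * 1000.0

    @staticmethod
    def mg_to_umol(mg: float, mw: float) -> float:
        """Milligrams of analyte to micromoles (mw in g/mol)."""
        return mg * 1000.0 / mw

    @staticmethod
    def umol_to_mg(umol: float, mw: float) -> float:
        return umol * mw / 1000.0

    @staticmethod
    def mg_glucose_to_umol(mg: float) -> float:
        return mg * 1000.0 / GLUCOSE_MW

    @staticmethod
    def mg_glycerol_to_umol(mg: float) -> float:
        return mg * 1000.0 / GLYCEROL_MW


class GIRProfile:
    """Piecewise-constant record of the variable dextrose infusion.

    The bedside pump rate (mg glucose.kg-1.min-1) is adjusted at discrete
    times; between adjustments it is constant, so window means integrate
    the step function exactly.
    """

    def __init__(self, times_min: Sequence[float], rates_mg_kg_min: Sequence[float]) -> None:
        t = np.asarray(times_min, dtype=float)
        r = np.asarray(rates_mg_kg_min, dtype=float)
        if t.ndim != 1 or t.shape != r.shape:
            raise ValueError("times and rates must be 1-D and equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("GIR record times must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("GIR rates must be non-negative")
        self.times = t
        self.rates = r

    def __len__(self) -> int:
        return int(self.times.size)

    def rate_at(self, t: float | np.ndarray) -> np.ndarray | float:
        """Pump rate in force at time t (zero before the first record)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.rates[np.clip(idx, 0, None)], 0.0)
        return float(out) if out.ndim == 0 else out

    def window_mean(self, start: float, end: float) -> float:
        """Exact time-average of the step function over [start, end]."""
        if end <= start:
            raise ValueError("window must have positive width")
        edges = np.concatenate([[start], self.times[(self.times > start) & (self.times < end)], [end]])
        mids = 0.5 * (edges[:-1] + edges[1:])
        vals = np.asarray(self.rate_at(mids), dtype=float)
        return float(np.sum(vals * np.diff(edges)) / (end - start))


# Measurement channels of a clamp series, in CSV column order.
CHANNELS = (
    "glucose_mmol_l",
    "insulin_pmol_l",
    "nefa_mmol_l",
    "glucose_ttr",
    "glycerol_umol_l",
    "glycerol_ttr",
)


@dataclass
class SampleSeries:
    """Irregularly sampled clamp measurements for one subject.

    Channel arrays are aligned with ``t_min``; missing samples are NaN.
    The dextrose record is kept separately as a step function because the
    pump changes between blood draws.
    """

    t_min: np.ndarray
    glucose_mmol_l: np.ndarray
    insulin_pmol_l: np.ndarray
    nefa_mmol_l: np.ndarray
    glucose_ttr: np.ndarray
    glycerol_umol_l: np.ndarray
    glycerol_ttr: np.ndarray
    gir: GIRProfile = field(default_factory=lambda: GIRProfile([], []))

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        if self.t_min.ndim != 1:
            raise ValueError("t_min must be a 1-D vector")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError("sample times must be strictly increasing")
        for name in CHANNELS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t_min.shape:
                raise ValueError(f"channel {name} length mismatch with t_min")
            finite = arr[np.isfinite(arr)]
            if np.any(finite < 0):
                raise ValueError(f"channel {name} has negative values")
            setattr(self, name, arr)

    def channel(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(t, y) with missing samples dropped."""
        y = getattr(self, name)
        ok = np.isfinite(y)
        return self.t_min[ok], y[ok]

    def n_in_window(self, name: str, window: tuple[float, float]) -> int:
        t, _ = self.channel(name)
        return int(np.sum((t >= window[0]) & (t <= window[1])))

    def window_mean(self, name: str, window: tuple[float, float]) -> float:
        """Mean of the non-missing samples of a channel inside [a, b]."""
        t, y = self.channel(name)
        m = (t >= window[0]) & (t <= window[1])
        if m.sum() == 0:
            raise ValueError(f"no {name} samples in window {window}")
        return float(np.mean(y[m]))


@dataclass
class KineticsResult:
    """Basal and clamp-window turnover for one subject.

    All rates in umol.kg-1.min-1. ``clamp_glucose_ra`` is endogenous glucose
    production over the low-dose window; ``clamp_glucose_rd`` is peripheral
    utilisation over the high-dose window. Negative EGP is retained and
    flagged NEGATIVE_EGP, never truncated.
    """

    basal_glucose_ra: float
    clamp_glucose_ra: float
    basal_glucose_rd: float
    clamp_glucose_rd: float
    basal_glycerol_ra: float
    clamp_glycerol_ra: float
    windows_used: dict[str, tuple[float, float]] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name in (
            "basal_glucose_ra", "clamp_glucose_ra", "basal_glucose_rd",
            "clamp_glucose_rd", "basal_glycerol_ra", "clamp_glycerol_ra",
        ):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{name} is not finite: {v}")
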