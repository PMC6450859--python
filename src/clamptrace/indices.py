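"""Insulin-sensitivity indices derived from the clamp.

* M value (mg.kg-1.min-1): mean dextrose infusion rate over the final
  30 min of the high-dose stage, corrected for any change in measured
  plasma glucose over the window (glucose-space correction).
* M/I: M per unit of prevailing insulin (pmol/l) in the same window.
* Percentage change from basal: +ve = stimulation (Rd, skeletal muscle),
  -ve = suppression (EGP -> hepatic; glycerol Ra -> adipose).
* Trapezium-rule AUCs of glucose, insulin and NEFA over the clamp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import GLUCOSE_MW, ClampProtocol, SampleSeries

__all__ = [
    "InsulinSensitivityIndices",
    "m_value",
    "m_over_i",
    "pct_change",
    "auc_trapezium",
    "compute_indices",
]


@dataclass
class InsulinSensitivityIndices:
    """Per-subject derived indices; NaN + flag when a denominator is missing."""

    m_value: float
    m_over_i: float
    pct_increase_rd: float
    pct_supp_egp: float
    pct_supp_glycerol_ra: float
    auc_glucose: float
    auc_insulin: float
    auc_nefa: float
    flags: set[str] = field(default_factory=set)


def m_value(
    series: SampleSeries,
    window: tuple[float, float] = (210.0, 240.0),
    v_space_l_per_kg: float = 0.22,
) -> float:
    """Whole-body glucose disposal M (mg.kg-1.min-1).

    Mean of the recorded dextrose step function over the window, corrected
    for the change in measured plasma glucose between the window endpoints:

        M = mean(GIR) - (C_end - C_start) * v_space * MW_glucose / dt

    with concentrations in mmol/l, v_space in l/kg (default: the tracer
    distribution volume, 0.22 l/kg) and dt the window width in min.
    """
    a, b = window
    gir_mean = series.gir.window_mean(a, b)
    t, c = series.channel("glucose_mmol_l")
    inside = (t >= a) & (t <= b)
    if inside.sum() < 2:
        raise ValueError(f"need >= 2 glucose samples in window {window}")
    t_in, c_in = t[inside], c[inside]
    dt = float(t_in[-1] - t_in[0])
    # mmol/l * l/kg = mmol/kg; * mg/mmol / min = mg/kg/min
    correction = (c_in[-1] - c_in[0]) * v_space_l_per_kg * GLUCOSE_MW / dt
    return float(gir_mean - correction)


def m_over_i(m: float, series: SampleSeries, window: tuple[float, float] = (210.0, 240.0)) -> float:
    """M normalised by the window-mean insulin concentration (pmol/l)."""
    i_mean = series.window_mean("insulin_pmol_l", window)
    if i_mean <= 0:
        raise ValueError(f"mean insulin must be positive, got {i_mean}")
    return m / i_mean


def pct_change(basal: float, clamp: float) -> float:
    """100 * (clamp - basal) / basal; negative = suppression.

    Raises when the basal denominator is zero (the index is undefined).
    """
    if basal == 0 or not math.isfinite(basal):
        raise ValueError(f"percentage change undefined for basal={basal}")
    return 100.0 * (clamp - basal) / basal


def auc_trapezium(t: np.ndarray, y: np.ndarray) -> float:
    """Trapezium-rule area under y(t); missing interior points are spanned.

    Points are sorted by time internally, so input order is irrelevant.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 2:
        raise ValueError(f"need >= 2 points for an AUC, got {t.size}")
    order = np.argsort(t)
    return float(np.trapezoid(y[order], t[order]))


def compute_indices(
    series: SampleSeries,
    kinetics,
    protocol: ClampProtocol | None = None,
    v_space_l_per_kg: float | None = None,
    auc_window: tuple[float, float] = (0.0, 240.0),
) -> InsulinSensitivityIndices:
    """All indices for one subject from the series and its KineticsResult."""
    if protocol is None:
        protocol = ClampProtocol()
    if v_space_l_per_kg is None:
        v_space_l_per_kg = protocol.v_frac
    flags: set[str] = set(kinetics.flags)

    m = m_value(series, protocol.high_window, v_space_l_per_kg)
    moi = m_over_i(m, series, protocol.high_window)

    def safe_pct(basal: float, clamp: float, flag: str) -> float:
        try:
            return pct_change(basal, clamp)
        except ValueError:
            flags.add(flag)
            return float("nan")

    pct_rd = safe_pct(kinetics.basal_glucose_rd, kinetics.clamp_glucose_rd, "PCT_RD_UNDEFINED")
    pct_egp = safe_pct(kinetics.basal_glucose_ra, kinetics.clamp_glucose_ra, "PCT_EGP_UNDEFINED")
    pct_gly = safe_pct(kinetics.basal_glycerol_ra, kinetics.clamp_glycerol_ra, "PCT_GLY_UNDEFINED")

    aucs = {}
    for ch in ("glucose_mmol_l", "insulin_pmol_l", "nefa_mmol_l"):
        t, y = series.channel(ch)
        sel = (t >= auc_window[0]) & (t <= auc_window[1])
        aucs[ch] = auc_trapezium(t[sel], y[sel])

    return InsulinSensitivityIndices(
        m_value=m,
        m_over_i=moi,
        pct_increase_rd=pct_rd,
        pct_supp_egp=pct_egp,
        pct_supp_glycerol_ra=pct_gly,
        auc_glucose=aucs["glucose_mmol_l"],
        auc_insulin=aucs["insulin_pmol_l"],
        auc_nefa=aucs["nefa_mmol_l"],
        flags=flags,
    )
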