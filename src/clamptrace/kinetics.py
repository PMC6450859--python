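"""Steele single-pool non-steady-state tracer kinetics for the clamp.

The tracee rate of appearance at time t is

    Ra(t) = [F(t) - V * C(t) * dZ/dt] / Z(t)

with F the tracer infusion rate (pump + any tracer carried by the spiked
dextrose infusate), C the tracee concentration, Z the plasma
tracer-to-tracee ratio, and V an effective distribution volume taken as
22% of body weight (the pool fraction is folded into V; there is no
separate p). The rate of disappearance is

    Rd(t) = Ra(t) - V * dC/dt,

so Rd = Ra whenever glycaemia is held constant. Endogenous glucose
production subtracts the exogenous dextrose:  EGP = Ra_total - GIR.

Basal turnover uses the steady-state reduction Ra = F / Z on window-mean
F and Z, since the basal period is an isotopic plateau by design. Clamp
rates are computed at the protocol's sample times from smoothed curves and
then window-averaged (never averaged-then-computed).

Units: rates umol.kg-1.min-1; V in ml/kg so V * C (C in umol/ml) is a
pool mass in umol/kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import (
    GLUCOSE_MW,
    GLYCEROL_MW,
    ClampProtocol,
    KineticsResult,
    SampleSeries,
    Subject,
    UnitContext,
)
from .smoothing import SmoothedCurve, fit_optimal_segments

__all__ = [
    "SteeleInputs",
    "basal_ra_steady_state",
    "steele_total_ra",
    "endogenous_ra",
    "glucose_rd",
    "glycerol_ra",
    "window_mean_rate",
    "analyze_kinetics",
]


@dataclass
class SteeleInputs:
    """Everything the Steele equations need, as callables of time (min).

    ``tracer_infusion`` F(t) and ``gir`` must already be in
    umol.kg-1.min-1; ``conc`` returns (C, dC/dt) in umol/ml (= mmol/l) and
    ``ttr`` returns (Z, dZ/dt).
    """

    tracer_infusion: Callable[[float], float]
    conc: Callable[[float], tuple]
    ttr: Callable[[float], tuple]
    v_ml_per_kg: float
    gir: Callable[[float], float] = lambda t: 0.0

    def __post_init__(self) -> None:
        if self.v_ml_per_kg <= 0:
            raise ValueError("distribution volume must be positive")


def basal_ra_steady_state(f_basal: float, z_basal: float) -> float:
    """Steady-state turnover F / Z at the basal isotopic plateau.

    ``f_basal`` is the window-mean tracer infusion (umol.kg-1.min-1) and
    ``z_basal`` the window-mean TTR. At basal steady state Rd = Ra.
    """
    if z_basal <= 0:
        raise ValueError(f"basal TTR must be positive, got {z_basal}")
    return f_basal / z_basal


def steele_total_ra(inputs: SteeleInputs, t: float) -> float:
    """Total tracee rate of appearance at time t (umol.kg-1.min-1)."""
    z, dzdt = inputs.ttr(t)
    if z <= 0:
        raise ValueError(f"TTR must be positive at t={t} min, got {z}")
    c, _ = inputs.conc(t)
    f = inputs.tracer_infusion(t)
    return (f - inputs.v_ml_per_kg * c * dzdt) / z


def endogenous_ra(total_ra: float, gir_umol_kg_min: float) -> tuple[float, set]:
    """EGP = total Ra - exogenous glucose infusion; negative flagged, kept."""
    egp = total_ra - gir_umol_kg_min
    flags = {"NEGATIVE_EGP"} if egp < 0 else set()
    return egp, flags


def glucose_rd(inputs: SteeleInputs, t: float) -> float:
    """Rate of disappearance: total Ra minus the pool-change term V*dC/dt."""
    _, dcdt = inputs.conc(t)
    return steele_total_ra(inputs, t) - inputs.v_ml_per_kg * dcdt


def glycerol_ra(
    inputs: SteeleInputs,
    window: tuple[float, float],
    sample_times: Sequence[float],
    protocol: ClampProtocol | None = None,
) -> float:
    """Window-mean glycerol rate of appearance (whole-body lipolysis).

    The glycerol tracer is stopped just before the high-dose stage, so
    only the basal and low-dose windows are legal; requesting a window
    that reaches into the high-dose stage raises.
    """
    stage2_start = protocol.stage2_start_min if protocol is not None else 120.0
    if window[1] > stage2_start:
        raise ValueError(
            f"glycerol tracer runs only until t={stage2_start} min; "
            f"window {window} is outside the traced period"
        )
    rates = [steele_total_ra(inputs, t) for t in _times_in(sample_times, window)]
    return window_mean_rate(rates)


def _times_in(sample_times: Sequence[float], window: tuple[float, float]) -> np.ndarray:
    t = np.asarray(sample_times, dtype=float)
    sel = t[(t >= window[0]) & (t <= window[1])]
    if sel.size < 2:
        raise ValueError(
            f"SPARSE_WINDOW: need >= 2 sample times in {window}, got {sel.size}"
        )
    return sel


def window_mean_rate(rates: Sequence[float]) -> float:
    """Mean of rates evaluated at the protocol sample times in a window."""
    rates = np.asarray(rates, dtype=float)
    if rates.size < 2:
        raise ValueError("SPARSE_WINDOW: need >= 2 evaluated rates")
    return float(np.mean(rates))


# -- per-subject driver -----------------------------------------------------

def _smooth_channel(
    series: SampleSeries,
    name: str,
    t_range: tuple[float, float] | None = None,
    max_segments: int = 4,
    degree: int = 2,
    weights_cv: float | None = None,
) -> SmoothedCurve:
    t, y = series.channel(name)
    if t_range is not None:
        sel = (t >= t_range[0]) & (t <= t_range[1])
        t, y = t[sel], y[sel]
    w = None
    if weights_cv:
        w = 1.0 / np.maximum(weights_cv * np.abs(y), 1e-12) ** 2
    return fit_optimal_segments(t, y, weights=w, max_segments=max_segments,
                                degree=degree, channel=name)


def analyze_kinetics(
    subject: Subject,
    series: SampleSeries,
    protocol: ClampProtocol | None = None,
    max_segments: int = 4,
    conc_degree: int = 2,
    ttr_degree: int = 2,
) -> KineticsResult:
    """Full tracer-kinetics analysis of one subject's clamp.

    Smooths glucose concentration and TTR over the whole record and
    glycerol concentration and TTR over the traced period, then computes:

    * basal glucose Ra (= Rd) and basal glycerol Ra by steady-state F/Z
      on basal-window means;
    * EGP over the low-dose window: Steele total Ra (with the infusate
      tracer contribution) minus GIR, sample-wise, then averaged;
    * glucose Rd over the high-dose window;
    * glycerol Ra over the low-dose window.

    All channels default to quadratic segments; the degrees are exposed
    separately because the dZ/dt term dominates the Steele correction and
    a lower-order TTR fit is a useful robustness check.
    """
    if protocol is None:
        protocol = ClampProtocol()
    units = UnitContext(subject.weight_kg, protocol.v_frac)
    v = units.v_ml_per_kg
    flags: set[str] = set()

    f_glc_pump = units.mg_glucose_to_umol(protocol.glucose_tracer_rate_mg_kg_min)
    f_gly_pump = units.mg_glycerol_to_umol(protocol.glycerol_tracer_rate_mg_kg_min)

    # --- basal plateau: steady-state F/Z on window means
    for ch in ("glucose_ttr", "glycerol_ttr"):
        if series.n_in_window(ch, protocol.basal_window) < 2:
            flags.add("SPARSE_WINDOW")
            raise ValueError(
                f"SPARSE_WINDOW: <2 basal samples for {ch}; cannot anchor basal turnover"
            )
    z_glc_basal = series.window_mean("glucose_ttr", protocol.basal_window)
    z_gly_basal = series.window_mean("glycerol_ttr", protocol.basal_window)
    basal_glucose_ra = basal_ra_steady_state(f_glc_pump, z_glc_basal)
    basal_glycerol_ra = basal_ra_steady_state(f_gly_pump, z_gly_basal)

    # --- smoothed curves for the non-steady clamp period
    c_glc = _smooth_channel(series, "glucose_mmol_l", max_segments=max_segments, degree=conc_degree)
    z_glc = _smooth_channel(series, "glucose_ttr", max_segments=max_segments, degree=ttr_degree)
    gly_range = (series.t_min[0], protocol.stage2_start_min)
    c_gly = _smooth_channel(series, "glycerol_umol_l", t_range=gly_range,
                            max_segments=max_segments, degree=conc_degree)
    z_gly = _smooth_channel(series, "glycerol_ttr", t_range=gly_range,
                            max_segments=max_segments, degree=ttr_degree)

    # A blood sample drawn at time t reflects infusion history up to t-,
    # so step functions (pump rate, infusate enrichment) and curve slopes
    # are taken as left limits; this matters only at the stage boundaries,
    # where the sampling schedule coincides with protocol switches.
    _EPS = 1e-9

    def gir_umol(t: float) -> float:
        return units.mg_glucose_to_umol(float(series.gir.rate_at(t - _EPS)))

    def f_glucose(t: float) -> float:
        # infusate carries e_inf mg tracer per g glucose; GIR is mg glucose/kg/min
        e_inf = protocol.infusate_enrichment_at(t - _EPS)
        gir_mg = float(series.gir.rate_at(t - _EPS))
        return f_glc_pump + units.mg_glucose_to_umol(gir_mg * e_inf / 1000.0)

    glc_inputs = SteeleInputs(
        tracer_infusion=f_glucose,
        conc=lambda t: c_glc.evaluate(t, side="left"),
        ttr=lambda t: z_glc.evaluate(t, side="left"),
        v_ml_per_kg=v,
        gir=gir_umol,
    )
    gly_inputs = SteeleInputs(
        tracer_infusion=lambda t: f_gly_pump,
        conc=lambda t: (c_gly.value(t) / 1000.0,
                        c_gly.derivative(t, side="left") / 1000.0),  # umol/l -> umol/ml
        ttr=lambda t: z_gly.evaluate(t, side="left"),
        v_ml_per_kg=v,
    )

    # --- low-dose window: EGP
    low_times = _times_in(series.channel("glucose_ttr")[0], protocol.low_window)
    egps = []
    for t in low_times:
        ra_tot = steele_total_ra(glc_inputs, float(t))
        egp, f = endogenous_ra(ra_tot, gir_umol(float(t)))
        flags |= f
        egps.append(egp)
    clamp_egp = window_mean_rate(egps)

    # --- high-dose window: Rd
    high_times = _times_in(series.channel("glucose_ttr")[0], protocol.high_window)
    rds = [glucose_rd(glc_inputs, float(t)) for t in high_times]
    clamp_rd = window_mean_rate(rds)

    # --- low-dose window: glycerol Ra
    gly_times = series.channel("glycerol_ttr")[0]
    clamp_gly = glycerol_ra(gly_inputs, protocol.low_window, gly_times, protocol)

    return KineticsResult(
        basal_glucose_ra=basal_glucose_ra,
        clamp_glucose_ra=clamp_egp,
        basal_glucose_rd=basal_glucose_ra,  # Rd = Ra at basal steady state
        clamp_glucose_rd=clamp_rd,
        basal_glycerol_ra=basal_glycerol_ra,
        clamp_glycerol_ra=clamp_gly,
        windows_used={
            "basal": protocol.basal_window,
            "low": protocol.low_window,
            "high": protocol.high_window,
        },
        flags=flags,
    )
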