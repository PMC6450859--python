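"""Synthetic clamp generator with known ground truth.

A single-pool glucose system and a glycerol pool are integrated through
the full protocol (tracer equilibration from t = -120 min, insulin stages
at 0 and 120 min):

    tracee:  V * dC/dt = EGP(t) + GIR(t) - Rd(t)
    tracer:  V * dQ/dt = F_pump(t) + e_inf * GIR_mass(t) - Rd(t) * Z(t)

with Q = C * Z the labelled concentration (analogously for glycerol,
which has no exogenous tracee and whose tracer stops at the second
stage). Insulin action enters through monotone Hill dose-responses on the
insulin increment above basal: EGP and glycerol Ra are suppressed, glucose
clearance is stimulated. Insulin itself is prescribed (first-order
approach to a stage plateau) because the downstream estimator uses only
measured concentrations, never insulin kinetics.

A proportional-integral controller in velocity form adjusts the dextrose
rate every 5 min to hold glucose at the 5 mmol/l target, mimicking
bedside titration. Tracer pools start on the basal isotopic plateau
(Z = F/Ra), i.e. a well-primed, fully equilibrated tracer.

Cumulative tracer in/out integrals ride along in the ODE state, so mass
conservation can be audited against the pool change exactly.

Everything is deterministic under a seed; sampling noise is multiplicative
Gaussian per channel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .core import (
    GLUCOSE_MW,
    GLYCEROL_MW,
    SAMPLING_SCHEDULE,
    ClampProtocol,
    GIRProfile,
    Group,
    SampleSeries,
    Subject,
    UnitContext,
)

__all__ = [
    "NoiseModel",
    "SimulationTruth",
    "SimulationResult",
    "GroupSpec",
    "CohortSpec",
    "simulate_subject",
    "draw_subject_truth",
    "generate_cohort",
    "default_cohort_spec",
]


def _hill(x: float, ec50: float, h: float) -> float:
    if x <= 0:
        return 0.0
    xh = x ** h
    return xh / (xh + ec50 ** h)


@dataclass
class NoiseModel:
    """Multiplicative Gaussian measurement noise, one CV per channel."""

    cv_glucose: float = 0.02
    cv_ttr: float = 0.015
    cv_insulin: float = 0.05
    cv_nefa: float = 0.07
    cv_glycerol: float = 0.07

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class SimulationTruth:
    """Ground-truth physiology of one simulated subject.

    Percentage targets are the suppression/stimulation reached at the
    stage insulin plateau; they parameterise the Hill dose-responses
    (suppression capped at 100%). ``pct_*`` values are positive
    magnitudes (e.g. 36.4 means EGP falls 36.4% at the low-dose plateau).
    """

    basal_egp: float = 9.0                 # umol/kg/min
    basal_glycerol_ra: float = 1.65        # umol/kg/min
    basal_insulin: float = 50.0            # pmol/l
    basal_nefa: float = 0.50               # mmol/l
    basal_glycerol_conc: float = 65.0      # umol/l
    pct_egp_supp: float = 35.6             # % at low-dose plateau
    pct_rd_increase: float = 185.0         # % at high-dose plateau
    pct_gly_supp: float = 37.3             # % at low-dose plateau
    pct_nefa_supp: float = 55.0            # % at low-dose plateau
    ec50_egp: float = 30.0                 # pmol/l above basal
    ec50_rd: float = 60.0
    ec50_gly: float = 25.0
    hill: float = 2.0
    insulin_incr_per_rate: float = 2.5     # pmol/l per mU.m-2.min-1
    tau_insulin_min: float = 8.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("basal_egp", "basal_glycerol_ra", "basal_insulin",
                     "basal_nefa", "basal_glycerol_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- dose-responses (x = insulin increment above basal, pmol/l) --------

    def _d_low(self, protocol: ClampProtocol) -> float:
        return self.insulin_incr_per_rate * protocol.insulin_rate_low_mU_m2_min

    def _d_high(self, protocol: ClampProtocol) -> float:
        return self.insulin_incr_per_rate * protocol.insulin_rate_high_mU_m2_min

    def egp_suppression(self, x: float, protocol: ClampProtocol) -> float:
        """Fractional EGP suppression at insulin increment x (monotone, <= 1)."""
        smax = min(self.pct_egp_supp / 100.0 / _hill(self._d_low(protocol), self.ec50_egp, self.hill), 1.0)
        return smax * _hill(x, self.ec50_egp, self.hill)

    def rd_stimulation(self, x: float, protocol: ClampProtocol) -> float:
        """Fractional increase of glucose clearance at insulin increment x."""
        stim = self.pct_rd_increase / 100.0 / _hill(self._d_high(protocol), self.ec50_rd, self.hill)
        return stim * _hill(x, self.ec50_rd, self.hill)

    def glycerol_suppression(self, x: float, protocol: ClampProtocol) -> float:
        smax = min(self.pct_gly_supp / 100.0 / _hill(self._d_low(protocol), self.ec50_gly, self.hill), 1.0)
        return smax * _hill(x, self.ec50_gly, self.hill)

    def nefa_suppression(self, x: float, protocol: ClampProtocol) -> float:
        smax = min(self.pct_nefa_supp / 100.0 / _hill(self._d_low(protocol), self.ec50_gly, self.hill), 1.0)
        return smax * _hill(x, self.ec50_gly, self.hill)

    def insulin_at(self, t: float, protocol: ClampProtocol) -> float:
        """Prescribed insulin trajectory: first-order rise to stage plateaus."""
        i0 = self.basal_insulin
        if t < protocol.stage1_start_min:
            return i0
        p1 = i0 + self._d_low(protocol)
        tau = self.tau_insulin_min
        if t < protocol.stage2_start_min:
            return p1 + (i0 - p1) * math.exp(-(t - protocol.stage1_start_min) / tau)
        i_120 = p1 + (i0 - p1) * math.exp(-(protocol.stage2_start_min - protocol.stage1_start_min) / tau)
        p2 = i0 + self._d_high(protocol)
        return p2 + (i_120 - p2) * math.exp(-(t - protocol.stage2_start_min) / tau)


@dataclass
class SimulationResult:
    """One simulated clamp: observed series, dense truth, and conservation audit."""

    series: SampleSeries
    truth: SimulationTruth
    grid_t: np.ndarray                 # dense integration grid, min
    truth_glucose: np.ndarray          # mmol/l
    truth_glucose_ttr: np.ndarray
    truth_egp: np.ndarray              # umol/kg/min
    truth_rd: np.ndarray
    truth_glycerol_ra: np.ndarray
    truth_glycerol_conc: np.ndarray    # umol/l
    truth_glycerol_ttr: np.ndarray
    truth_insulin: np.ndarray
    gir: GIRProfile                    # mg/kg/min (also attached to series)
    conservation: dict
    flags: set = field(default_factory=set)

    def truth_at(self, channel: str, t: np.ndarray) -> np.ndarray:
        """Truth trajectory interpolated onto arbitrary times."""
        y = getattr(self, f"truth_{channel}")
        return np.interp(np.asarray(t, dtype=float), self.grid_t, y)

    def truth_window_mean(self, channel: str, window: tuple, sample_times=None) -> float:
        """Mean truth over a window, at the protocol's sample times."""
        if sample_times is None:
            sample_times = np.asarray(SAMPLING_SCHEDULE)
        st = np.asarray(sample_times, dtype=float)
        sel = st[(st >= window[0]) & (st <= window[1])]
        return float(np.mean(self.truth_at(channel, sel)))


def simulate_subject(
    subject: Subject,
    protocol: ClampProtocol | None = None,
    truth: SimulationTruth | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | int | None = None,
    dt: float = 0.5,
    control_period: float = 5.0,
    control_tau: float = 12.0,
) -> SimulationResult:
    """Integrate one subject's clamp and emit the sampled, noisy series.

    The controller reads the true glucose every ``control_period`` min and
    updates the dextrose rate in velocity-form PI fashion with horizon
    ``control_tau`` min; runs where glucose leaves [3, 9] mmol/l are
    flagged UNSTABLE.
    """
    protocol = protocol or ClampProtocol()
    truth = truth or SimulationTruth()
    noise = noise if noise is not None else NoiseModel()
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    units = UnitContext(subject.weight_kg, protocol.v_frac)
    v = units.v_ml_per_kg  # ml/kg

    # pump tracer rates, umol/kg/min
    f_glc = units.mg_glucose_to_umol(protocol.glucose_tracer_rate_mg_kg_min)
    f_gly0 = units.mg_glycerol_to_umol(protocol.glycerol_tracer_rate_mg_kg_min)

    c_b = protocol.glycaemic_target_mmol_l            # umol/ml; starts at target
    cg_b = truth.basal_glycerol_conc / 1000.0         # umol/ml
    z_glc0 = f_glc / truth.basal_egp                  # basal isotopic plateau
    z_gly0 = f_gly0 / truth.basal_glycerol_ra
    k_cl_b = truth.basal_egp / c_b                    # basal glucose clearance
    k_gly = truth.basal_glycerol_ra / cg_b            # glycerol clearance (fixed)

    def egp_at(t: float) -> float:
        x = truth.insulin_at(t, protocol) - truth.basal_insulin
        return truth.basal_egp * (1.0 - truth.egp_suppression(x, protocol))

    def clearance_at(t: float) -> float:
        x = truth.insulin_at(t, protocol) - truth.basal_insulin
        return k_cl_b * (1.0 + truth.rd_stimulation(x, protocol))

    def gly_ra_at(t: float) -> float:
        x = truth.insulin_at(t, protocol) - truth.basal_insulin
        return truth.basal_glycerol_ra * (1.0 - truth.glycerol_suppression(x, protocol))

    def f_gly_at(t: float) -> float:
        return f_gly0 if t < protocol.stage2_start_min else 0.0

    t0, t_end = protocol.basal_start_min, protocol.clamp_end_min
    n_per_block = max(1, int(round(control_period / dt)))
    dt = control_period / n_per_block

    # state: C, Q, Cg, Qg, cumFglc, cumOutGlc, cumFgly, cumOutGly
    state = [c_b, c_b * z_glc0, cg_b, cg_b * z_gly0, 0.0, 0.0, 0.0, 0.0]

    gir_umol = 0.0          # current dextrose rate, umol/kg/min
    gir_times: list[float] = []
    gir_rates: list[float] = []
    c_prev_reading = c_b
    e_prev = 0.0

    grid_t: list[float] = [t0]
    traj: list[list[float]] = [list(state)]
    gir_max = 150.0  # umol/kg/min (~27 mg/kg/min), generous pump ceiling

    def rhs(t: float, s: list[float], u: float) -> list[float]:
        c, q, cg, qg = s[0], s[1], s[2], s[3]
        z = q / c if c > 0 else 0.0
        zg = qg / cg if cg > 0 else 0.0
        rd = clearance_at(t) * c
        e_inf = protocol.infusate_enrichment_at(t)    # mg tracer / g glucose
        u_mg = units.umol_to_mg(u, GLUCOSE_MW)        # mg glucose/kg/min
        f_inf = units.mg_glucose_to_umol(u_mg * e_inf / 1000.0)
        f_tot = f_glc + f_inf
        rd_g = k_gly * cg
        f_gly = f_gly_at(t)
        return [
            (egp_at(t) + u - rd) / v,
            (f_tot - rd * z) / v,
            (gly_ra_at(t) - rd_g) / v,
            (f_gly - rd_g * zg) / v,
            f_tot,
            rd * z,
            f_gly,
            rd_g * zg,
        ]

    flags: set = set()
    n_blocks = int(round((t_end - t0) / control_period))
    t = t0
    for block in range(n_blocks):
        # controller acts from insulin start onward
        if t >= protocol.stage1_start_min - 1e-9:
            c_read = state[0]
            e = protocol.glycaemic_target_mmol_l - c_read
            # velocity-form PI: track the pool trend, close the error over tau
            gir_umol += v * (c_prev_reading - c_read) / control_period
            gir_umol += v * e / control_tau
            gir_umol = min(max(gir_umol, 0.0), gir_max)
            c_prev_reading = c_read
            e_prev = e
            gir_times.append(round(t, 6))
            gir_rates.append(units.umol_to_mg(gir_umol, GLUCOSE_MW))
        u = gir_umol
        for _ in range(n_per_block):
            k1 = rhs(t, state, u)
            s2 = [si + 0.5 * dt * ki for si, ki in zip(state, k1)]
            k2 = rhs(t + 0.5 * dt, s2, u)
            s3 = [si + 0.5 * dt * ki for si, ki in zip(state, k2)]
            k3 = rhs(t + 0.5 * dt, s3, u)
            s4 = [si + dt * ki for si, ki in zip(state, k3)]
            k4 = rhs(t + dt, s4, u)
            state = [
                si + dt / 6.0 * (a + 2 * b2 + 2 * b3 + b4)
                for si, a, b2, b3, b4 in zip(state, k1, k2, k3, k4)
            ]
            t += dt
            grid_t.append(round(t, 9))
            traj.append(list(state))
        if not 3.0 <= state[0] <= 9.0:
            flags.add("UNSTABLE")

    grid = np.asarray(grid_t)
    arr = np.asarray(traj)
    c_t, q_t, cg_t, qg_t = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    z_t = q_t / c_t
    zg_t = qg_t / cg_t

    ins_t = np.array([truth.insulin_at(x, protocol) for x in grid])
    egp_t = np.array([egp_at(x) for x in grid])
    rd_t = np.array([clearance_at(x) for x in grid]) * c_t
    glyra_t = np.array([gly_ra_at(x) for x in grid])

    # conservation audit: pool change vs cumulative in/out (identical quadrature)
    pool_glc = v * (q_t[-1] - q_t[0])
    pool_gly = v * (qg_t[-1] - qg_t[0])
    conservation = {
        "glucose_tracer_in": float(arr[-1, 4]),
        "glucose_tracer_out": float(arr[-1, 5]),
        "glucose_pool_change": float(pool_glc),
        "glucose_residual_rel": float(
            abs(arr[-1, 4] - arr[-1, 5] - pool_glc) / max(arr[-1, 4], 1e-12)
        ),
        "glycerol_tracer_in": float(arr[-1, 6]),
        "glycerol_tracer_out": float(arr[-1, 7]),
        "glycerol_pool_change": float(pool_gly),
        "glycerol_residual_rel": float(
            abs(arr[-1, 6] - arr[-1, 7] - pool_gly) / max(arr[-1, 6], 1e-12)
        ),
    }

    # ---- sample the observation schedule with noise
    st = np.asarray(SAMPLING_SCHEDULE)
    idx = np.searchsorted(grid, st)

    def noisy(vals: np.ndarray, cv: float) -> np.ndarray:
        if cv == 0.0:
            return vals.copy()
        out = vals * (1.0 + cv * rng.standard_normal(vals.size))
        return np.maximum(out, 0.0)

    nefa_true = np.array([
        truth.basal_nefa * (1.0 - truth.nefa_suppression(
            truth.insulin_at(x, protocol) - truth.basal_insulin, protocol))
        for x in st
    ])
    gly_mask = st <= protocol.stage2_start_min  # tracer (and assay) stop at stage 2

    glycerol_conc_obs = np.full(st.size, np.nan)
    glycerol_ttr_obs = np.full(st.size, np.nan)
    glycerol_conc_obs[gly_mask] = noisy(cg_t[idx][gly_mask] * 1000.0, noise.cv_glycerol)
    glycerol_ttr_obs[gly_mask] = noisy(zg_t[idx][gly_mask], noise.cv_ttr)

    gir_profile = GIRProfile(gir_times, gir_rates)
    series = SampleSeries(
        t_min=st.astype(float),
        glucose_mmol_l=noisy(c_t[idx], noise.cv_glucose),
        insulin_pmol_l=noisy(ins_t[idx], noise.cv_insulin),
        nefa_mmol_l=noisy(nefa_true, noise.cv_nefa),
        glucose_ttr=noisy(z_t[idx], noise.cv_ttr),
        glycerol_umol_l=glycerol_conc_obs,
        glycerol_ttr=glycerol_ttr_obs,
        gir=gir_profile,
    )

    return SimulationResult(
        series=series,
        truth=truth,
        grid_t=grid,
        truth_glucose=c_t,
        truth_glucose_ttr=z_t,
        truth_egp=egp_t,
        truth_rd=rd_t,
        truth_glycerol_ra=glyra_t,
        truth_glycerol_conc=cg_t * 1000.0,
        truth_glycerol_ttr=zg_t,
        truth_insulin=ins_t,
        gir=gir_profile,
        conservation=conservation,
        flags=flags,
    )


# -- cohort generation ------------------------------------------------------

@dataclass
class GroupSpec:
    """Distributional targets for one study arm (means/SDs on the printed scale)."""

    n: int
    weight_kg: tuple[float, float]
    height_cm: tuple[float, float]
    vat_kg: tuple[float, float]
    sat_kg: tuple[float, float]
    muscle_kg: tuple[float, float]
    basal_egp: tuple[float, float]                 # umol/kg/min
    basal_glycerol_ra_log10: tuple[float, float]   # log10 gm, log10 sd
    basal_insulin_log10: tuple[float, float]
    basal_nefa: tuple[float, float]
    pct_egp_supp: tuple[float, float]              # positive magnitudes
    pct_rd_increase: tuple[float, float]
    pct_gly_supp: tuple[float, float]
    muscle_adipose_corr: float                     # corr(pct_rd, pct_gly_supp)


def default_cohort_spec() -> "CohortSpec":
    """Two arms calibrated to the published study's group summaries."""
    bam = GroupSpec(
        n=18,
        weight_kg=(90.9, 9.3), height_cm=(175.6, 7.6),
        vat_kg=(3.72, 1.07), sat_kg=(11.8, 3.9), muscle_kg=(20.7, 2.5),
        basal_egp=(8.82, 1.49),
        basal_glycerol_ra_log10=(math.log10(1.51), 0.11),
        basal_insulin_log10=(math.log10(45.7), 0.14),
        basal_nefa=(0.48, 0.17),
        pct_egp_supp=(36.4, 19.7),
        pct_rd_increase=(203.5, 126.2),
        pct_gly_supp=(37.2, 16.0),
        muscle_adipose_corr=0.25,
    )
    wem = GroupSpec(
        n=15,
        weight_kg=(94.2, 11.6), height_cm=(176.8, 5.8),
        vat_kg=(5.68, 2.43), sat_kg=(11.8, 2.6), muscle_kg=(18.5, 3.0),
        basal_egp=(9.25, 1.66),
        basal_glycerol_ra_log10=(math.log10(1.82), 0.11),
        basal_insulin_log10=(math.log10(57.3), 0.24),
        basal_nefa=(0.55, 0.18),
        pct_egp_supp=(34.8, 20.7),
        pct_rd_increase=(166.3, 102.5),
        pct_gly_supp=(37.5, 13.7),
        muscle_adipose_corr=0.78,
    )
    return CohortSpec(groups={Group.BAM: bam, Group.WEM: wem})


@dataclass
class CohortSpec:
    """Two-group study design for the generator."""

    groups: dict
    seed: int | None = None

    def __post_init__(self) -> None:
        for g, spec in self.groups.items():
            for name, val in asdict(spec).items():
                if isinstance(val, tuple) and len(val) == 2 and name != "basal_glycerol_ra_log10":
                    if val[1] < 0:
                        raise ValueError(f"{g}.{name}: SD must be >= 0")


def _trunc_normal(rng, mean, sd, lo, hi, counter) -> float:
    """Normal draw truncated to [lo, hi] by rejection; counts rejections."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
        counter[0] += 1
    raise RuntimeError(f"truncated draw failed for N({mean},{sd}) on [{lo},{hi}]")


def draw_subject_truth(
    rng: np.random.Generator, spec: GroupSpec, group: Group, idx: int
) -> tuple[Subject, SimulationTruth, int]:
    """One subject's anthropometry + physiology from the group distributions.

    Muscle (Rd stimulation) and adipose (glycerol suppression) sensitivity
    are drawn from a Gaussian copula with the group's correlation.
    Returns (subject, truth, n_rejected).
    """
    rej = [0]
    weight = _trunc_normal(rng, *spec.weight_kg, 50.0, 160.0, rej)
    height = _trunc_normal(rng, *spec.height_cm, 140.0, 210.0, rej)
    vat = _trunc_normal(rng, *spec.vat_kg, 0.3, 20.0, rej)
    sat = _trunc_normal(rng, *spec.sat_kg, 1.0, 40.0, rej)
    muscle = _trunc_normal(rng, *spec.muscle_kg, 8.0, 40.0, rej)
    basal_egp = _trunc_normal(rng, *spec.basal_egp, 3.0, 20.0, rej)
    basal_gly = 10.0 ** rng.normal(*spec.basal_glycerol_ra_log10)
    basal_ins = 10.0 ** rng.normal(*spec.basal_insulin_log10)
    basal_nefa = _trunc_normal(rng, *spec.basal_nefa, 0.05, 2.0, rej)
    pct_egp = _trunc_normal(rng, *spec.pct_egp_supp, 2.0, 95.0, rej)

    # correlated (muscle, adipose) pair via Gaussian copula
    r = spec.muscle_adipose_corr
    for _ in range(1000):
        z1, z2 = rng.standard_normal(2)
        z2 = r * z1 + math.sqrt(max(0.0, 1.0 - r * r)) * z2
        pct_rd = spec.pct_rd_increase[0] + spec.pct_rd_increase[1] * z1
        pct_gly = spec.pct_gly_supp[0] + spec.pct_gly_supp[1] * z2
        if 10.0 <= pct_rd <= 650.0 and 2.0 <= pct_gly <= 95.0:
            break
        rej[0] += 1
    else:
        raise RuntimeError("correlated sensitivity draw failed")

    subject = Subject(
        id=f"{group.value}{idx:03d}",
        group=group,
        weight_kg=weight,
        height_cm=height,
        vat_kg=vat,
        sat_kg=sat,
        muscle_kg=muscle,
    )
    truth = SimulationTruth(
        basal_egp=basal_egp,
        basal_glycerol_ra=basal_gly,
        basal_insulin=basal_ins,
        basal_nefa=basal_nefa,
        pct_egp_supp=pct_egp,
        pct_rd_increase=pct_rd,
        pct_gly_supp=pct_gly,
    )
    return subject, truth, rej[0]


def generate_cohort(
    spec: CohortSpec | None = None,
    protocol: ClampProtocol | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Simulate a full two-group study.

    Returns ``{"subjects": [...], "results": [SimulationResult, ...],
    "n_rejected": int}`` in a stable order (BAM then WEM, by index).
    With ``out_dir``, writes the subject table, one series CSV per subject
    and one truth JSON per subject; byte-identical for the same seed.
    """
    from . import io as cio

    spec = spec or default_cohort_spec()
    protocol = protocol or ClampProtocol()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)

    subjects: list[Subject] = []
    results: list[SimulationResult] = []
    n_rejected = 0
    for group in (Group.BAM, Group.WEM):
        gspec = spec.groups[group]
        for i in range(gspec.n):
            subj, truth, rej = draw_subject_truth(rng, gspec, group, i + 1)
            n_rejected += rej
            res = simulate_subject(subj, protocol, truth, noise=noise, rng=rng)
            subjects.append(subj)
            results.append(res)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_subject_table(subjects, out / "subjects.csv")
        series_dir = out / "series"
        series_dir.mkdir(exist_ok=True)
        for subj, res in zip(subjects, results):
            cio.write_series(res.series, series_dir / f"{subj.id}.csv")
            truth_path = out / "truth" / f"{subj.id}.json"
            truth_path.parent.mkdir(exist_ok=True)
            payload = asdict(res.truth)
            payload["conservation"] = res.conservation
            payload["flags"] = sorted(res.flags)
            truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True))

    return {"subjects": subjects, "results": results, "n_rejected": n_rejected}
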