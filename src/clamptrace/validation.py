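"""Validation studies: printed-summary arithmetic, parameter recovery,
and statistical calibration.

The study's raw subject-level data were never deposited, so validation
rests on three legs:

1. arithmetic on the published group summaries (mean differences, CI
   reconstruction from n/mean/SD, geometric-mean ratios);
2. parameter recovery on simulated cohorts whose ground truth is known
   (window-mean EGP, Rd and glycerol Ra bias/RMSE; suppression and
   stimulation percentages noise-free);
3. calibration of the route-then-test comparison procedure on null
   cohorts at the study's group sizes.

Every function here recomputes its result from scratch when called.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from .core import ClampProtocol, Group, Subject
from .pipeline import analyze_subject
from .simulator import (
    NoiseModel,
    default_cohort_spec,
    draw_subject_truth,
    simulate_subject,
)
from .stats import compare_variable, geometric_ratio_ci, mean_difference_from_summary

__all__ = [
    "published_summaries",
    "printed_contrasts",
    "ci_reconstruction",
    "recovery_study",
    "noisefree_suppression_study",
    "type_i_calibration",
]


def published_summaries() -> dict:
    """The published study's group-level summary statistics (package data)."""
    text = resources.files("clamptrace.data").joinpath(
        "published_cohort_summaries.yaml"
    ).read_text()
    return yaml.safe_load(text)


def printed_contrasts(summaries: dict | None = None) -> dict:
    """Recompute the between-group contrasts from the printed group means.

    Differences are first group minus second (BAM - WEM); the glycerol
    contrast is the ratio of the printed geometric means; the body
    composition contrasts are also expressed as percentages of the
    comparison group.
    """
    s = summaries or published_summaries()
    vat = s["anthropometry"]["vat_kg"]["mean"]
    mus = s["anthropometry"]["muscle_kg"]["mean"]
    turn = s["turnover"]
    gm = turn["basal_glycerol_ra_umol_kg_min_gm"]["gm"]
    return {
        "vat_difference_kg": vat[0] - vat[1],
        "vat_pct_of_wem": 100.0 * (vat[0] - vat[1]) / vat[1],
        "muscle_difference_kg": mus[0] - mus[1],
        "muscle_pct_of_wem": 100.0 * (mus[0] - mus[1]) / mus[1],
        "m_value_difference": turn["m_value_mg_kg_min"]["mean"][0]
        - turn["m_value_mg_kg_min"]["mean"][1],
        "rd_difference": turn["rd_umol_kg_min"]["mean"][0]
        - turn["rd_umol_kg_min"]["mean"][1],
        "basal_ra_difference": turn["basal_ra_umol_kg_min"]["mean"][0]
        - turn["basal_ra_umol_kg_min"]["mean"][1],
        "clamp_ra_difference": turn["clamp_ra_umol_kg_min"]["mean"][0]
        - turn["clamp_ra_umol_kg_min"]["mean"][1],
        "glycerol_gm_ratio": gm[0] / gm[1],
    }


def ci_reconstruction(summaries: dict | None = None) -> dict:
    """Pooled-t mean differences and 95% CIs rebuilt from printed n/mean/SD.

    Returns, per normally-distributed turnover row, the recomputed
    (difference, ci_low, ci_high) alongside the printed interval.
    """
    s = summaries or published_summaries()
    out = {}
    for key, row in s["turnover"].items():
        if "sd" not in row:
            continue  # geometric-mean rows handled separately
        n, mean, sd = row["n"], row["mean"], row["sd"]
        diff, ci, p = mean_difference_from_summary(
            n[0], mean[0], sd[0], n[1], mean[1], sd[1]
        )
        out[key] = {
            "difference": diff,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": p,
            "printed_difference": row["printed_difference"],
            "printed_ci": tuple(row["printed_ci"]),
        }
    return out


def _alternating_draws(rng, spec, n):
    for i in range(n):
        group = Group.BAM if i % 2 == 0 else Group.WEM
        yield draw_subject_truth(rng, spec.groups[group], group, i)


def recovery_study(
    n_subjects: int = 200,
    seed: int = 0,
    noise: NoiseModel | None = None,
    protocol: ClampProtocol | None = None,
) -> dict:
    """Estimator recovery over simulated subjects at default noise.

    Simulates subjects drawn from the default cohort spec (groups
    alternating), runs the full pipeline on the noisy observations, and
    compares window-mean EGP, Rd and glycerol Ra against the simulator
    truth. Returns percent bias and RMSE per quantity.
    """
    protocol = protocol or ClampProtocol()
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    spec = default_cohort_spec()
    errs = {"egp": [], "rd": [], "glycerol_ra": [], "basal_ra": []}
    for subject, truth, _ in _alternating_draws(rng, spec, n_subjects):
        res = simulate_subject(subject, protocol, truth, noise=noise, rng=rng)
        row = analyze_subject(subject, res.series, protocol)
        pairs = {
            "egp": (row["clamp_glucose_ra"],
                    res.truth_window_mean("egp", protocol.low_window)),
            "rd": (row["clamp_glucose_rd"],
                   res.truth_window_mean("rd", protocol.high_window)),
            "glycerol_ra": (row["clamp_glycerol_ra"],
                            res.truth_window_mean("glycerol_ra", protocol.low_window)),
            "basal_ra": (row["basal_glucose_ra"], truth.basal_egp),
        }
        for k, (est, tru) in pairs.items():
            errs[k].append((est - tru) / tru)
    out = {}
    for k, e in errs.items():
        e = np.asarray(e)
        out[f"{k}_bias_pct"] = float(100.0 * e.mean())
        out[f"{k}_rmse_pct"] = float(100.0 * np.sqrt((e ** 2).mean()))
    out["n_subjects"] = n_subjects
    return out


def noisefree_suppression_study(
    n_subjects: int = 12,
    seed: int = 0,
    protocol: ClampProtocol | None = None,
) -> dict:
    """Worst-case noise-free error (percentage points) of the suppression
    and stimulation percentages across heterogeneous simulated subjects."""
    protocol = protocol or ClampProtocol()
    rng = np.random.default_rng(seed)
    spec = default_cohort_spec()
    worst = {"egp_supp": 0.0, "rd_increase": 0.0, "glycerol_supp": 0.0}
    for subject, truth, _ in _alternating_draws(rng, spec, n_subjects):
        res = simulate_subject(subject, protocol, truth, noise=NoiseModel.none(), rng=rng)
        row = analyze_subject(subject, res.series, protocol)
        t_egp = 100.0 * (res.truth_window_mean("egp", protocol.low_window)
                         / truth.basal_egp - 1.0)
        t_rd = 100.0 * (res.truth_window_mean("rd", protocol.high_window)
                        / truth.basal_egp - 1.0)
        t_gly = 100.0 * (res.truth_window_mean("glycerol_ra", protocol.low_window)
                         / truth.basal_glycerol_ra - 1.0)
        worst["egp_supp"] = max(worst["egp_supp"], abs(row["pct_supp_egp"] - t_egp))
        worst["rd_increase"] = max(worst["rd_increase"], abs(row["pct_increase_rd"] - t_rd))
        worst["glycerol_supp"] = max(
            worst["glycerol_supp"], abs(row["pct_supp_glycerol_ra"] - t_gly)
        )
    worst["n_subjects"] = n_subjects
    return worst


def type_i_calibration(
    n_reps: int = 2000,
    seed: int = 0,
    n_a: int = 18,
    n_b: int = 15,
    alpha: float = 0.05,
) -> dict:
    """False-positive rate of the full route-then-test procedure on null
    cohorts (both groups drawn from the same distribution)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        a = rng.normal(10.0, 2.0, n_a)
        b = rng.normal(10.0, 2.0, n_b)
        hits += compare_variable("null", a, b, alpha=alpha).p < alpha
    return {"rate": hits / n_reps, "n_reps": n_reps}
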