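"""Optimal-segments smoothing of clamp concentration and enrichment curves.

Tracer calculations need smooth values and first derivatives of plasma
concentration C(t) and enrichment Z(t) at arbitrary times between samples.
We fit a continuous piecewise polynomial (degree <= 2 by default) whose
breakpoints are restricted to interior sample times, choosing the
breakpoint set by exhaustive search minimising a BIC-penalised weighted
sum of squared errors. The fit is linear in a truncated-power basis

    1, t, ..., t^d, (t - k_j)_+^1, ..., (t - k_j)_+^d   for each knot k_j,

which spans exactly the continuous (C0) piecewise polynomials of degree d
with the chosen knots: value is continuous across a breakpoint while slope
and curvature may jump, so genuine kinks (insulin-stage transitions) are
representable. The search is deterministic for fixed input.

Derivatives at interior breakpoints use the right-hand piece; at the final
point, the left-hand (only) piece.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = ["SmoothedCurve", "fit_optimal_segments"]

_EXACT_SSE = 1e-18  # below this the fit is treated as exact (log-SSE floor)


@dataclass(frozen=True)
class SmoothedCurve:
    """A fitted continuous piecewise-polynomial curve for one channel.

    Evaluation outside ``[t_min, t_max]`` raises; the clamp record ends at
    the last sample and extrapolated tracer slopes are meaningless.
    """

    knots: np.ndarray          # interior breakpoints, min
    coef: np.ndarray           # truncated-power basis coefficients
    degree: int
    t_min: float
    t_max: float
    residual_sd: float
    channel: str = ""
    t_shift: float = 0.0       # basis is built in shifted time for conditioning
    t_scale: float = 1.0

    def _design(self, t: np.ndarray, deriv: bool = False, side: str = "right") -> np.ndarray:
        u = (t - self.t_shift) / self.t_scale
        uk = (self.knots - self.t_shift) / self.t_scale
        cols = []
        for p in range(self.degree + 1):
            if not deriv:
                cols.append(u ** p)
            else:
                cols.append(p * u ** (p - 1) / self.t_scale if p >= 1 else np.zeros_like(u))
        for k in uk:
            d = u - k
            # at a breakpoint the default convention is the right piece;
            # side="left" evaluates the limit from below instead
            pos = d >= 0 if side == "right" else d > 0
            for p in range(1, self.degree + 1):
                if not deriv:
                    cols.append(np.where(pos, d ** p, 0.0))
                else:
                    cols.append(np.where(pos, p * d ** (p - 1) / self.t_scale, 0.0))
        return np.column_stack(cols)

    def _check_range(self, t: np.ndarray) -> None:
        tol = 1e-9 * max(1.0, abs(self.t_min), abs(self.t_max))
        if np.any(t < self.t_min - tol) or np.any(t > self.t_max + tol):
            raise ValueError(
                f"evaluation time outside fitted range "
                f"[{self.t_min}, {self.t_max}] for channel {self.channel!r}"
            )

    def value(self, t: float | np.ndarray) -> float | np.ndarray:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        self._check_range(t_arr)
        v = self._design(t_arr) @ self.coef
        return float(v[0]) if np.isscalar(t) or np.ndim(t) == 0 else v

    def derivative(self, t: float | np.ndarray, side: str = "right") -> float | np.ndarray:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        self._check_range(t_arr)
        d = self._design(t_arr, deriv=True, side=side) @ self.coef
        return float(d[0]) if np.isscalar(t) or np.ndim(t) == 0 else d

    def evaluate(self, t: float | np.ndarray, side: str = "right") -> tuple:
        """(value, d/dt value) at t; range-checked, never extrapolated.

        ``side`` picks the one-sided derivative when t is a breakpoint
        (values are continuous either way).
        """
        return self.value(t), self.derivative(t, side=side)

    @property
    def n_segments(self) -> int:
        return int(self.knots.size) + 1


def _fit_with_knots(
    t: np.ndarray, y: np.ndarray, w: np.ndarray, knots: np.ndarray,
    degree: int, t_shift: float, t_scale: float,
) -> tuple[np.ndarray, float, int]:
    """Weighted least squares in the truncated-power basis; returns
    (coefficients, weighted SSE, n_params)."""
    curve = SmoothedCurve(
        knots=knots, coef=np.zeros(1), degree=degree,
        t_min=t[0], t_max=t[-1], residual_sd=0.0,
        t_shift=t_shift, t_scale=t_scale,
    )
    X = curve._design(t)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ coef
    sse = float(np.sum(w * resid ** 2))
    return coef, sse, X.shape[1]


def fit_optimal_segments(
    t: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    max_segments: int = 4,
    degree: int = 2,
    penalty: float | None = None,
    min_points_per_segment: int = 2,
    channel: str = "",
) -> SmoothedCurve:
    """Fit a continuous piecewise polynomial with optimally placed breakpoints.

    Breakpoints are restricted to interior sample times; every subset of up
    to ``max_segments - 1`` of them (respecting ``min_points_per_segment``)
    is scored and the minimiser of

        n * log(SSE_w / n) + penalty(p) * p     (p = number of coefficients)

    is kept. By default the per-parameter penalty is the small-sample BIC
    ``log(n) * n / (n - p - 1)``, which guards against the free-knot
    search's tendency to overfit short series; passing a numeric
    ``penalty`` uses that constant per parameter instead. Exact fits
    (SSE ~ 0) are compared by parameter count alone. Deterministic for
    fixed input; ties broken toward fewer, earlier knots.

    Parameters
    ----------
    weights
        Per-point inverse-variance weights; uniform when omitted.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    t, y = t[ok], y[ok]
    if weights is None:
        w = np.ones_like(t)
    else:
        w = np.asarray(weights, dtype=float)[ok]
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    n = t.size
    if n < 4:
        raise ValueError(f"need >= 4 non-missing points to smooth, got {n}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    if t[-1] - t[0] <= 0:
        raise ValueError("degenerate time range")

    def penalty_at(p: int) -> float:
        if penalty is not None:
            return float(penalty)
        # small-sample BIC: inflate log(n) when p approaches n
        return float(np.log(n)) * n / max(n - p - 1, 1)

    t_shift, t_scale = float(t[0]), float(t[-1] - t[0])
    interior = t[1:-1]

    best = None  # (score, n_params, knot_tuple, coef, sse)
    max_knots = max(0, max_segments - 1)
    for k in range(0, max_knots + 1):
        for combo in combinations(range(interior.size), k):
            knots = interior[list(combo)]
            # enforce a minimum number of samples strictly inside each segment
            edges = np.concatenate([[t[0]], knots, [t[-1] + 1e-12]])
            counts = np.histogram(t, bins=edges)[0]
            if np.any(counts < min_points_per_segment):
                continue
            n_params = (degree + 1) + degree * k
            if n_params > n:
                continue
            coef, sse, p = _fit_with_knots(t, y, w, knots, degree, t_shift, t_scale)
            if sse < _EXACT_SSE * max(1.0, float(np.sum(w * y ** 2))):
                score = -np.inf  # exact: rank by parameter count via tie-break
            else:
                score = n * np.log(sse / n) + penalty_at(p) * p
            key = (score, p, combo)
            if best is None or key < (best[0], best[1], best[2]):
                best = (score, p, combo, coef, sse, knots)

    if best is None:
        raise ValueError("no admissible segmentation (too few points per segment)")
    _, p, _, coef, sse, knots = best
    dof = max(n - p, 1)
    return SmoothedCurve(
        knots=np.asarray(knots, dtype=float),
        coef=coef,
        degree=degree,
        t_min=float(t[0]),
        t_max=float(t[-1]),
        residual_sd=float(np.sqrt(sse / dof)),
        channel=channel,
        t_shift=t_shift,
        t_scale=t_scale,
    )
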