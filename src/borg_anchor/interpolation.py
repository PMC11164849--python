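"""Monotone cubic Hermite interpolation of RPE over blood lactate.

Each participant contributes a handful of (lactate, RPE) pairs, one per
completed stage.  A shape-preserving C¹ interpolant links them so that the
ordinal RPE can be read off at lactate concentrations that were never
measured directly (2, 3, 4 mmol/l and the individual LT2 anchor).

The knot slopes follow Fritsch & Carlson's construction: initial slopes
are the averages of adjacent secants (one-sided at the endpoints); on any
interval with a flat secant both bracketing slopes are zeroed; and where
the normalised slopes (α, β) = (m_i, m_{i+1})/d_i leave the monotonicity
region — 2α+β > 3, α+2β > 3 and 3α(α+β−2) < (2α+β−3)² — they are pulled
back onto the circle of radius 3 by τ = 3/√(α²+β²).  This is exactly the
rule implemented by R's ``splinefun(method = "monoH.FC")``, so for
monotone data the interpolant is monotone on every interval.

Anchors outside the observed lactate range are reported missing rather
than extrapolated: a clamped cubic evaluated beyond the data would
fabricate measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort_io import CPXRecord
from .errors import DomainError, OutOfRangeError
from .thresholds import ThresholdResult

__all__ = [
    "MonotoneSpline",
    "AnchorRPE",
    "increasing_bla_filter",
    "fritsch_carlson_slopes",
    "build_spline",
    "eval_spline",
    "anchors_for_record",
    "round_half_up",
    "FIXED_ANCHORS",
    "MIN_PAIRS",
]

FIXED_ANCHORS = (2.0, 3.0, 4.0)  # mmol/l
MIN_PAIRS = 3  # minimal number of (lactate, RPE) pairs for an interpolant
RPE_MIN, RPE_MAX = 6, 20


def increasing_bla_filter(
    pairs: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Running-maximum subsequence: keep a pair iff its lactate strictly
    exceeds every previously kept lactate.  Output abscissae are strictly
    increasing, as the interpolation requires."""
    kept: list[tuple[float, float]] = []
    best = -math.inf
    for bla, rpe in pairs:
        if bla > best:
            kept.append((bla, rpe))
            best = bla
    return kept


def _in_monotone_region(alpha: float, beta: float) -> bool:
    """Fritsch-Carlson monotonicity region for normalised slopes
    (alpha, beta) = (m_i, m_{i+1}) / d_i, both non-negative."""
    a2b3 = 2.0 * alpha + beta - 3.0
    ab23 = alpha + 2.0 * beta - 3.0
    if a2b3 <= 0.0 or ab23 <= 0.0:
        return True
    # both positive implies alpha + beta > 2; phi >= 0 closes the region
    return alpha * (a2b3 + ab23) >= a2b3 * a2b3


def fritsch_carlson_slopes(x, y) -> np.ndarray:
    """Knot slopes of the Fritsch-Carlson monotone Hermite interpolant.

    The main sweep is the classic one: where the normalised slopes leave
    the monotonicity region they are projected onto the circle of radius
    3 by tau = 3/sqrt(alpha^2 + beta^2).  Because the sweep runs
    interval-by-interval, a later flat-secant zeroing can shrink a slope
    that an earlier interval was already checked against, stranding that
    interval outside the region; a fixpoint pass re-projects any such
    interval.  The pass only fires in those degenerate configurations
    (projections shrink slopes, so it terminates), and elsewhere the
    slopes equal the classic construction exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 2:
        raise DomainError("need at least two knots with matching y values")
    if np.any(np.diff(x) <= 0):
        raise DomainError("knot abscissae must be strictly increasing")

    d = np.diff(y) / np.diff(x)  # secants
    m = np.empty(n)
    m[0] = d[0]
    m[-1] = d[-1]
    if n > 2:
        m[1:-1] = (d[:-1] + d[1:]) / 2.0

    for i in range(n - 1):
        if d[i] == 0.0:
            m[i] = m[i + 1] = 0.0
        else:
            alpha = m[i] / d[i]
            beta = m[i + 1] / d[i]
            if not _in_monotone_region(alpha, beta):
                tau = 3.0 * d[i] / math.sqrt(alpha * alpha + beta * beta)
                m[i] = tau * alpha
                m[i + 1] = tau * beta

    for _ in range(n):  # order-robustness fixpoint (degenerate inputs only)
        changed = False
        for i in range(n - 1):
            if d[i] == 0.0:
                continue
            alpha = m[i] / d[i]
            beta = m[i + 1] / d[i]
            if alpha < 0.0 or beta < 0.0:
                continue  # locally non-monotone data: nothing to preserve
            if not _in_monotone_region(alpha, beta):
                tau = 3.0 * d[i] / math.sqrt(alpha * alpha + beta * beta)
                m[i] = tau * alpha
                m[i + 1] = tau * beta
                changed = True
        if not changed:
            break
    return m


@dataclass(frozen=True)
class MonotoneSpline:
    """A C¹ piecewise-cubic Hermite interpolant with Fritsch-Carlson slopes."""

    x: np.ndarray
    y: np.ndarray
    m: np.ndarray

    def __call__(self, q):
        return eval_spline(self, q)

    @property
    def range(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])


def build_spline(pairs, min_knots: int = MIN_PAIRS) -> MonotoneSpline:
    """Interpolant through strictly-increasing (lactate, RPE) knots."""
    if len(pairs) < min_knots:
        raise DomainError(f"need at least {min_knots} knots, got {len(pairs)}")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    return MonotoneSpline(x=x, y=y, m=fritsch_carlson_slopes(x, y))


def eval_spline(spline: MonotoneSpline, q):
    """Evaluate the interpolant at ``q`` (scalar or array) inside the knot
    range; raises :class:`OutOfRangeError` for queries outside it."""
    x, y, m = spline.x, spline.y, spline.m
    q_arr = np.asarray(q, dtype=float)
    scalar = q_arr.ndim == 0
    q_arr = np.atleast_1d(q_arr)
    if np.any(q_arr < x[0]) or np.any(q_arr > x[-1]):
        raise OutOfRangeError(
            f"query outside knot range [{x[0]}, {x[-1]}] (no extrapolation)"
        )
    i = np.clip(np.searchsorted(x, q_arr, side="right") - 1, 0, len(x) - 2)
    h = x[i + 1] - x[i]
    t = (q_arr - x[i]) / h
    t2 = t * t
    t3 = t2 * t
    h00 = 2.0 * t3 - 3.0 * t2 + 1.0
    h10 = t3 - 2.0 * t2 + t
    h01 = -2.0 * t3 + 3.0 * t2
    h11 = t3 - t2
    val = h00 * y[i] + h10 * h * m[i] + h01 * y[i + 1] + h11 * h * m[i + 1]
    return float(val[0]) if scalar else val


def round_half_up(value: float) -> int:
    """Round to nearest integer with ties away from the floor (14.5 -> 15)."""
    return int(math.floor(value + 0.5))


def _round(value: float, rounding: str) -> int:
    if rounding == "half-up":
        return round_half_up(value)
    if rounding == "half-even":
        return int(round(value))
    raise ValueError(f"unknown rounding {rounding!r}")


@dataclass
class AnchorRPE:
    """Ordinal RPE (or missing) at the four lactate anchors of one record."""

    participant_id: str
    rpe_2: int | None = None
    rpe_3: int | None = None
    rpe_4: int | None = None
    rpe_lt2: int | None = None
    flags: dict[str, str] = field(default_factory=dict)

    def value(self, anchor: str) -> int | None:
        return getattr(self, f"rpe_{anchor}")


def anchors_for_record(
    record: CPXRecord,
    thresholds: ThresholdResult,
    rounding: str = "half-up",
) -> AnchorRPE | None:
    """Ordinal RPE at 2, 3, 4 mmol/l and LT2 for one record.

    Pairs with either measurement missing are dropped, the running-maximum
    lactate filter is applied, and a record with fewer than three usable
    pairs is skipped (returns ``None``; callers log and count it).  Each
    anchor inside the knot range yields the rounded spline prediction
    clipped to the Borg 6-20 scale; anchors outside the range, or LT2 when
    LT1 was not detected, are missing with a reason in ``flags``.
    """
    pairs = [
        (st.bla, float(st.rpe))
        for st in record.stages
        if st.bla is not None and st.rpe is not None
    ]
    pairs = increasing_bla_filter(pairs)
    if len(pairs) < MIN_PAIRS:
        return None
    spline = build_spline(pairs)
    lo, hi = spline.range

    result = AnchorRPE(participant_id=record.participant_id)
    targets = {
        "2": FIXED_ANCHORS[0],
        "3": FIXED_ANCHORS[1],
        "4": FIXED_ANCHORS[2],
        "lt2": thresholds.lt2_bla,
    }
    for name, conc in targets.items():
        if conc is None:
            result.flags[name] = "lt2_undefined"
            continue
        if conc < lo or conc > hi:
            result.flags[name] = "out_of_range"
            continue
        pred = eval_spline(spline, conc)
        setattr(result, f"rpe_{name}", min(max(_round(pred, rounding), RPE_MIN), RPE_MAX))
    return result
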