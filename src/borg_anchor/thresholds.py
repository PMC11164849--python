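"""Lactate-threshold detection on graded exercise tests.

The individual anaerobic threshold used here is the Dickhuth-style offset
construction: LT1 is the first sustained rise of blood lactate above the
baseline level, and LT2 is the lactate concentration at LT1 plus
1.5 mmol/l.  LT2 is a *concentration anchor* on the individual's
lactate-RPE curve, not a workload.

The "first rise" needs a tolerance: a stage counts as risen only when its
lactate exceeds baseline by more than ``delta`` (default 0.2 mmol/l, the
conventional minimal rise used with earlobe capillary sampling) and the
rise is sustained, i.e. the next measured stage does not fall back below
it.  The sustained-rise guard keeps a single noisy sample from triggering
LT1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort_io import CPXRecord
from .errors import ThresholdUndetectable

__all__ = [
    "ThresholdResult",
    "estimate_baseline",
    "detect_lt1",
    "lt2_anchor",
    "compute_thresholds",
    "DEFAULT_DELTA",
    "LT2_OFFSET",
]

DEFAULT_DELTA = 0.2  # mmol/l, minimal rise over baseline that counts as LT1
LT2_OFFSET = 1.5  # mmol/l, LT2 = lactate at LT1 + 1.5


@dataclass(frozen=True)
class ThresholdResult:
    """Baseline, LT1 and the LT2 anchor concentration for one record."""

    participant_id: str
    baseline_bla: float
    lt1_stage: int | None
    lt1_bla: float | None
    lt2_bla: float | None
    delta: float = DEFAULT_DELTA

    def __post_init__(self):
        if self.lt1_bla is not None:
            assert self.lt2_bla == self.lt1_bla + LT2_OFFSET
            assert self.lt1_stage is not None and self.lt1_stage >= 1


def estimate_baseline(record: CPXRecord, mode: str = "min") -> float:
    """Baseline lactate for a record.

    ``mode="min"`` (default): the minimum of the resting sample and the
    first stage's lactate — protects against a warm-up-elevated resting
    sample.  ``mode="resting"``: the resting sample alone, falling back to
    the first stage only when resting lactate was not measured.
    """
    first_stage = next((st.bla for st in record.stages if st.bla is not None), None)
    if record.resting_bla is None and first_stage is None:
        raise ThresholdUndetectable(
            f"record {record.participant_id}: no blood lactate measurements"
        )
    if mode == "resting":
        value = record.resting_bla if record.resting_bla is not None else first_stage
    elif mode == "min":
        value = min(v for v in (record.resting_bla, first_stage) if v is not None)
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    if value <= 0:
        raise ThresholdUndetectable(
            f"record {record.participant_id}: non-positive baseline {value}"
        )
    return value


def detect_lt1(
    record: CPXRecord, baseline: float, delta: float = DEFAULT_DELTA
) -> tuple[int, float] | None:
    """First sustained rise of stage lactate above ``baseline + delta``.

    Returns ``(stage_index, lactate)`` of the first stage whose lactate
    exceeds baseline + delta and is either the last measured stage or not
    followed by a drop; ``None`` when no stage qualifies (flat curve).
    """
    seq = [(st.stage_index, st.bla) for st in record.stages if st.bla is not None]
    for j, (stage_index, bla) in enumerate(seq):
        if bla > baseline + delta and (j == len(seq) - 1 or seq[j + 1][1] >= bla):
            return stage_index, bla
    return None


def lt2_anchor(lt1_bla: float | None) -> float | None:
    """LT2 anchor concentration: lactate at LT1 + 1.5 mmol/l (exact)."""
    if lt1_bla is None:
        return None
    return lt1_bla + LT2_OFFSET


def compute_thresholds(
    record: CPXRecord, delta: float = DEFAULT_DELTA, baseline_mode: str = "min"
) -> ThresholdResult:
    """Baseline, LT1 and LT2 for one record; LT1/LT2 may be missing."""
    baseline = estimate_baseline(record, mode=baseline_mode)
    hit = detect_lt1(record, baseline, delta=delta)
    if hit is None:
        return ThresholdResult(record.participant_id, baseline, None, None, None, delta)
    stage, bla = hit
    return ThresholdResult(record.participant_id, baseline, stage, bla, lt2_anchor(bla), delta)
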