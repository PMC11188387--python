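"""Forecast swim race times and compare them with standing world records."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_model import (
    DEFAULT_CONSTANTS,
    AthleteProfile,
    InfeasibleParametersError,
    ModelConstants,
    PhysioParams,
    SwimParams,
    solve_swim_time,
)
from .fitting import SWIM_DISTANCES

__all__ = ["RecordComparison", "predict_times", "compare_to_records", "summarize_comparisons"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecordComparison:
    """One predicted time set against the standing world record."""

    sex: str
    distance: float  # m
    wr_time: float  # s
    predicted_time: float  # s
    signed_pct_diff: float  # 100 * (predicted - wr) / wr
    broken: bool  # predicted would beat the record
    year_subset: str = "all"  # "all" or "olympic"

    def __post_init__(self) -> None:
        if self.broken != (self.signed_pct_diff < 0):
            raise ValueError("broken flag inconsistent with signed_pct_diff")


def predict_times(
    physio: PhysioParams,
    swim: SwimParams,
    profile: AthleteProfile,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    distances: Sequence[float] = SWIM_DISTANCES,
) -> np.ndarray:
    """Solve the supply-demand balance for each distance, in order.

    Returns an array of durations (s), one per distance; strictly increasing
    in distance because longer races demand more time at lower speed.
    """
    times = []
    for d in distances:
        try:
            times.append(solve_swim_time(d, physio, swim, profile, constants))
        except InfeasibleParametersError as err:
            raise InfeasibleParametersError(
                f"prediction failed at distance {d:g} m: {err}"
            ) from err
    return np.asarray(times)


def compare_to_records(
    predictions: Mapping[float, float],
    wr_table: Mapping[float, float],
    sex: str = "",
    year_subset: str = "all",
) -> list[RecordComparison]:
    """Pair each predicted time with the standing record at that distance.

    ``predictions`` and ``wr_table`` map distance (m) -> time (s) and must
    cover identical distance sets.  The comparison is pure arithmetic on the
    inputs: signed percent difference 100*(predicted - wr)/wr, negative
    meaning the record is predicted to fall.
    """
    if set(predictions) != set(wr_table):
        raise ValueError(
            f"distance mismatch: predictions {sorted(predictions)} vs "
            f"records {sorted(wr_table)}"
        )
    out = []
    for d in sorted(predictions):
        pred, wr = float(predictions[d]), float(wr_table[d])
        pct = 100.0 * (pred - wr) / wr
        out.append(
            RecordComparison(
                sex=sex,
                distance=float(d),
                wr_time=wr,
                predicted_time=pred,
                signed_pct_diff=pct,
                broken=pct < 0,
                year_subset=year_subset,
            )
        )
    n_broken = sum(c.broken for c in out)
    logger.info(
        "%s/%s: %d of %d records predicted broken", sex or "?", year_subset,
        n_broken, len(out),
    )
    return out


def summarize_comparisons(
    comparisons: Sequence[RecordComparison], ddof: int = 0
) -> dict:
    """Count of records predicted broken and mean +/- sd of percent differences.

    ``ddof=0`` (population standard deviation) by default.
    """
    pct = np.array([c.signed_pct_diff for c in comparisons])
    n_broken = int(np.sum(pct < 0))
    assert n_broken == sum(c.broken for c in comparisons)
    return {
        "n": len(comparisons),
        "n_broken": n_broken,
        "mean_pct_diff": float(pct.mean()),
        "sd_pct_diff": float(pct.std(ddof=ddof)),
    }
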