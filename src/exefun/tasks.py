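"""Task-level executive measures.

Eight measures are extracted from six tasks: Stroop interference
(inhibition), 2-back correct responses (updating), plus–minus shifting
cost, verbal fluency total (shifting), WCST perseverative-error percentage
(flexibility) and non-perseverative error count (inhibition), and the two
RNG summary scores from :mod:`exefun.sequences`. WCST scores are accepted
as given (card-by-card administration is out of scope), as are the
per-condition fluency counts (repetitions and errors already excluded
upstream).
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .sequences import rng_inhibition_score, rng_updating_score

__all__ = [
    "MEASURE_COLUMNS",
    "MEASURE_ORIENTATION",
    "FLUENCY_CONDITIONS",
    "stroop_interference",
    "plus_minus_cost",
    "fluency_total",
    "assemble_measures",
]

log = logging.getLogger(__name__)

FLUENCY_CONDITIONS = [
    "fluency_p",
    "fluency_r",
    "fluency_v",
    "fluency_animals",
    "fluency_fruits",
    "fluency_furniture",
]

#: The eight executive measures, in composite-ingredient order.
MEASURE_COLUMNS = [
    "rng_inhibition",
    "rng_updating",
    "stroop_interference",
    "nback_correct",
    "plus_minus_cost",
    "fluency_total",
    "wcst_perseverative_pct",
    "wcst_nonperseverative_errors",
]

#: +1 where a high raw score reflects good performance, −1 where it
#: reflects poor performance. These flags carry the minus signs of the
#: composite formulas as data.
MEASURE_ORIENTATION = {
    "rng_inhibition": +1,
    "rng_updating": +1,
    "stroop_interference": -1,
    "nback_correct": +1,
    "plus_minus_cost": -1,
    "fluency_total": +1,
    "wcst_perseverative_pct": -1,
    "wcst_nonperseverative_errors": -1,
}


def stroop_interference(color: float, colorword: float) -> float:
    """(color − colorword) / color from the two 45-s naming counts.

    Low values indicate good inhibition; negative values (faster in the
    interference condition) are legitimate and retained.
    """
    if color <= 0:
        raise ValueError("stroop color-naming count must be positive")
    return (color - colorword) / color


def plus_minus_cost(time_a: float, time_b: float, time_c: float) -> float:
    """Shifting cost in seconds: C − (A + B)/2.

    A is the all-addition list, B all-subtraction, C alternating; higher
    cost means lower shifting capacity.
    """
    if min(time_a, time_b, time_c) <= 0:
        raise ValueError("subtest times must be positive")
    return time_c - (time_a + time_b) / 2.0


def fluency_total(counts: Sequence[float]) -> float:
    """Sum of the six fluency condition counts (3 phonemic + 3 semantic)."""
    counts = list(counts)
    if len(counts) != 6:
        raise ValueError(f"expected 6 fluency conditions, got {len(counts)}")
    if any(c < 0 for c in counts):
        raise ValueError("fluency counts must be non-negative")
    return float(sum(counts))


def assemble_measures(
    raw: pd.DataFrame,
    rng_indices: pd.DataFrame,
    *,
    rng_reference_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Build the eight-measure table from raw task inputs and RNG indices.

    ``raw`` has one row per participant with the RawTaskInputs columns
    (stroop_*_correct, nback_correct, pm_time_a/b/c, the six fluency
    conditions, wcst_perseverative_pct, wcst_nonperseverative_errors).
    ``rng_indices`` is the output of :func:`exefun.sequences.score_sequences`.

    ``rng_reference_ids`` selects the participants whose index
    distribution standardizes the two RNG scores (the younger group under
    the younger-reference scheme); default is everyone. Missing cells stay
    NaN and are flagged in ``<measure>_missing`` columns for downstream
    group-mean imputation; a participant missing more than one measure is
    logged as a warning but still emitted.
    """
    raw = raw.copy()
    raw["participant_id"] = raw["participant_id"].astype(str)
    idx = rng_indices.copy()
    idx["participant_id"] = idx["participant_id"].astype(str)
    idx = idx.set_index("participant_id")
    if rng_reference_ids is None:
        reference = idx
    else:
        ref_ids = [str(i) for i in rng_reference_ids]
        reference = idx.loc[idx.index.intersection(ref_ids)]

    rng_inh = rng_inhibition_score(idx, reference)
    rng_upd = rng_updating_score(idx, reference)

    out = pd.DataFrame({"participant_id": raw["participant_id"]})
    out["rng_inhibition"] = raw["participant_id"].map(rng_inh)
    out["rng_updating"] = raw["participant_id"].map(rng_upd)

    with np.errstate(divide="ignore", invalid="ignore"):
        color = raw["stroop_color_correct"].astype(float)
        out["stroop_interference"] = np.where(
            color > 0,
            (color - raw["stroop_colorword_correct"].astype(float)) / color,
            np.nan,
        )
    out["nback_correct"] = raw["nback_correct"].astype(float)
    out["plus_minus_cost"] = (
        raw["pm_time_c"].astype(float)
        - (raw["pm_time_a"].astype(float) + raw["pm_time_b"].astype(float)) / 2.0
    )
    out["fluency_total"] = raw[FLUENCY_CONDITIONS].astype(float).sum(axis=1, min_count=6)
    out["wcst_perseverative_pct"] = raw["wcst_perseverative_pct"].astype(float)
    out["wcst_nonperseverative_errors"] = raw["wcst_nonperseverative_errors"].astype(float)

    for col in MEASURE_COLUMNS:
        out[f"{col}_missing"] = out[col].isna()
    n_missing = out[[f"{c}_missing" for c in MEASURE_COLUMNS]].sum(axis=1)
    for pid, k in zip(out["participant_id"], n_missing):
        if k > 1:
            log.warning("participant %s is missing %d of 8 measures", pid, k)
    return out
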