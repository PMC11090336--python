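"""Composite executive z-scores under two referencing schemes.

Three steps build the inhibition / shifting / updating composites from the
eight task measures:

1. each measure is z-scored against a reference sample;
2. the relevant z-scores are averaged with signs taken from the measure
   orientation registry, so every composite reads "higher = better":

   * inhibition = (z RNG-inhibition − z Stroop − z WCST-nonperseverative)/3
   * shifting   = (−z WCST-error − z plus–minus + z fluency)/3
   * updating   = (z 2-back + z RNG-updating)/2

3. each mean composite is z-scored again against the same reference.

Two schemes fix the reference sample at steps 1 and 3: the
``younger_reference`` scheme standardizes on the younger group (the
younger composites then have mean 0 / SD 1 and older scores read as
deviations from the young norm); ``pooled`` standardizes on the whole
sample.

The WCST ingredient of the shifting composite is configurable: the
``corrected`` default uses the perseverative-error percentage (the
flexibility score), the ``literal`` variant uses the non-perseverative
error count.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .sequences import DegenerateScaleError
from .tasks import MEASURE_COLUMNS, MEASURE_ORIENTATION

__all__ = [
    "SCHEMES",
    "composite_definitions",
    "impute_group_mean",
    "zscore",
    "composite_inhibition",
    "composite_shifting",
    "composite_updating",
    "finalize_composites",
    "build_composites",
]

SCHEMES = ("younger_reference", "pooled")

COMPOSITE_NAMES = ("inhibition", "shifting", "updating")


def composite_definitions(shifting_wcst: str = "corrected") -> dict[str, list[str]]:
    """Ingredient measures per composite.

    Signs are not stored here: each ingredient enters with the sign given
    by its orientation flag (:data:`exefun.tasks.MEASURE_ORIENTATION`), so
    a low-is-good measure is automatically subtracted.
    """
    if shifting_wcst == "corrected":
        wcst_shift = "wcst_perseverative_pct"
    elif shifting_wcst == "literal":
        wcst_shift = "wcst_nonperseverative_errors"
    else:
        raise ValueError(f"shifting_wcst must be 'corrected' or 'literal', got {shifting_wcst!r}")
    return {
        "inhibition": ["rng_inhibition", "stroop_interference", "wcst_nonperseverative_errors"],
        "shifting": [wcst_shift, "plus_minus_cost", "fluency_total"],
        "updating": ["nback_correct", "rng_updating"],
    }


def impute_group_mean(
    measures: pd.DataFrame,
    groups: pd.Series,
    columns: Sequence[str] = MEASURE_COLUMNS,
) -> tuple[pd.DataFrame, int]:
    """Replace missing measure cells by the mean of the participant's group.

    ``groups`` maps each row to its age×genotype cell. Returns the
    completed table and the number of imputed cells. A cell whose whole
    group is missing on that measure cannot be imputed and raises.
    """
    out = measures.copy()
    groups = groups.reindex(out.index)
    n_imputed = 0
    for col in columns:
        missing = out[col].isna()
        if not missing.any():
            continue
        group_means = out.groupby(groups)[col].transform("mean")
        if group_means[missing].isna().any():
            bad = sorted(set(groups[missing & group_means.isna()]))
            raise ValueError(f"group(s) {bad} entirely missing on {col}: unimputable")
        out.loc[missing, col] = group_means[missing]
        n_imputed += int(missing.sum())
    return out, n_imputed


def zscore(values: pd.Series, reference: pd.Series) -> pd.Series:
    """(x − mean(ref)) / sd(ref), with the n−1 SD convention."""
    ref = pd.to_numeric(reference, errors="coerce").dropna()
    sd = ref.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateScaleError(
            f"reference sample for {values.name!r} has zero standard deviation"
        )
    return (pd.to_numeric(values, errors="coerce") - ref.mean()) / sd


def _oriented_mean(z: pd.DataFrame, ingredients: Sequence[str]) -> pd.Series:
    signed = [MEASURE_ORIENTATION[m] * z[m] for m in ingredients]
    return sum(signed) / len(ingredients)


def composite_inhibition(z: pd.DataFrame) -> pd.Series:
    """Mean inhibition composite from the step-1 z-scores."""
    return _oriented_mean(z, composite_definitions()["inhibition"])


def composite_shifting(z: pd.DataFrame, shifting_wcst: str = "corrected") -> pd.Series:
    """Mean shifting composite from the step-1 z-scores."""
    return _oriented_mean(z, composite_definitions(shifting_wcst)["shifting"])


def composite_updating(z: pd.DataFrame) -> pd.Series:
    """Mean updating composite from the step-1 z-scores."""
    return _oriented_mean(z, composite_definitions()["updating"])


def finalize_composites(
    mean_composites: pd.DataFrame, reference_index: pd.Index
) -> pd.DataFrame:
    """Step 3: re-standardize each mean composite against the reference rows."""
    out = mean_composites.copy()
    for name in COMPOSITE_NAMES:
        out[name] = zscore(out[name], out.loc[reference_index, name])
    return out


def build_composites(
    measures: pd.DataFrame,
    participants: pd.DataFrame,
    scheme: str = "younger_reference",
    *,
    shifting_wcst: str = "corrected",
    impute: bool = True,
) -> pd.DataFrame:
    """Full three-step composite construction for one cohort.

    ``measures`` is the eight-measure table (``participant_id`` +
    :data:`~exefun.tasks.MEASURE_COLUMNS`); ``participants`` supplies
    ``age_group`` ('younger'/'older') and ``genotype`` for the 6-cell
    grouping used by the imputation and for the scheme reference.
    Returns ``participant_id, scheme, inhibition, shifting, updating``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    meas = measures.copy()
    meas["participant_id"] = meas["participant_id"].astype(str)
    part = participants.copy()
    part["participant_id"] = part["participant_id"].astype(str)
    part = part.set_index("participant_id")
    meas = meas.set_index("participant_id")
    missing_ids = meas.index.difference(part.index)
    if len(missing_ids):
        raise ValueError(f"participants table lacks rows for {list(missing_ids)[:5]}")

    groups = part.loc[meas.index, "age_group"].str.cat(
        part.loc[meas.index, "genotype"], sep="/"
    )
    if impute:
        meas, _ = impute_group_mean(meas, groups)
    incomplete = meas[list(MEASURE_COLUMNS)].isna().any(axis=1)
    if incomplete.any():
        raise ValueError(
            f"measures still missing after imputation for {list(meas.index[incomplete])[:5]}"
        )

    if scheme == "younger_reference":
        ref_index = meas.index[part.loc[meas.index, "age_group"] == "younger"]
    else:
        ref_index = meas.index

    z = pd.DataFrame(index=meas.index)
    for col in MEASURE_COLUMNS:
        z[col] = zscore(meas[col], meas.loc[ref_index, col])

    mean_comp = pd.DataFrame(
        {
            "inhibition": composite_inhibition(z),
            "shifting": composite_shifting(z, shifting_wcst),
            "updating": composite_updating(z),
        },
        index=meas.index,
    )
    final = finalize_composites(mean_comp, ref_index)
    final.insert(0, "scheme", scheme)
    return final.reset_index().rename(columns={"index": "participant_id"})
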