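"""Randomness indices for the random number generation (RNG) task.

Participants produce a paced sequence of digits 1..9 that is meant to be
"random"; systematic departures from randomness index executive control.
This module computes the six classical order statistics of such sequences —
Turning Point Index, Adjacency, Runs variability, Redundancy, Coupon and
Mean Repetition Gap — together with the two executive summary scores built
from them:

* inhibition  = (z(TPI) − z(Adjacency) + z(Runs)) / 3
* updating    = (−z(Redundancy) − z(Coupon) + z(MRG)) / 3

where z is taken against a caller-supplied reference sample, so the scores
are scale-free and the referencing scheme (younger group vs whole sample)
stays a downstream decision.

Conventions that the underlying literature leaves open are explicit keyword
arguments: the expected-turning-point count uses the realized sequence
length by default (``expected_n``), the repetition gap counts positional
distance (immediate repeat = 1) unless ``mrg_convention="intervening"``.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DigitSequence",
    "RNGIndices",
    "InvalidSequenceError",
    "UndefinedIndexError",
    "DegenerateScaleError",
    "turning_points",
    "expected_turning_points",
    "tpi",
    "adjacency",
    "runs_index",
    "redundancy",
    "coupon",
    "mean_repetition_gap",
    "compute_indices",
    "score_sequences",
    "rng_inhibition_score",
    "rng_updating_score",
    "read_sequences_csv",
]

INDEX_COLUMNS = ["tpi", "adjacency", "runs", "redundancy", "coupon", "mrg"]


class InvalidSequenceError(ValueError):
    """Sequence violates a precondition (too short, out-of-alphabet digit)."""


class UndefinedIndexError(ValueError):
    """Index undefined for this sequence (e.g. no repeats, <3 turning points)."""


class DegenerateScaleError(ValueError):
    """A z-score reference sample has zero standard deviation."""


@dataclass(frozen=True)
class DigitSequence:
    """A participant's retained (correct) responses, 1-based positions.

    ``alphabet`` is the number of response alternatives; digits must lie in
    ``1..alphabet``. ``n_errors`` counts discarded erroneous responses —
    they are excluded before scoring and only bookkept here.
    """

    participant_id: str
    responses: tuple[int, ...]
    n_errors: int = 0
    alphabet: int = 9

    def __post_init__(self) -> None:
        object.__setattr__(self, "responses", tuple(int(r) for r in self.responses))
        if self.n_errors < 0:
            raise InvalidSequenceError("n_errors must be non-negative")
        if self.alphabet < 2:
            raise InvalidSequenceError("alphabet must have at least two symbols")
        for r in self.responses:
            if not 1 <= r <= self.alphabet:
                raise InvalidSequenceError(
                    f"response {r} outside alphabet 1..{self.alphabet}"
                )

    def __len__(self) -> int:
        return len(self.responses)


@dataclass(frozen=True)
class RNGIndices:
    """The six randomness indices for one sequence.

    ``runs`` and ``mrg`` are NaN when undefined (fewer than three turning
    points / no repeated digit); downstream imputation handles them like any
    other missing measure. ``coupon_complete`` records whether at least one
    full pass through the alphabet was observed — when False, ``coupon`` is
    the censored value (the sequence length).
    """

    participant_id: str
    tpi: float
    adjacency: float
    runs: float
    redundancy: float
    coupon: float
    mrg: float
    coupon_complete: bool
    n_responses: int


def _as_responses(seq: DigitSequence | Sequence[int]) -> tuple[np.ndarray, int]:
    if isinstance(seq, DigitSequence):
        return np.asarray(seq.responses, dtype=np.int64), seq.alphabet
    arr = np.asarray(list(seq), dtype=np.int64)
    return arr, 9


# ---------------------------------------------------------------------------
# the six indices
# ---------------------------------------------------------------------------

def turning_points(seq: DigitSequence | Sequence[int]) -> list[int]:
    """1-based interior positions where the sequence turns.

    A pair direction is the sign of the step between consecutive responses;
    ties (zero steps) carry the last non-zero direction forward, so a
    plateau counts at most one turn, at its far end. Position ``i`` is a
    turning point when the (carried) direction of pair ``i`` reverses the
    previous non-zero direction.
    """
    r, _ = _as_responses(seq)
    if r.size < 3:
        raise InvalidSequenceError("turning points need at least 3 responses")
    steps = np.sign(np.diff(r))
    points: list[int] = []
    last = 0
    for i, s in enumerate(steps, start=1):  # pair i joins positions i, i+1
        if s == 0:
            continue
        if last != 0 and s != last:
            points.append(i)
        last = s
    return points


def expected_turning_points(n: int, alphabet: int | None = 9) -> float:
    """Null expectation of the turning-point count for length ``n``.

    For continuously distributed iid responses the classical value is
    (2/3)(n−2). Digits from a finite alphabet tie with probability 1/A,
    and under the carry-forward tie rule the exact iid-uniform expectation
    becomes

        E[T] = (2A−1)/(3(A−1)) · ((n−1)(A−1)/A − 1),

    which recovers (2/3)(n−2) as A → ∞. ``alphabet=None`` selects the
    continuous form.
    """
    if alphabet is None:
        return (2.0 / 3.0) * (n - 2)
    a = alphabet
    return (2 * a - 1) / (3.0 * (a - 1)) * ((n - 1) * (a - 1) / a - 1)


def tpi(
    seq: DigitSequence | Sequence[int],
    *,
    expected_n: int | None = None,
    expectation: str = "discrete",
) -> float:
    """Turning Point Index: observed turns as % of the random expectation.

    ``expectation="discrete"`` (default) normalizes by the exact
    finite-alphabet null expectation, so uniform random digit sequences
    average 100; ``"continuous"`` uses the classical (2/3)(n−2) form,
    which over-counts expected turns when ties are possible. By default
    the realized length is used; ``expected_n`` pins the expectation to a
    fixed nominal length instead (e.g. 100).
    """
    r, alphabet = _as_responses(seq)
    n = expected_n if expected_n is not None else r.size
    if r.size < 3 or n < 3:
        raise InvalidSequenceError("TPI needs at least 3 responses")
    if expectation == "discrete":
        expected = expected_turning_points(n, alphabet)
    elif expectation == "continuous":
        expected = expected_turning_points(n, None)
    else:
        raise ValueError(f"unknown expectation {expectation!r}")
    return 100.0 * len(turning_points(seq)) / expected


def adjacency(seq: DigitSequence | Sequence[int]) -> float:
    """Percent of consecutive response pairs differing by exactly 1.

    Ascending and descending steps count alike; there is no 9↔1 wraparound.
    Stereotyped counting (…4,5,6…) drives this up, so low adjacency reads
    as good inhibition.
    """
    r, _ = _as_responses(seq)
    if r.size < 2:
        raise InvalidSequenceError("adjacency needs at least 2 responses")
    d = np.abs(np.diff(r))
    return 100.0 * np.count_nonzero(d == 1) / (r.size - 1)


def runs_index(seq: DigitSequence | Sequence[int]) -> float:
    """Variance of phase lengths: gaps between consecutive turning points.

    Sample variance (n−1 denominator); segments before the first and after
    the last turning point are not phases and are excluded. Needs at least
    three turning points (two gaps).
    """
    points = turning_points(seq)
    if len(points) < 3:
        raise UndefinedIndexError("runs index needs at least 3 turning points")
    gaps = np.diff(points)
    return float(np.var(gaps, ddof=1))


def redundancy(seq: DigitSequence | Sequence[int]) -> float:
    """Shannon-entropy departure of digit frequencies from equality, in %.

    0 for perfectly equal use of the alternatives, 100 when a single digit
    is used. R = 100·(1 − H/log2(A)) with H the empirical entropy.
    """
    r, alphabet = _as_responses(seq)
    if r.size < 1:
        raise InvalidSequenceError("redundancy needs a non-empty sequence")
    counts = np.bincount(r, minlength=alphabet + 1)[1:]
    p = counts[counts > 0] / r.size
    h = float(-(p * np.log2(p)).sum())
    return 100.0 * (1.0 - h / math.log2(alphabet))


def coupon(seq: DigitSequence | Sequence[int]) -> tuple[float, bool]:
    """Mean responses consumed per completed pass through the alphabet.

    Scans left to right; every time all A alternatives have appeared since
    the last completion, the count restarts. Returns ``(mean, True)`` over
    completed passes, or ``(len(seq), False)`` when the participant never
    used up all alternatives (the censored maximum).
    """
    r, alphabet = _as_responses(seq)
    if r.size < 1:
        raise InvalidSequenceError("coupon needs a non-empty sequence")
    seen: set[int] = set()
    count = 0
    completed: list[int] = []
    for d in r:
        count += 1
        seen.add(int(d))
        if len(seen) == alphabet:
            completed.append(count)
            seen.clear()
            count = 0
    if not completed:
        return float(r.size), False
    return float(np.mean(completed)), True


def mean_repetition_gap(
    seq: DigitSequence | Sequence[int], *, convention: str = "positional"
) -> float:
    """Mean distance between successive productions of the same digit.

    ``positional`` (default): gap is the position difference, so an
    immediate repeat scores 1. ``intervening``: gap is the number of
    responses strictly between the two productions (immediate repeat = 0).
    """
    if convention not in ("positional", "intervening"):
        raise ValueError(f"unknown MRG convention {convention!r}")
    r, _ = _as_responses(seq)
    last: dict[int, int] = {}
    gaps: list[int] = []
    for pos, d in enumerate(r.tolist(), start=1):
        if d in last:
            gaps.append(pos - last[d])
        last[d] = pos
    if not gaps:
        raise UndefinedIndexError("mean repetition gap needs at least one repeat")
    offset = 1 if convention == "intervening" else 0
    return float(np.mean(gaps)) - offset


def compute_indices(
    seq: DigitSequence,
    *,
    expected_n: int | None = None,
    mrg_convention: str = "positional",
) -> RNGIndices:
    """All six indices for one sequence; undefined ones become NaN."""
    try:
        runs = runs_index(seq)
    except UndefinedIndexError:
        runs = float("nan")
    try:
        mrg = mean_repetition_gap(seq, convention=mrg_convention)
    except UndefinedIndexError:
        mrg = float("nan")
    cpn, complete = coupon(seq)
    return RNGIndices(
        participant_id=seq.participant_id,
        tpi=tpi(seq, expected_n=expected_n),
        adjacency=adjacency(seq),
        runs=runs,
        redundancy=redundancy(seq),
        coupon=cpn,
        mrg=mrg,
        coupon_complete=complete,
        n_responses=len(seq),
    )


def score_sequences(
    sequences: Iterable[DigitSequence],
    *,
    expected_n: int | None = None,
    mrg_convention: str = "positional",
) -> pd.DataFrame:
    """Index table for a collection of sequences, one row per participant."""
    rows = []
    for seq in sequences:
        idx = compute_indices(seq, expected_n=expected_n, mrg_convention=mrg_convention)
        rows.append(
            {
                "participant_id": idx.participant_id,
                "tpi": idx.tpi,
                "adjacency": idx.adjacency,
                "runs": idx.runs,
                "redundancy": idx.redundancy,
                "coupon": idx.coupon,
                "mrg": idx.mrg,
                "coupon_complete": idx.coupon_complete,
                "n_responses": idx.n_responses,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RNG executive summary scores
# ---------------------------------------------------------------------------

def _reference_z(values: pd.Series, reference: pd.Series, label: str) -> pd.Series:
    ref = pd.to_numeric(reference, errors="coerce").dropna()
    sd = ref.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateScaleError(f"zero-variance reference sample for {label}")
    return (pd.to_numeric(values, errors="coerce") - ref.mean()) / sd


def rng_inhibition_score(
    indices: pd.DataFrame, reference: pd.DataFrame | None = None
) -> pd.Series:
    """(z(TPI) − z(Adjacency) + z(Runs)) / 3; higher = better inhibition.

    ``reference`` supplies the standardization sample (rows of the same
    three index columns); defaults to ``indices`` itself. Many turning
    points, few stereotyped adjacent steps and variable phase lengths all
    raise the score.
    """
    ref = indices if reference is None else reference
    z_tpi = _reference_z(indices["tpi"], ref["tpi"], "tpi")
    z_adj = _reference_z(indices["adjacency"], ref["adjacency"], "adjacency")
    z_runs = _reference_z(indices["runs"], ref["runs"], "runs")
    return (z_tpi - z_adj + z_runs) / 3.0


def rng_updating_score(
    indices: pd.DataFrame, reference: pd.DataFrame | None = None
) -> pd.Series:
    """(−z(Redundancy) − z(Coupon) + z(MRG)) / 3; higher = better updating."""
    ref = indices if reference is None else reference
    z_ri = _reference_z(indices["redundancy"], ref["redundancy"], "redundancy")
    z_cpn = _reference_z(indices["coupon"], ref["coupon"], "coupon")
    z_mrg = _reference_z(indices["mrg"], ref["mrg"], "mrg")
    return (-z_ri - z_cpn + z_mrg) / 3.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sequences_csv(path, *, alphabet: int = 9) -> list[DigitSequence]:
    """Read digit sequences from CSV.

    Two layouts are accepted: long format with columns
    ``participant_id, position, digit`` (sorted by position within
    participant), or compact format with ``participant_id, responses``
    where responses are space-separated digits. An optional ``n_errors``
    column is honoured in the compact format.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    sequences: list[DigitSequence] = []
    if {"participant_id", "position", "digit"} <= cols:
        for pid, sub in df.groupby("participant_id", sort=False):
            sub = sub.sort_values("position")
            sequences.append(
                DigitSequence(str(pid), tuple(sub["digit"].astype(int)), alphabet=alphabet)
            )
    elif {"participant_id", "responses"} <= cols:
        for _, row in df.iterrows():
            digits = tuple(int(tok) for tok in str(row["responses"]).split())
            n_err = int(row["n_errors"]) if "n_errors" in cols and pd.notna(row.get("n_errors")) else 0
            sequences.append(
                DigitSequence(str(row["participant_id"]), digits, n_errors=n_err, alphabet=alphabet)
            )
    else:
        raise ValueError(
            "sequences CSV needs columns (participant_id, position, digit) "
            "or (participant_id, responses)"
        )
    return sequences
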