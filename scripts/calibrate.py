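"""Calibrate the synthetic generator's older-group parameters.

Runs the real pipeline (sequences → indices → measures → composites,
younger-reference scheme) on batches of cohorts and adjusts the older
group's Gaussian measure offsets until the expected older composite
deviations hit the targets (inhibition −1.42, updating −0.49, shifting
−0.44). The RNG-sequence biases are held at their chosen human-like
values; whatever shift they produce in the two RNG measures is measured
and the Gaussian ingredients absorb the remainder.

Usage: python scripts/calibrate.py [--cohorts 40] [--rounds 4]
The printed DEFAULT_MEASURE_PARAMS block is what ships in
exefun/simulate.py.
"""

from __future__ import annotations

import argparse

import numpy as np
import pandas as pd

from exefun import composites as comp
from exefun import simulate as sim
from exefun.sequences import DigitSequence, score_sequences
from exefun.simulate import _WORSE_SIGN, COMPOSITE_TARGETS
from exefun.tasks import MEASURE_COLUMNS, assemble_measures

GAUSSIAN_INGREDIENTS = {
    "inhibition": ["stroop_interference", "wcst_nonperseverative_errors"],
    "shifting": ["wcst_perseverative_pct", "plus_minus_cost", "fluency_total"],
    "updating": ["nback_correct"],
}
N_INGREDIENTS = {"inhibition": 3, "shifting": 3, "updating": 2}


def run_batch(config: sim.CohortConfig, n_cohorts: int, seed0: int):
    """Older final composite means, younger step-2 composite SDs, and
    oriented per-measure older deltas, averaged over cohorts."""
    finals, sdcs, deltas = [], [], []
    for i in range(n_cohorts):
        cohort = sim.generate_cohort(config, seed=seed0 + i)
        seqs = [DigitSequence(r.participant_id, tuple(map(int, r.responses.split())))
                for r in cohort.sequences.itertuples()]
        indices = score_sequences(seqs)
        young_ids = cohort.participants.loc[
            cohort.participants.age_group == "younger", "participant_id"]
        measures = assemble_measures(cohort.raw_tasks, indices,
                                     rng_reference_ids=young_ids)
        part = cohort.participants.set_index("participant_id")
        meas = measures.set_index("participant_id")
        groups = part.loc[meas.index, "age_group"].str.cat(
            part.loc[meas.index, "genotype"], sep="/")
        meas, _ = comp.impute_group_mean(meas, groups)
        young = part.loc[meas.index, "age_group"] == "younger"
        z = pd.DataFrame(index=meas.index)
        drow = {}
        for col in MEASURE_COLUMNS:
            z[col] = comp.zscore(meas[col], meas.loc[young, col])
            drow[col] = z.loc[~young, col].mean()
        deltas.append(drow)
        defs = comp.composite_definitions()
        frow, srow = {}, {}
        from exefun.tasks import MEASURE_ORIENTATION
        for name, ings in defs.items():
            mc = sum(MEASURE_ORIENTATION[m] * z[m] for m in ings) / len(ings)
            sd_c = mc[young].std(ddof=1)
            final = (mc - mc[young].mean()) / sd_c
            frow[name] = final[~young].mean()
            srow[name] = sd_c
        finals.append(frow)
        sdcs.append(srow)
    return (pd.DataFrame(finals).mean(), pd.DataFrame(sdcs).mean(),
            pd.DataFrame(deltas).mean())


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohorts", type=int, default=40)
    ap.add_argument("--rounds", type=int, default=4)
    ap.add_argument("--seed", type=int, default=20_000)
    args = ap.parse_args()

    config = sim.CohortConfig()
    for rnd in range(args.rounds):
        finals, sdc, deltas = run_batch(config, args.cohorts, args.seed + 1000 * rnd)
        print(f"\n== round {rnd}: achieved older composite means ==")
        print(finals.round(3).to_string())
        print("younger step-2 SDs:", sdc.round(3).to_dict())
        print("oriented measure deltas (older, in younger SD):")
        print((-deltas).round(3).to_string())
        offsets = {}
        for name, target in COMPOSITE_TARGETS.items():
            shortfall = target - finals[name]
            gauss = GAUSSIAN_INGREDIENTS[name]
            per_measure = -shortfall * N_INGREDIENTS[name] * sdc[name] / len(gauss)
            for meas in gauss:
                ym, ysd, om, osd = config.measure_params[meas]
                current = _WORSE_SIGN[meas] * (om - ym) / ysd
                offsets[meas] = current + per_measure
        config = sim.with_measure_offsets(sim.CohortConfig(), offsets)

    print("\nDEFAULT_MEASURE_PARAMS = {")
    for meas, vals in config.measure_params.items():
        print(f'    "{meas}": ({vals[0]}, {vals[1]}, {round(vals[2], 4)}, {vals[3]}),')
    print("}")


if __name__ == "__main__":
    main()
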