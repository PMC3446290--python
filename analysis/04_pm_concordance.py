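#!/usr/bin/env python
"""PM quantitation and model-vs-experiment concordance.

Simulates replicate PM plates for both strains from the transcribed
experimental grades, quantitates them (trapezoidal areas, replicate
averaging, control subtraction, grade calls), and scores concordance of
the binarized grades against the FBA growth predictions.  Writes
results/pm_calls.tsv and results/pm_concordance.tsv.
"""

from pathlib import Path

import pandas as pd

from strainflux.fba import ConditionError, call_growth, solve_fba
from strainflux.models import GrowthCall
from strainflux.pm import concordance, quantitate_plate, save_calls
from strainflux.synthetic_data import pm_tier_cutoffs, simulate_pm_plate, table1_fixture

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    target, reference, _, conditions, pm_grades = table1_fixture()
    cutoffs = pm_tier_cutoffs()

    all_calls = []
    tables = []
    for i, model in enumerate((target, reference)):
        strain = model.id
        grades = dict(
            pm_grades[pm_grades["strain"] == strain][["condition", "call"]].values
        )
        wells = simulate_pm_plate(grades, n_replicates=4, noise_sd=2.0,
                                  seed=SEED + i)
        calls = quantitate_plate(wells, strain=strain, cutoffs=cutoffs)
        all_calls.append(calls)

        predictions = {}
        for cond in conditions:
            try:
                predictions[cond.name] = call_growth(solve_fba(model, cond))
            except ConditionError:
                predictions[cond.name] = GrowthCall.NO_GROWTH
        frac, table = concordance(calls, predictions, strain)
        table.insert(0, "strain", strain)
        tables.append(table)
        print(f"{strain}: concordance {frac:.1%} "
              f"({int(table['agree'].sum())}/{len(table)} conditions)")

    save_calls(pd.concat(all_calls, ignore_index=True), OUT / "pm_calls.tsv")
    pd.concat(tables, ignore_index=True).to_csv(
        OUT / "pm_concordance.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
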