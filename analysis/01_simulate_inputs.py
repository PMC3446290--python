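#!/usr/bin/env python
"""Generate every pipeline input with known planted truth.

Writes, under results/inputs/:
  * the checked-in ten-condition strain pair (models, delta, conditions,
    transcribed PM grades),
  * a random seeded strain pair with decoy groups,
  * a simulated PM plate (4 replicates, mild noise),
  * a synthetic genome with one planted compositional island.
"""

from pathlib import Path

from strainflux.models import save_conditions, save_model
from strainflux.pm import save_calls, save_pm_kinetics
from strainflux.strain_delta import save_delta
from strainflux import synthetic_data as synth

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    target, reference, delta, conditions, pm = synth.table1_fixture()
    save_model(target, OUT / "REL606_like.json")
    save_model(reference, OUT / "MG1655_like.json")
    save_delta(delta, OUT / "strain_delta.tsv")
    save_conditions(conditions, OUT / "conditions.tsv")
    save_calls(pm, OUT / "pm_grades.tsv")
    print(f"strain pair: {len(target.reactions)} vs {len(reference.reactions)} "
          f"reactions, {len(delta.groups)} modification groups, "
          f"{len(conditions)} conditions")

    rt, rr, rd, truth, rconds = synth.make_toy_strain_pair(
        n_conditions=4, n_decoy_groups=3, seed=SEED
    )
    save_model(rt, OUT / "random_target.json")
    save_model(rr, OUT / "random_reference.json")
    save_delta(rd, OUT / "random_delta.tsv")
    save_conditions(rconds, OUT / "random_conditions.tsv")
    print(f"random pair (seed {SEED}): planted map {truth.condition_map}")

    grades = {"substrate_minus": "minus", "substrate_plus": "plus",
              "substrate_plus_plus": "plus_plus"}
    wells = synth.simulate_pm_plate(grades, n_replicates=4, noise_sd=2.0, seed=SEED)
    save_pm_kinetics(wells, OUT / "pm_kinetics.csv")
    print(f"PM plate: {len(wells)} wells "
          f"({len(grades)} substrates x 4 replicates + controls)")

    seq, gene_table, gtruth = synth.simulate_genome(
        150, [(60, 12, 0.15, 8.0)], seed=SEED
    )
    synth.write_genome_fasta(seq, OUT / "genome.fa")
    synth.write_gene_table(gene_table, OUT / "genes.tsv")
    print(f"genome: {len(seq)} bp, 150 genes, planted island genes "
          f"{gtruth.island_spans[0]}")


if __name__ == "__main__":
    main()
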