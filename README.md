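# strainflux

Strain-differential genome-scale metabolic modeling for closely related
bacterial strains.

Two strains of the same species — say an *E. coli* B-lineage production
strain and a K-12 laboratory strain — can differ in only a few percent
of their genomes yet show starkly different substrate-utilization
phenotypes. `strainflux` turns those genetic differences into testable
growth predictions and back-traces each strain-specific phenotype to the
reaction-level change that causes it. It is aimed at microbial systems
biologists who have two annotated genomes, a constraint-based model for
one of the strains, and phenotype-microarray (PM) data for both.

## What it computes

**Flux balance analysis (FBA).** Growth on a substrate is predicted by
maximizing the biomass objective flux v_biomass subject to steady-state
mass balance S·v = 0 and flux bounds l ≤ v ≤ u, where S is the
stoichiometric matrix. A growth condition fixes nutrient availability:
the named substrate exchange gets lower bound max(l, −uptake) (uptake
8 mmol/gDCW/h for carbon sources, oxygen 18.5 mmol/gDCW/h), every other
nutrient exchange is closed to uptake. Growth is called when the optimal
objective exceeds a small epsilon (default 1e-6 /h).

**Strain deltas.** A target-strain model is derived from a reference
model by an ordered set of named modification groups: reaction
*additions* (pathways unique to the target), *deletions* (reference
reactions whose gene–protein–reaction boolean rule goes false under the
target's gene table — pseudogenes count as non-functional), and
*regulatory switch-offs* (reactions retained with both bounds pinned to
zero).

**In silico complementation.** For every condition where the two
strains' growth calls differ, subsets of modification groups are
reverted in the target model, in increasing cardinality, and growth is
re-predicted. A subset is *responsible* for the phenotype when its
reversion makes the target's call equal the reference's; only minimal
subsets are reported, and the union of their reactions is the set of
reactions responsible for the strain-specific phenotypes.

**PM quantitation and concordance.** PM kinetic curves are quantitated
as unitless trapezoidal areas, averaged over replicates, negative-
control-subtracted (floored at 0), graded into −/+/++ tiers, binarized
(− → no growth), and scored for agreement with the FBA calls.

**Genomic-island scan.** A gene is *foreign* when its G+C content
deviates from the all-gene mean by more than 1.5 σ (two-sided) **and**
its codon usage differs from the genome-wide sense-codon frequencies at
P < 0.05 (chi-square goodness of fit). A ten-gene sliding window with
four or more foreign genes marks an island; neighboring hits are merged.

## Worked example

The checked-in fixture `strainflux.synthetic_data.table1_fixture()`
encodes ten carbon sources whose utilization differs between a B-like
target strain and a K-12-like reference, each hinging on exactly one
modification group. Reproduce the complementation table:

```bash
python analysis/03_complementation.py
```

which prints (abridged):

```
                  condition pm_target pm_reference prediction_target prediction_reference    responsible_reactions modification
                L-Arabinose         -           ++                 -                    +                     ARAI     Deletion
              Succinic acid         +           ++                 -                    +               EX_succ(e)   Turned off
               D-Malic acid         -           ++                 -                    +  EX_mal_D(e), MALDt2_2pp   Turned off
   N-Acetyl-D-galactosamine        ++            -                 +                    -     ACGALptspp, ACGAL6PI     Addition
                D-Arabinose        ++            -                 +                    -  EX_arab-D(e), DARBtex, ARABDI, RBK_D1     Addition
...
distinct responsible reactions across all conditions: 23
```

Each row pairs the experimental PM grades (target/reference) with the
binary FBA predictions and the minimal reaction set whose reversion
abolishes the differential call. The summary line counts the distinct
reactions across all rows — here 23. The same run is available through
the CLI:

```bash
strainflux simulate strains --table1 --out inputs/
strainflux complement --target inputs/target.json --reference inputs/reference.json \
    --delta inputs/delta.tsv --conditions inputs/conditions.tsv \
    --pm inputs/pm_calls.tsv --out complementation.tsv
```

The other numbered drivers under `analysis/` exercise the remaining
stages: `01` writes all synthetic inputs, `02` the per-condition growth
predictions, `04` PM quantitation + concordance, `05` the island scan
(planted 12-gene island recovered as one merged call).

Real published inputs work through the same interfaces: the JSON model
dialect mirrors the community constraint-based layout, deltas and gene
status are plain TSV, PM kinetics are long-format CSV, and genomes are
FASTA + GFF3/TSV coordinates.

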