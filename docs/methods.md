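# Methods

## Constraint-based model and FBA

A model is a stoichiometric matrix S (metabolites × reactions) with flux
bounds in mmol/gDCW/h, a boolean gene–protein–reaction (GPR) rule per
reaction, and a biomass pseudo-reaction whose flux is the specific
growth rate (1/h). FBA solves

    max c·v   s.t.   S·v = 0,   l ≤ v ≤ u

with scipy's HiGHS LP backend. Exchange reactions are written in the
export-positive convention (`met_e →`), so uptake is a negative exchange
flux.

**Medium application.** A growth condition names a substrate exchange
(default uptake 8 mmol/gDCW/h), an oxygen exchange (18.5 mmol/gDCW/h)
and optional co-substrates. Before solving, each named exchange's lower
bound becomes `max(model_lb, −uptake)` and every other exchange's lower
bound becomes `max(model_lb, 0)`. Taking the max against the strain's
own bound is deliberate: a medium can only *restrict* availability, it
can never re-open an exchange that a regulatory switch-off pinned to
(0, 0). Setting the bound to −uptake unconditionally would silently undo
regulatory modifications whenever the switched-off reaction is itself
the substrate exchange, which is precisely the situation in the
turned-off uptake phenotypes the complementation analysis attributes.
Upper bounds are left open, so secretion is unconstrained.

**Growth call.** Growth iff the LP is optimal and the objective exceeds
`growth_epsilon` (default 1e-6 /h, strictly). The epsilon separates
numerical zeros from genuine growth; qualitative calls on the toy
networks are insensitive to it over many orders of magnitude because
feasible growth rates are O(uptake).

**Alternate optima.** Only the objective value is contractually
guaranteed; individual non-objective fluxes may differ between solvers.
No test or report asserts on them.

**Maintenance.** Toy models carry no ATP-maintenance demand (it is an
ordinary bounded reaction if a loaded model includes one). Maintenance
shifts quantitative growth rates but not the qualitative calls these
analyses compare, and the LP-homogeneity property (objective scales
linearly with uptake) holds exactly only without fixed demands — the
property test relies on that.

## Strain deltas

`build_delta` generates a deletion group for every reference reaction
whose GPR is true under the reference gene table and false under the
target's. Pseudogenes evaluate as non-functional, identically to absent
genes, but keep their distinct status in tables and reports. Genes
missing from a table default to present (logged): strain tables
typically list only the genes that differ. Reactions disabled by the
same set of lost genes form one group, reflecting that a single
pathway-level gene loss is one evolutionary event and one unit of
reversion.

Regulatory switch-offs zero both bounds but retain the reaction, so the
group can be reverted without payload loss. Each group stores its own
restore payload (reference reaction/metabolite definitions, original
bounds) at construction time; `revert_groups` therefore needs no
reference model at hand, though it accepts one as a fallback payload
source for deltas loaded from TSV, where only additions carry equations.

`apply_delta` drops metabolites that no remaining reaction references;
reversion re-inserts them from the payload, making
apply → revert-all an exact field-by-field round trip (tested on 100
random pairs).

## In silico complementation

Subsets of modification groups are enumerated in increasing cardinality
up to `max_revert_subset` (default 3; the analyses here run exhaustively
since group counts are ≤ 10). A subset is responsible when reverting it
makes the target's growth call equal the reference's — in both
directions, covering loss-of-function (target stopped growing) and
gain-of-function (target acquired growth) phenotypes. Supersets of
already-found responsible sets are pruned: they cannot be minimal, so
pruning does not change the reported set. Results are ordered by
(cardinality, lexicographic group names), making reports byte-stable.
Groups, not reactions, are the reversion unit; reports expand each group
to its reaction ids, and the summary line counts the distinct union.

## PM quantitation

Area under each growth-time curve is trapezoidal, unitless. Replicate
areas are averaged, the mean negative-control area (well A01 by plate
convention, overridable) subtracted, and the result floored at 0 —
net respiration below the control carries no information the binary
comparison can use. Grades: − if net ≤ low, + if ≤ high, ++ above.
Vendor grading thresholds are proprietary, so defaults are plate-driven
quantiles (low = 10th percentile of net areas, high = median), always
overridable; tests and drivers pass cutoffs matched to the simulator's
tiers. For model comparison − maps to no-growth and both + grades to
growth, since FBA yields binary calls.

## Island scan

G+C z-scores use the population standard deviation over all genes
(σ = 0 gives all-zero z). The criterion is two-sided (|z| > 1.5):
horizontally acquired DNA can be GC-richer or GC-poorer than the host.
The codon test is a per-gene chi-square goodness of fit of sense-codon
counts against genome-wide sense-codon frequencies (stop codons
excluded); codons with zero expected count are dropped and df is the
remaining codon count minus one. It is one test per gene with no
multiplicity correction — the P < 0.05 threshold is a per-gene flagging
rule inside a conjunction, not a genome-wide inference, and the window
criterion (≥ 4 foreign genes in 10) supplies the real specificity.
A gene is foreign only when *both* signatures are aberrant. Windows
slide one gene at a time; qualifying windows that overlap or directly
abut in gene index are merged (no gap allowance). Internally coordinates
are 0-based half-open; emitted GFF3 is 1-based inclusive and BED 0-based
half-open.

## Synthetic data

All generators are pure functions of parameters and seed.

**Strain pairs.** Every substrate funnels through
exchange → transport → catabolism into a single biomass precursor, so
each condition's growth is coupled to exactly one planted modification
group; decoy groups touch only dead-end reactions that can carry no
steady-state flux and hence can never flip a call. The checked-in
ten-condition fixture is hand-written rather than generated so the
primary worked example is stable and reviewable; its group sizes
(9-, 4-, 2- and 1-reaction additions, single-reaction deletions, one
two-reaction switch-off) give a 23-reaction union across the ten
minimal responsible sets.

**PM plates.** Logistic curves sampled every 0.5 h over 48 h, lag 4 h,
rate 0.3 /h, control asymptote 25 (unitless); grade asymptotes are
1×/4×/8× the control, so noiseless net areas sit at 0, 3 and 7 control
areas — well-separated tiers. Four replicates by default. Gaussian
pointwise noise, floored at 0.

**Genomes.** Sense-codon sampling weights are exp(β·GC(codon)) with β
solved numerically for the desired gene G+C; island genes additionally
up-weight one codon per synonymous family (skew factor 8 by default),
giving them both signatures of foreignness. Genes are 200–400 codons,
all on the + strand, separated by 50 bp spacers. What this does *not*
emulate: real gene-length and strand distributions, amelioration
gradients at island edges, mobile-element signatures, and genome-scale
heterogeneity (rRNA operons, highly expressed core genes with extreme
codon bias). Passing recovery tests therefore demonstrates correctness
of the statistics and the scan, not field performance on real genomes,
where the foreign-gene false-positive structure is richer.

## Problem sizes and numerics

Analyses and tests run on networks of ≤ ~40 reactions, strain pairs
with ≤ 10 modification groups (complementation enumerations up to 2^10
subsets with minimality pruning), 100–150-gene genomes and 20-seed
replications — sizes at which every search can be cross-checked against
exhaustive oracles. LP feasibility tolerance is 1e-7; objective
comparisons against the vertex-enumeration oracle hold to 1e-9.
Ties between equally minimal responsible sets are broken
lexicographically. Degenerate inputs (empty deltas, empty condition
lists, σ = 0 gene sets, all-equal PM plates) are defined outcomes, not
errors, except where a contract requires data (≥ 2 genes, ≥ 1
replicate, ≥ 2 time points).

## Known limitations

* The LP-based calls inherit FBA's assumptions: steady state, a fixed
  biomass composition, no kinetic or regulatory dynamics beyond static
  switch-offs.
* Responsible sets are reported per condition; epistasis across
  conditions is not scored.
* The SBML reader covers a Level 3 FBC subset and requires libsbml; the
  first-class dialects are JSON and TSV.
* Real-genome island detection typically augments composition with
  phylogenetic confirmation; this implementation is composition-only.
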