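"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators cover the pipeline's input surface without any external
download:

* small growth-coupled strain pairs (``make_toy_strain_pair``) in which
  each growth condition depends on exactly one planted modification
  group, plus decoy groups that can never carry flux;
* PM-style logistic growth curves whose asymptote encodes a planted
  -, +, ++ grade (``simulate_pm_plate``);
* gene sequences with planted compositional islands of shifted G+C and
  skewed synonymous-codon usage (``simulate_genome``).

``table1_fixture`` is a hand-written, checked-in toy strain pair in
which ten carbon sources are each growth-dependent on exactly one named
reaction group — the repository's primary worked example of the in
silico complementation procedure.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from strainflux.models import (
    Compartment,
    GrowthCondition,
    Metabolite,
    MetabolicModel,
    Reaction,
)
from strainflux.strain_delta import (
    ADDITION,
    DELETION,
    REGULATION_OFF,
    ModificationGroup,
    StrainDelta,
    apply_delta,
)
from strainflux.islands import SENSE_CODONS
from strainflux.pm import PMWell, DEFAULT_CONTROL_WELL


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator, for closed-loop testing."""

    delta: StrainDelta | None = None
    condition_map: dict[str, set[str]] = field(default_factory=dict)
    island_spans: list[tuple[int, int]] = field(default_factory=list)
    pm_truth: dict[tuple[str, str], str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# model-construction helpers
# ---------------------------------------------------------------------------

def _met(mid: str) -> Metabolite:
    if mid.endswith("_e"):
        comp = Compartment.EXTRACELLULAR
    elif mid.endswith("_p"):
        comp = Compartment.PERIPLASM
    else:
        comp = Compartment.CYTOSOL
    return Metabolite(id=mid, compartment=comp)


def _exchange(rid: str, mid: str) -> Reaction:
    return Reaction(
        id=rid, stoichiometry={mid: -1.0}, lower_bound=-1000.0, upper_bound=1000.0,
        is_exchange=True,
    )


def _irreversible(rid: str, consumed: str, produced: str, gpr: str = "") -> Reaction:
    return Reaction(
        id=rid,
        stoichiometry={consumed: -1.0, produced: 1.0},
        lower_bound=0.0,
        upper_bound=1000.0,
        gpr=gpr,
    )


def _chain(ids: list[str], mets: list[str]) -> list[Reaction]:
    """Linear unit-stoichiometry chain reactions ids[i]: mets[i] -> mets[i+1]."""
    return [_irreversible(rid, mets[i], mets[i + 1]) for i, rid in enumerate(ids)]


def _base_model(model_id: str) -> MetabolicModel:
    """Skeleton shared by all toy strains: oxygen exchange and a biomass
    sink draining the catabolic funnel metabolite ``carbon_c``."""
    return MetabolicModel(
        id=model_id,
        metabolites=[_met("carbon_c"), _met("o2_e")],
        reactions=[
            _exchange("EX_o2(e)", "o2_e"),
            Reaction(
                id="BIOMASS",
                stoichiometry={"carbon_c": -1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
            ),
        ],
        objective_id="BIOMASS",
    )


def _add(model: MetabolicModel, reactions: list[Reaction]) -> None:
    known = set(model.metabolite_ids)
    for r in reactions:
        for mid in r.stoichiometry:
            if mid not in known:
                model.metabolites.append(_met(mid))
                known.add(mid)
        model.reactions.append(r)


# ---------------------------------------------------------------------------
# the checked-in ten-condition fixture
# ---------------------------------------------------------------------------

def table1_fixture() -> tuple[
    MetabolicModel, MetabolicModel, StrainDelta, list[GrowthCondition], pd.DataFrame
]:
    """Hand-written toy strain pair (B-like target vs K-12-like reference)
    encoding ten differential carbon-source phenotypes.

    Each carbon source funnels into biomass through a linear pathway, and
    growth in exactly one strain hinges on exactly one named modification
    group: two reference-pathway deletions (arabinose isomerase ARAI,
    fucose transporter FUCtpp), four regulatory switch-offs (succinate,
    L-aspartate, D-malate and L-malate uptake), and four target-specific
    pathway additions (the nine-reaction hydroxyphenylacetate cluster,
    the two-reaction N-acetyl-galactosamine route, the four-reaction
    D-arabinose route, and the single N-acetyl-glutamate transporter).
    The union of the groups' reactions has 23 elements.

    Returns (target model, reference model, delta, conditions, PM grade
    table transcribed for the ten substrates).
    """
    ref = _base_model("MG1655")

    # shared machinery per substrate (present in both strains)
    _add(ref, [_exchange("EX_arab_L(e)", "arab_L_e")] + _chain(
        ["ARAt", "ARAI"], ["arab_L_e", "arab_L_c", "carbon_c"]))
    _add(ref, [_exchange("EX_succ(e)", "succ_e")] + _chain(
        ["SUCCt", "SUCCcat"], ["succ_e", "succ_c", "carbon_c"]))
    _add(ref, [_exchange("EX_asp_L(e)", "asp_L_e")] + _chain(
        ["ASPt", "ASPcat"], ["asp_L_e", "asp_L_c", "carbon_c"]))
    _add(ref, [_exchange("EX_fuc_L(e)", "fuc_L_e")] + _chain(
        ["FUCtpp", "FUCcat"], ["fuc_L_e", "fuc_L_c", "carbon_c"]))
    _add(ref, [_exchange("EX_mal_D(e)", "mal_D_e")] + _chain(
        ["MALDt2_2pp", "MALDcat"], ["mal_D_e", "mal_D_c", "carbon_c"]))
    _add(ref, [_exchange("EX_mal_L(e)", "mal_L_e")] + _chain(
        ["MALt2", "MALLcat"], ["mal_L_e", "mal_L_c", "carbon_c"]))
    # dead-end exchanges shared by both strains; only the target gains
    # the catabolic machinery behind them
    _add(ref, [_exchange("EX_acgal(e)", "acgal_e")])
    _add(ref, [_exchange("EX_nacglu(e)", "nacglu_e")] + _chain(
        ["NACGLUcat"], ["nacglu_c", "carbon_c"]))

    hpa_ids = ["HPAtex", "HPAP", "HPAI", "4H3M", "34DH23OR",
               "5C2HMSO", "5C2HMDI", "5O3E125TC"]
    hpa_mets = ["4hpa_e", "4hpa_p", "4hpa_c", "hpa_i1_c", "hpa_i2_c",
                "hpa_i3_c", "hpa_i4_c", "hpa_i5_c", "carbon_c"]
    hpa_reactions = [_exchange("EX_4hpa(e)", "4hpa_e")] + _chain(hpa_ids, hpa_mets)
    darab_reactions = [_exchange("EX_arab-D(e)", "arab_D_e")] + _chain(
        ["DARBtex", "ARABDI", "RBK_D1"],
        ["arab_D_e", "arab_D_p", "arab_D_c", "carbon_c"],
    )
    acgal_reactions = _chain(
        ["ACGALptspp", "ACGAL6PI"], ["acgal_e", "acgal6p_c", "carbon_c"]
    )
    nacglu_reactions = _chain(["NACGLUtmp"], ["nacglu_e", "nacglu_c"])

    def payload_mets(reactions: list[Reaction]) -> list[Metabolite]:
        ref_mets = set(ref.metabolite_ids)
        mids: set[str] = set()
        for r in reactions:
            mids.update(m for m in r.stoichiometry if m not in ref_mets)
        return [_met(m) for m in sorted(mids)]

    def deletion_group(name: str, rids: list[str]) -> ModificationGroup:
        return ModificationGroup(
            name=name,
            kind=DELETION,
            reaction_ids=rids,
            payload_reactions=[ref.get_reaction(r).copy() for r in rids],
            payload_metabolites=[],
        )

    def regulation_group(name: str, rids: list[str]) -> ModificationGroup:
        return ModificationGroup(
            name=name,
            kind=REGULATION_OFF,
            reaction_ids=rids,
            original_bounds={
                r: (ref.get_reaction(r).lower_bound, ref.get_reaction(r).upper_bound)
                for r in rids
            },
        )

    delta = StrainDelta(
        reference_id="MG1655",
        target_id="REL606",
        groups=[
            deletion_group("araI_loss", ["ARAI"]),
            regulation_group("succ_uptake_off", ["EX_succ(e)"]),
            regulation_group("asp_uptake_off", ["EX_asp_L(e)"]),
            deletion_group("fucT_loss", ["FUCtpp"]),
            regulation_group("malD_uptake_off", ["EX_mal_D(e)", "MALDt2_2pp"]),
            regulation_group("malL_uptake_off", ["EX_mal_L(e)"]),
            ModificationGroup(
                name="hpa_cluster",
                kind=ADDITION,
                reaction_ids=[r.id for r in hpa_reactions],
                payload_reactions=hpa_reactions,
                payload_metabolites=payload_mets(hpa_reactions),
            ),
            ModificationGroup(
                name="acgal_cluster",
                kind=ADDITION,
                reaction_ids=[r.id for r in acgal_reactions],
                payload_reactions=acgal_reactions,
                payload_metabolites=payload_mets(acgal_reactions),
            ),
            ModificationGroup(
                name="darab_cluster",
                kind=ADDITION,
                reaction_ids=[r.id for r in darab_reactions],
                payload_reactions=darab_reactions,
                payload_metabolites=payload_mets(darab_reactions),
            ),
            ModificationGroup(
                name="nacglu_transport",
                kind=ADDITION,
                reaction_ids=[r.id for r in nacglu_reactions],
                payload_reactions=nacglu_reactions,
                payload_metabolites=[],
            ),
        ],
    )
    target = apply_delta(ref, delta)

    conditions = [
        GrowthCondition(name="L-Arabinose", substrate_exchange_id="EX_arab_L(e)"),
        GrowthCondition(name="Succinic acid", substrate_exchange_id="EX_succ(e)"),
        GrowthCondition(name="L-Aspartic acid", substrate_exchange_id="EX_asp_L(e)"),
        GrowthCondition(name="L-Fucose", substrate_exchange_id="EX_fuc_L(e)"),
        GrowthCondition(name="D-Malic acid", substrate_exchange_id="EX_mal_D(e)"),
        GrowthCondition(name="L-Malic acid", substrate_exchange_id="EX_mal_L(e)"),
        GrowthCondition(
            name="p-Hydroxyphenyl acetic acid", substrate_exchange_id="EX_4hpa(e)"
        ),
        GrowthCondition(
            name="N-Acetyl-D-galactosamine", substrate_exchange_id="EX_acgal(e)"
        ),
        GrowthCondition(name="D-Arabinose", substrate_exchange_id="EX_arab-D(e)"),
        GrowthCondition(
            name="N-Acetyl-L-glutamic acid", substrate_exchange_id="EX_nacglu(e)"
        ),
    ]

    pm_grades = {
        "L-Arabinose": ("minus", "plus_plus"),
        "Succinic acid": ("plus", "plus_plus"),
        "L-Aspartic acid": ("plus", "plus_plus"),
        "L-Fucose": ("minus", "plus_plus"),
        "D-Malic acid": ("minus", "plus_plus"),
        "L-Malic acid": ("plus", "plus_plus"),
        "p-Hydroxyphenyl acetic acid": ("plus_plus", "minus"),
        "N-Acetyl-D-galactosamine": ("plus_plus", "minus"),
        "D-Arabinose": ("plus_plus", "minus"),
        "N-Acetyl-L-glutamic acid": ("plus_plus", "minus"),
    }
    pm_table = pd.DataFrame(
        [
            {"strain": strain, "condition": cond, "area": float("nan"), "call": grade}
            for cond, (g_target, g_ref) in pm_grades.items()
            for strain, grade in (("REL606", g_target), ("MG1655", g_ref))
        ]
    )
    return target, ref, delta, conditions, pm_table


# ---------------------------------------------------------------------------
# random strain pairs with planted responsible groups
# ---------------------------------------------------------------------------

def make_toy_strain_pair(
    n_conditions: int,
    n_decoy_groups: int = 0,
    seed: int = 0,
) -> tuple[MetabolicModel, MetabolicModel, StrainDelta, PlantedTruth, list[GrowthCondition]]:
    """Random growth-coupled strain pair with one planted responsible
    group per condition and flux-dead decoy groups.

    Each condition's substrate funnels through exchange -> transport ->
    catabolism into biomass; the planted modification (a deletion,
    addition or regulatory switch-off, chosen per the seed) makes growth
    on that substrate strain-specific.  Decoy groups touch only dead-end
    reactions that can never carry steady-state flux, so reverting them
    can never flip any growth call.
    """
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    rng = np.random.default_rng(seed)
    ref = _base_model("ref")
    groups: list[ModificationGroup] = []
    truth = PlantedTruth(condition_map={})
    conditions = []
    for i in range(n_conditions):
        sub = f"sub{i}"
        ex, tr, cat = f"EX_{sub}(e)", f"T_{sub}", f"CAT_{sub}"
        mets = [f"{sub}_e", f"{sub}_c", "carbon_c"]
        reactions = [_exchange(ex, mets[0])] + _chain([tr, cat], mets)
        kind = rng.choice([DELETION, ADDITION, REGULATION_OFF])
        name = f"group_{sub}"
        if kind == DELETION:
            _add(ref, reactions)
            victim = str(rng.choice([tr, cat]))
            groups.append(
                ModificationGroup(
                    name=name,
                    kind=DELETION,
                    reaction_ids=[victim],
                    payload_reactions=[ref.get_reaction(victim).copy()],
                )
            )
        elif kind == REGULATION_OFF:
            _add(ref, reactions)
            off = [ex] if rng.random() < 0.5 else [ex, tr]
            groups.append(
                ModificationGroup(
                    name=name,
                    kind=REGULATION_OFF,
                    reaction_ids=off,
                    original_bounds={
                        r: (ref.get_reaction(r).lower_bound, ref.get_reaction(r).upper_bound)
                        for r in off
                    },
                )
            )
        else:  # ADDITION: target-only pathway; reference keeps the exchange
            if rng.random() < 0.5:
                _add(ref, [reactions[0]])  # exchange shared, pathway added
                added = reactions[1:]
            else:
                added = reactions  # whole route incl. exchange is target-only
            groups.append(
                ModificationGroup(
                    name=name,
                    kind=ADDITION,
                    reaction_ids=[r.id for r in added],
                    payload_reactions=added,
                    payload_metabolites=[
                        _met(m)
                        for m in sorted(
                            {mm for r in added for mm in r.stoichiometry}
                            - set(ref.metabolite_ids)
                        )
                    ],
                )
            )
        cond = GrowthCondition(name=f"cond_{sub}", substrate_exchange_id=ex)
        conditions.append(cond)
        truth.condition_map[cond.name] = {name}
    for j in range(n_decoy_groups):
        d1, d2 = f"decoy{j}_a_c", f"decoy{j}_b_c"
        r = _irreversible(f"DECOY_{j}", d1, d2)
        kind = rng.choice([DELETION, ADDITION, REGULATION_OFF])
        name = f"decoy_group_{j}"
        if kind == ADDITION:
            groups.append(
                ModificationGroup(
                    name=name,
                    kind=ADDITION,
                    reaction_ids=[r.id],
                    payload_reactions=[r],
                    payload_metabolites=[_met(d1), _met(d2)],
                )
            )
        else:
            _add(ref, [r])
            if kind == DELETION:
                groups.append(
                    ModificationGroup(
                        name=name,
                        kind=DELETION,
                        reaction_ids=[r.id],
                        payload_reactions=[r.copy()],
                        payload_metabolites=[_met(d1), _met(d2)],
                    )
                )
            else:
                groups.append(
                    ModificationGroup(
                        name=name,
                        kind=REGULATION_OFF,
                        reaction_ids=[r.id],
                        original_bounds={r.id: (r.lower_bound, r.upper_bound)},
                    )
                )
    delta = StrainDelta(reference_id="ref", target_id="target", groups=groups)
    target = apply_delta(ref, delta)
    truth.delta = delta
    return target, ref, delta, truth, conditions


# ---------------------------------------------------------------------------
# PM plate simulation
# ---------------------------------------------------------------------------

#: fixed kinetic defaults: lag 4 h, logistic rate 0.3 /h, control asymptote
#: 25 unitless; grade asymptotes are 1x / 4x / 8x the control level
PM_LAG_H = 4.0
PM_RATE = 0.3
PM_CONTROL_ASYMPTOTE = 25.0
PM_GRADE_FACTOR = {"minus": 1.0, "plus": 4.0, "plus_plus": 8.0}
PM_TIME_H = 48.0
PM_STEP_H = 0.5


def _logistic_curve(times: np.ndarray, asymptote: float) -> np.ndarray:
    # midpoint placed one e-folding past the lag
    t0 = PM_LAG_H + 1.0 / PM_RATE
    return asymptote / (1.0 + np.exp(-PM_RATE * (times - t0)))


def simulate_pm_plate(
    truth_grades: dict[str, str],
    n_replicates: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
    plate: str = "PM1",
) -> list[PMWell]:
    """Logistic growth-time curves encoding planted grades.

    One well per substrate per replicate plus a negative-control well
    (A01) per replicate; independent Gaussian noise of the given standard
    deviation is added pointwise and the signal floored at 0.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, PM_TIME_H + PM_STEP_H / 2, PM_STEP_H)
    wells = []
    layout = _well_labels(len(truth_grades) + 1)
    for rep in range(1, n_replicates + 1):
        control = _logistic_curve(times, PM_CONTROL_ASYMPTOTE)
        noisy = np.maximum(control + rng.normal(0.0, noise_sd, size=times.shape), 0.0)
        wells.append(
            PMWell(
                plate=plate,
                well=DEFAULT_CONTROL_WELL,
                substrate="negative control",
                replicate=rep,
                time=times.tolist(),
                signal=noisy.tolist(),
            )
        )
        for label, (substrate, grade) in zip(layout[1:], sorted(truth_grades.items())):
            asymptote = PM_CONTROL_ASYMPTOTE * PM_GRADE_FACTOR[grade]
            clean = _logistic_curve(times, asymptote)
            noisy = np.maximum(clean + rng.normal(0.0, noise_sd, size=times.shape), 0.0)
            wells.append(
                PMWell(
                    plate=plate,
                    well=label,
                    substrate=substrate,
                    replicate=rep,
                    time=times.tolist(),
                    signal=noisy.tolist(),
                )
            )
    return wells


def _well_labels(n: int) -> list[str]:
    labels = [f"{row}{col:02d}" for row in "ABCDEFGH" for col in range(1, 13)]
    if n > len(labels):
        raise ValueError("too many substrates for one 96-well plate")
    return labels[:n]


def pm_tier_cutoffs() -> tuple[float, float]:
    """Grade cutoffs matched to the simulator's noiseless tier net areas:
    low = half the plus-tier net area, high = midpoint of the plus and
    plus-plus tiers."""
    times = np.arange(0.0, PM_TIME_H + PM_STEP_H / 2, PM_STEP_H)
    control = float(np.trapezoid(_logistic_curve(times, PM_CONTROL_ASYMPTOTE), times))
    net_plus = control * (PM_GRADE_FACTOR["plus"] - 1.0)
    net_pp = control * (PM_GRADE_FACTOR["plus_plus"] - 1.0)
    return net_plus / 2.0, (net_plus + net_pp) / 2.0


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _codon_gc_counts() -> np.ndarray:
    return np.array([sum(b in "GC" for b in c) for c in SENSE_CODONS], dtype=float)


def _codon_weights_for_gc(target_gc: float, skew: float = 1.0, rng=None) -> np.ndarray:
    """Sense-codon sampling weights whose expected G+C equals target_gc.

    Weights are exp(beta * gc_count(codon)); beta is solved numerically.
    With skew > 1 one randomly chosen codon per synonymous family is
    up-weighted by that factor before re-solving, emulating the biased
    synonymous usage of horizontally acquired genes.
    """
    gc_counts = _codon_gc_counts()
    base = np.ones(len(SENSE_CODONS))
    if skew > 1.0:
        if rng is None:
            rng = np.random.default_rng(0)
        for family in _synonymous_families():
            chosen = rng.choice(family)
            base[chosen] *= skew

    def expected_gc(beta: float) -> float:
        w = base * np.exp(beta * gc_counts)
        p = w / w.sum()
        return float(np.dot(p, gc_counts) / 3.0)

    beta = brentq(lambda b: expected_gc(b) - target_gc, -12.0, 12.0)
    w = base * np.exp(beta * gc_counts)
    return w / w.sum()


def _synonymous_families() -> list[np.ndarray]:
    from Bio.Data.CodonTable import standard_dna_table

    by_aa: dict[str, list[int]] = {}
    for i, codon in enumerate(SENSE_CODONS):
        aa = standard_dna_table.forward_table.get(codon)
        if aa is not None:
            by_aa.setdefault(aa, []).append(i)
    return [np.array(v) for v in by_aa.values() if len(v) > 1]


def simulate_genome(
    n_genes: int,
    island_specs: list[tuple[int, int, float, float]],
    seed: int = 0,
    background_gc: float = 0.50,
    codons_per_gene: tuple[int, int] = (200, 400),
) -> tuple[str, list[tuple[str, int, int, str]], PlantedTruth]:
    """Synthetic genome with planted compositional islands.

    ``island_specs`` is a list of (start_gene, length, gc_shift,
    codon_skew) tuples; island genes are drawn from a codon model with
    G+C shifted by ``gc_shift`` and synonymous usage skewed by factor
    ``codon_skew``.  Background genes follow a fixed codon-frequency
    model at ``background_gc``.  Genes are contiguous on the + strand
    with 50 bp intergenic spacers.

    Returns (sequence, gene table rows (id, start, end, strand), planted
    truth with island gene-index spans, 0-based half-open).
    """
    rng = np.random.default_rng(seed)
    in_island = np.full(n_genes, -1)
    for k, (start, length, _, _) in enumerate(island_specs):
        if start < 0 or start + length > n_genes:
            raise ValueError(f"island spec {k} out of gene range")
        if np.any(in_island[start : start + length] >= 0):
            raise ValueError(f"island spec {k} overlaps another island")
        in_island[start : start + length] = k
    background_w = _codon_weights_for_gc(background_gc)
    island_w = [
        _codon_weights_for_gc(
            background_gc + gc_shift, skew=codon_skew, rng=np.random.default_rng(seed + 7 * k + 1)
        )
        for k, (_, _, gc_shift, codon_skew) in enumerate(island_specs)
    ]
    codons = np.array(SENSE_CODONS)
    spacer_len = 50
    parts: list[str] = []
    gene_table: list[tuple[str, int, int, str]] = []
    pos = 1
    for i in range(n_genes):
        w = background_w if in_island[i] < 0 else island_w[in_island[i]]
        n_codons = int(rng.integers(codons_per_gene[0], codons_per_gene[1] + 1))
        seq = "".join(rng.choice(codons, size=n_codons, p=w))
        start = pos
        end = pos + len(seq) - 1
        gene_table.append((f"gene_{i:04d}", start, end, "+"))
        parts.append(seq)
        spacer = "".join(
            rng.choice(list("ACGT"), size=spacer_len,
                       p=[(1 - background_gc) / 2, background_gc / 2,
                          background_gc / 2, (1 - background_gc) / 2])
        )
        parts.append(spacer)
        pos = end + spacer_len + 1
    truth = PlantedTruth(
        island_spans=[(start, start + length) for start, length, _, _ in island_specs]
    )
    return "".join(parts), gene_table, truth


def write_genome_fasta(sequence: str, path, seqid: str = "synthetic_genome") -> None:
    lines = [f">{seqid}"]
    lines += [sequence[i : i + 70] for i in range(0, len(sequence), 70)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_gene_table(gene_table: list[tuple[str, int, int, str]], path) -> None:
    lines = ["id\tstart\tend\tstrand"]
    lines += [f"{gid}\t{start}\t{end}\t{strand}" for gid, start, end, strand in gene_table]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
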