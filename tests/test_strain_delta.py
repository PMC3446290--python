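"""GPR evaluation, delta construction, and apply/revert round trips."""

from itertools import product

import pytest

from strainflux.models import GeneStatus, Metabolite, MetabolicModel, Reaction, Compartment
from strainflux.strain_delta import (
    ADDITION,
    DELETION,
    REGULATION_OFF,
    DeltaError,
    GPRSyntaxError,
    ModificationGroup,
    StrainDelta,
    apply_delta,
    build_delta,
    evaluate_gpr,
    load_delta,
    revert_groups,
    save_delta,
)
from strainflux.synthetic_data import make_toy_strain_pair, table1_fixture

from tests.conftest import make_linear_chain

STATUSES = (GeneStatus.PRESENT, GeneStatus.ABSENT, GeneStatus.PSEUDOGENE)


class TestEvaluateGPR:
    def test_empty_expression_is_true(self):
        assert evaluate_gpr("", {}) is True
        assert evaluate_gpr("   ", {"g1": GeneStatus.ABSENT}) is True

    def test_pseudogene_disables_complex(self):
        genes = {"g1": GeneStatus.PRESENT, "g2": GeneStatus.PSEUDOGENE}
        assert evaluate_gpr("(g1 and g2)", genes) is False
        assert evaluate_gpr("(g1 or g2)", genes) is True

    def test_missing_gene_defaults_to_present(self):
        assert evaluate_gpr("unknown_gene", {}) is True

    @pytest.mark.parametrize(
        "template",
        [
            "g1 and g2 and g3",
            "g1 or g2 or g3",
            "(g1 and g2) or g3",
            "g1 and (g2 or g3)",
            "(g1 or g2) and (g2 or g3)",
            "((g1))",
            "g1 and g2 or g3",  # 'or' binds looser than 'and'
        ],
    )
    def test_matches_truth_table_oracle(self, template):
        """All 3^3 status assignments match a python-eval oracle."""
        for statuses in product(STATUSES, repeat=3):
            table = dict(zip(("g1", "g2", "g3"), statuses))
            expected = eval(
                template,
                {},
                {g: s is GeneStatus.PRESENT for g, s in table.items()},
            )
            assert evaluate_gpr(template, table) is expected, (template, statuses)

    @pytest.mark.parametrize(
        "bad", ["g1 and", "(g1 or g2", "and g1", "g1 g2", "g1 )", "( )"]
    )
    def test_syntax_error_reports_position(self, bad):
        with pytest.raises(GPRSyntaxError, match="position"):
            evaluate_gpr(bad, {})


def _gene_model() -> MetabolicModel:
    model = make_linear_chain()
    model.reactions[1].gpr = "gA"
    model.reactions.insert(
        2,
        Reaction(id="T_A_alt", stoichiometry={"A_e": -1.0, "A_c": 1.0},
                 lower_bound=0.0, upper_bound=1000.0, gpr="gB and gC"),
    )
    return model


class TestBuildDelta:
    def test_identical_tables_give_empty_delta(self):
        model = _gene_model()
        genes = {"gA": GeneStatus.PRESENT, "gB": GeneStatus.PRESENT,
                 "gC": GeneStatus.PRESENT}
        delta = build_delta(model, genes, dict(genes))
        assert delta.groups == []

    def test_single_gene_loss_gives_one_deletion_group(self):
        model = _gene_model()
        ref = {"gA": GeneStatus.PRESENT, "gB": GeneStatus.PRESENT,
               "gC": GeneStatus.PRESENT}
        tgt = dict(ref, gA=GeneStatus.ABSENT)
        delta = build_delta(model, ref, tgt)
        assert len(delta.groups) == 1
        (group,) = delta.groups
        assert group.kind == DELETION
        assert group.reaction_ids == ["T_A"]
        assert group.payload_reactions[0].gpr == "gA"

    def test_excluded_set_matches_per_reaction_brute_force(self):
        """build_delta excludes exactly the reactions whose GPR truth value
        flips, across random gene-status assignments."""
        import numpy as np

        model = _gene_model()
        model.reactions[3].gpr = "gA or (gB and gC)"  # biomass? no - index 3
        rng = np.random.default_rng(7)
        gene_ids = ["gA", "gB", "gC"]
        for _ in range(30):
            ref = {g: STATUSES[rng.integers(3)] for g in gene_ids}
            tgt = {g: STATUSES[rng.integers(3)] for g in gene_ids}
            delta = build_delta(model, ref, tgt)
            got = {rid for g in delta.groups for rid in g.reaction_ids}
            expected = {
                r.id
                for r in model.reactions
                if r.gpr.strip()
                and evaluate_gpr(r.gpr, ref)
                and not evaluate_gpr(r.gpr, tgt)
            }
            assert got == expected

    def test_reactions_lost_to_same_gene_share_a_group(self):
        model = _gene_model()
        model.get_reaction("T_A_alt").gpr = "gA"
        ref = {"gA": GeneStatus.PRESENT}
        tgt = {"gA": GeneStatus.PSEUDOGENE}
        delta = build_delta(model, ref, tgt)
        assert len(delta.groups) == 1
        assert sorted(delta.groups[0].reaction_ids) == ["T_A", "T_A_alt"]

    def test_addition_collision_is_conflict_error(self):
        model = _gene_model()
        clash = ModificationGroup(
            name="x", kind=ADDITION, reaction_ids=["T_A"],
            payload_reactions=[model.get_reaction("T_A").copy()],
        )
        with pytest.raises(DeltaError, match="collides"):
            build_delta(model, {}, {}, target_additions=[clash])


class TestApplyRevert:
    def test_empty_delta_is_identity(self):
        model = make_linear_chain()
        delta = StrainDelta(reference_id="r", target_id="t", groups=[])
        out = apply_delta(model, delta)
        out.id = model.id  # target id differs by design
        assert out.equal_fields(model)

    def test_mixed_delta_net_reaction_count_and_switch_off(self):
        """1 addition + 1 deletion + 1 switch-off: net count unchanged,
        switched-off reaction has bounds (0, 0)."""
        model = _gene_model()
        add = Reaction(id="NEW", stoichiometry={"A_c": -1.0, "B_c": 1.0},
                       lower_bound=0.0, upper_bound=1000.0)
        delta = StrainDelta(
            reference_id="r", target_id="t",
            groups=[
                ModificationGroup(
                    name="add", kind=ADDITION, reaction_ids=["NEW"],
                    payload_reactions=[add],
                    payload_metabolites=[Metabolite(id="B_c", compartment=Compartment.CYTOSOL)],
                ),
                ModificationGroup(
                    name="del", kind=DELETION, reaction_ids=["T_A_alt"],
                    payload_reactions=[model.get_reaction("T_A_alt").copy()],
                ),
                ModificationGroup(
                    name="off", kind=REGULATION_OFF, reaction_ids=["EX_A(e)"],
                    original_bounds={"EX_A(e)": (-1000.0, 1000.0)},
                ),
            ],
        )
        out = apply_delta(model, delta)
        assert len(out.reactions) == len(model.reactions)
        off = out.get_reaction("EX_A(e)")
        assert (off.lower_bound, off.upper_bound) == (0.0, 0.0)
        assert not out.has_reaction("T_A_alt")
        assert out.has_reaction("NEW")

    def test_orphan_metabolites_dropped_on_deletion(self):
        model = _gene_model()
        model.reactions.append(
            Reaction(id="DEAD", stoichiometry={"X_c": -1.0, "Y_c": 1.0},
                     lower_bound=0.0, upper_bound=10.0)
        )
        model.metabolites += [Metabolite(id="X_c"), Metabolite(id="Y_c")]
        delta = StrainDelta(
            reference_id="r", target_id="t",
            groups=[ModificationGroup(
                name="del", kind=DELETION, reaction_ids=["DEAD"],
                payload_reactions=[model.get_reaction("DEAD").copy()],
                payload_metabolites=[Metabolite(id="X_c"), Metabolite(id="Y_c")],
            )],
        )
        out = apply_delta(model, delta)
        assert "X_c" not in out.metabolite_ids and "Y_c" not in out.metabolite_ids
        back = revert_groups(out, delta, {"del"})
        assert {"X_c", "Y_c"} <= set(back.metabolite_ids)

    def test_deleting_missing_reaction_is_consistency_error(self):
        model = make_linear_chain()
        delta = StrainDelta(
            reference_id="r", target_id="t",
            groups=[ModificationGroup(name="del", kind=DELETION,
                                      reaction_ids=["GHOST"],
                                      payload_reactions=[
                                          Reaction(id="GHOST", stoichiometry={"A_c": -1.0})
                                      ])],
        )
        with pytest.raises(DeltaError, match="GHOST"):
            apply_delta(model, delta)

    def test_revert_unknown_group_is_key_error(self, table1):
        target, _, delta, _, _ = table1
        with pytest.raises(KeyError, match="nonexistent"):
            revert_groups(target, delta, {"nonexistent"})

    def test_revert_empty_subset_is_identity(self, table1):
        target, _, delta, _, _ = table1
        assert revert_groups(target, delta, set()).equal_fields(target)

    def test_revert_all_restores_reference(self, table1):
        target, reference, delta, _, _ = table1
        back = revert_groups(target, delta, set(delta.group_names))
        back.id = reference.id
        assert back.equal_fields(reference)

    @pytest.mark.parametrize("seed", range(100))
    def test_round_trip_on_random_pairs(self, seed):
        """revert-all after apply reproduces the reference field-by-field
        on 100 random (model, delta) pairs."""
        target, reference, delta, _, _ = make_toy_strain_pair(
            n_conditions=1 + seed % 5, n_decoy_groups=seed % 4, seed=seed
        )
        back = revert_groups(target, delta, set(delta.group_names))
        back.id = reference.id
        assert back.equal_fields(reference)

    @pytest.mark.parametrize("seed", range(10))
    def test_revert_then_reapply_subset_restores_target(self, seed):
        """apply_delta and revert_groups are inverse on any subset."""
        import numpy as np

        target, _, delta, _, _ = make_toy_strain_pair(
            n_conditions=2, n_decoy_groups=2, seed=seed
        )
        rng = np.random.default_rng(seed)
        names = delta.group_names
        subset = {n for n in names if rng.random() < 0.5}
        reverted = revert_groups(target, delta, subset)
        sub_delta = StrainDelta(
            reference_id="x", target_id=target.id,
            groups=[g for g in delta.groups if g.name in subset],
        )
        again = apply_delta(reverted, sub_delta)
        again.id = target.id
        assert again.equal_fields(target)

    def test_fucose_transport_reversion_restores_growth(self, table1):
        """Restoring the lost fucose transporter gives the deletion strain
        reference-like growth on L-fucose."""
        from strainflux.fba import call_growth, solve_fba
        from strainflux.models import GrowthCall

        target, _, delta, conditions, _ = table1
        fucose = conditions[3]
        assert call_growth(solve_fba(target, fucose)) is GrowthCall.NO_GROWTH
        restored = revert_groups(target, delta, {"fucT_loss"})
        assert call_growth(solve_fba(restored, fucose)) is GrowthCall.GROWTH


class TestDeltaTSV:
    def test_round_trip_with_reference(self, tmp_path, table1):
        target, reference, delta, _, _ = table1
        path = tmp_path / "delta.tsv"
        save_delta(delta, path)
        loaded = load_delta(path, reference=reference)
        assert loaded.group_names == delta.group_names
        assert [g.kind for g in loaded.groups] == [g.kind for g in delta.groups]
        # applying the reloaded delta reproduces the same target strain
        out = apply_delta(reference, loaded)
        assert out.equal_fields(target)

    def test_loaded_delta_reverts_like_original(self, tmp_path, table1):
        target, reference, delta, _, _ = table1
        path = tmp_path / "delta.tsv"
        save_delta(delta, path)
        loaded = load_delta(path, reference=reference)
        back = revert_groups(target, loaded, set(loaded.group_names))
        back.id = reference.id
        assert back.equal_fields(reference)


class TestGroupInvariants:
    def test_duplicate_group_names_rejected(self):
        g = ModificationGroup(name="g", kind=REGULATION_OFF, reaction_ids=["R"])
        with pytest.raises(DeltaError, match="unique"):
            StrainDelta(reference_id="r", target_id="t", groups=[g, g])

    def test_reaction_in_two_groups_rejected(self):
        g1 = ModificationGroup(name="g1", kind=REGULATION_OFF, reaction_ids=["R"])
        g2 = ModificationGroup(name="g2", kind=REGULATION_OFF, reaction_ids=["R"])
        with pytest.raises(DeltaError, match="appears in groups"):
            StrainDelta(reference_id="r", target_id="t", groups=[g1, g2])

    def test_addition_without_payload_rejected(self):
        with pytest.raises(DeltaError, match="payload"):
            ModificationGroup(name="g", kind=ADDITION, reaction_ids=["R"])
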