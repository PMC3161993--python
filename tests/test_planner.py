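"""Assembly planning: balanced trees, addition-chain concatemers,
backbone assignment."""

import math
import random

import pytest

from bricklab import planner, registry
from bricklab.planner import (PlanningError, assign_backbones,
                              concatemer_oracle_steps,
                              design_monocistronic, plan_balanced,
                              plan_concatemer)
from bricklab.registry import BACKBONE_RESISTANCES

DESIGN8 = ["CMV", "Kozak", "Cerulean", "MCS1a", "MCS2a", "IRES",
           "FNeomycin", "SV40pA"]


# --------------------------------------------------------------------------
# balanced trees

def test_eight_part_design_plans_in_three_rounds():
    tree = plan_balanced(DESIGN8)
    assert tree.rounds == 3
    round1 = [(n.left.name, n.right.name)
              for n in tree.nodes_by_round()[1]]
    assert round1 == [("CMV", "Kozak"), ("Cerulean", "MCS1a"),
                      ("MCS2a", "IRES"), ("FNeomycin", "SV40pA")]
    round2 = [n.name for n in tree.nodes_by_round()[2]]
    assert round2 == ["CMV-Kozak-Cerulean-MCS1a",
                      "MCS2a-IRES-FNeomycin-SV40pA"]


def test_single_part_needs_no_rounds():
    assert plan_balanced(["CMV"]).rounds == 0


def test_five_parts_take_three_rounds_with_carry():
    tree = plan_balanced(["A", "B", "C", "D", "E"])
    assert tree.rounds == 3
    assert tree.leaves() == ["A", "B", "C", "D", "E"]


@pytest.mark.parametrize("n", range(1, 33))
def test_round_count_is_log2_ceiling(n):
    tree = plan_balanced([f"p{i}" for i in range(n)])
    assert tree.rounds == (math.ceil(math.log2(n)) if n > 1 else 0)
    assert tree.leaves() == [f"p{i}" for i in range(n)]


def test_empty_design_is_an_error():
    with pytest.raises(PlanningError):
        plan_balanced([])


# --------------------------------------------------------------------------
# monocistronic helper

def test_monocistronic_design_has_five_parts():
    coll = registry.load_registry()
    parts = design_monocistronic("CMV", "EGFP", "SV40pA", coll)
    assert parts == ["CMV", "Kozak", "EGFP", "Stop", "SV40pA"]


def test_monocistronic_rejects_translation_unit_reporter():
    coll = registry.load_registry()
    with pytest.raises(PlanningError):
        design_monocistronic("CMV", "FNeomycin", "SV40pA", coll)


def test_monocistronic_rejects_empty_promoter():
    with pytest.raises(PlanningError):
        design_monocistronic("", "EGFP", "SV40pA")


# --------------------------------------------------------------------------
# concatemers

def test_twelve_copies_in_four_steps():
    sched = plan_concatemer(12)
    assert len(sched) == 4
    assert sched.steps[-1][2] == 12


def test_single_copy_needs_no_steps():
    assert len(plan_concatemer(1)) == 0


def test_seven_copies_need_four_steps():
    assert len(plan_concatemer(7)) == 4


def test_out_of_bounds_copy_number():
    with pytest.raises(PlanningError):
        plan_concatemer(0)
    with pytest.raises(PlanningError):
        plan_concatemer(65)


def test_schedule_validity_and_minimality_against_bfs_oracle():
    for n in range(1, 21):
        sched = plan_concatemer(n)
        built = {1}
        for a, b, c in sched.steps:
            assert a in built and b in built and c == a + b
            built.add(c)
        assert (n == 1) or sched.steps[-1][2] == n
        assert len(sched) == concatemer_oracle_steps(n)


def test_doubling_first_preference():
    assert [s[2] for s in plan_concatemer(16).steps] == [2, 4, 8, 16]
    assert plan_concatemer(12).steps[:3] == [(1, 1, 2), (2, 2, 4),
                                             (4, 4, 8)]


# --------------------------------------------------------------------------
# backbone assignment

def leafmap(tree, codes):
    return dict(zip(tree.leaves(), codes))


def test_children_ak_ac_get_at():
    tree = plan_balanced(["a", "b"])
    assign_backbones(tree, {"a": "AK", "b": "AC"})
    assert tree.root.backbone == "AT"
    assert tree.root.antibiotic == "tet"


def test_children_at_at_tie_break_kan():
    tree = plan_balanced(["a", "b"])
    assign_backbones(tree, {"a": "AT", "b": "AT"})
    assert tree.root.backbone == "AK" and tree.root.antibiotic == "kan"


def test_assignment_satisfies_antibiotic_rule_everywhere():
    """With single-marker source codes two children can never exhaust all
    three selection antibiotics, so an 8-leaf tree must assign cleanly and
    every node must obey the exclusion rule."""
    tree = plan_balanced(["a", "b", "c", "d", "e", "f", "g", "h"])
    codes = dict(zip(tree.leaves(),
                     ["AK", "AC", "AT", "AK", "AC", "AT", "AK", "AC"]))
    assign_backbones(tree, codes)
    for node in tree.root.internal_nodes():
        used = (BACKBONE_RESISTANCES[node.left.backbone]
                | BACKBONE_RESISTANCES[node.right.backbone])
        assert node.antibiotic not in used
        assert node.antibiotic in BACKBONE_RESISTANCES[node.backbone]


def test_assignment_valid_on_random_trees():
    rng = random.Random(17)
    for _ in range(30):
        n = rng.randrange(2, 17)
        tree = plan_balanced([f"p{i}" for i in range(n)])
        codes = {f"p{i}": rng.choice(["A", "AK", "AC", "AT"])
                 for i in range(n)}
        try:
            assign_backbones(tree, codes)
        except PlanningError:
            continue
        for node in tree.root.internal_nodes():
            used = (BACKBONE_RESISTANCES[node.left.backbone]
                    | BACKBONE_RESISTANCES[node.right.backbone])
            assert node.antibiotic not in used and node.antibiotic != "amp"


def test_unknown_leaf_backbone_is_an_error():
    tree = plan_balanced(["a", "b"])
    with pytest.raises(PlanningError):
        assign_backbones(tree, {"a": "AK"})


def test_concatemer_length_model_exposes_both_readings():
    from bricklab.planner import concatemer_length
    assert concatemer_length(1) == 39
    assert concatemer_length(12) == 12 * 39 + 11 * 6
    assert concatemer_length(12, scar_inclusive=True) == 12 * 45
    with pytest.raises(PlanningError):
        concatemer_length(0)


def test_concatemer_length_matches_simulated_fusion(collection):
    """The scar-between-copies reading must equal what iterated assembly
    of the binding-site part actually produces."""
    from bricklab import fixtures, assembly, registry as _r
    from bricklab.planner import concatemer_length
    rec = _r.lookup(collection, "MS2BS")
    one = fixtures.clone_into_backbone(
        rec, fixtures.make_backbone({"amp", "chl"}, seed=81))
    other = fixtures.clone_into_backbone(
        rec, fixtures.make_backbone({"amp", "kan"}, seed=82))
    two = assembly.standard_assembly(
        one, other, fixtures.make_backbone({"amp", "tet"}, seed=83))
    assert len(two.product.record.payload) == concatemer_length(2)
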