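"""Three-antibiotic assembly: destination choice, product structure,
idempotence, fusion translation."""

import itertools

import pytest

from bricklab import assembly, fixtures, registry
from bricklab.assembly import (AssemblyError, Backbone, select_destination,
                               standard_assembly, translate_fusion)
from bricklab.grammar import detect_format
from bricklab.registry import BACKBONE_RESISTANCES

CODES = ("A", "AK", "AC", "AT")


def pool():
    return [Backbone(c) for c in ("AK", "AC", "AT")]


# --------------------------------------------------------------------------
# destination selection

def test_ak_x_ac_selects_tetracycline_backbone():
    dest, ab = select_destination("AK", "AC", pool())
    assert dest.code == "AT" and ab == "tet"


def test_ak_x_at_selects_chloramphenicol_backbone():
    dest, ab = select_destination("AK", "AT", pool())
    assert dest.code == "AC" and ab == "chl"


def test_at_x_at_tie_breaks_to_kanamycin():
    dest, ab = select_destination("AT", "AT", pool())
    assert dest.code == "AK" and ab == "kan"


def test_selection_brute_force_over_all_source_pairs():
    """select_destination succeeds exactly when some antibiotic remains,
    never returns ampicillin, and always returns a qualifying backbone."""
    for up, down in itertools.product(CODES, CODES):
        used = BACKBONE_RESISTANCES[up] | BACKBONE_RESISTANCES[down]
        feasible = bool({"kan", "chl", "tet"} - used)
        if feasible:
            dest, ab = select_destination(up, down, pool())
            assert ab != "amp"
            assert ab in dest.resistances and ab not in used
        else:
            with pytest.raises(AssemblyError):
                select_destination(up, down, pool())


def test_exhausted_antibiotics_is_infeasible():
    with pytest.raises(AssemblyError) as err:
        select_destination("AK", "AC",
                           [Backbone("AK"), Backbone("AC")])
    assert "no selection antibiotic" in str(err.value) or \
        err.value.code == "NO_ANTIBIOTIC"


# --------------------------------------------------------------------------
# standard assembly

def clone(collection, nickname, resist, seed):
    return fixtures.clone_into_backbone(
        registry.lookup(collection, nickname),
        fixtures.make_backbone(resist, seed=seed))


@pytest.fixture(scope="module")
def kozak_linker(collection):
    up = clone(collection, "Kozak", {"amp", "kan"}, 31)
    down = clone(collection, "Linker", {"amp", "chl"}, 32)
    dest = fixtures.make_backbone({"amp", "tet"}, seed=33)
    return standard_assembly(up, down, dest)


def test_payload_length_law(kozak_linker):
    # 12 bp Kozak + 6 bp scar + 72 bp Linker
    assert len(kozak_linker.product.record.payload) == 90
    assert kozak_linker.scar == "ACTAGA"


def test_product_regenerates_rfc23_affixes(kozak_linker, collection):
    prod = kozak_linker.product
    assert prod.format == "RFC23"
    from bricklab.grammar import affix
    assert detect_format(affix(prod.record.payload)).format == "RFC23"


def test_product_drops_ccdb_and_records_antibiotic(kozak_linker):
    assert not kozak_linker.product.plasmid.has_feature("ccdB")
    assert kozak_linker.selection_antibiotic == "tet"
    assert any(m.has_feature("ccdB") for m in kozak_linker.byproducts)


def test_product_is_idempotent_reusable_both_ways(kozak_linker, collection):
    """The fusion product re-enters assembly as upstream or downstream."""
    prod = kozak_linker.product   # in AT
    other_up = clone(collection, "HA", {"amp", "kan"}, 34)
    res_down = standard_assembly(other_up, prod,
                                 fixtures.make_backbone({"amp", "chl"},
                                                        seed=35))
    assert len(res_down.product.record.payload) == 27 + 6 + 90
    other_down = clone(collection, "HA", {"amp", "kan"}, 36)
    res_up = standard_assembly(prod, other_down,
                               fixtures.make_backbone({"amp", "chl"},
                                                      seed=37))
    assert len(res_up.product.record.payload) == 90 + 6 + 27


def test_order_matters_for_sequence_not_length(collection):
    a = clone(collection, "Flag", {"amp", "kan"}, 41)
    b = clone(collection, "HA", {"amp", "chl"}, 42)
    ab = standard_assembly(a, b, fixtures.make_backbone({"amp", "tet"},
                                                        seed=43))
    ba = standard_assembly(b, a, fixtures.make_backbone({"amp", "tet"},
                                                        seed=44))
    pa, pb = ab.product.record.payload, ba.product.record.payload
    assert len(pa) == len(pb)
    assert pa != pb


def test_payload_associativity(collection):
    def pay(res):
        return res.product.record.payload

    a = clone(collection, "Flag", {"amp", "kan"}, 51)
    b = clone(collection, "HA", {"amp", "chl"}, 52)
    c = clone(collection, "His", {"amp", "kan"}, 53)
    ab = standard_assembly(a, b, fixtures.make_backbone({"amp", "tet"},
                                                        seed=54))
    ab_c = standard_assembly(ab.product, c,
                             fixtures.make_backbone({"amp", "chl"},
                                                    seed=55))
    bc = standard_assembly(b, c, fixtures.make_backbone({"amp", "tet"},
                                                        seed=56))
    a_bc = standard_assembly(a, bc.product,
                             fixtures.make_backbone({"amp", "chl"},
                                                    seed=57))
    assert pay(ab_c) == pay(a_bc)


def test_dam_blocked_downstream_part_raises(collection):
    tc_part = fixtures.make_part(
        fixtures.PartSpec(role=assembly.Role.NON_CODING, payload_length=20,
                          leading_TC=True, seed=9))
    up = clone(collection, "Flag", {"amp", "kan"}, 61)
    down = fixtures.clone_into_backbone(
        tc_part, fixtures.make_backbone({"amp", "chl"}, seed=62))
    dest = fixtures.make_backbone({"amp", "tet"}, seed=63)
    with pytest.raises(AssemblyError) as err:
        standard_assembly(up, down, dest)
    assert err.value.code == "DAM_XBAI_BLOCK"
    # the same part is fine as the upstream partner (EcoRI+SpeI digest)
    res = standard_assembly(down, up, dest)
    assert res.scar == "ACTAGA"


def test_internal_biobrick_site_rejected(collection):
    bad = fixtures.make_part(
        fixtures.PartSpec(role=assembly.Role.NON_CODING, payload_length=30,
                          internal_sites=["EcoRI"], seed=10))
    up = fixtures.clone_into_backbone(
        bad, fixtures.make_backbone({"amp", "kan"}, seed=64))
    down = clone(collection, "Flag", {"amp", "chl"}, 65)
    with pytest.raises(AssemblyError) as err:
        standard_assembly(up, down,
                          fixtures.make_backbone({"amp", "tet"}, seed=66))
    assert err.value.code == "BB_SITE_INTERNAL"


# --------------------------------------------------------------------------
# fusion translation

def test_head_internal_tail_translation_inserts_thr_arg(collection):
    parts = [registry.lookup(collection, n)
             for n in ("Kozak", "Linker", "Stop")]
    pep = translate_fusion(parts)
    # 24-residue linker framed by Thr-Arg scar dipeptides
    assert pep.count("TR") >= 2
    assert pep.startswith("M")
    assert len(pep) == 1 + 1 + 2 + 24 + 2


def test_premature_stop_detected(collection):
    parts = [registry.lookup(collection, n)
             for n in ("Kozak", "Stop", "Stop")]
    with pytest.raises(AssemblyError) as err:
        translate_fusion(parts)
    assert err.value.code == "PREMATURE_STOP"


def test_rfc10_member_causes_frameshift(collection):
    parts = [registry.lookup(collection, n)
             for n in ("Kozak", "Linker", "Stop")]
    with pytest.raises(AssemblyError) as err:
        translate_fusion(parts, formats=["RFC23", "RFC10", "RFC23"])
    assert err.value.code == "FRAMESHIFT"
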