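"""Digestion/ligation core: site scanning, fragment bookkeeping, sealing."""

import random

import pytest

from bricklab import seqmodel
from bricklab.seqmodel import (BLUNT, Fragment, LigationError, Molecule,
                               Overhang, digest, find_sites, get_enzyme,
                               ligate, load_enzymes, revcomp)

PREFIX = "GAATTCGCGGCCGCTTCTAGA"
SUFFIX = "ACTAGTAGCGGCCGCTGCAG"


def lin(seq, **kw):
    return Molecule("m", seq, "linear", **kw)


def circ(seq, **kw):
    return Molecule("m", seq, "circular", **kw)


# --------------------------------------------------------------------------
# molecule invariants

def test_molecule_rejects_ambiguity_codes():
    with pytest.raises(seqmodel.BrickLabError):
        lin("ACGTN")


def test_circular_molecules_carry_no_overhangs():
    with pytest.raises(seqmodel.BrickLabError):
        circ("ACGT", end5=Overhang("5p", "AATT"))


def test_packaged_enzymes_palindromic_with_consistent_overhangs():
    for enz in load_enzymes().values():
        assert revcomp(enz.recognition) == enz.recognition
        assert enz.overhang_len == abs(enz.cut_top - enz.cut_bottom)


# --------------------------------------------------------------------------
# find_sites

@pytest.mark.parametrize("seq,enzyme,expected", [
    (PREFIX, "EcoRI", [0]),
    (PREFIX, "XbaI", [15]),
    (SUFFIX, "SpeI", [0]),
    (SUFFIX, "PstI", [14]),
    ("", "EcoRI", []),
    ("ACGTACGT", "NotI", []),
])
def test_find_sites_on_affixes(seq, enzyme, expected):
    assert find_sites(lin(seq), enzyme) == expected


def test_find_sites_unknown_enzyme():
    with pytest.raises(seqmodel.UnknownEnzymeError):
        find_sites(lin("ACGT"), seqmodel.get_enzyme("nosuch"))


def test_find_sites_wraps_circular_origin():
    # GAATTC split across the origin: ...GAA | TTC...
    mol = circ("TTC" + "A" * 40 + "GAA")
    assert find_sites(mol, "EcoRI") == [43]


def test_find_sites_agrees_with_window_scan_oracle():
    """Site scan vs a naive O(n*m) window comparison on random sequences."""
    rng = random.Random(42)
    enzymes = [get_enzyme(n) for n in ("EcoRI", "NotI", "PstI", "SmaI")]
    for _ in range(100):
        seq = "".join(rng.choice("ACGT") for _ in range(2000))
        mol = lin(seq)
        for enz in enzymes:
            naive = [i for i in range(len(seq) - len(enz.recognition) + 1)
                     if seq[i:i + len(enz.recognition)] == enz.recognition]
            assert find_sites(mol, enz) == naive


# --------------------------------------------------------------------------
# digestion

def test_circular_two_cuts_two_fragments():
    plasmid = circ("GAATTC" + "A" * 50 + "CTGCAG" + "G" * 50)
    frags = digest(plasmid, ["EcoRI", "PstI"])
    assert len(frags) == 2
    assert sum(len(f) for f in frags) == len(plasmid)


def test_zero_cuts_returns_molecule_unchanged():
    mol = circ("ACGT" * 30)
    frags = digest(mol, ["EcoRI"])
    assert len(frags) == 1
    assert frags[0].molecule.seq == mol.seq
    assert frags[0].molecule.is_circular


def test_rfc23_insert_overhangs():
    """EcoRI+SpeI release of an RFC23 part leaves AATT and CTAG ends."""
    payload = "GGCGCAGCC"
    plasmid = circ("T" * 40 + PREFIX + payload + SUFFIX + "G" * 40)
    frags = digest(plasmid, ["EcoRI", "SpeI"])
    insert = next(f for f in frags if payload in f.molecule.seq)
    assert insert.molecule.end5 == Overhang("5p", "AATT")
    assert insert.molecule.end3 == Overhang("5p", revcomp("CTAG"))


def test_dam_blocks_xbai_in_gatc_context():
    blocked = lin("AAAA" + "GA" + "TCTAGA" + "AAAA")   # GATCTAGA
    assert digest(blocked, ["XbaI"], dam_plus=True)[0].molecule.seq \
        == blocked.seq
    assert len(digest(blocked, ["XbaI"], dam_plus=False)) == 2
    blocked2 = lin("AAAA" + "TCTAGA" + "TC" + "AAAA")  # TCTAGATC
    assert len(digest(blocked2, ["XbaI"], dam_plus=True)) == 1
    clean = lin("AAAA" + "TCTAGA" + "GG" + "AAAA")
    assert len(digest(clean, ["XbaI"], dam_plus=True)) == 2


def test_length_conservation_over_random_digests():
    rng = random.Random(7)
    names = list(load_enzymes())
    for _ in range(25):
        seq = "".join(rng.choice("ACGT") for _ in range(1500))
        subset = rng.sample(names, rng.randrange(1, 5))
        for mol in (lin(seq), circ(seq)):
            frags = digest(mol, subset, dam_plus=False)
            assert sum(len(f) for f in frags) == len(seq)


def test_rotation_invariance_of_circular_digestion():
    rng = random.Random(11)
    seq = "".join(rng.choice("ACGT") for _ in range(800)) + "GAATTC" + \
        "".join(rng.choice("ACGT") for _ in range(300)) + "CTGCAG"
    mol = circ(seq)
    base = sorted(len(f) for f in digest(mol, ["EcoRI", "PstI"]))
    for k in (1, 137, 450, 1100):
        rot = mol.rotated(k)
        assert sorted(len(f) for f in digest(rot, ["EcoRI", "PstI"])) == base


# --------------------------------------------------------------------------
# ligation

def test_digest_ligate_round_trip_regenerates_plasmid():
    rng = random.Random(3)
    filler = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
    seq = ("GAATTC" + filler(200) + "CTGCAG" + filler(150)
           + "AAGCTT" + filler(250))
    mol = circ(seq)
    frags = digest(mol, ["EcoRI", "PstI", "HindIII"])
    assert len(frags) == 3
    products = ligate(frags)
    regenerated = [p for p in products if len(p) == len(mol)]
    assert regenerated, "full-length product missing"
    doubled = regenerated[0].seq * 2
    assert mol.seq in doubled or revcomp(mol.seq) in doubled


def test_spei_xbai_scar_junction_is_recuttable_by_neither():
    payload_up, payload_dn = "GGCGCAGCC", "GGTGCTGGA"
    up = lin(PREFIX + payload_up + SUFFIX)
    dn = lin(PREFIX + payload_dn + SUFFIX)
    left = digest(up, ["SpeI"])[0]
    right = digest(dn, ["XbaI"])[1]
    assert left.molecule.end3.matches(right.molecule.end5)
    joined = left.molecule.seq + right.molecule.seq
    middle = joined[len(PREFIX):joined.index(payload_dn) + 9]
    junction = joined[joined.index(payload_up) + 9:
                      joined.index(payload_dn)]
    assert "TCTAGA" not in middle[middle.index(payload_up):]
    assert junction == "ACTAGA"
    assert "ACTAGT" not in junction


def test_xbai_joins_nhei_compatible_cohesive_ends():
    a = lin("AAAA" + "TCTAGA" + "CCCC")
    b = lin("GGGG" + "GCTAGC" + "TTTT")
    fa = digest(a, ["XbaI"])[1]     # starts CTAGA...
    fb = digest(b, ["NheI"])[0]     # ends ...G with CTAG bottom overhang
    assert fb.molecule.end3.matches(fa.molecule.end5)
    junction = fb.molecule.seq[-1] + fa.molecule.seq[:5]
    assert junction == "GCTAGA"
    assert "TCTAGA" not in junction and "GCTAGC" not in junction


def test_ecoRI_end_does_not_join_psti_end():
    a = digest(lin("AAAA" + "GAATTC" + "CCCC"), ["EcoRI"])[0]
    b = digest(lin("GGGG" + "CTGCAG" + "TTTT"), ["PstI"])[1]
    assert not a.molecule.end3.matches(b.molecule.end5)
    with pytest.raises(LigationError):
        ligate([a, b])


def test_single_fragment_self_circularizes():
    frags = digest(circ("GAATTC" + "A" * 60), ["EcoRI"])
    assert len(frags) == 1 and not frags[0].molecule.is_circular
    products = ligate(frags)
    assert len(products) == 1
    assert products[0].is_circular and len(products[0]) == 66


def test_blunt_ends_join_blunt():
    a = Fragment(lin("AAACCC"))
    b = Fragment(lin("GGGTTT"))
    products = ligate([a, b], circular_only=False)
    assert any(len(p) == 12 for p in products)


# --------------------------------------------------------------------------
# I/O

def test_fasta_round_trip_preserves_topology(tmp_path):
    mols = [circ("ACGT" * 10), lin("TTGGCCAA")]
    path = tmp_path / "m.fa"
    seqmodel.write_fasta(mols, path)
    back = seqmodel.read_fasta(path)
    assert [(m.seq, m.topology) for m in back] == \
        [(m.seq, m.topology) for m in mols]


def test_genbank_round_trip_preserves_features(tmp_path):
    mol = circ("ACGT" * 50)
    mol.features.append(seqmodel.Feature("testfeat", 10, 40, 1, "CDS"))
    path = tmp_path / "m.gb"
    seqmodel.write_genbank(mol, path)
    back = seqmodel.read_genbank(path)
    assert back.topology == "circular"
    f = back.feature("testfeat")
    assert (f.start, f.end, f.kind) == (10, 40, "CDS")
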