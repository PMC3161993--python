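"""Deterministic synthetic-data generator.

Everything here is a placeholder standing in for real laboratory sequences
that are not distributed with the toolkit: payloads are random codon/base
strings constrained to reproduce every tabulated property of the part they
stand for (size, 3n, Kozak/stop content, classical restriction-site
inventory, no internal assembly-enzyme sites, no leading TC), and backbones
are synthetic circular plasmids with a prefix/ccdB/suffix cloning
interface, standard sequencing-primer landing sites and resistance-marker
annotations.  All outputs are byte-deterministic under a seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import grammar
from .assembly import Backbone, ClonedPart
from .grammar import RFC23_PREFIX, RFC23_SUFFIX, Role
from .registry import (BACKBONE_RESISTANCES, PartCollection, PartRecord,
                       load_registry)
from .rmdi import core_sequence
from .seqmodel import (BrickLabError, Feature, Molecule, find_sites,
                       get_enzyme, load_enzymes, revcomp)


class FixtureError(BrickLabError):
    pass


STOPS = ("TAA", "TAG", "TGA")
NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOPS
)
KOZAK_MOTIF = "GCCACC"

#: standard BioBrick sequencing primers flanking the cloning interface
BBA_G00100 = "TGCCACCTGACGTCTAAGAA"
BBA_G00101 = "ATTACCGCCTTTGAGTGAGC"

#: sEspin cloning primers (forward adds nothing; reverse tails a stop and
#: an AgeI site onto the amplicon)
SESPIN_F = "AAGAGGGATCCATGAACTCCC"
SESPIN_R = "CTTCTTACCGGTTTACTTAGGGATCTCCCCCTTC"

# the vector context between the sequencing-primer sites and the part
# contributes 312 bp to a colony-PCR amplicon (primers included)
_SPACER_UP = 115
_SPACER_DOWN = 116

#: hand-designed placeholder payloads where internal structure matters;
#: MCS frame variants pad at the 5' end, lox parts pad their 34 bp core to
#: the tabulated 36 bp at the 3' end (keeping frame 0 stop-free)
FIXED_PAYLOADS = {
    "Kozak": KOZAK_MOTIF + "ATGGCA",
    "Stop": "TAAGTAAGTAA",                       # stops in all three frames
    "MCS1a": "GGGCCCCTCGAGGGATCCAAGCTTCACCAACC",
    "MCS1b": "G" + "GGGCCCCTCGAGGGATCCAAGCTTCACCAACC",
    "MCS1c": "GC" + "GGGCCCCTCGAGGGATCCAAGCTTCACCAACC",
    "MCS2a": "GAGCTCAGATCTGGTACCACCGGTCAACCA",
    "MCS2b": "G" + "GAGCTCAGATCTGGTACCACCGGTCAACCA",
    "MCS2c": "GC" + "GAGCTCAGATCTGGTACCACCGGTCAACCA",
    "MCS3a": "TGTACAAGGCCTGTCGACGCATGCATCGATGCAGCTGCA",
    "MCS3b": "G" + "TGTACAAGGCCTGTCGACGCATGCATCGATGCAGCTGCA",
    "MCS3c": "GC" + "TGTACAAGGCCTGTCGACGCATGCATCGAT" + "ATAAGCAGC",
    "Loxp": core_sequence("loxP") + "CA",
    "Lox66": core_sequence("lox66") + "AA",
    "Lox71": core_sequence("lox71") + "CA",
}


@dataclass
class PartSpec:
    """Request for one synthetic part."""

    role: Role = Role.INTERNAL
    payload_length: int = 72
    frame_safe: bool | None = None
    leading_TC: bool = False
    internal_sites: list[str] = field(default_factory=list)
    kozak: bool | None = None
    stop: bool | None = None
    seed: int = 0


def _rng(*key) -> random.Random:
    return random.Random(repr(key))


# --------------------------------------------------------------------------
# low-level sequence surgery

def _contained(pos: int, length: int, ranges) -> bool:
    return any(a <= pos and pos + length <= b for a, b in ranges)


def _in_ranges(idx: int, ranges) -> bool:
    return any(a <= idx < b for a, b in ranges)


def _unwanted_sites(seq: str, protected, circular: bool):
    mol = Molecule("scan", seq, "circular" if circular else "linear")
    n = len(seq)
    hits = []
    for name, enz in load_enzymes().items():
        m = len(enz.recognition)
        for pos in find_sites(mol, enz):
            if pos + m <= n and _contained(pos, m, protected):
                continue
            hits.append((pos, m))
    return sorted(hits)


def _scrub(seq: str, rng: random.Random, protected=(),
           stop_free: bool = False, circular: bool = False,
           max_rounds: int = 2000) -> str:
    """Mutate single bases until no enzyme site survives outside the
    protected ranges.  With ``stop_free`` no mutation may introduce a
    frame-0 stop codon."""
    s = list(seq)
    n = len(s)
    for _ in range(max_rounds):
        hits = _unwanted_sites("".join(s), protected, circular)
        if not hits:
            return "".join(s)
        pos, m = hits[0]
        free = [(pos + j) % n for j in range(m)
                if not _in_ranges((pos + j) % n, protected)]
        if not free:
            raise FixtureError("restriction site wholly inside protected "
                               "ranges cannot be scrubbed")
        done = False
        for _ in range(12):
            idx = rng.choice(free)
            new = rng.choice("ACGT")
            if new == s[idx]:
                continue
            old = s[idx]
            s[idx] = new
            if stop_free:
                c = (idx // 3) * 3
                if "".join(s[c:c + 3]) in STOPS:
                    s[idx] = old
                    continue
            done = True
            break
        if not done:
            raise FixtureError("scrubbing stalled")
    raise FixtureError("could not scrub unwanted restriction sites")


def _random_codons(rng: random.Random, n_codons: int) -> str:
    return "".join(rng.choice(NONSTOP_CODONS) for _ in range(n_codons))


def _random_bases(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _drop_frame0_stops(seq: str, rng: random.Random, skip=()) -> str:
    s = list(seq)
    for i in range(0, len(s) - 2, 3):
        while "".join(s[i:i + 3]) in STOPS:
            j = i + rng.randrange(3)
            if _in_ranges(j, skip):
                j = next(k for k in (i, i + 1, i + 2)
                         if not _in_ranges(k, skip))
            s[j] = rng.choice("ACGT")
    return "".join(s)


def _embed(seq: str, inserts) -> str:
    s = list(seq)
    for pos, sub in inserts:
        s[pos: pos + len(sub)] = sub
    return "".join(s)


# --------------------------------------------------------------------------
# make_part

def make_part(spec: PartSpec) -> PartRecord:
    """Generate a placeholder part record satisfying every toggle exactly.

    The payload is RFC23-compatible by construction: free of assembly-enzyme
    sites (unless explicitly requested via ``internal_sites``), no leading
    TC (unless requested), stop/Kozak content per the toggles.
    """
    role = spec.role if isinstance(spec.role, Role) else Role(spec.role)
    n = spec.payload_length
    kozak = spec.kozak if spec.kozak is not None else \
        role in (Role.HEAD, Role.TRANSLATION_UNIT)
    stop = spec.stop if spec.stop is not None else \
        role in (Role.TAIL, Role.TRANSLATION_UNIT)
    frame_safe = spec.frame_safe if spec.frame_safe is not None else \
        n % 3 == 0

    if frame_safe != (n % 3 == 0):
        raise FixtureError(
            f"frame_safe={frame_safe} contradicts payload_length={n}")
    if role == Role.INTERNAL and (stop or kozak or not frame_safe):
        raise FixtureError("an internal domain is 3n with neither Kozak "
                           "nor stop")
    if role == Role.HEAD and (stop or not kozak):
        raise FixtureError("a head domain has a Kozak and no stop")
    if role == Role.TAIL and (kozak or not stop):
        raise FixtureError("a tail domain has a stop and no Kozak")
    if role == Role.TRANSLATION_UNIT and not (kozak and stop):
        raise FixtureError("a translation unit has both Kozak and stop")
    if role == Role.NON_CODING and kozak:
        raise FixtureError("a non-coding part carries no Kozak")
    if kozak and spec.leading_TC:
        raise FixtureError("a Kozak part cannot start with TC")
    if kozak and n < len(KOZAK_MOTIF) + 6:
        raise FixtureError(f"payload_length {n} too short for a Kozak head")

    rng = _rng("part", spec.seed, role.value, n, spec.leading_TC,
               tuple(spec.internal_sites), kozak, stop)
    payload = build_payload(rng, n, kozak=kozak, stop=stop,
                            leading_TC=spec.leading_TC,
                            internal_sites=list(spec.internal_sites))
    return PartRecord(
        nickname=f"syn{role.value.title().replace('_', '')}{n}",
        group="Others", description=f"synthetic {role.value} placeholder",
        size_bp=n, backbone_code="AC", has_kozak=kozak, has_stop=stop,
        frame_safe=frame_safe, payload=payload, synthetic=True,
    )


def build_payload(rng: random.Random, n: int, kozak: bool = False,
                  stop: bool = False, leading_TC: bool = False,
                  internal_sites=()) -> str:
    """Random payload of length ``n`` with exactly the requested content.

    The sequence is scrubbed of restriction sites *in its wrapped RFC23
    context*, so affix junctions cannot create accidental sites either.
    """
    head = KOZAK_MOTIF + "ATG" if kozak else ""
    payload = head + _random_bases(rng, n - len(head))
    if leading_TC:
        payload = "TC" + payload[2:]
    elif payload.startswith("TC"):
        payload = "CC" + payload[2:]

    protected = []
    if head:
        protected.append((0, len(head)))
    if leading_TC:
        protected.append((0, 2))

    inserts = []
    at = ((max(len(head), 3) + 2) // 3) * 3
    for name in internal_sites:
        site = get_enzyme(name).recognition
        if at + len(site) > n - (3 if stop else 0):
            raise FixtureError("payload too short for the requested sites")
        inserts.append((at, site))
        protected.append((at, at + len(site)))
        at = ((at + len(site) + 5) // 3) * 3
    payload = _embed(payload, inserts)

    payload = _drop_frame0_stops(payload, rng, skip=protected)
    if stop:
        if n % 3 == 0 and not _in_ranges(n - 3, protected):
            payload = payload[: n - 3] + "TAA"
            protected.append((n - 3, n))
        else:
            spot = next(i for i in range(0, n - 2, 3)
                        if i >= len(head)
                        and not any(a < i + 3 and i < b
                                    for a, b in protected))
            payload = payload[:spot] + "TAA" + payload[spot + 3:]
            protected.append((spot, spot + 3))

    # scrub in wrapped context so the affix junctions stay clean too; the
    # RFC23 prefix is 21 bp, so frame 0 of the wrapped sequence coincides
    # with frame 0 of the payload and stop-freeness can be preserved there
    pre, suf = RFC23_PREFIX, RFC23_SUFFIX
    off = len(pre)
    wrapped = pre + payload + suf
    wrapped_prot = [(a + off, b + off) for a, b in protected]
    wrapped_prot += [(0, len(pre)), (len(pre) + n, len(wrapped))]
    wrapped = _scrub(wrapped, rng, protected=wrapped_prot,
                     stop_free=not stop)
    payload = wrapped[off: off + n]
    # scrubbing a site that spans the prefix junction can leave a leading
    # TC; repair and re-scrub until stable
    for _ in range(20):
        if leading_TC or not payload.startswith("TC"):
            break
        payload = "C" + payload[1:]
        wrapped = _scrub(pre + payload + suf, rng,
                         protected=wrapped_prot, stop_free=not stop)
        payload = wrapped[off: off + n]
    if not stop and grammar.frame0_stops(payload):
        raise FixtureError("could not build a stop-free payload")
    if stop and not grammar.frame0_stops(payload):
        raise FixtureError("lost the required stop codon")
    if not leading_TC and payload.startswith("TC"):
        raise FixtureError("payload unexpectedly starts with TC")
    return payload


# --------------------------------------------------------------------------
# backbones

def make_backbone(resistances, with_ccdB: bool = True,
                  with_primer_sites: bool = True, seed: int = 0,
                  size: int | None = None, classical_sites=(),
                  name: str | None = None) -> Backbone:
    """Synthetic circular destination/backbone plasmid.

    Layout (clockwise from 0): sequencing-primer site (BBa_G00100),
    upstream spacer, RFC23 prefix, ccdB stuffer (optional), RFC23 suffix,
    downstream spacer, reverse sequencing-primer site (BBa_G00101, bottom
    strand), one annotated marker per resistance, filler carrying any
    requested classical sites.
    """
    resistances = frozenset(resistances)
    if "amp" not in resistances:
        raise FixtureError("every backbone carries ampicillin resistance")
    code = next((c for c, r in BACKBONE_RESISTANCES.items()
                 if r == resistances), None)
    if code is None:
        raise FixtureError(
            f"no backbone code for resistances {sorted(resistances)}")
    rng = _rng("backbone", seed, code, size, with_ccdB, with_primer_sites,
               tuple(classical_sites))

    ccdb_len = 300 if with_ccdB else 0
    marker_len = 240
    fixed = (20 + _SPACER_UP + len(RFC23_PREFIX) + ccdb_len
             + len(RFC23_SUFFIX) + _SPACER_DOWN + 20
             + marker_len * len(resistances))
    filler_len = (size - fixed) if size is not None else 400
    if filler_len < 60:
        raise FixtureError(f"requested size {size} is too small")

    pieces: list[str] = []
    feats: list[Feature] = []

    def add(seq_part: str, label: str | None = None,
            kind: str = "misc_feature", strand: int = 1):
        start = sum(len(p) for p in pieces)
        pieces.append(seq_part)
        if label:
            feats.append(Feature(label, start, start + len(seq_part),
                                 strand, kind))

    add(BBA_G00100 if with_primer_sites else _random_bases(rng, 20),
        "BBa_G00100", "primer_bind")
    add(_random_bases(rng, _SPACER_UP))
    add(RFC23_PREFIX, "prefix")
    if with_ccdB:
        add(_random_codons(rng, ccdb_len // 3), "ccdB", "misc_feature")
    add(RFC23_SUFFIX, "suffix")
    add(_random_bases(rng, _SPACER_DOWN))
    add(revcomp(BBA_G00101) if with_primer_sites
        else _random_bases(rng, 20), "BBa_G00101", "primer_bind", -1)
    marker_names = {"amp": "AmpR", "kan": "KanR", "chl": "CmR",
                    "tet": "TetR"}
    for res in sorted(resistances):
        add(_random_codons(rng, marker_len // 3), marker_names[res],
            "marker")
    filler_start = sum(len(p) for p in pieces)
    add(_random_bases(rng, filler_len), "ori_region")

    seq = "".join(pieces)
    prot = [(f.start, f.end) for f in feats
            if f.label in ("prefix", "suffix")]
    if with_primer_sites:
        prot += [(f.start, f.end) for f in feats
                 if f.label in ("BBa_G00100", "BBa_G00101")]
    inserts = []
    at = filler_start + 10
    for enz_name in classical_sites:
        site = get_enzyme(enz_name).recognition
        inserts.append((at, site))
        prot.append((at, at + len(site)))
        at += len(site) + 4
    seq = _embed(seq, inserts)
    seq = _scrub(seq, rng, protected=prot, circular=True)
    mol = Molecule(name or f"pSB1{code}3syn", seq, "circular",
                   features=feats)
    return Backbone(code=code, has_ccdB=with_ccdB, molecule=mol)


def clone_into_backbone(rec: PartRecord, backbone: Backbone,
                        format: str = "RFC23") -> ClonedPart:
    """Place a payload between a backbone's prefix and suffix (replacing
    any ccdB stuffer), as if the part had been cloned there."""
    if rec.payload is None:
        raise FixtureError(f"{rec.nickname}: no payload to clone")
    mol = backbone.molecule
    pre = mol.feature("prefix")
    suf = mol.feature("suffix")
    pre_s, suf_s = grammar.AFFIXES[format]
    seq = (mol.seq[: pre.start] + pre_s + rec.payload + suf_s
           + mol.seq[suf.end:])
    delta = len(seq) - len(mol.seq)
    feats = [
        Feature("prefix", pre.start, pre.start + len(pre_s)),
        Feature(f"part:{rec.nickname}", pre.start + len(pre_s),
                pre.start + len(pre_s) + len(rec.payload)),
        Feature("suffix", pre.start + len(pre_s) + len(rec.payload),
                pre.start + len(pre_s) + len(rec.payload) + len(suf_s)),
    ]
    for f in mol.features:
        if f.label in ("prefix", "suffix", "ccdB"):
            continue
        if f.end <= pre.start:
            feats.append(f)
        elif f.start >= suf.end:
            feats.append(Feature(f.label, f.start + delta, f.end + delta,
                                 f.strand, f.kind))
    plasmid = Molecule(f"p{rec.nickname}", seq, "circular", features=feats)
    return ClonedPart(record=rec,
                      backbone=Backbone(backbone.code, has_ccdB=False,
                                        molecule=plasmid),
                      plasmid=plasmid, format=format)


# --------------------------------------------------------------------------
# the full synthetic collection

def load_collection(seed: int = 0) -> PartCollection:
    """The packaged registry with a synthetic placeholder payload attached
    to every record (designed payloads where structure matters, seeded
    random payloads elsewhere, backbone plasmids at their tabulated size)."""
    coll = load_registry()
    for rec in coll:
        if rec.is_backbone:
            bb = make_backbone(
                BACKBONE_RESISTANCES[_backbone_code_of(rec.nickname)],
                with_ccdB=True, seed=seed, size=rec.size_bp,
                classical_sites=tuple(rec.restriction_sites),
                name=rec.nickname)
            rec.payload = bb.molecule.seq
        elif rec.nickname in FIXED_PAYLOADS:
            rec.payload = FIXED_PAYLOADS[rec.nickname]
        else:
            rng = _rng("collection", seed, rec.nickname)
            rec.payload = build_payload(
                rng, rec.size_bp, kozak=rec.has_kozak, stop=rec.has_stop,
                leading_TC=False,
                internal_sites=tuple(rec.restriction_sites))
        rec.synthetic = True
    return coll


def _backbone_code_of(nickname: str) -> str:
    return {"pSB1A3": "A", "pSB1AK3": "AK", "pSB1AC3": "AC",
            "pSB1AT3": "AT"}[nickname]


def backbone_of(coll: PartCollection, rec: PartRecord,
                seed: int = 0) -> Backbone:
    """A fresh synthetic plasmid of the backbone the record is shipped in."""
    return make_backbone(BACKBONE_RESISTANCES[rec.backbone_code],
                         with_ccdB=True, seed=seed)


def collection_fasta(path, seed: int = 0) -> None:
    """Write the synthetic collection as FASTA, affixes in capitals and
    payloads in lower case (backbone plasmids all-capitals, circular)."""
    coll = load_collection(seed)
    lines = []
    for rec in coll:
        if rec.is_backbone:
            lines.append(f">{rec.nickname} topology=circular synthetic=true")
            lines.append(rec.payload)
        else:
            lines.append(f">{rec.nickname} topology=linear synthetic=true")
            lines.append(RFC23_PREFIX + rec.payload.lower() + RFC23_SUFFIX)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# composite demo constructs

def make_rmdi_pair(seed: int = 0) -> tuple[Molecule, Molecule]:
    """Target locus and donor plasmid reproducing the gene-switch design.

    Target (linear chromosomal locus): promoter, then a tdTomato-placeholder
    CDS carrying an in-frame lox66 inside its coding sequence.  Donor
    (circular, promoterless): lox71 followed by an EGFP-placeholder CDS.
    """
    rng = _rng("rmdi", seed)
    lox66 = FIXED_PAYLOADS["Lox66"]
    lox71 = FIXED_PAYLOADS["Lox71"]

    up_flank = _random_bases(rng, 200)
    promoter = _random_bases(rng, 654)
    gap = _random_bases(rng, 21)
    td_a = _random_codons(rng, 150)
    td_b = _random_codons(rng, 150)
    td_cds = "ATG" + td_a + lox66 + td_b + "TAA"
    down_flank = _random_bases(rng, 150)

    t_seq = up_flank + promoter + gap + td_cds + down_flank
    t_feats = [
        Feature("CMV_promoter", len(up_flank), len(up_flank) + 654,
                kind="promoter"),
        Feature("tdTomato", len(up_flank) + 654 + len(gap),
                len(up_flank) + 654 + len(gap) + len(td_cds), kind="CDS"),
        Feature("lox66", len(up_flank) + 654 + len(gap) + 3 + len(td_a),
                len(up_flank) + 654 + len(gap) + 3 + len(td_a) + 34,
                kind="protein_bind"),
    ]
    target = Molecule("tdTomato_locus", t_seq, "linear", features=t_feats)

    spacer = _random_bases(rng, 30)
    egfp = "ATG" + _random_codons(rng, 236) + "TAA"   # 714 bp placeholder
    filler = _random_bases(rng, 120)
    d_seq = lox71 + spacer + egfp + filler
    d_feats = [
        Feature("lox71", 0, 34, kind="protein_bind"),
        Feature("EGFP", len(lox71) + len(spacer),
                len(lox71) + len(spacer) + len(egfp), kind="CDS"),
    ]
    donor = Molecule("EGFP_donor", d_seq, "circular", features=d_feats)

    from .rmdi import find_lox_sites
    for mol, want in ((target, "lox66"), (donor, "lox71")):
        sites = find_lox_sites(mol)
        if len(sites) != 1 or sites[0].variant != want:
            raise FixtureError(f"{mol.id}: expected a single {want} site")
    return target, donor


def make_sespin_template(seed: int = 0) -> Molecule:
    """Circular plasmid carrying a small-Espin placeholder ORF that the
    published primer pair amplifies (both primers fully template-matched at
    their 3' ends; the reverse primer tails a stop codon and an AgeI site)."""
    rng = _rng("sespin", seed)
    # ORF body between the primer-matched ends; length chosen so that the
    # stop codon supplied by the reverse-primer tail lands in frame with
    # the ATG inside the forward primer footprint
    left = SESPIN_F                         # ...GGATCC ATG AACTCCC
    right = "GAAGGGGGAGATCCCTAAG"           # revcomp of sEspinR 3' anneal
    atg = left.index("ATG")
    for _ in range(200):
        # M sits at offset 10 from the ATG: pad to the codon boundary,
        # fill with non-stop codons, and close the last codon with the
        # first base of the primer-matched right block (a G)
        last2 = rng.choice(["GC", "CA", "GG", "CT", "AC"])
        m = (_random_bases(rng, 2) + _random_codons(rng, 99) + last2)
        orf_region = left + m + right
        coding = orf_region[atg:]
        if any(coding[i:i + 3] in STOPS
               for i in range(0, len(coding) - 2, 3)):
            continue
        probe = Molecule("probe", orf_region, "linear")
        if any(find_sites(probe, e) for e in
               ("BamHI", "AgeI", "EcoRI", "NotI", "XbaI", "SpeI", "PstI")
               if e != "BamHI") or \
                len(find_sites(probe, "BamHI")) != 1:
            continue
        break
    else:
        raise FixtureError("could not build an sEspin template")
    pre = _random_bases(rng, 300)
    post = _random_bases(rng, 200)
    seq = _scrub(pre + orf_region + post, rng,
                 protected=[(len(pre), len(pre) + len(orf_region))],
                 circular=True)
    feats = [Feature("sEspin", len(pre) + atg,
                     len(pre) + len(orf_region), kind="CDS")]
    return Molecule("sEspin_source", seq, "circular", features=feats)


def make_classic_vector(seed: int = 0) -> Molecule:
    """Synthetic stand-in for a CMV expression vector with an NheI/PstI
    cloning window (promoter upstream of NheI, polyA downstream of PstI) —
    the receiving vector of the biobrick XbaI/PstI subcloning route."""
    rng = _rng("classic_vector", seed)
    promoter = _random_bases(rng, 500)
    a = _random_bases(rng, 30)
    stuffer = _random_bases(rng, 700)
    b = _random_bases(rng, 30)
    polyA = _random_bases(rng, 200)
    backbone = _random_bases(rng, 1200)
    seq = (promoter + a + "GCTAGC" + stuffer + "CTGCAG" + b + polyA
           + backbone)
    feats = [
        Feature("CMV_promoter", 0, 500, kind="promoter"),
        Feature("NheI_site", 530, 536),
        Feature("PstI_site", 536 + 700, 542 + 700),
        Feature("SV40_polyA", 542 + 700 + 30, 542 + 700 + 30 + 200,
                kind="polyA_signal"),
    ]
    # the flank junctions may have grown sites during concatenation
    prot = [(530, 536), (1236, 1242)]
    final = _scrub(seq, rng, protected=prot, circular=True)
    return Molecule("pEGFP_C1_syn", final, "circular", features=feats)


DEMO_DESIGN = ("CMV", "Kozak", "Cerulean", "MCS1a", "MCS2a", "IRES",
               "FNeomycin", "SV40pA")


def make_bicistronic_demo(seed: int = 0):
    """Plan and simulate the 8-part bicistronic MCS construct end to end.

    Returns ``(final ClonedPart, assigned AssemblyTree, collection)``.  The
    final plasmid carries a Kozak-Cerulean CDS feature so that MCS
    subcloning can report frame against the fluorophore fusion.
    """
    from . import planner, registry as _registry

    coll = load_collection(seed)
    tree = planner.plan_balanced(list(DEMO_DESIGN))
    tree = planner.assign_backbones(
        tree, {n: _registry.lookup(coll, n).backbone_code
               for n in DEMO_DESIGN})
    leaves = {}
    for i, n in enumerate(DEMO_DESIGN):
        rec = _registry.lookup(coll, n)
        bb = make_backbone(BACKBONE_RESISTANCES[rec.backbone_code],
                           seed=seed * 100 + i)
        leaves[n] = clone_into_backbone(rec, bb)
    final, results = planner.execute_plan(
        tree, leaves,
        lambda code: make_backbone(BACKBONE_RESISTANCES[code],
                                   seed=seed * 100 + 50 + ord(code[-1])))
    # annotate the first-cistron CDS (Kozak ATG through Cerulean)
    seq = final.plasmid.seq
    atg = seq.index(FIXED_PAYLOADS["Kozak"]) + 6
    cer = _registry.lookup(coll, "Cerulean").payload
    final.plasmid.features.append(
        Feature("Kozak-Cerulean", atg, seq.index(cer) + len(cer),
                kind="CDS"))
    return final, tree, coll
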