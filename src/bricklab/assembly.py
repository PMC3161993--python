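"""Standard three-antibiotic (3A) BioBrick assembly, simulated end to end.

One assembly fuses an upstream part (cut EcoRI+SpeI) and a downstream part
(cut XbaI+PstI) into a ccdB destination vector (cut EcoRI+PstI).  The
destination must carry an antibiotic resistance absent from both source
backbones, so only correctly assembled, ccdB-free products survive
selection.  Everything here goes through the digestion/ligation simulator —
products are never built by string concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

from . import grammar
from .grammar import FormatCall, Role, detect_format, fusion_frame_report
from .registry import BACKBONE_RESISTANCES, PartRecord
from .seqmodel import (BrickLabError, Feature, Molecule, digest, get_enzymes,
                       ligate)


class AssemblyError(BrickLabError):
    def __init__(self, message: str, code: str = "ASSEMBLY"):
        super().__init__(message)
        self.code = code


#: deterministic antibiotic preference for destination selection
ANTIBIOTIC_ORDER = ("kan", "chl", "tet")

#: ampicillin is carried by every backbone and can never select an assembly
NEVER_SELECTABLE = "amp"


@dataclass
class Backbone:
    code: str                       # A | AK | AC | AT
    has_ccdB: bool = True
    molecule: Molecule | None = None

    def __post_init__(self):
        if self.code not in BACKBONE_RESISTANCES:
            raise AssemblyError(f"unknown backbone code {self.code!r}")

    @property
    def resistances(self) -> frozenset[str]:
        return BACKBONE_RESISTANCES[self.code]


@dataclass
class ClonedPart:
    """A part sitting between prefix and suffix in a backbone plasmid."""

    record: PartRecord
    backbone: Backbone
    plasmid: Molecule
    format: str = "RFC23"


@dataclass
class ProtocolStep:
    action: str
    detail: str


@dataclass
class AssemblyResult:
    product: ClonedPart
    scar: str
    selection_antibiotic: str
    protocol: list[ProtocolStep] = field(default_factory=list)
    byproducts: list[Molecule] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def select_destination(up: Backbone | str, down: Backbone | str,
                       available: Iterable[Backbone]
                       ) -> tuple[Backbone, str]:
    """Pick a destination backbone whose selection antibiotic is absent from
    both source backbones (tie-break order kan < chl < tet)."""
    up_res = up.resistances if isinstance(up, Backbone) else \
        BACKBONE_RESISTANCES[up]
    down_res = down.resistances if isinstance(down, Backbone) else \
        BACKBONE_RESISTANCES[down]
    used = up_res | down_res
    pool = list(available)
    if not pool:
        raise AssemblyError("no destination backbones available")
    for ab in ANTIBIOTIC_ORDER:
        if ab in used:
            continue
        for bb in sorted(pool, key=lambda b: b.code):
            if ab in bb.resistances:
                return bb, ab
    raise AssemblyError(
        f"infeasible: sources jointly cover {sorted(used)}; no selection "
        "antibiotic remains", code="NO_ANTIBIOTIC")


# --------------------------------------------------------------------------

_PROTOCOL = [
    ProtocolStep("digest upstream part",
                 "500 ng digested with 20000 U of EcoRI and 10000 U of SpeI "
                 "in NEB EcoRI buffer"),
    ProtocolStep("digest downstream part",
                 "500 ng digested with 20000 U of XbaI and 20000 U of PstI "
                 "in NEB Buffer 3"),
    ProtocolStep("digest destination plasmid",
                 "500 ng digested with 20000 U of EcoRI and 20000 U of PstI "
                 "in NEB EcoRI buffer"),
    ProtocolStep("incubate and heat-inactivate",
                 "digestions at 37°C for 1 hour followed by heat "
                 "inactivation at 80°C for 20 minutes"),
    ProtocolStep("two-way ligation",
                 "4 µl upstream digest + 4 µl downstream digest + "
                 "2 µl destination digest, rapid DNA ligation kit; no "
                 "gel isolation needed (ccdB dropout)"),
    ProtocolStep("transform and select",
                 "transform Top10 E. coli, plate on LB agar with the "
                 "destination antibiotic, incubate overnight"),
]


def _insert_fragment(frags, payload: str, what: str):
    hits = [f for f in frags if payload in f.molecule.seq]
    if len(hits) != 1:
        raise AssemblyError(f"cannot identify the {what} insert fragment")
    return hits[0]


def standard_assembly(up: ClonedPart, down: ClonedPart, dest: Backbone,
                      dam_plus: bool = True) -> AssemblyResult:
    """Simulate one standard assembly of ``up`` + ``down`` into ``dest``.

    Both parts must be free of internal assembly-enzyme sites; the
    downstream part must not start with TC in a dam+ host (Dam methylation
    blocks its XbaI cut).  The viable product regenerates the upstream
    standard's prefix and the downstream standard's suffix and drops ccdB.
    """
    if dest.molecule is None:
        raise AssemblyError("destination backbone has no sequence attached")
    for cp in (up, down):
        rep = grammar.validate_part(cp.record, FormatCall(cp.format))
        bad = [f for f in rep.errors if f.code == "BB_SITE_INTERNAL"]
        if bad:
            raise AssemblyError(
                f"{cp.record.nickname}: {bad[0].message}",
                code="BB_SITE_INTERNAL")
    if dam_plus and down.format == "RFC23" and \
            down.record.payload.startswith("TC"):
        raise AssemblyError(
            f"{down.record.nickname}: payload starts with TC; the XbaI site "
            "is Dam-blocked in a dam+ host (DAM_XBAI_BLOCK)",
            code="DAM_XBAI_BLOCK")

    up_frags = digest(up.plasmid, get_enzymes(["EcoRI", "SpeI"]), dam_plus)
    down_frags = digest(down.plasmid, get_enzymes(["XbaI", "PstI"]), dam_plus)
    dest_frags = digest(dest.molecule, get_enzymes(["EcoRI", "PstI"]),
                        dam_plus)
    for frags, what in ((up_frags, "upstream"), (down_frags, "downstream"),
                        (dest_frags, "destination")):
        if len(frags) != 2:
            raise AssemblyError(
                f"{what} plasmid produced {len(frags)} fragments "
                "(expected 2): unexpected extra cut sites",
                code="EXTRA_SITES")

    up_ins = _insert_fragment(up_frags, up.record.payload, "upstream")
    down_ins = _insert_fragment(down_frags, down.record.payload,
                                "downstream")
    bb_frag, stuffer = (
        (dest_frags[0], dest_frags[1])
        if not dest_frags[0].molecule.has_feature("ccdB")
        else (dest_frags[1], dest_frags[0]))
    if dest.has_ccdB and not stuffer.molecule.has_feature("ccdB"):
        raise AssemblyError("destination stuffer lacks the ccdB cassette")

    products = ligate([bb_frag, stuffer, up_ins, down_ins],
                      circular_only=True)
    viable, background = [], []
    for mol in products:
        if (up.record.payload in mol.seq + mol.seq
                and down.record.payload in mol.seq + mol.seq
                and not mol.has_feature("ccdB")):
            viable.append(mol)
        else:
            background.append(mol)
    if len(viable) != 1:
        raise AssemblyError(
            f"expected exactly one viable product, got {len(viable)}")

    antibiotic = next(
        (ab for ab in ANTIBIOTIC_ORDER
         if ab in dest.resistances
         and ab not in up.backbone.resistances | down.backbone.resistances),
        None)
    if antibiotic is None:
        raise AssemblyError(
            f"destination {dest.code} provides no selection antibiotic "
            f"against {up.backbone.code} x {down.backbone.code}",
            code="NO_ANTIBIOTIC")
    assert antibiotic != NEVER_SELECTABLE

    product = _annotate_product(viable[0], up, down, dest)
    scar = product.plasmid.feature("scar")
    scar_seq = product.plasmid.seq[scar.start:scar.end]

    notes = []
    if up.format != down.format:
        notes.append("assembly compatible, not RFC23 compatible: mixed "
                     "affix standards; the scar does not preserve frame")
    return AssemblyResult(product=product, scar=scar_seq,
                          selection_antibiotic=antibiotic,
                          protocol=list(_PROTOCOL),
                          byproducts=background, notes=notes)


def _annotate_product(mol: Molecule, up: ClonedPart, down: ClonedPart,
                      dest: Backbone) -> ClonedPart:
    pre, _ = grammar.AFFIXES[up.format]
    _, suf = grammar.AFFIXES[down.format]
    doubled = mol.seq + mol.seq
    p = doubled.index(pre)
    rot = mol.rotated(p % len(mol.seq))
    a = rot.seq.index(up.record.payload, len(pre))
    b = rot.seq.index(down.record.payload, a + len(up.record.payload))
    scar = rot.seq[a + len(up.record.payload): b]
    payload = rot.seq[a: b + len(down.record.payload)]
    sfx = rot.seq.index(suf, b + len(down.record.payload))
    rot.features = [f for f in rot.features
                    if not f.label.startswith(("prefix", "suffix", "scar"))]
    rot.features += [
        Feature("prefix", 0, len(pre), kind="misc_feature"),
        Feature(f"part:{up.record.nickname}", a,
                a + len(up.record.payload), kind="misc_feature"),
        Feature("scar", a + len(up.record.payload), b, kind="misc_feature"),
        Feature(f"part:{down.record.nickname}", b,
                b + len(down.record.payload), kind="misc_feature"),
        Feature("suffix", sfx, sfx + len(suf), kind="misc_feature"),
    ]
    nickname = f"{up.record.nickname}-{down.record.nickname}"
    rec = PartRecord(
        nickname=nickname, group="Construction",
        description=f"assembly of {up.record.nickname} and "
                    f"{down.record.nickname}",
        size_bp=len(payload), backbone_code=dest.code,
        has_kozak=up.record.has_kozak or down.record.has_kozak,
        has_stop=bool(grammar.frame0_stops(payload)),
        frame_safe=len(payload) % 3 == 0,
        payload=payload, synthetic=True,
    )
    rot.id = f"p{nickname}"
    fmt = detect_format(pre + payload + suf).format
    return ClonedPart(record=rec, backbone=dest, plasmid=rot,
                      format=fmt if fmt != "nonstandard" else up.format)


# --------------------------------------------------------------------------
# fusion translation

def translate_fusion(parts: Sequence[PartRecord],
                     formats: Sequence[str] | None = None) -> str:
    """Translate an ordered head / internal* / tail fusion.

    Each junction contributes the simulated assembly scar (Thr-Arg for a
    pure RFC23 chain).  Raises ``FRAMESHIFT`` when a junction scar is not a
    multiple of three, and ``PREMATURE_STOP`` when a stop codon appears
    before the tail part.
    """
    if len(parts) < 2:
        raise AssemblyError("a fusion needs at least head and tail parts")
    roles = [grammar.classify_role(p) for p in parts]
    if roles[0] != Role.HEAD:
        raise AssemblyError(f"{parts[0].nickname} is {roles[0].value}, "
                            "not a head domain")
    if roles[-1] != Role.TAIL:
        raise AssemblyError(f"{parts[-1].nickname} is {roles[-1].value}, "
                            "not a tail domain")
    for p, r in zip(parts[1:-1], roles[1:-1]):
        if r != Role.INTERNAL:
            if r == Role.TAIL and grammar.frame0_stops(p.payload):
                pos = grammar.frame0_stops(p.payload)[0]
                raise AssemblyError(
                    f"{p.nickname}: in-frame stop at payload position {pos}",
                    code="PREMATURE_STOP")
            raise AssemblyError(f"{p.nickname} is {r.value}, not an "
                                "internal domain")
    fmts = list(formats) if formats is not None else ["RFC23"] * len(parts)

    fused = parts[0].payload
    boundaries = [0]
    for prev_fmt, fmt, part in zip(fmts, fmts[1:], parts[1:]):
        scar_len, scar, frame_ok, _ = fusion_frame_report(prev_fmt, fmt)
        if not frame_ok:
            raise AssemblyError(
                f"junction scar {scar!r} ({scar_len} bp) breaks the reading "
                "frame", code="FRAMESHIFT")
        fused += scar
        boundaries.append(len(fused))
        fused += part.payload

    atg = fused.find("ATG")
    if atg < 0:
        raise AssemblyError("head part contains no ATG")
    tail_start = boundaries[-1]
    cds = fused[atg:]
    peptide = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    stop_idx = peptide.find("*")
    if stop_idx < 0:
        raise AssemblyError("no stop codon reached in the tail part")
    stop_pos = atg + stop_idx * 3
    if stop_pos < tail_start:
        raise AssemblyError(
            f"in-frame stop at fusion position {stop_pos}, upstream of the "
            "tail part", code="PREMATURE_STOP")
    return peptide[:stop_idx]
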