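"""Classical cloning on top of BioBrick constructs: restriction-site
uniqueness, PCR simulation and directional MCS subcloning with frame checks.

PCR is modelled as exact annealing of each primer's 3'-terminal bases
(default 12) with any non-matching 5' bases incorporated as tails — the
way restriction sites are added to an amplicon for subcloning.  Subcloning
is directional: two different enzymes leave distinct (or
compatible-cohesive, e.g. XbaI x NheI) overhangs that force the insert
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from Bio.Seq import Seq

from .seqmodel import (BrickLabError, Enzyme, Feature, Fragment, Molecule,
                       digest, find_sites, get_enzyme, ligate, revcomp)


class PcrError(BrickLabError):
    pass


class SubcloneError(BrickLabError):
    pass


@dataclass
class Amplicon:
    """A blunt double-stranded PCR product with primer annotations."""

    molecule: Molecule
    fwd: str
    rev: str
    fwd_footprint: tuple[int, int]   # template coords of fwd annealing
    rev_footprint: tuple[int, int]   # template coords of rev annealing (top)
    fwd_tail: str = ""
    rev_tail: str = ""

    def __len__(self) -> int:
        return len(self.molecule)


@dataclass
class FrameReport:
    cds_label: str | None
    in_frame: bool
    junction: int | None = None
    note: str = ""


def site_uniqueness(plasmid: Molecule, enzymes: Iterable[Enzyme | str]
                    ) -> dict[str, dict]:
    """Count sites per enzyme over the full plasmid; an enzyme is usable
    for classical cloning only when its count is exactly 1."""
    out = {}
    for enz in enzymes:
        enz = get_enzyme(enz) if isinstance(enz, str) else enz
        count = len(find_sites(plasmid, enz))
        out[enz.name] = {"count": count, "usable": count == 1}
    return out


# --------------------------------------------------------------------------
# PCR

def _anneal_positions(hay: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def simulate_pcr(template: Molecule, fwd: str, rev: str,
                 min_anneal: int = 12) -> Amplicon:
    """Amplify ``template`` with two primers.

    Annealing requires an exact match of each primer's 3'-terminal
    ``min_anneal`` bases (fwd on the top strand, rev on the bottom); the
    match is then extended 5'-ward as far as the template agrees, and any
    remaining 5' bases become tails incorporated into the product.  The
    product runs from the fwd primer's 5' end to the rev primer's 5' end.
    """
    fwd, rev = fwd.upper(), rev.upper()
    if len(fwd) < min_anneal or len(rev) < min_anneal:
        raise PcrError(f"primers must be at least {min_anneal} nt")
    n = len(template.seq)
    hay = template.seq + (template.seq[: n - 1] if template.is_circular
                          else "")

    f_hits = _anneal_positions(hay, fwd[-min_anneal:])
    f_hits = [p for p in f_hits if p < n]
    r_core = revcomp(rev[-min_anneal:])
    r_hits = [p for p in _anneal_positions(hay, r_core) if p < n]
    if not f_hits:
        raise PcrError("forward primer does not anneal to the template")
    if not r_hits:
        raise PcrError("reverse primer does not anneal to the template")

    products = []
    for fp in f_hits:
        # extend the fwd match 5'-ward
        kf = min_anneal
        while kf < len(fwd) and fp - (kf - min_anneal) > 0 and \
                hay[fp - (kf - min_anneal) - 1] == fwd[-kf - 1]:
            kf += 1
        a = fp - (kf - min_anneal)          # template start of fwd footprint
        for rp in r_hits:
            kr = min_anneal
            while kr < len(rev) and rp + min_anneal + (kr - min_anneal) \
                    < len(hay) and \
                    hay[rp + min_anneal + (kr - min_anneal)] == \
                    revcomp(rev)[min_anneal + (kr - min_anneal)]:
                kr += 1
            b_end = rp + kr                  # template end of rev footprint
            if template.is_circular:
                span = (b_end - a) % n or n
                seg = "".join(template.seq[(a + i) % n] for i in range(span))
            else:
                if b_end <= a:
                    continue                 # divergent primers
                seg = template.seq[a:b_end]
            fwd_tail = fwd[: len(fwd) - kf]
            rev_tail = rev[: len(rev) - kr]
            seq = fwd_tail + seg + revcomp(rev_tail)
            feats = [Feature("fwd_primer", 0, len(fwd), kind="primer_bind"),
                     Feature("rev_primer", len(seq) - len(rev), len(seq),
                             strand=-1, kind="primer_bind")]
            mol = Molecule(f"{template.id}_amplicon", seq, "linear",
                           features=feats)
            products.append(Amplicon(mol, fwd, rev, (a, a + kf),
                                     ((b_end - kr) % n, b_end % n or n),
                                     fwd_tail, rev_tail))
    if not products:
        raise PcrError("primers are divergent: no product")
    if len(products) > 1:
        sizes = sorted(len(p) for p in products)
        raise PcrError(f"multiple annealing sites: {len(products)} "
                       f"products of sizes {sizes}")
    amp = products[0]
    # invariant: product begins with fwd and ends with revcomp(rev)
    assert amp.molecule.seq.startswith(fwd)
    assert amp.molecule.seq.endswith(revcomp(rev))
    return amp


# --------------------------------------------------------------------------
# subcloning

def _middle_fragment(frags: list[Fragment]) -> Fragment:
    if len(frags) < 3:
        raise SubcloneError(
            "insert digestion did not release an internal fragment "
            f"(got {len(frags)} fragments)")
    if len(frags) > 3:
        raise SubcloneError("insert carries extra cut sites")
    return frags[1]


def subclone(insert: Amplicon | Molecule, vector: Molecule,
             enzA: Enzyme | str, enzB: Enzyme | str,
             cds_anchor: str | None = None
             ) -> tuple[Molecule, FrameReport]:
    """Directionally clone ``insert`` into ``vector`` via two enzymes.

    Both enzymes must cut the vector exactly once.  An :class:`Amplicon`
    insert is digested to release its internal fragment; a linear
    :class:`Molecule` with sticky ends (e.g. a BioBrick XbaI/PstI fragment)
    is used as is.  The frame report anchors on the nearest upstream
    ATG-initiated CDS feature of the vector and asks whether the insert's
    first ATG continues its frame.
    """
    enzA = get_enzyme(enzA) if isinstance(enzA, str) else enzA
    enzB = get_enzyme(enzB) if isinstance(enzB, str) else enzB
    if enzA.name == enzB.name:
        raise SubcloneError("two different enzymes are required")
    counts = site_uniqueness(vector, [enzA, enzB])
    for name, info in counts.items():
        if not info["usable"]:
            raise SubcloneError(
                f"{name} cuts the vector {info['count']} times; a unique "
                "site is required")

    if isinstance(insert, Amplicon):
        ins_frag = _middle_fragment(
            digest(insert.molecule, [enzA, enzB], dam_plus=True))
    else:
        ins_frag = Fragment(insert, source_id=insert.id)

    vec_frags = digest(vector, [enzA, enzB], dam_plus=True)
    if len(vec_frags) != 2:
        raise SubcloneError("vector digestion did not give two fragments")
    backbone = max(vec_frags, key=len)

    products = ligate([backbone, ins_frag], circular_only=True)
    with_insert = [p for p in products if ins_frag.molecule.seq in
                   p.seq + p.seq or
                   revcomp(ins_frag.molecule.seq) in p.seq + p.seq]
    if not with_insert:
        raise SubcloneError("insert and vector ends are incompatible")
    if len(with_insert) > 1:
        raise SubcloneError("ligation is not directional with these ends")
    product = with_insert[0]
    product.id = f"{vector.id}::{ins_frag.molecule.id}"
    return product, _frame_report(product, ins_frag.molecule.seq, cds_anchor)


def _frame_report(product: Molecule, insert_seq: str,
                  cds_anchor: str | None) -> FrameReport:
    doubled = product.seq + product.seq
    ins_at = doubled.find(insert_seq)
    if ins_at < 0:
        return FrameReport(None, False, note="insert not found in product")
    cds = None
    best = None
    for f in product.features:
        if f.kind != "CDS" or f.strand != 1:
            continue
        if cds_anchor is not None and f.label != cds_anchor:
            continue
        start = f.start if f.start <= ins_at else f.start - len(product.seq)
        if start <= ins_at and (best is None or start > best):
            best, cds = start, f
    if cds is None:
        return FrameReport(None, False, note="no upstream CDS feature")
    atg_ins = insert_seq.find("ATG")
    if atg_ins < 0:
        return FrameReport(cds.label, False, note="insert has no ATG")
    dist = ins_at + atg_ins - best
    seg = doubled[best: ins_at + atg_ins]
    open_frame = not any(seg[i:i + 3] in ("TAA", "TAG", "TGA")
                         for i in range(0, len(seg) - 2, 3))
    return FrameReport(cds.label, dist % 3 == 0 and open_frame,
                       junction=ins_at,
                       note="" if open_frame else "stop codon upstream of "
                                                  "the insert ATG")
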