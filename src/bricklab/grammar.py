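"""BioBrick format detection, part validation and role classification.

Two affix standards are modelled.  The original standard (RFC10) wraps a
part in the prefix GAATTCGCGGCCGCTTCTAGAG and the suffix
TACTAGTAGCGGCCGCTGCAG; its assembly scar is 8 bp and breaks the reading
frame.  The fusion standard (RFC23) drops the last prefix base and the
first suffix base, leaving a 6 bp scar (ACTAGA, Thr-Arg) so that protein
domains can be chained in frame.  A truncated prefix variant
(RFC10_ATG, for coding parts that start directly with ATG) is detected but
excluded from automated fusion planning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING

from Bio.Seq import Seq

from .seqmodel import (BrickLabError, Fragment, Molecule, digest, find_sites,
                       get_enzyme)
from .registry import BIOBRICK_ENZYMES

if TYPE_CHECKING:  # pragma: no cover
    from .registry import PartRecord

RFC23_PREFIX = "GAATTCGCGGCCGCTTCTAGA"
RFC23_SUFFIX = "ACTAGTAGCGGCCGCTGCAG"
RFC10_PREFIX = RFC23_PREFIX + "G"
RFC10_SUFFIX = "T" + RFC23_SUFFIX
RFC10_ATG_PREFIX = RFC23_PREFIX[:-1]  # for coding parts starting with ATG

AFFIXES = {
    "RFC23": (RFC23_PREFIX, RFC23_SUFFIX),
    "RFC10": (RFC10_PREFIX, RFC10_SUFFIX),
    "RFC10_ATG": (RFC10_ATG_PREFIX, RFC10_SUFFIX),
}

STOP_CODONS = ("TAA", "TAG", "TGA")


class FormatError(BrickLabError):
    pass


@dataclass
class FormatCall:
    format: str                      # RFC23 | RFC10 | RFC10_ATG | nonstandard
    payload_span: tuple[int, int] = (0, 0)
    notes: list[str] = field(default_factory=list)


@dataclass
class Finding:
    code: str
    severity: str                    # error | warning | info
    message: str
    position: int | None = None


@dataclass
class ValidationReport:
    part_id: str
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    def to_dict(self) -> dict:
        return {
            "part_id": self.part_id,
            "ok": self.ok,
            "findings": [
                {"code": f.code, "severity": f.severity,
                 "message": f.message, "position": f.position}
                for f in self.findings
            ],
        }


class Role(Enum):
    NON_CODING = "non_coding"
    HEAD = "head"
    INTERNAL = "internal"
    TAIL = "tail"
    TRANSLATION_UNIT = "translation_unit"


def affix(payload: str, format: str = "RFC23") -> str:
    """Wrap a payload in the prefix/suffix of the given standard."""
    try:
        pre, suf = AFFIXES[format]
    except KeyError:
        raise FormatError(f"unknown format {format!r}") from None
    return pre + payload.upper() + suf


def detect_format(seq: str) -> FormatCall:
    """Classify a sequence by its BioBrick affixes.

    Precedence on the prefix is longest-match (RFC10's prefix is RFC23's
    plus a trailing G; the ATG variant is a strict prefix of both), with the
    suffix — which is unambiguous — breaking ties.
    """
    seq = seq.upper()
    for fmt in ("RFC10", "RFC23", "RFC10_ATG"):
        pre, suf = AFFIXES[fmt]
        if (seq.startswith(pre) and seq.endswith(suf)
                and len(seq) >= len(pre) + len(suf)):
            return FormatCall(fmt, (len(pre), len(seq) - len(suf)))
    return FormatCall("nonstandard", (0, len(seq)),
                      notes=["no recognised prefix/suffix pair"])


def frame0_stops(payload: str) -> list[int]:
    """Positions of stop codons read in frame 0 (first codon at base 0)."""
    return [i for i in range(0, len(payload) - 2, 3)
            if payload[i:i + 3] in STOP_CODONS]


def stops_in_all_frames(payload: str) -> bool:
    return all(
        any(payload[i:i + 3] in STOP_CODONS
            for i in range(f, len(payload) - 2, 3))
        for f in range(3)
    )


def validate_part(part: "PartRecord", format: FormatCall | None = None
                  ) -> ValidationReport:
    """Check a payload-carrying part against the BioBrick preparation rules.

    Findings (never raised):
      * ``BB_SITE_INTERNAL`` (error) — an assembly-enzyme site inside the
        payload would be cut during assembly;
      * ``DAM_XBAI_BLOCK`` (warning) — an RFC23 payload starting with TC
        completes a Dam site (GATC) with the prefix and blocks XbaI in a
        dam+ host;
      * ``FLAG_MISMATCH`` (error) — payload contradicts the tabulated 3n or
        stop flags.
    """
    if part.payload is None:
        raise BrickLabError(f"{part.nickname}: no payload attached")
    payload = part.payload
    fmt = format.format if format is not None else "RFC23"
    report = ValidationReport(part.nickname)
    mol = Molecule(part.nickname, payload, "linear")
    for name in BIOBRICK_ENZYMES:
        for pos in find_sites(mol, name):
            report.findings.append(Finding(
                "BB_SITE_INTERNAL", "error",
                f"internal {name} site in payload", pos))
    if fmt == "RFC23" and payload.startswith("TC"):
        report.findings.append(Finding(
            "DAM_XBAI_BLOCK", "warning",
            "payload starts with TC: prefix junction forms a Dam site "
            "(GATC) and XbaI digestion is blocked in dam+ hosts", 0))
    if part.frame_safe != (len(payload) % 3 == 0):
        report.findings.append(Finding(
            "FLAG_MISMATCH", "error",
            f"3n flag {part.frame_safe} contradicts payload length "
            f"{len(payload)}", None))
    has_stop = bool(frame0_stops(payload))
    if part.has_stop != has_stop:
        report.findings.append(Finding(
            "FLAG_MISMATCH", "error",
            f"stop flag {part.has_stop} contradicts frame-0 scan "
            f"({'stop found' if has_stop else 'no stop'})", None))
    return report


def classify_role(part: "PartRecord") -> Role:
    """Assign the collection's five functional classes from payload content.

    Head: Kozak, no stop.  Translation unit: Kozak and stop.  Internal:
    3n, no Kozak, no in-frame stop.  Tail: in-frame stop (no Kozak).
    Everything else is non-coding.  The classification is sequence/flag
    driven and total; intent (e.g. a promoter that happens to contain an
    in-frame stop) is not second-guessed.
    """
    if part.payload is None:
        raise BrickLabError(f"{part.nickname}: no payload attached")
    stop = bool(frame0_stops(part.payload))
    if part.has_kozak:
        return Role.TRANSLATION_UNIT if stop else Role.HEAD
    if stop:
        return Role.TAIL
    if len(part.payload) % 3 == 0:
        return Role.INTERNAL
    return Role.NON_CODING


# --------------------------------------------------------------------------
# fusion scar, by simulation

def _join_sticky(left: Fragment, right: Fragment) -> str:
    if not left.molecule.end3.matches(right.molecule.end5):
        raise FormatError("fragment ends do not anneal")
    return left.molecule.seq + right.molecule.seq


def fusion_frame_report(up_format: str, down_format: str
                        ) -> tuple[int, str, bool, str | None]:
    """Scar produced by fusing an upstream part (SpeI end) to a downstream
    part (XbaI end) of the given standards.

    The scar is computed by actually digesting and annealing the two affix
    standards around marker payloads, never from a lookup table.  Returns
    ``(scar_len, scar_seq, frame_preserved, scar_residues)`` where
    ``scar_residues`` is the translated scar peptide when the frame is kept.
    """
    for fmt in (up_format, down_format):
        if fmt not in ("RFC10", "RFC23"):
            raise FormatError(
                f"{fmt!r} takes no part in automated fusion planning")
    up_payload = "GGCGGAGGC"   # arbitrary in-frame markers
    down_payload = "GGTGGAGGT"
    up = Molecule("up", affix(up_payload, up_format), "linear")
    down = Molecule("down", affix(down_payload, down_format), "linear")
    up_frags = digest(up, [get_enzyme("SpeI")], dam_plus=True)
    down_frags = digest(down, [get_enzyme("XbaI")], dam_plus=True)
    if len(up_frags) != 2 or len(down_frags) != 2:
        raise FormatError("affix digestion did not produce two fragments")
    joined = _join_sticky(up_frags[0], down_frags[1])
    a = joined.index(up_payload) + len(up_payload)
    b = joined.index(down_payload)
    scar = joined[a:b]
    frame_ok = len(scar) % 3 == 0
    residues = str(Seq(scar).translate()) if frame_ok and scar else None
    return len(scar), scar, frame_ok, residues
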