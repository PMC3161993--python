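"""The packaged part collection: readers, integrity checks, sequence attachment.

The collection is a 52-record table (4 plasmid backbones + 48 insert parts)
shipped as ``data/registry.tsv``.  Payload sequences are attached separately
from FASTA; the toolkit's own synthetic placeholders (see
:mod:`bricklab.fixtures`) satisfy every tabulated constraint — size, 3n
flag, Kozak/stop content and classical restriction-site inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .seqmodel import BrickLabError, Molecule, find_sites, get_enzyme


class RegistryError(BrickLabError):
    pass


GROUPS = ("Backbones", "Construction", "Selection", "Reporters", "Tags",
          "Localization", "Recombination", "Cistron", "Others")

#: antibiotic resistance sets per backbone code
BACKBONE_RESISTANCES = {
    "A": frozenset({"amp"}),
    "AK": frozenset({"amp", "kan"}),
    "AC": frozenset({"amp", "chl"}),
    "AT": frozenset({"amp", "tet"}),
}

#: classical cloning enzymes inventoried in the restriction_sites column
CLASSICAL_ENZYMES = ("ClaI", "HindIII", "SmaI", "XhoI", "SacI", "BamHI",
                     "SalI", "SphI", "ApaI", "BglII", "KpnI", "AgeI",
                     "BsrGI", "StuI")

#: the five BioBrick assembly enzymes that must never occur inside a payload
BIOBRICK_ENZYMES = ("EcoRI", "NotI", "XbaI", "SpeI", "PstI")


@dataclass
class PartRecord:
    nickname: str
    group: str
    description: str = ""
    registry_id: str = ""
    genbank_id: str = ""
    size_bp: int = 0
    backbone_code: str = "none"   # A | AK | AC | AT | none (backbone rows)
    has_kozak: bool = False
    has_stop: bool = False
    frame_safe: bool = False      # the "3n" column
    preexisting: bool = False
    restriction_sites: list[str] = field(default_factory=list)
    well: str = ""
    payload: str | None = None
    synthetic: bool = False       # payload is a generated placeholder

    @property
    def is_backbone(self) -> bool:
        return self.group == "Backbones"

    @property
    def coding_incompatible(self) -> bool:
        """True for parts that cannot sit inside a continuous coding fusion
        (a stop signal, or a length that is not a multiple of three)."""
        return self.has_stop or not self.frame_safe

    @property
    def resistances(self) -> frozenset[str]:
        if self.backbone_code in BACKBONE_RESISTANCES:
            return BACKBONE_RESISTANCES[self.backbone_code]
        return frozenset()


@dataclass
class PartCollection:
    records: dict[str, PartRecord] = field(default_factory=dict)
    provenance: str = ""
    load_report: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def parts(self):
        """Insert parts only (backbone plasmids excluded)."""
        return [r for r in self if not r.is_backbone]

    def backbones(self):
        return [r for r in self if r.is_backbone]


def lookup(coll: PartCollection, nickname: str) -> PartRecord:
    try:
        return coll.records[nickname]
    except KeyError:
        raise RegistryError(f"unknown part nickname {nickname!r}") from None


def _bool(token: str, row: str) -> bool:
    if token in ("YES", "Y"):
        return True
    if token in ("N", "NO", "-", ""):
        return False
    raise RegistryError(f"malformed boolean {token!r} in row {row!r}")


def load_registry(table: str | Path | None = None) -> PartCollection:
    """Load and validate the part table (packaged table when no path given).

    Integrity violations are collected into ``load_report`` rather than
    silently dropped; structural problems (duplicate nicknames, malformed
    rows, an empty table) raise :class:`RegistryError`.
    """
    if table is None:
        text = (resources.files("bricklab") / "data/registry.tsv").read_text()
        provenance = "packaged collection table"
    else:
        text = Path(table).read_text()
        provenance = str(table)
    coll = PartCollection(provenance=provenance)
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.rstrip("\n").split("\t")
        if header is None:
            header = cells
            continue
        if len(cells) != len(header):
            raise RegistryError(f"malformed row (expected {len(header)} "
                                f"columns): {line!r}")
        row = dict(zip(header, cells))
        rec = PartRecord(
            nickname=row["nickname"],
            group=row["group"],
            description=row["description"],
            registry_id=row["registry_id"],
            genbank_id=row["genbank_id"],
            size_bp=int(row["size_bp"]),
            backbone_code=row["backbone"],
            has_kozak=_bool(row["kozak"], line),
            has_stop=_bool(row["stop"], line),
            frame_safe=_bool(row["frame3n"], line),
            preexisting=_bool(row["preexisting"], line),
            restriction_sites=[s for s in row["restriction_sites"].split(",")
                               if s],
            well=row["well"],
        )
        if rec.nickname in coll.records:
            raise RegistryError(f"duplicate nickname {rec.nickname!r}")
        _validate_record(rec, coll.load_report)
        coll.records[rec.nickname] = rec
    if header is None or not coll.records:
        raise RegistryError("empty registry table")
    return coll


def _validate_record(rec: PartRecord, report: list[str]) -> None:
    if rec.group not in GROUPS:
        report.append(f"{rec.nickname}: unknown group {rec.group!r}")
    if rec.is_backbone:
        if rec.backbone_code != "none":
            report.append(f"{rec.nickname}: backbone rows carry no "
                          "backbone code")
    else:
        if rec.backbone_code not in BACKBONE_RESISTANCES:
            report.append(f"{rec.nickname}: bad backbone code "
                          f"{rec.backbone_code!r}")
        # the 3n column must agree with size arithmetic
        if rec.frame_safe != (rec.size_bp % 3 == 0):
            report.append(
                f"{rec.nickname}: 3n flag {rec.frame_safe} contradicts "
                f"size {rec.size_bp} (mod 3 = {rec.size_bp % 3})")
    for enz in rec.restriction_sites:
        try:
            get_enzyme(enz)
        except BrickLabError:
            report.append(f"{rec.nickname}: unknown enzyme {enz!r}")


def _split_capitals(seq: str) -> tuple[str, str, str] | None:
    """Split an affix-capitalised sequence into (prefix, payload, suffix).

    The collection FASTA convention writes prefix and suffix in capitals and
    the payload in lower case."""
    if seq.isupper() or seq.islower():
        return None
    i = 0
    while i < len(seq) and seq[i].isupper():
        i += 1
    j = len(seq)
    while j > i and seq[j - 1].isupper():
        j -= 1
    if i == 0 or j == len(seq):
        return None
    return seq[:i], seq[i:j].upper(), seq[j:]


def attach_sequences(coll: PartCollection, fasta: str | Path,
                     synthetic: bool = False) -> PartCollection:
    """Attach payloads from a FASTA file whose record ids match nicknames.

    Prefix/suffix are stripped (case convention first, affix detection as a
    fallback); size and restriction-site inventories are cross-checked and
    mismatches recorded in ``load_report``.  Records without a matching
    FASTA entry are left sequence-free and flagged.
    """
    from Bio import SeqIO

    from . import grammar  # deferred: grammar imports PartRecord from here

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    matched = set()
    for rec in coll:
        raw = seqs.get(rec.nickname)
        if raw is None:
            coll.load_report.append(f"{rec.nickname}: no sequence in FASTA")
            continue
        matched.add(rec.nickname)
        if rec.is_backbone:
            rec.payload = raw.upper()
        else:
            split = _split_capitals(raw)
            if split is not None:
                rec.payload = split[1]
            else:
                call = grammar.detect_format(raw.upper())
                if call.format == "nonstandard":
                    coll.load_report.append(
                        f"{rec.nickname}: sequence is not in a recognised "
                        "BioBrick format")
                    continue
                s, e = call.payload_span
                rec.payload = raw.upper()[s:e]
        rec.synthetic = synthetic
        if len(rec.payload) != rec.size_bp:
            coll.load_report.append(
                f"{rec.nickname}: MISMATCH payload length "
                f"{len(rec.payload)} != tabulated size {rec.size_bp}")
        topo = "circular" if rec.is_backbone else "linear"
        mol = Molecule(rec.nickname, rec.payload, topo)
        found = {enz for enz in CLASSICAL_ENZYMES if find_sites(mol, enz)}
        if found != set(rec.restriction_sites):
            coll.load_report.append(
                f"{rec.nickname}: MISMATCH restriction sites "
                f"{sorted(found)} != tabulated "
                f"{sorted(rec.restriction_sites)}")
    for nick in seqs:
        if nick not in coll.records:
            coll.load_report.append(f"FASTA record {nick!r} matches no part")
    _ = matched
    return coll


def write_registry(coll: PartCollection, path: str | Path,
                   template: str | Path | None = None) -> None:
    """Write the collection back to TSV in the packaged layout.

    Comment header lines are copied from ``template`` (the packaged table by
    default) so that load -> write round-trips byte-identically.
    """
    if template is None:
        src = (resources.files("bricklab") / "data/registry.tsv").read_text()
    else:
        src = Path(template).read_text()
    comments = [l for l in src.splitlines() if l.startswith("#")]
    header = ("group\tnickname\tdescription\tregistry_id\tgenbank_id\t"
              "backbone\tsize_bp\tkozak\tstop\tframe3n\tpreexisting\t"
              "restriction_sites\twell")

    def b(v: bool, backbone_row: bool) -> str:
        if backbone_row:
            return "-"
        return "YES" if v else "N"

    lines = comments + [header]
    for rec in coll:
        bb = rec.is_backbone
        lines.append("\t".join([
            rec.group, rec.nickname, rec.description, rec.registry_id,
            rec.genbank_id, rec.backbone_code, str(rec.size_bp),
            b(rec.has_kozak, bb), b(rec.has_stop, bb),
            b(rec.frame_safe, bb), "YES" if rec.preexisting else "N",
            ",".join(rec.restriction_sites), rec.well,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
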