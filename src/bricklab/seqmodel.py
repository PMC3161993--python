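"""Core DNA data model: molecules, restriction digestion and sticky-end ligation.

The model is deliberately minimal.  A :class:`Molecule` is a top-strand
sequence (5'->3') plus topology; linear molecules additionally carry an
:class:`Overhang` descriptor at each end.  Restriction digestion partitions
the top strand at the enzymes' top-strand cut positions, so concatenating
fragment sequences (in order) always reconstructs the parent — overhang
bookkeeping only decides which ends may be resealed by ligation.

Conventions
-----------
* Coordinates are 0-based, half-open, on the top strand.
* An overhang stores the protruding single strand read 5'->3' *on its own
  strand*.  A right end therefore joins a left end exactly when the two
  stored sequences are reverse complements (equal, for palindromic cutters).
* For a 5' extension the protruding strand at a *left* end is the top
  strand, so the extension bases are part of ``seq``; at a *right* end they
  live on the bottom strand and are not.  3' extensions are the mirror
  image.  This keeps "sum of fragment lengths == parent length" exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

# --------------------------------------------------------------------------
# errors

class BrickLabError(Exception):
    """Base class for all toolkit errors."""


class UnknownEnzymeError(BrickLabError):
    pass


class LigationError(BrickLabError):
    pass


DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise BrickLabError(
            f"sequence contains non-ACGT characters: {sorted(bad)}"
        )


# --------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class Overhang:
    """End state of a linear duplex: blunt, 5' or 3' single-strand extension."""

    kind: str = "blunt"  # "blunt" | "5p" | "3p"
    seq: str = ""

    def __post_init__(self):
        if self.kind not in ("blunt", "5p", "3p"):
            raise BrickLabError(f"bad overhang kind {self.kind!r}")
        if self.kind == "blunt" and self.seq:
            raise BrickLabError("blunt end cannot carry extension bases")

    def matches(self, other: "Overhang") -> bool:
        """True when self (a right end) can anneal to other (a left end)."""
        if self.kind != other.kind:
            return False
        if self.kind == "blunt":
            return True
        return self.seq == revcomp(other.seq)


BLUNT = Overhang()


@dataclass
class Feature:
    """Annotated interval on a molecule (0-based, half-open, top strand)."""

    label: str
    start: int
    end: int
    strand: int = 1
    kind: str = "misc_feature"
    wraps: bool = False  # feature spans the origin of a circular molecule


@dataclass
class Molecule:
    """A double-stranded DNA record, linear or circular."""

    id: str
    seq: str
    topology: str = "linear"  # "linear" | "circular"
    end5: Overhang = BLUNT    # left end (5' end of the top strand)
    end3: Overhang = BLUNT    # right end
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        self.seq = self.seq.upper()
        _check_alphabet(self.seq)
        if self.topology not in ("linear", "circular"):
            raise BrickLabError(f"bad topology {self.topology!r}")
        if self.topology == "circular" and (
            self.end5 != BLUNT or self.end3 != BLUNT
        ):
            raise BrickLabError("circular molecules carry no overhangs")
        n = len(self.seq)
        for f in self.features:
            if not (0 <= f.start < max(n, 1)) or not (0 <= f.end <= n):
                raise BrickLabError(
                    f"feature {f.label!r} coordinates outside [0, {n})"
                )
            if f.start > f.end and not f.wraps:
                raise BrickLabError(
                    f"feature {f.label!r} is inverted but not flagged as "
                    "origin-spanning"
                )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def rotated(self, k: int) -> "Molecule":
        """Rotate a circular molecule so position ``k`` becomes position 0."""
        if not self.is_circular:
            raise BrickLabError("only circular molecules can be rotated")
        n = len(self.seq)
        k %= n
        feats = []
        for f in self.features:
            s = (f.start - k) % n
            e = (f.end - k) % n
            if e == 0 and f.end != f.start:
                e = n
            feats.append(replace(f, start=s, end=e, wraps=s > e))
        return Molecule(self.id, self.seq[k:] + self.seq[:k], "circular",
                        features=feats)

    def reverse_complement(self) -> "Molecule":
        n = len(self.seq)
        if self.is_circular:
            seq = revcomp(self.seq)
            feats = [replace(f, start=n - f.end, end=n - f.start,
                             strand=-f.strand) for f in self.features
                     if not f.wraps]
            return Molecule(self.id, seq, "circular", features=feats)
        # linear: strip top-strand extensions, flip, re-add (see module notes)
        core = self.seq
        left, right = self.end5, self.end3
        if left.kind == "5p":
            core = core[len(left.seq):]
        if right.kind == "3p":
            core = core[: len(core) - len(right.seq)]
        seq = (right.seq if right.kind == "5p" else "") + revcomp(core) + (
            left.seq if left.kind == "3p" else "")
        feats = [replace(f, start=len(seq) - f.end, end=len(seq) - f.start,
                         strand=-f.strand) for f in self.features
                 if 0 <= len(seq) - f.end and len(seq) - f.start <= len(seq)]
        return Molecule(self.id, seq, "linear", end5=right, end3=left,
                        features=feats)

    def feature(self, label: str) -> Feature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(label)

    def has_feature(self, label: str) -> bool:
        return any(f.label == label for f in self.features)


@dataclass(frozen=True)
class Enzyme:
    """A type-II restriction enzyme with palindromic recognition."""

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int
    dam_sensitive: bool = False

    @property
    def overhang_len(self) -> int:
        return abs(self.cut_top - self.cut_bottom)

    @property
    def overhang_kind(self) -> str:
        if self.cut_top < self.cut_bottom:
            return "5p"
        if self.cut_top > self.cut_bottom:
            return "3p"
        return "blunt"


@dataclass
class Fragment:
    """A digestion product: a linear molecule plus provenance."""

    molecule: Molecule
    source_id: str = ""
    cut_positions: tuple[int, int] = (0, 0)

    def __len__(self) -> int:
        return len(self.molecule)


# --------------------------------------------------------------------------
# enzyme table

_ENZYMES: dict[str, Enzyme] | None = None


def load_enzymes(path: str | Path | None = None) -> dict[str, Enzyme]:
    """Load the packaged enzyme table (or a user TSV of the same layout)."""
    global _ENZYMES
    if path is None and _ENZYMES is not None:
        return _ENZYMES
    if path is None:
        text = (resources.files("bricklab") / "data/enzymes.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, Enzyme] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        name, rec, ct, cb, dam = line.split("\t")
        enz = Enzyme(name, rec.upper(), int(ct), int(cb), bool(int(dam)))
        if revcomp(enz.recognition) != enz.recognition:
            raise BrickLabError(f"{name}: packaged sites must be palindromic")
        table[name] = enz
    if path is None:
        _ENZYMES = table
    return table


def get_enzyme(name: str) -> Enzyme:
    table = load_enzymes()
    try:
        return table[name]
    except KeyError:
        raise UnknownEnzymeError(name) from None


def get_enzymes(names: Iterable[str]) -> list[Enzyme]:
    return [get_enzyme(n) for n in names]


# --------------------------------------------------------------------------
# site scanning

def _iupac_match(seq: str, pos: int, pattern: str) -> bool:
    for i, p in enumerate(pattern):
        if seq[pos + i] not in IUPAC[p]:
            return False
    return True


def find_sites(mol: Molecule, enzyme: Enzyme | str) -> list[int]:
    """0-based start positions of top-strand recognition matches.

    Circular molecules are scanned across the origin; positions are reported
    mod length.  Palindromic sites yield one hit per physical site.
    """
    if isinstance(enzyme, str):
        enzyme = get_enzyme(enzyme)
    n, m = len(mol.seq), len(enzyme.recognition)
    if n == 0 or m == 0 or (not mol.is_circular and m > n):
        return []
    scan = mol.seq + (mol.seq[: m - 1] if mol.is_circular else "")
    limit = n if mol.is_circular else n - m + 1
    return [i for i in range(limit) if _iupac_match(scan, i, enzyme.recognition)]


def dam_blocked(mol: Molecule, enzyme: Enzyme, pos: int) -> bool:
    """True when Dam methylation of an overlapping GATC blocks this site.

    Only XbaI (TCTAGA) is affected in the BioBrick workflow: the blocking
    contexts are GA|TCTAGA and TCTAGA|TC, each completing a GATC.
    """
    if not enzyme.dam_sensitive:
        return False
    n, m = len(mol.seq), len(enzyme.recognition)

    def chunk(a: int, b: int) -> str:
        if mol.is_circular:
            return "".join(mol.seq[i % n] for i in range(a, b))
        if a < 0 or b > n:
            return ""
        return mol.seq[a:b]

    return chunk(pos - 2, pos) == "GA" or chunk(pos + m, pos + m + 2) == "TC"


# --------------------------------------------------------------------------
# digestion

def _cut_events(mol: Molecule, enzymes: Sequence[Enzyme], dam_plus: bool):
    """(top_cut, right_left_end, left_right_end, enzyme) per effective cut."""
    n = len(mol.seq)
    events = []
    for enz in enzymes:
        k = enz.overhang_len
        lo = min(enz.cut_top, enz.cut_bottom)
        for pos in find_sites(mol, enz):
            if dam_plus and dam_blocked(mol, enz, pos):
                continue
            top_cut = pos + enz.cut_top
            if mol.is_circular:
                top_cut %= n
            elif not (0 <= top_cut <= n):
                continue
            ov = "".join(mol.seq[(pos + lo + i) % n] for i in range(k)) \
                if mol.is_circular else mol.seq[pos + lo: pos + lo + k]
            if enz.overhang_kind == "5p":
                left_of_right = Overhang("5p", ov)
                right_of_left = Overhang("5p", revcomp(ov))
            elif enz.overhang_kind == "3p":
                left_of_right = Overhang("3p", revcomp(ov))
                right_of_left = Overhang("3p", ov)
            else:
                left_of_right = right_of_left = BLUNT
            events.append((top_cut, left_of_right, right_of_left, enz))
    events.sort(key=lambda e: e[0])
    return events


def _slice_features(mol: Molecule, start: int, end: int) -> list[Feature]:
    """Features of ``mol`` wholly inside [start, end) (linear coordinates)."""
    out = []
    for f in mol.features:
        if f.wraps:
            continue
        if start <= f.start and f.end <= end:
            out.append(replace(f, start=f.start - start, end=f.end - start))
    return out


def digest(mol: Molecule, enzymes: Iterable[Enzyme | str],
           dam_plus: bool = True) -> list[Fragment]:
    """Cut a molecule with a set of enzymes.

    Returns one fragment per cut for circular input (cuts+1 for linear);
    with zero effective cuts the molecule is returned unchanged inside a
    single Fragment.  Dam-blocked XbaI sites are skipped when ``dam_plus``.
    """
    enzs = [get_enzyme(e) if isinstance(e, str) else e for e in enzymes]
    events = _cut_events(mol, enzs, dam_plus)
    n = len(mol.seq)
    if not events:
        return [Fragment(mol, source_id=mol.id, cut_positions=(0, n))]

    frags: list[Fragment] = []
    if mol.is_circular:
        k = len(events)
        for i in range(k):
            a = events[i]
            b = events[(i + 1) % k]
            start, stop = a[0], b[0]
            seq = mol.seq[start:stop] if start < stop else \
                mol.seq[start:] + mol.seq[:stop]
            feats = _slice_features(mol.rotated(start), 0, len(seq))
            m = Molecule(f"{mol.id}[{start}:{stop}]", seq, "linear",
                         end5=a[1], end3=b[2], features=feats)
            frags.append(Fragment(m, source_id=mol.id,
                                  cut_positions=(start, stop)))
    else:
        cuts = [e[0] for e in events]
        bounds = [0] + cuts + [n]
        left_ends = [mol.end5] + [e[1] for e in events]
        right_ends = [e[2] for e in events] + [mol.end3]
        for i in range(len(bounds) - 1):
            start, stop = bounds[i], bounds[i + 1]
            m = Molecule(f"{mol.id}[{start}:{stop}]", mol.seq[start:stop],
                         "linear", end5=left_ends[i], end3=right_ends[i],
                         features=_slice_features(mol, start, stop))
            frags.append(Fragment(m, source_id=mol.id,
                                  cut_positions=(start, stop)))
    return frags


# --------------------------------------------------------------------------
# ligation

def _canonical_circular(seq: str) -> str:
    n = len(seq)
    rc = revcomp(seq)
    return min(min(seq[i:] + seq[:i] for i in range(n)),
               min(rc[i:] + rc[:i] for i in range(n)))


def _orientations(frag: Fragment) -> list[Molecule]:
    m = frag.molecule
    rc = m.reverse_complement()
    outs = [m]
    if rc.seq != m.seq or rc.end5 != m.end5 or rc.end3 != m.end3:
        outs.append(rc)
    return outs


def _join_features(mols: Sequence[Molecule]) -> list[Feature]:
    feats, off = [], 0
    for m in mols:
        feats.extend(replace(f, start=f.start + off, end=f.end + off)
                     for f in m.features)
        off += len(m.seq)
    return feats


def ligate(fragments: Sequence[Fragment], circular_only: bool = True,
           max_fragments: int = 10) -> list[Molecule]:
    """Enumerate distinct sealed (circular) ligation products.

    Ends join only when their overhangs are reverse-complement matches
    (blunt joins blunt).  Each input fragment is used at most once per
    product, in either orientation; products are reported once up to
    rotation and reflection.  Self-circularisation of a single fragment is
    allowed.  With ``circular_only=False`` fully-joined linear products of
    two or more fragments are reported as well.

    Raises :class:`LigationError` when nothing can be sealed.
    """
    if not fragments:
        raise LigationError("no fragments supplied")
    if len(fragments) > max_fragments:
        raise LigationError(
            f"refusing to enumerate products of >{max_fragments} fragments")

    pool: list[list[Molecule]] = [_orientations(f) for f in fragments]
    products: dict[str, Molecule] = {}
    linear_products: dict[str, Molecule] = {}

    def emit_circle(chain: list[Molecule]):
        seq = "".join(m.seq for m in chain)
        key = _canonical_circular(seq)
        if key not in products:
            mol = Molecule("+".join(m.id for m in chain), seq, "circular",
                           features=_join_features(chain))
            products[key] = mol

    def emit_linear(chain: list[Molecule]):
        seq = "".join(m.seq for m in chain)
        key = min(seq, revcomp(seq))
        if key not in linear_products and len(chain) > 1:
            first, last = chain[0], chain[-1]
            mol = Molecule("+".join(m.id for m in chain), seq, "linear",
                           end5=first.end5, end3=last.end3,
                           features=_join_features(chain))
            linear_products[key] = mol

    def extend(chain: list[Molecule], used: set[int]):
        if chain[-1].end3.matches(chain[0].end5):
            emit_circle(chain)
        if not circular_only:
            emit_linear(chain)
        for i, orients in enumerate(pool):
            if i in used:
                continue
            for mol in orients:
                if chain[-1].end3.matches(mol.end5):
                    extend(chain + [mol], used | {i})

    for i, orients in enumerate(pool):
        extend([orients[0]], {i})

    out = list(products.values()) + \
        ([] if circular_only else list(linear_products.values()))
    if not out:
        raise LigationError("no sealable ligation product")
    return out


# --------------------------------------------------------------------------
# FASTA / GenBank I/O

def read_fasta(path: str | Path) -> list[Molecule]:
    """Read molecules from FASTA; ``topology=circular|linear`` may appear in
    the description line (default linear)."""
    mols = []
    for rec in SeqIO.parse(str(path), "fasta"):
        topo = "circular" if "topology=circular" in rec.description else "linear"
        mols.append(Molecule(rec.id, str(rec.seq), topo))
    return mols


def write_fasta(mols: Iterable[Molecule], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(m.seq), id=m.id, description=f"topology={m.topology}")
        for m in mols
    ]
    SeqIO.write(recs, str(path), "fasta")


def to_seqrecord(mol: Molecule) -> SeqRecord:
    rec = SeqRecord(Seq(mol.seq), id=mol.id[:16] or "molecule",
                    name=(mol.id[:16] or "molecule"), description=mol.id)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = mol.topology
    n = len(mol.seq)
    for f in mol.features:
        if f.wraps and mol.is_circular:
            loc = CompoundLocation([FeatureLocation(f.start, n, f.strand),
                                    FeatureLocation(0, f.end, f.strand)])
        else:
            loc = FeatureLocation(f.start, f.end, f.strand)
        rec.features.append(
            SeqFeature(loc, type=f.kind or "misc_feature",
                       qualifiers={"label": [f.label]}))
    return rec


def write_genbank(mol: Molecule, path: str | Path) -> None:
    SeqIO.write(to_seqrecord(mol), str(path), "genbank")


def read_genbank(path: str | Path) -> Molecule:
    rec = SeqIO.read(str(path), "genbank")
    topo = rec.annotations.get("topology", "linear")
    feats = []
    for f in rec.features:
        if f.type == "source":
            continue
        label = f.qualifiers.get("label", [f.type])[0]
        parts = f.location.parts
        if len(parts) == 2 and int(parts[0].end) == len(rec.seq) \
                and int(parts[1].start) == 0:
            feats.append(Feature(label, int(parts[0].start),
                                 int(parts[1].end), f.location.strand or 1,
                                 f.type, wraps=True))
        else:
            feats.append(Feature(label, int(f.location.start),
                                 int(f.location.end), f.location.strand or 1,
                                 f.type))
    return Molecule(rec.description or rec.id, str(rec.seq), topo,
                    features=feats)
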