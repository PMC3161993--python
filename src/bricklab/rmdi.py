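"""Cre/lox recombinase-mediated DNA insertion (RMDI).

A lox site is a 13 bp arm, an 8 bp asymmetric spacer and a 13 bp arm.  The
heteromeric pair lox66 (mutant right element) x lox71 (mutant left element)
recombines to a wild-type loxP plus a double-mutant loxM; because Cre binds
loxM poorly the insertion is effectively one-way, which is what makes the
gene-switching experiment work: a donor plasmid carrying a promoterless
reporter behind lox71 integrates into a chromosomal lox66 placed inside an
expressed reporter's coding sequence, disrupting the resident gene and
putting the incoming one under the resident promoter.

Arm sequences follow the canonical loxP and the Albert/Araki mutant-arm
convention; they are packaged here as data because the source experiment
defines the sites by name only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .seqmodel import BrickLabError, Feature, Molecule, revcomp


class RecombinationError(BrickLabError):
    pass


# canonical arm/spacer sequences (wild-type loxP; LE/RE mutant arms)
WT_LEFT_ARM = "ATAACTTCGTATA"
WT_RIGHT_ARM = "TATACGAAGTTAT"          # revcomp of the left arm
MUT_LEFT_ARM = "TACCGTTCGTATA"          # lox71 left element
MUT_RIGHT_ARM = "TATACGAACGGTA"         # lox66 right element
LOXP_SPACER = "ATGTATGC"

ARM_LEN, SPACER_LEN = 13, 8
CORE_LEN = 2 * ARM_LEN + SPACER_LEN      # 34 bp

VARIANTS = {
    (False, False): "loxP",
    (True, False): "lox71",
    (False, True): "lox66",
    (True, True): "loxM",
}


def core_sequence(variant: str, spacer: str = LOXP_SPACER) -> str:
    """34 bp arm-spacer-arm core for a named variant."""
    inv = {v: k for k, v in VARIANTS.items()}
    try:
        left_mut, right_mut = inv[variant]
    except KeyError:
        raise RecombinationError(f"unknown lox variant {variant!r}") from None
    left = MUT_LEFT_ARM if left_mut else WT_LEFT_ARM
    right = MUT_RIGHT_ARM if right_mut else WT_RIGHT_ARM
    return left + spacer + right


@dataclass
class LoxSite:
    left_arm: str
    spacer: str
    right_arm: str
    start: int                 # top-strand start of the 34 bp core
    orientation: int = 1       # strand carrying the spacer as stored

    @property
    def left_mutant(self) -> bool:
        return self.left_arm == MUT_LEFT_ARM

    @property
    def right_mutant(self) -> bool:
        return self.right_arm == MUT_RIGHT_ARM

    @property
    def variant(self) -> str:
        return VARIANTS[(self.left_mutant, self.right_mutant)]

    @property
    def end(self) -> int:
        return self.start + CORE_LEN

    @property
    def core(self) -> str:
        return self.left_arm + self.spacer + self.right_arm


@dataclass
class IntegrationResult:
    product: Molecule
    site_upstream: LoxSite
    site_downstream: LoxSite
    disrupted: list[str] = field(default_factory=list)
    expressed: list[str] = field(default_factory=list)
    reversible: bool = False


# --------------------------------------------------------------------------
# site finding

_LEFT_ARMS = (WT_LEFT_ARM, MUT_LEFT_ARM)
_RIGHT_ARMS = (WT_RIGHT_ARM, MUT_RIGHT_ARM)


def find_lox_sites(mol: Molecule) -> list[LoxSite]:
    """Locate arm-spacer-arm lox cores and classify their arms.

    Because the wild-type arms are mutual reverse complements (and so is
    the lox66/lox71 mutant pair), a flipped site still arm-matches on the
    top strand: the non-palindromic spacer alone decides orientation.  A
    window whose reverse-complement reading carries the canonical spacer is
    reported with orientation -1; divergent spacers are kept as written —
    distinct, mutually incompatible sites.
    """
    seq, n = mol.seq, len(mol.seq)
    hay = seq + (seq[: CORE_LEN - 1] if mol.is_circular else "")
    limit = n if mol.is_circular else n - CORE_LEN + 1
    sites = []
    for i in range(max(0, limit)):
        window = hay[i: i + CORE_LEN]
        left = window[:ARM_LEN]
        spacer = window[ARM_LEN: ARM_LEN + SPACER_LEN]
        right = window[ARM_LEN + SPACER_LEN:]
        if left not in _LEFT_ARMS or right not in _RIGHT_ARMS:
            continue
        if spacer == LOXP_SPACER:
            sites.append(LoxSite(left, spacer, right, start=i,
                                 orientation=1))
        elif revcomp(spacer) == LOXP_SPACER:
            sites.append(LoxSite(revcomp(right), revcomp(spacer),
                                 revcomp(left), start=i, orientation=-1))
        else:
            sites.append(LoxSite(left, spacer, right, start=i,
                                 orientation=1))
    return sites


def _single_site(mol: Molecule, what: str) -> LoxSite:
    sites = find_lox_sites(mol)
    if len(sites) != 1:
        raise RecombinationError(
            f"{what} must carry exactly one lox site, found {len(sites)}")
    return sites[0]


# --------------------------------------------------------------------------
# insertion

def _shift_features(feats: Iterable[Feature], off: int) -> list[Feature]:
    return [Feature(f.label, f.start + off, f.end + off, f.strand, f.kind)
            for f in feats]


def cre_insert(target: Molecule, donor: Molecule) -> IntegrationResult:
    """Integrate a circular donor into a target at matching lox sites.

    The crossover happens within the spacer, so each product site inherits
    the left arm of one parent site and the right arm of the other:
    lox66 x lox71 yields one wild-type loxP and one double-mutant loxM
    flanking the insert, and the product length is the sum of the parents'.
    A loxP x loxP insertion is returned too, flagged ``reversible`` since
    the excision reaction is favoured.
    """
    if not donor.is_circular:
        raise RecombinationError("the donor must be circular")
    t_site = _single_site(target, "target")
    d_site = _single_site(donor, "donor")
    if t_site.spacer != d_site.spacer:
        raise RecombinationError(
            f"spacer mismatch: {t_site.spacer} vs {d_site.spacer}; the "
            "sites are incompatible")

    if d_site.orientation != t_site.orientation:
        donor = donor.reverse_complement()
        d_site = _single_site(donor, "donor")
    if t_site.orientation == -1:
        # normalise to top-strand spacers on both molecules
        target = target.reverse_complement()
        donor = donor.reverse_complement()
        t_site = _single_site(target, "target")
        d_site = _single_site(donor, "donor")

    # split both molecules right after arm+spacer
    t_cut = t_site.start + ARM_LEN + SPACER_LEN
    d_cut = d_site.start + ARM_LEN + SPACER_LEN
    donor_lin = donor.rotated(d_cut)   # starts with donor right arm
    t_left, t_right = target.seq[:t_cut], target.seq[t_cut:]

    seq = t_left + donor_lin.seq + t_right
    feats = []
    for f in target.features:
        if f.end <= t_cut:
            feats.append(f)
        elif f.start >= t_cut:
            feats.append(Feature(f.label, f.start + len(donor_lin.seq),
                                 f.end + len(donor_lin.seq), f.strand,
                                 f.kind))
        else:
            feats.append(Feature(f"{f.label}_5p", f.start, t_cut, f.strand,
                                 "cds_disrupted"))
            feats.append(Feature(f"{f.label}_3p",
                                 t_cut + len(donor_lin.seq),
                                 f.end + len(donor_lin.seq), f.strand,
                                 "cds_disrupted"))
    feats += [f for f in _shift_features(
        [g for g in donor_lin.features if not g.wraps], t_cut)]
    product = Molecule(f"{target.id}::{donor.id}", seq, target.topology,
                       end5=target.end5, end3=target.end3, features=feats)

    sites = find_lox_sites(product)
    if len(sites) != 2:
        raise RecombinationError(
            f"expected two lox sites in the product, found {len(sites)}")
    up, dn = sites
    product.features += [
        Feature(up.variant, up.start, up.end, up.orientation, "protein_bind"),
        Feature(dn.variant, dn.start, dn.end, dn.orientation, "protein_bind"),
    ]
    # arm bookkeeping must be conserved through the crossover
    parent_flags = sorted([(t_site.left_mutant, t_site.right_mutant),
                           (d_site.left_mutant, d_site.right_mutant)])
    child_flags = sorted([(up.left_mutant, up.right_mutant),
                          (dn.left_mutant, dn.right_mutant)])
    assert sorted(a for pair in parent_flags for a in pair) == \
        sorted(a for pair in child_flags for a in pair)

    disrupted = [f.label for f in product.features
                 if f.kind == "cds_disrupted"]
    expressed = [cds for _, cds in predict_expression(product)]
    return IntegrationResult(
        product=product, site_upstream=up, site_downstream=dn,
        disrupted=disrupted, expressed=expressed,
        reversible=(up.variant == "loxP" and dn.variant == "loxP"))


def excise(mol: Molecule) -> tuple[Molecule, Molecule]:
    """Cre excision between two same-orientation lox sites in one molecule:
    returns (remaining molecule, excised circle).  Inverse of a loxP x loxP
    insertion."""
    sites = [s for s in find_lox_sites(mol)]
    if len(sites) != 2:
        raise RecombinationError("excision needs exactly two lox sites")
    up, dn = sites
    if up.orientation != dn.orientation:
        raise RecombinationError("sites are inverted: excision impossible")
    if up.spacer != dn.spacer:
        raise RecombinationError("spacer mismatch between the two sites")
    a = up.start + ARM_LEN + SPACER_LEN
    b = dn.start + ARM_LEN + SPACER_LEN
    circle_seq = mol.seq[a:b]
    remaining_seq = mol.seq[:a] + mol.seq[b:]
    circle = Molecule(f"{mol.id}_excised", circle_seq, "circular")
    remaining = Molecule(f"{mol.id}_remaining", remaining_seq, mol.topology,
                         end5=mol.end5, end3=mol.end3)
    return remaining, circle


# --------------------------------------------------------------------------
# expression prediction

def predict_expression(mol: Molecule) -> list[tuple[str, str]]:
    """(promoter label, expressed CDS label) pairs.

    For each promoter feature the first downstream, ATG-initiated CDS that
    is neither interrupted by an insertion (``cds_disrupted``) nor by an
    internal in-frame stop is reported; a promoterless molecule yields an
    empty list.
    """
    out = []
    n = len(mol.seq)
    promoters = [f for f in mol.features if f.kind == "promoter"]
    cdss = sorted((f for f in mol.features if f.kind == "CDS"),
                  key=lambda f: f.start)
    for prom in promoters:
        for cds in cdss:
            start = cds.start
            if not mol.is_circular and start < prom.end:
                continue
            if mol.is_circular:
                dist = (start - prom.end) % n
                if dist > n // 2:   # behind the promoter, not downstream
                    continue
            if _cds_intact(mol, cds):
                out.append((prom.label, cds.label))
                break
    return out


def _cds_intact(mol: Molecule, cds: Feature) -> bool:
    seq = mol.seq[cds.start: cds.end]
    if not seq.startswith("ATG") or len(seq) < 6:
        return False
    stops = ("TAA", "TAG", "TGA")
    for i in range(0, len(seq) - 5, 3):   # internal codons only
        if seq[i:i + 3] in stops:
            return False
    return len(seq) % 3 == 0
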