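# Methods

This note records what `bricklab` models, the choices made where the
design was open, and what the synthetic fixtures do and do not stand for.

## DNA model

A `Molecule` is the top strand (5'→3', strict A/C/G/T; IUPAC ambiguity is
accepted in enzyme recognition patterns but rejected in molecule
sequences), a topology, and — for linear molecules — one overhang
descriptor per end.  Coordinates are 0-based half-open on the top strand;
origin-spanning features carry an explicit wrap flag.

An overhang stores the protruding single strand read 5'→3' *on its own
strand* plus its sense (5' extension, 3' extension, blunt).  A right end
anneals to a left end exactly when the stored sequences are reverse
complements and the senses match.  Digestion partitions the top strand at
the enzymes' top-strand cut offsets, so fragment lengths always sum to
the parent length and concatenating compatible fragments reconstructs
sequences exactly — the overhang bookkeeping only gates which joins are
allowed.  This is what makes scar arithmetic emerge from simulation: the
SpeI x XbaI junction is sealed but matches neither recognition site, and
the 6 bp (RFC 23) / 8 bp (RFC 10) scars are measured from simulated
products, not tabulated.

The enzyme table (20 type-II enzymes, all palindromic) ships as package
data; recognition sequences and cut offsets are canonical catalogue
knowledge, with provenance noted in the file header.

### Digestion

* Circular molecules yield one fragment per cut, linear molecules
  cuts + 1; zero effective cuts return the input unchanged.
* Dam methylation is modelled only where it matters to the workflow: an
  XbaI site is skipped (when `dam_plus`, the default, matching a dam+
  cloning strain) if its hexamer completes a GATC on either side
  (`GATCTAGA` / `TCTAGATC`).  Other methylation, partial digestion and
  star activity are not modelled.

### Ligation

`ligate` enumerates distinct sealed circles over subsets, orderings and
orientations of the supplied fragments, deduplicated up to rotation and
reflection; single-fragment self-circularisation is allowed.  Enumeration
is exponential in fragment count and intentionally capped (default 10
fragments) — the tool's use cases ligate 2–4 fragments.  Linear products
are available behind `circular_only=False`.

## Registry

The packaged TSV transcribes the 52-record collection: nickname, group,
accessions, payload size (plasmid size for the four backbones),
backbone code (A/AK/AC/AT ↔ resistance sets {amp}, {amp,kan}, {amp,chl},
{amp,tet}), Kozak/stop flags, the 3n flag and the classical
restriction-site inventory.  Loading validates 3n-vs-size arithmetic and
flags problems into a report instead of dropping records; the
fusion-incompatible designation is reproduced as `has_stop or not
frame_safe` and holds for every non-backbone record with no exceptions.
Sequence attachment strips affixes by the case convention (affixes in
capitals, payload lower case) with format detection as fallback, then
cross-checks length and site inventory per record.

## Format grammar

Detection is longest-match on the prefix with the suffix breaking ties
(the RFC 10 prefix is the RFC 23 prefix plus `G`, so a payload starting
with G is ambiguous from the prefix alone; the suffixes differ
unambiguously).  The truncated-prefix variant for ATG-initial coding
parts is detected but excluded from fusion planning, as no collection
part uses it.  Stop detection scans frame 0 from the payload start;
Kozak content is taken from the registry flag (the collection treats the
Kozak as a discrete part), with the `GCCACC`+ATG motif used only by the
generator.  Role classification is a total function of flags and payload:
head = Kozak without stop, translation unit = Kozak with stop, tail =
in-frame stop, internal = 3n without either, else non-coding.  A promoter
or spacer that happens to contain an in-frame stop therefore classifies
as "tail" — classification is sequence-driven by design and the registry
report, not the classifier, is the place intent lives.

## Assembly

`standard_assembly` runs the real protocol: EcoRI+SpeI on the upstream
plasmid, XbaI+PstI on the downstream plasmid, EcoRI+PstI on the ccdB
destination, one pot ligation, then selection filtering.  Products
containing ccdB or missing an insert are returned as marked byproducts
(religation background is simulated, not assumed away).  Errors are
specific: internal assembly-enzyme sites, Dam-blocked downstream XbaI
(leading TC), unexpected extra cuts, no remaining selection antibiotic.
Ampicillin can never select (every backbone carries it); the tie-break
order for destinations is kan < chl < tet and is asserted deterministic.
Mixed-standard fusions are allowed and annotated as assembly-compatible
but not frame-preserving.  Protocol text (amounts, temperatures) is
emitted as fixed metadata, never computed.

## Planning

Ordered designs: adjacent pairing left to right per round, odd construct
carried; rounds = ⌈log₂ n⌉.  Only adjacent merges are considered because
standard assembly preserves part order.  Backbone assignment walks the
tree post-order trying the deterministic antibiotic order with
backtracking; with the standard single-marker codes two children can
never exhaust all three selection antibiotics, so infeasibility can only
arise with user-supplied exotic codes.

Concatemers reduce to shortest addition chains: one step fuses any two
previously built copy numbers, including a construct with itself.  The
planner searches ascending chains by iterative deepening, trying larger
extensions first so the doubling-prefix chain (1,2,4,8,…) is returned
among minimal schedules; minimality is cross-checked (in tests and in the
acceptance script) against an independent breadth-first search over
reachable copy-number sets, exhaustive for n ≤ 20.  The copy-number bound
defaults to 64.

Gel-ladder arithmetic for tandem repeats is ambiguous about whether the
per-copy spacing quotes the bare 39 bp motif or motif + 6 bp scar;
`concatemer_length` exposes both readings instead of choosing.

## Classical cloning

PCR is exact-match annealing of each primer's 3'-terminal 12 bases
(configurable), extended 5'-ward as far as the template agrees; remaining
5' bases become tails in the product.  Mismatch priming, Tm and
mutagenic PCR are out of scope.  Circular templates amplify across the
origin; multiple annealing sites are an error listing the products.
Subcloning requires both enzymes unique in the vector, releases the
insert's internal fragment, and relies on distinct (or
compatible-cohesive, e.g. XbaI x NheI) overhangs for directionality.
The frame report anchors on the nearest upstream forward-strand CDS
feature — deterministic, matching the fluorophore-fusion use case —
rather than scanning all open reading frames.

## Cre/lox

Sites are modelled as 13 bp arm / 8 bp spacer / 13 bp arm.  Wild-type
arms are mutual reverse complements, and so are the lox66/lox71 mutant
elements, so a flipped site still arm-matches on the top strand: the
non-palindromic spacer alone assigns orientation, and windows whose
reverse-complement reading carries the canonical spacer are reported on
the minus strand.  Divergent spacers are kept as distinct, mutually
incompatible sites.  Arm sequences follow the canonical loxP and the
published left/right-element mutant convention and are packaged as data.

Insertion cuts both molecules after arm+spacer and splices, so each
product site inherits the left arm of one parent and the right arm of the
other: lox66 x lox71 gives exactly one loxP and one loxM, conserving
total length and mutant-arm count.  loxP x loxP insertion is returned but
flagged reversible (excision-favoured); excision is implemented and
inverts it exactly.  Cre kinetics, multi-copy loci and population-level
outcomes (flow-cytometry fractions) are not modelled — those are wet-lab
quantities, represented here only by the structural switch the simulator
predicts: a promoterless donor expresses nothing alone, and after
insertion into a lox66 inside an expressed CDS the resident promoter's
first intact downstream ATG-initiated CDS changes from the disrupted
resident gene to the incoming one.

The registry's 36 bp lox parts exceed the 34 bp core by two bases; the
synthetic parts pad at the 3' end (chosen so the in-frame lox66 reading
stays stop-free, which the expressed-then-switched design requires), and
the locator searches for the core anywhere regardless.

## Synthetic fixtures

No real payload or vector sequences are redistributed; every sequence the
tests and the acceptance script consume is generated, byte-deterministic
under a seed.  Payloads are random bases/codons constrained to match the
registry row exactly: length, 3n, frame-0 stop content, Kozak motif,
required classical sites embedded exactly once (codon-aligned), no
assembly-enzyme sites, no leading TC — enforced by single-base scrubbing
performed in the wrapped-affix context so junction-spanning sites cannot
survive either.  Hand-designed payloads are used where internal structure
matters (Kozak, the all-three-frames Stop part, the three MCS families
with 5'-padded frame variants, the lox parts).  Backbones are circular
placeholders with the prefix/ccdB/suffix interface, sequencing-primer
sites placed so a colony-PCR amplicon is payload + 312 bp, resistance
markers, tabulated classical sites and the tabulated plasmid size.

What passing tests show, and do not show: the simulator's sequence
arithmetic (scars, frames, overhang compatibility, site counts, length
conservation) holds on sequences that satisfy the collection's documented
constraints.  Real payloads additionally carry biological structure
(codon bias, promoter elements, repeats) that placeholders lack; results
depending only on the constraints transfer, anything
sequence-composition-specific does not.  Dropping in the real FASTA via
`registry.attach_sequences` replaces the placeholders wholesale.

## Problem sizes and numerics

The test suite runs the site-scan oracle on 100 random 2 kb sequences,
length-conservation on 25 random digests, the concatemer oracle
exhaustively to n = 20, format-detection fuzzing at 200 cases and
generator soundness at 120 property cases (hypothesis, derandomised) —
sizes chosen to exercise every branch while keeping the default run fast.
All randomness is seeded; ligation enumeration and chain search are
exact, so there are no numerical tolerances anywhere: every comparison in
the package is integer or string equality.
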