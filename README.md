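# bricklab

In-silico BioBrick engineering for eukaryotic expression plasmids: a
validator, restriction/ligation simulator and multi-round assembly planner
for the standard BioBrick formats, plus classical MCS subcloning and
Cre/lox recombinase-mediated DNA insertion (RMDI).

## Who it is for

Cloning with standardised parts replaces bespoke plasmid surgery with a
single idempotent operation: every part is wrapped in a fixed prefix
(`GAATTCGCGGCCGCTTCTAGA`, carrying EcoRI/NotI/XbaI sites) and suffix
(`ACTAGTAGCGGCCGCTGCAG`, carrying SpeI/NotI/PstI sites).  Digesting an
upstream part with EcoRI+SpeI, a downstream part with XbaI+PstI and a
ccdB destination vector with EcoRI+PstI, then ligating, fuses the parts:
the SpeI and XbaI overhangs are complementary (`CTAG`) but their join —
the *scar* — is recuttable by neither enzyme, and the product regenerates
the original prefix and suffix, so it is itself a part.  `bricklab` lets
you design and sanity-check such builds at the bench-planning stage:
which parts can be fused in frame, which destination backbone to pick,
how many rounds a design takes, which classical restriction sites remain
unique for conventional subcloning, and what a Cre-mediated insertion
will do to expression.

The core rules it implements:

* **Formats.** The original standard (RFC 10) leaves an 8 bp scar
  (`TACTAGAG`) that breaks the reading frame; the fusion standard
  (RFC 23) shortens the affixes so the scar is 6 bp, `ACTAGA`, read as
  Thr-Arg — protein domains chain in frame.  Scars here are computed by
  simulating the digestion and ligation, never looked up.
* **The 3n rule.** A coding part keeps downstream parts in frame only if
  its payload length is a multiple of 3; parts are classed as head
  (Kozak, no stop), internal (3n, no stop), tail (stop), translation unit
  (Kozak + stop) or non-coding.
* **Three-antibiotic selection.** Each backbone carries ampicillin plus at
  most one of kanamycin/chloramphenicol/tetracycline (codes A, AK, AC,
  AT).  A destination must provide a resistance absent from both source
  backbones (deterministic tie-break kan < chl < tet), and its ccdB death
  cassette removes religation background.
* **Dam blocking.** An XbaI site overlapping a GATC (part payload starting
  `TC` behind the RFC 23 prefix) is uncuttable in a dam+ host; the
  validator warns and the simulator refuses the downstream role.
* **Planning.** Ordered n-part designs assemble in ⌈log₂ n⌉ rounds of
  adjacent pairwise fusions; n-copy concatemers of one part reduce to
  shortest addition chains (a 12-mer takes 4 fusions), verified against a
  breadth-first oracle.
* **RMDI.** Cre recombination between the heteromeric sites lox66 and
  lox71 produces one wild-type loxP and one double-mutant loxM, making
  insertion effectively irreversible; inserting a promoterless reporter
  donor into a lox66 placed inside an expressed gene switches which
  coding sequence the resident promoter drives.

The packaged registry transcribes the 52-record collection (4 plasmid
backbones + 48 insert parts, 9 pre-existing and 43 new) with sizes,
Kozak/stop/3n flags and classical restriction-site inventories.  Real
payload sequences are not redistributed; deterministic synthetic
placeholders satisfying every tabulated constraint are generated on
demand (`bricklab.fixtures`), so the whole toolkit is testable offline.

## Worked example

```python
from bricklab import assembly, fixtures, planner, registry

coll = fixtures.load_collection(seed=1)          # 52 records + payloads
up = fixtures.clone_into_backbone(
    registry.lookup(coll, "Kozak"),
    fixtures.make_backbone({"amp", "kan"}, seed=1))    # pSB1AK3-like
down = fixtures.clone_into_backbone(
    registry.lookup(coll, "Linker"),
    fixtures.make_backbone({"amp", "chl"}, seed=2))    # pSB1AC3-like

dest, antibiotic = assembly.select_destination(
    up.backbone, down.backbone,
    [fixtures.make_backbone(r, seed=3)
     for r in ({"amp", "kan"}, {"amp", "chl"}, {"amp", "tet"})])
print("destination:", dest.code, "select on", antibiotic)

res = assembly.standard_assembly(up, down, dest)
print("scar:", res.scar, "| product payload:",
      len(res.product.record.payload), "bp")

pep = assembly.translate_fusion(
    [registry.lookup(coll, n) for n in ("Kozak", "Linker", "Stop")])
print("fusion peptide:", pep)

sched = planner.plan_concatemer(12)
print("12-copy schedule:", len(sched), "steps:", sched.steps)
```

prints

```
destination: AT select on tet
scar: ACTAGA | product payload: 90 bp
fusion peptide: MATRCAHFAPRSPLWKYNILLALITLERTR
12-copy schedule: 4 steps: [(1, 1, 2), (2, 2, 4), (4, 4, 8), (8, 4, 12)]
```

Reading the numbers: the AK x AC sources force the tetracycline
destination (AT); the 12 bp Kozak head plus 6 bp scar plus 72 bp linker
gives a 90 bp product payload that is again a valid RFC 23 part; the
three-part fusion translates with a Thr-Arg (`TR`) dipeptide at each
scar; and twelve tandem copies of a motif need only four bench rounds
(1+1, 2+2, 4+4, 8+4).

A command-line interface mirrors the library:

```sh
bricklab plan --design CMV,Kozak,Cerulean,MCS1a,MCS2a,IRES,FNeomycin,SV40pA
bricklab concat --part MS2BS --copies 12
bricklab registry show EGFP
bricklab fixtures make-rmdi --seed 1 --out demo/
```

## Layout

| module | contents |
| --- | --- |
| `seqmodel` | Molecule/Enzyme/Fragment model, site scan, digestion, ligation, FASTA/GenBank I/O |
| `registry` | packaged 52-record part table, loaders, integrity checks, sequence attachment |
| `grammar` | affix detection, part validation, role classification, scar/frame reports |
| `assembly` | destination selection, standard 3A assembly, fusion translation |
| `planner` | balanced assembly trees, addition-chain concatemers, backbone assignment |
| `classic` | site uniqueness, PCR simulation, directional MCS subcloning |
| `rmdi` | lox site model, Cre insertion/excision, expression prediction |
| `fixtures` | deterministic synthetic parts, backbones, loci and demo constructs |
| `reporting` | plan/validation/RMDI reports, JSON schemas, GenBank rendering |

See `docs/methods.md` for the modelling assumptions and their limits.
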