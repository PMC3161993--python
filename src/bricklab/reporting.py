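"""Human- and machine-readable outputs: plan summaries, validation
reports, protocol sheets and annotated GenBank.

JSON layouts are documented by the schema files under
``bricklab/schemas/``; GenBank output re-parses losslessly for the feature
kinds the tool writes.  Logging goes to standard error.
"""

from __future__ import annotations

import io
import json
import logging
import sys
from dataclasses import dataclass, field

from Bio import SeqIO

from .planner import AssemblyTree
from .seqmodel import Molecule, to_seqrecord

log = logging.getLogger("bricklab")


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING - 10 * min(verbosity, 2)
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(levelname)s %(name)s: %(message)s")


@dataclass
class PlanReport:
    design: list[str]
    rounds: dict[int, list[dict]]
    n_rounds: int
    warnings: list[str] = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "n_rounds": self.n_rounds,
            "rounds": {str(k): v for k, v in sorted(self.rounds.items())},
            "warnings": self.warnings,
            "seed": self.seed,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        lines = [f"design: {','.join(self.design)}",
                 f"rounds: {self.n_rounds}"]
        for r in sorted(self.rounds):
            names = ", ".join(step["name"] for step in self.rounds[r])
            lines.append(f"  round {r}: {names}")
        return "\n".join(lines)


def render_plan(tree: AssemblyTree, seed: int | None = None) -> PlanReport:
    """Round-grouped fusion list (hyphen-joined construct names)."""
    rounds: dict[int, list[dict]] = {}
    for node in tree.root.internal_nodes():
        rounds.setdefault(node.round, []).append({
            "name": node.name,
            "left": node.left.name,
            "right": node.right.name,
            "backbone": node.backbone,
            "antibiotic": node.antibiotic,
            "round": node.round,
        })
    report = PlanReport(design=tree.leaves(), rounds=rounds,
                        n_rounds=tree.rounds, seed=seed)
    seen = [s["name"] for steps in rounds.values() for s in steps]
    if len(seen) != len(set(seen)):
        report.warnings.append("duplicate construct names in the plan")
    expect = list(range(1, tree.rounds + 1))
    if sorted(rounds) != expect:
        report.warnings.append(
            f"rounds {sorted(rounds)} are not contiguous from 1")
    return report


def render_genbank(mol: Molecule) -> str:
    """GenBank flat-file text with the molecule's feature annotations."""
    buf = io.StringIO()
    SeqIO.write(to_seqrecord(mol), buf, "genbank")
    return buf.getvalue()


def validation_to_json(reports) -> str:
    return json.dumps({"parts": [r.to_dict() for r in reports]}, indent=2)
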