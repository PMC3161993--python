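"""Multi-round assembly planning.

Ordered designs are planned as balanced binary fusion trees: each round
pairs adjacent constructs left to right (an odd construct is carried over),
so an n-part design needs ceil(log2 n) bench rounds.  Concatemers of a
single repeated part are the unordered special case — any two previously
built copy numbers may be fused, including a construct with itself — and
reduce to shortest addition chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .assembly import (ANTIBIOTIC_ORDER, AssemblyResult, Backbone,
                       ClonedPart, standard_assembly)
from .registry import BACKBONE_RESISTANCES
from .seqmodel import BrickLabError


class PlanningError(BrickLabError):
    pass


@dataclass
class PlanNode:
    name: str
    part: str | None = None               # leaf: part nickname
    left: "PlanNode | None" = None
    right: "PlanNode | None" = None
    backbone: str | None = None           # A | AK | AC | AT
    antibiotic: str | None = None
    round: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.part is not None

    def leaves(self) -> list["PlanNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def internal_nodes(self) -> list["PlanNode"]:
        """Post-order internal nodes (children before parents)."""
        if self.is_leaf:
            return []
        return (self.left.internal_nodes() + self.right.internal_nodes()
                + [self])


@dataclass
class AssemblyTree:
    root: PlanNode

    @property
    def rounds(self) -> int:
        return self.root.round

    def leaves(self) -> list[str]:
        return [n.part for n in self.root.leaves()]

    def nodes_by_round(self) -> dict[int, list[PlanNode]]:
        out: dict[int, list[PlanNode]] = {}
        for n in self.root.internal_nodes():
            out.setdefault(n.round, []).append(n)
        return out


@dataclass
class ConcatemerSchedule:
    target: int
    steps: list[tuple[int, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)


# --------------------------------------------------------------------------

def plan_balanced(parts: Sequence[str]) -> AssemblyTree:
    """Balanced fusion plan preserving the requested part order."""
    if not parts:
        raise PlanningError("empty design")
    level = [PlanNode(name=p, part=p) for p in parts]
    while len(level) > 1:
        nxt = []
        for i in range(0, len(level) - 1, 2):
            a, b = level[i], level[i + 1]
            nxt.append(PlanNode(name=f"{a.name}-{b.name}", left=a, right=b,
                                round=1 + max(a.round, b.round)))
        if len(level) % 2:
            nxt.append(level[-1])
        level = nxt
    tree = AssemblyTree(level[0])
    assert tree.rounds == (math.ceil(math.log2(len(parts))) if len(parts) > 1
                           else 0)
    return tree


def design_monocistronic(promoter: str, reporter: str, polyA: str,
                         coll=None) -> list[str]:
    """Expand a promoter/reporter/polyA request into the five-part design
    [promoter, Kozak, reporter, Stop, polyA]."""
    from . import registry as _registry

    if not promoter or not reporter or not polyA:
        raise PlanningError("promoter, reporter and polyA are all required")
    if coll is not None:
        for nick in (promoter, "Kozak", reporter, "Stop", polyA):
            _registry.lookup(coll, nick)
        rep = _registry.lookup(coll, reporter)
        if rep.has_kozak and rep.has_stop:
            raise PlanningError(
                f"{reporter} is already a translation unit; the design adds "
                "its own Kozak and Stop parts")
        if rep.has_kozak or rep.has_stop or not rep.frame_safe:
            raise PlanningError(
                f"{reporter} is not an internal-domain part")
    return [promoter, "Kozak", reporter, "Stop", polyA]


# --------------------------------------------------------------------------
# concatemer planning (shortest addition chains)

def plan_concatemer(n: int, bound: int = 64) -> ConcatemerSchedule:
    """Minimal fusion schedule building an n-copy concatemer from 1 copy.

    One step fuses any two previously built copy numbers (both operands may
    be the same construct).  Among minimal schedules the doubling-first
    chain (1, 2, 4, 8, ...) is preferred for reagent reuse.
    """
    if n < 1 or n > bound:
        raise PlanningError(f"copy number {n} outside [1, {bound}]")
    chain = _shortest_chain(n)
    steps = []
    for value in chain[1:]:
        built = chain[: chain.index(value)]
        a = next(a for a in sorted(built, reverse=True)
                 if value - a in built)
        steps.append((a, value - a, value))
    return ConcatemerSchedule(target=n, steps=steps)


def _shortest_chain(n: int) -> list[int]:
    """Shortest ascending addition chain for n, preferring doublings.

    Iterative-deepening DFS; candidate extensions are tried in descending
    order so the doubling-first chain is found first among minimal ones.
    """
    if n == 1:
        return [1]
    limit = max(1, math.ceil(math.log2(n)))
    while True:
        found = _dfs_chain([1], n, limit)
        if found is not None:
            return found
        limit += 1


def _dfs_chain(chain: list[int], n: int, limit: int) -> list[int] | None:
    last = chain[-1]
    if last == n:
        return list(chain)
    steps_left = limit - (len(chain) - 1)
    if steps_left <= 0 or last << steps_left < n:
        return None
    sums = {a + b for i, a in enumerate(chain) for b in chain[i:]}
    for s in sorted(sums, reverse=True):
        if last < s <= n:
            chain.append(s)
            found = _dfs_chain(chain, n, limit)
            chain.pop()
            if found is not None:
                return found
    return None


def concatemer_oracle_steps(n: int) -> int:
    """Breadth-first search over reachable copy-number sets: the true
    minimum number of fusion steps to reach n.  Independent of the chain
    search above; intended for cross-checks at small n."""
    if n == 1:
        return 0
    frontier = {frozenset({1})}
    depth = 0
    seen = set(frontier)
    while frontier:
        depth += 1
        nxt = set()
        for state in frontier:
            vals = sorted(state)
            for i, a in enumerate(vals):
                for b in vals[i:]:
                    s = a + b
                    if s == n:
                        return depth
                    if s < n:
                        new = frozenset(state | {s})
                        if new not in seen:
                            seen.add(new)
                            nxt.add(new)
        frontier = nxt
    raise PlanningError(f"unreachable copy number {n}")


# --------------------------------------------------------------------------
# backbone assignment

def assign_backbones(tree: AssemblyTree, leaf_backbones: dict[str, str]
                     ) -> AssemblyTree:
    """Assign a backbone and selection antibiotic to every internal node.

    Each node's backbone must provide an antibiotic absent from both
    children's backbones.  Candidates are tried in the deterministic
    kan < chl < tet order with backtracking up the tree; an infeasible node
    is reported with its name.
    """
    for leaf in tree.root.leaves():
        try:
            code = leaf_backbones[leaf.part]
        except KeyError:
            raise PlanningError(f"no backbone known for leaf "
                               f"{leaf.part!r}") from None
        if code not in BACKBONE_RESISTANCES:
            raise PlanningError(f"{leaf.part}: bad backbone code {code!r}")
        leaf.backbone = code

    nodes = tree.root.internal_nodes()  # post-order: children first

    def candidates(node: PlanNode) -> list[tuple[str, str]]:
        used = (BACKBONE_RESISTANCES[node.left.backbone]
                | BACKBONE_RESISTANCES[node.right.backbone])
        out = []
        for ab, code in zip(ANTIBIOTIC_ORDER, ("AK", "AC", "AT")):
            if ab not in used:
                out.append((code, ab))
        return out

    def solve(i: int) -> PlanNode | None:
        if i == len(nodes):
            return None
        node = nodes[i]
        cands = candidates(node)
        if not cands:
            return node
        for code, ab in cands:
            node.backbone, node.antibiotic = code, ab
            bad = solve(i + 1)
            if bad is None:
                return None
        node.backbone = node.antibiotic = None
        return node

    bad = solve(0)
    if bad is not None:
        raise PlanningError(
            f"infeasible backbone assignment at node {bad.name!r}: children "
            f"{bad.left.backbone}/{bad.right.backbone} exhaust the "
            "selection antibiotics")
    return tree


# --------------------------------------------------------------------------
# plan execution

def execute_plan(tree: AssemblyTree, leaves: dict[str, ClonedPart],
                 backbone_factory) -> tuple[ClonedPart,
                                            dict[str, AssemblyResult]]:
    """Run every fusion of an assigned tree through the assembly simulator.

    ``leaves`` maps leaf part names to cloned parts; ``backbone_factory``
    is called with a backbone code to produce a fresh ccdB destination for
    each internal node.  Returns the final construct and the per-node
    assembly results.
    """
    built: dict[str, ClonedPart] = dict(leaves)
    results: dict[str, AssemblyResult] = {}
    for node in tree.root.internal_nodes():
        if node.backbone is None:
            raise PlanningError(
                f"node {node.name!r} has no backbone assigned; run "
                "assign_backbones first")
        up = built[node.left.name]
        down = built[node.right.name]
        dest = backbone_factory(node.backbone)
        res = standard_assembly(up, down, dest)
        if res.selection_antibiotic != node.antibiotic:
            raise PlanningError(
                f"node {node.name!r}: simulated selection "
                f"({res.selection_antibiotic}) disagrees with the plan "
                f"({node.antibiotic})")
        built[node.name] = res.product
        results[node.name] = res
    return built[tree.root.name], results


def concatemer_length(n: int, unit_len: int = 39,
                      scar_inclusive: bool = False) -> int:
    """Payload length of an n-copy concatemer of a ``unit_len`` bp part.

    Gel-ladder arithmetic for tandem repeats is ambiguous about whether the
    per-copy spacing quotes the bare part or the part plus its assembly
    scar, so both readings are exposed: with ``scar_inclusive`` each copy
    counts ``unit_len + 6``; otherwise the n-copy payload is
    ``n*unit_len + (n-1)*6`` (scars only between copies).
    """
    if n < 1:
        raise PlanningError("a concatemer has at least one copy")
    scar = 6
    if scar_inclusive:
        return n * (unit_len + scar)
    return n * unit_len + (n - 1) * scar
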