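"""Stage 0: staple routing trees (SRTs).

For each (virtual) staple, the SRT enumerates candidate Watson-Crick routes
across the scaffold. A tree node ``(start: mu)`` is a staple section whose
first staple base pairs scaffold base ``start`` and which runs ``mu`` bases
toward scaffold 5' (staple and scaffold are antiparallel, so staple base
``staple_offset + j`` pairs scaffold base ``start - j``). Root-to-leaf paths
that consume the whole staple are complete routes; partial routes are never
stored.

Two parameters shape the tree:

* ``mu_min`` -- minimum staple-scaffold complementary run length admitted as
  a section (in practice 5 or 6 bp);
* ``sigma`` -- competitor window: within each sibling set, only sections
  within ``sigma`` bases of the longest sibling are kept (e.g. with a 16 bp
  best sibling and sigma = 5, siblings need mu >= 11).

Matches are *maximal runs*: a candidate section extends greedily until the
first mismatch or the staple end, never splitting early. This is what makes
sequence-matching "overshoot" possible (a section absorbing a base past the
designed crossover when the complementarity happens to continue).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .seqio import Material, Scaffold, Section, VirtualStaple, wc_partner

log = logging.getLogger(__name__)

DEFAULT_NODE_CAP = 10**6

Route = tuple["Section", ...]


class SolverMode(str, Enum):
    DETERMINISTIC = "deterministic"
    NONDETERMINISTIC = "nondeterministic"


@dataclass(frozen=True)
class SolverParams:
    """REVNANO solver parameters (consensus defaults are raster: 6, 4, 0.3)."""

    mu_min: int = 6
    sigma: int = 4
    beta: float = 0.3
    mode: SolverMode = SolverMode.DETERMINISTIC
    seed: int = 0
    node_cap: int = DEFAULT_NODE_CAP

    def __post_init__(self) -> None:
        if self.mu_min < 1:
            raise ValueError("mu_min must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")


@dataclass
class SRTNode:
    start: int | None  # None for the sentinel root (staple 5')
    mu: int
    staple_offset: int
    children: list["SRTNode"] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "start": self.start,
            "mu": self.mu,
            "staple_offset": self.staple_offset,
            "children": [c.to_dict() for c in self.children],
        }


@dataclass
class SRT:
    """Routing tree of one virtual staple plus its derived route list."""

    staple: VirtualStaple
    root: SRTNode
    routes: list[Route]
    aborted: bool = False  # tree-size cap hit; routes is empty

    @property
    def n_routes(self) -> int:
        return len(self.routes)

    def to_json(self) -> str:
        return json.dumps({"staple": self.staple.parent_id,
                           "segment": self.staple.parent_segment_index,
                           "aborted": self.aborted,
                           "tree": self.root.to_dict()}, indent=1)

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(node: SRTNode, depth: int) -> None:
            if node.start is not None:
                lines.append("  " * depth + f"({node.start}: {node.mu})")
            for c in node.children:
                walk(c, depth + 1)

        walk(self.root, -1)
        return "\n".join(lines)


def route_bases(route: Iterable[Section], n: int, circular: bool) -> frozenset[int]:
    """All scaffold bases claimed by a route."""
    out: set[int] = set()
    for sec in route:
        out.update(sec.scaffold_bases(n, circular))
    return frozenset(out)


def footprint(routes: Sequence[Route], n: int, circular: bool) -> frozenset[int]:
    """Scaffold bases common to every surviving route: the bases the staple
    definitely claims. Empty when no route survives or routes share nothing;
    maximal (the whole route) when exactly one route survives."""
    if not routes:
        return frozenset()
    sets = [route_bases(r, n, circular) for r in routes]
    fp = sets[0]
    for s in sets[1:]:
        fp &= s
    return fp


def maximal_matches(
    staple_suffix: str, scaffold: Scaffold, mu_min: int, staple_offset: int = 0
) -> list[Section]:
    """All scaffold positions where the suffix starts an antiparallel
    complementary run of at least ``mu_min`` bases, each extended greedily
    until mismatch or staple end (maximal runs only).

    Returns candidate :class:`Section` objects sorted by scaffold start.
    """
    if not staple_suffix:
        raise ValueError("empty staple suffix")
    n = scaffold.n
    seq = scaffold.sequence
    # partner[i] = staple letter that pairs scaffold base i
    partner = [wc_partner(b, scaffold.material) for b in seq]
    suffix = staple_suffix.upper()
    lmax = min(len(suffix), n)
    out: list[Section] = []
    for s in range(n):
        if suffix[0] != partner[s]:
            continue
        mu = 1
        if scaffold.circular:
            while mu < lmax and suffix[mu] == partner[(s - mu) % n]:
                mu += 1
        else:
            while mu < lmax and s - mu >= 0 and suffix[mu] == partner[s - mu]:
                mu += 1
        if mu >= mu_min:
            out.append(Section(s, mu, staple_offset))
    return out


class _TreeCap(Exception):
    pass


def build_srt(
    staple: VirtualStaple,
    scaffold: Scaffold,
    mu_min: int,
    sigma: int,
    node_cap: int = DEFAULT_NODE_CAP,
) -> SRT:
    """Depth-first construction of a staple routing tree.

    Children of a node are the maximal matches of the remaining staple
    suffix over the whole scaffold, minus candidates that would overlap
    scaffold bases already claimed by ancestor sections of the same route
    (physically impossible self-hybridisation), then sigma-pruned within the
    sibling set. Dead branches (staple not fully consumed, no children) are
    discarded, so the stored tree contains complete routes only.

    If the node count exceeds ``node_cap`` the staple is aborted (empty SRT,
    logged) rather than exhausting memory.
    """
    seq = staple.sequence
    length = len(seq)
    n = scaffold.n
    root = SRTNode(None, 0, 0)
    routes: list[Route] = []
    count = 0

    def expand(node: SRTNode, offset: int, used: frozenset[int], path: tuple[Section, ...]) -> bool:
        nonlocal count
        candidates = maximal_matches(seq[offset:], scaffold, mu_min, staple_offset=offset)
        # reject self-overlap first so an unusable long match cannot set the
        # sigma bar for its siblings
        candidates = [
            c for c in candidates
            if not used & set(c.scaffold_bases(n, scaffold.circular))
        ]
        if not candidates:
            return False
        best = max(c.mu for c in candidates)
        candidates = [c for c in candidates if c.mu >= best - sigma]
        any_complete = False
        for cand in candidates:
            count += 1
            if count > node_cap:
                raise _TreeCap
            child = SRTNode(cand.start, cand.mu, cand.staple_offset)
            new_path = path + (cand,)
            if offset + cand.mu == length:
                node.children.append(child)
                routes.append(new_path)
                any_complete = True
            else:
                ok = expand(
                    child,
                    offset + cand.mu,
                    used | set(cand.scaffold_bases(n, scaffold.circular)),
                    new_path,
                )
                if ok:
                    node.children.append(child)
                    any_complete = True
        return any_complete

    try:
        expand(root, 0, frozenset(), ())
    except _TreeCap:
        log.warning(
            "staple %d segment %d: SRT exceeded %d nodes, aborted",
            staple.parent_id, staple.parent_segment_index, node_cap,
        )
        return SRT(staple, SRTNode(None, 0, 0), [], aborted=True)
    return SRT(staple, root, routes)


def enumerate_tilings(
    staple_seq: str, scaffold: Scaffold, mu_min: int
) -> set[tuple[tuple[int, int], ...]]:
    """Brute-force enumeration oracle: all complete tilings of a staple by
    maximal antiparallel complementary runs, with no sibling pruning and no
    shared machinery with :func:`build_srt`.

    Returns routes as tuples of (scaffold start, mu) pairs. Intended for
    testing on small inputs (scaffold <= ~300 nt).
    """
    n = scaffold.n
    mat: Material = scaffold.material
    seq = staple_seq.upper()

    def pair_ok(scaf_idx: int, staple_letter: str) -> bool:
        if scaffold.circular:
            scaf_idx %= n
        elif not 0 <= scaf_idx < n:
            return False
        return wc_partner(scaffold.sequence[scaf_idx], mat) == staple_letter

    results: set[tuple[tuple[int, int], ...]] = set()

    def rec(offset: int, used: set[int], acc: tuple[tuple[int, int], ...]) -> None:
        if offset == len(seq):
            results.add(acc)
            return
        remaining = len(seq) - offset
        for s in range(n):
            # maximal run starting at scaffold s for the suffix at offset
            mu = 0
            while (
                mu < remaining
                and mu < n
                and pair_ok(s - mu, seq[offset + mu])
            ):
                mu += 1
            if mu < mu_min:
                continue
            bases = {(s - j) % n if scaffold.circular else s - j for j in range(mu)}
            if bases & used:
                continue
            rec(offset + mu, used | bases, acc + ((s, mu),))

    rec(0, set(), ())
    return results


@dataclass
class RouteStats:
    n_staples: int
    zero_route: int
    one_route: int
    multi_route: int
    multi_route_mean: float  # 0.0 when there are no multi-route staples
    multi_route_max: int
    aborted: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def route_stats(srts: Sequence[SRT]) -> RouteStats:
    """Stage-0 summary: counts of 0-, 1- and multi-route staples plus the
    mean and max route count among multi-route staples."""
    multi = [s.n_routes for s in srts if s.n_routes > 1]
    stats = RouteStats(
        n_staples=len(srts),
        zero_route=sum(1 for s in srts if s.n_routes == 0),
        one_route=sum(1 for s in srts if s.n_routes == 1),
        multi_route=len(multi),
        multi_route_mean=(sum(multi) / len(multi)) if multi else 0.0,
        multi_route_max=max(multi, default=0),
        aborted=sum(1 for s in srts if s.aborted),
    )
    log.info(
        "Stage 0: %d staples (%d one-route, %d multi-route, %d unrouteable, %d aborted); "
        "mean %.1f routes among multi-route staples",
        stats.n_staples, stats.one_route, stats.multi_route, stats.zero_route,
        stats.aborted, stats.multi_route_mean,
    )
    return stats
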