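"""The constraint-programming solver (Stages 0-4) and the NAIVE baseline.

Pipeline: split staples into virtual staples (one per hybridising segment),
build staple routing trees (Stage 0), propagate footprint constraints until
no staple's footprint grows (Stage 1), abort if fewer than 65 % of staples
are placed (error E2), force remaining multi-route staples one at a time by
the clearest-shortest-path heuristic over the scaffold base graph (Stage 2),
repair staple-staple overlaps by trimming overshooting section termini
(Stage 3, error E4 when unresolvable), and reassemble virtual staples into
physical staples (Stage 4) to produce the recovered contact map.

The NAIVE baseline routes each staple independently by repeatedly committing
the longest complementary match of the remaining staple prefix; it works on
repeat-free scaffolds but misroutes staples whenever a repeated scaffold
region replicates a binding site.
"""

from __future__ import annotations

import logging
import random
import time
from dataclasses import dataclass, field

import networkx as nx

from .contactmap import ContactMap
from .errors import OverlapError, Stage2Error
from .seqio import Design, Section, VirtualStaple, merge_virtual, split_virtual
from .srt import (
    SRT,
    Route,
    SolverMode,
    SolverParams,
    build_srt,
    footprint,
    maximal_matches,
    route_stats,
)

log = logging.getLogger(__name__)

E2_THRESHOLD = 0.65  # fixed, not a tunable parameter


@dataclass
class _StapleState:
    routes: list[Route]
    footprint: frozenset[int] = frozenset()
    unplaceable: bool = False

    @property
    def placed(self) -> bool:
        return len(self.routes) == 1

    @property
    def multi(self) -> bool:
        return len(self.routes) > 1


class ClaimState:
    """Current solver state: per-staple surviving routes and footprints, and
    the per-scaffold-base sets of claiming staples."""

    def __init__(self, design: Design, virtuals: list[VirtualStaple],
                 srts: list[SRT], params: SolverParams):
        self.design = design
        self.scaffold = design.scaffold
        self.virtuals = virtuals
        self.srts = srts
        self.params = params
        self.states = [_StapleState(list(s.routes)) for s in srts]
        self.claimed_by: list[set[int]] = [set() for _ in range(self.scaffold.n)]
        for i, st in enumerate(self.states):
            if not st.routes:
                st.unplaceable = True
            else:
                self._set_footprint(i, footprint(st.routes, self.scaffold.n, self.scaffold.circular))

    # -- bookkeeping -----------------------------------------------------

    def _set_footprint(self, i: int, fp: frozenset[int]) -> None:
        old = self.states[i].footprint
        if not fp >= old:
            raise RuntimeError(f"footprint of staple {i} shrank: monotonicity violated")
        for b in fp - old:
            self.claimed_by[b].add(i)
        self.states[i].footprint = fp

    def _drop_staple(self, i: int) -> None:
        st = self.states[i]
        st.unplaceable = True
        st.routes = []
        for b in st.footprint:
            self.claimed_by[b].discard(i)
        st.footprint = frozenset()
        log.warning("virtual staple %d (parent %d) became unplaceable",
                    i, self.virtuals[i].parent_id)

    def _section_blocked(self, sec: Section, i: int) -> bool:
        bases = sec.scaffold_bases(self.scaffold.n, self.scaffold.circular)
        claimed = sum(1 for b in bases if self.claimed_by[b] - {i})
        return claimed / len(bases) >= self.params.beta

    def _route_blocked(self, route: Route, i: int) -> bool:
        return any(self._section_blocked(sec, i) for sec in route)

    # -- counters ---------------------------------------------------------

    @property
    def n_total(self) -> int:
        return len(self.states)

    @property
    def n_placed(self) -> int:
        return sum(1 for st in self.states if st.placed)

    @property
    def n_multi(self) -> int:
        return sum(1 for st in self.states if st.multi)

    @property
    def n_unplaceable(self) -> int:
        return sum(1 for st in self.states if st.unplaceable)

    def placed_fraction(self) -> float:
        return self.n_placed / self.n_total if self.n_total else 1.0

    def placed_routes(self) -> dict[int, Route]:
        return {i: st.routes[0] for i, st in enumerate(self.states) if st.placed}


def stage1_propagate(claims: ClaimState) -> int:
    """Constraint propagation: repeated sweeps polling every staple, pruning
    routes containing a section whose scaffold bases are >= beta-fraction
    claimed by other staples' footprints; claims are updated immediately
    (Gauss-Seidel), and sweeps stop when none enlarges a footprint.

    Returns the number of sweeps run.
    """
    params = claims.params
    rng = random.Random(params.seed) if params.mode is SolverMode.NONDETERMINISTIC else None
    n = claims.scaffold.n
    circular = claims.scaffold.circular
    sweeps = 0
    while True:
        sweeps += 1
        order = list(range(claims.n_total))
        if rng is not None:
            rng.shuffle(order)
        grew = False
        for i in order:
            st = claims.states[i]
            if st.unplaceable or st.placed:
                continue
            surviving = [r for r in st.routes if not claims._route_blocked(r, i)]
            if len(surviving) == len(st.routes):
                continue
            st.routes = surviving
            if not surviving:
                claims._drop_staple(i)
                continue
            fp = footprint(surviving, n, circular)
            if fp != st.footprint:
                claims._set_footprint(i, fp)
                grew = True
        if not grew:
            break
    return sweeps


def stage2_check(claims: ClaimState) -> None:
    """Raise E2 when fewer than 65 % of (virtual) staples are placed: the
    scaffold base graph would be too sparse for reliable shortest paths."""
    frac = claims.placed_fraction()
    if frac < E2_THRESHOLD:
        raise Stage2Error(
            f"only {frac:.1%} of staples placed after Stage 1 "
            f"(< {E2_THRESHOLD:.0%}); not enough staples placed to perform "
            "reliable shortest-path calculations"
        )


def build_base_graph(claims: ClaimState) -> nx.Graph:
    """Scaffold base graph B: scaffold bases as nodes, joined by backbone
    adjacency and by crossover edges of *placed* staples."""
    n = claims.scaffold.n
    b = nx.Graph()
    b.add_nodes_from(range(n))
    b.add_edges_from((i, i + 1) for i in range(n - 1))
    if claims.scaffold.circular:
        b.add_edge(n - 1, 0)
    for route in claims.placed_routes().values():
        for s1, s2 in zip(route, route[1:]):
            u = (s1.start - (s1.mu - 1)) % n  # base paired to s1's last staple base
            v = s2.start % n  # base paired to s2's first staple base
            b.add_edge(u, v)
    return b


def _route_endpoints(route: Route, n: int) -> tuple[int, int]:
    e5 = route[0].start % n
    e3 = (route[-1].start - (route[-1].mu - 1)) % n
    return e5, e3


def stage2_place(claims: ClaimState) -> int:
    """Clearest-shortest-path placement of the G1 staples (those left with
    more than one route after Stage 1).

    Each iteration values every G1 route by its shortest-path length (edge
    count) through B between the scaffold bases paired to the staple's 5'
    and 3' ends, forces the staple with the greatest margin between its best
    and second-best route to its best route (ties go to the highest staple
    id), and re-runs constraint propagation to capture the ripple cascade
    before rebuilding B. Staples whose routes all have unreachable endpoints
    are left multi-route and end up omitted from the contact map.

    Returns the number of force-placement iterations.
    """
    n = claims.scaffold.n
    iters = 0
    while True:
        g1 = [i for i, st in enumerate(claims.states) if st.multi]
        if not g1:
            break
        b = build_base_graph(claims)
        best: tuple[float, int, int, Route] | None = None  # margin, staple key, idx, route
        for i in g1:
            values: list[tuple[float, int]] = []
            for k, route in enumerate(claims.states[i].routes):
                e5, e3 = _route_endpoints(route, n)
                try:
                    v = float(nx.shortest_path_length(b, e5, e3))
                except nx.NetworkXNoPath:
                    v = float("inf")
                values.append((v, k))
            values.sort()
            if values[0][0] == float("inf"):
                continue  # all endpoints unreachable: staple is omitted
            v1, k1 = values[0]
            v2 = values[1][0]
            margin = v2 - v1
            cand = (margin, i, i, claims.states[i].routes[k1])
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
        if best is None:
            break
        _, _, idx, route = best
        iters += 1
        st = claims.states[idx]
        st.routes = [route]
        claims._set_footprint(idx, footprint(st.routes, n, claims.scaffold.circular))
        stage1_propagate(claims)  # ripple cascade; B rebuilt on next loop
    return iters


def _overlap_candidates(sec: Section, shared: set[int], n: int, circular: bool):
    """Which terminus of ``sec`` (if any) could yield the shared bases.

    Returns '3' when the shared bases are a contiguous run ending at the
    section's staple-3' terminus (the greedy-matching overshoot end), '5'
    for a run at the staple-5' start, else None.
    """
    bases = list(sec.scaffold_bases(n, circular))  # in staple order, 5'->3'
    k = len(shared)
    if k > len(bases):
        return None
    if set(bases[-k:]) == shared:
        return "3"
    if set(bases[:k]) == shared:
        return "5"
    return None


def stage3_fix_overlaps(routes: dict[int, Route], virtuals: list[VirtualStaple],
                        n: int, circular: bool) -> dict[int, Route]:
    """Repair staple-staple overlaps by trimming overshooting termini.

    For every scaffold base claimed by two staples, the two overlapping
    sections are identified and the section whose terminus intrudes into the
    other yields: its overlapping bases are trimmed off and become unpaired.
    Staple-3' termini are preferred (sequence-matching overshoot extends the
    3' end of a match); ties go to the higher staple id. A base claimed by
    three staples, an overlap with no terminus-only resolution, or a trim
    that would erase a section raises E4.
    """
    routes = {i: tuple(r) for i, r in routes.items()}

    def claims_map() -> dict[int, list[tuple[int, int]]]:
        cm: dict[int, list[tuple[int, int]]] = {}
        for i, route in routes.items():
            for si, sec in enumerate(route):
                for bidx in sec.scaffold_bases(n, circular):
                    cm.setdefault(bidx, []).append((i, si))
        return cm

    while True:
        cmap = claims_map()
        conflict = None
        for base, claimants in cmap.items():
            if len(claimants) >= 3:
                raise OverlapError(
                    f"unresolvable 3-staple overlap exists at scaffold base {base}"
                )
            if len(claimants) == 2:
                conflict = (base, claimants)
                break
        if conflict is None:
            return {i: tuple(r) for i, r in routes.items()}

        _, ((ia, sa), (ib, sb)) = conflict
        sec_a, sec_b = routes[ia][sa], routes[ib][sb]
        bases_a = set(sec_a.scaffold_bases(n, circular))
        bases_b = set(sec_b.scaffold_bases(n, circular))
        shared = bases_a & bases_b

        cand_a = _overlap_candidates(sec_a, shared, n, circular)
        cand_b = _overlap_candidates(sec_b, shared, n, circular)
        k = len(shared)

        def viable(sec: Section, cand) -> bool:
            return cand is not None and sec.mu - k >= 1

        picks = []
        for i, si, sec, cand in ((ia, sa, sec_a, cand_a), (ib, sb, sec_b, cand_b)):
            if viable(sec, cand):
                # prefer 3'-terminus trims, then higher parent staple id
                picks.append((cand == "3", virtuals[i].parent_id, i, si, sec, cand))
        if not picks:
            raise OverlapError(
                "staple-staple overlap without a terminus-only resolution "
                f"between virtual staples {ia} and {ib}"
            )
        picks.sort(reverse=True)
        _, _, i, si, sec, cand = picks[0]
        if cand == "3":
            new_sec = Section(sec.start, sec.mu - k, sec.staple_offset)
        else:
            new_start = (sec.start - k) % n if circular else sec.start - k
            new_sec = Section(new_start, sec.mu - k, sec.staple_offset + k)
        log.info(
            "Stage 3: trimmed %d base(s) off the %s end of virtual staple %d section %d",
            k, "3'" if cand == "3" else "5'", i, si,
        )
        route = list(routes[i])
        route[si] = new_sec
        routes[i] = tuple(route)


@dataclass
class SolveReport:
    solver: str
    params: dict
    n_staples: int
    n_virtual: int
    stage0: dict = field(default_factory=dict)
    stage1_sweeps: int = 0
    stage1_placed: int = 0
    stage2_iterations: int = 0
    stage2_placed: int = 0
    omitted_virtual: list[int] = field(default_factory=list)
    omitted_parents: list[int] = field(default_factory=list)
    partial_parents: list[int] = field(default_factory=list)
    sp_percent: float = 100.0
    elapsed_s: float = 0.0

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _finalise(design: Design, virtuals: list[VirtualStaple],
              routes: dict[int, Route], report: SolveReport) -> tuple[ContactMap, SolveReport]:
    """Stage 4: overlap repair happened already; reassemble virtual staples,
    compute SP% over parent staples, and emit the contact map."""
    placements = merge_virtual(virtuals, routes, design)
    scaffold = design.scaffold
    cm = ContactMap.empty(scaffold.n, scaffold.circular, scaffold.material)
    for pl in placements:
        for sec in pl.sections:
            for j, b in enumerate(sec.scaffold_bases(scaffold.n, scaffold.circular)):
                if cm.staple_id[b] != -1:
                    raise OverlapError(f"residual overlap at scaffold base {b}")
                cm.set_pair(b, pl.staple_id, sec.staple_offset + j)

    total_parents = len(design.staples)
    routed_parents = {pl.staple_id for pl in placements if not pl.partial}
    report.partial_parents = sorted(pl.staple_id for pl in placements if pl.partial)
    report.omitted_parents = sorted(
        set(range(total_parents)) - {pl.staple_id for pl in placements}
    )
    if total_parents:
        report.sp_percent = 100.0 * len(routed_parents) / total_parents
    else:
        report.sp_percent = 100.0  # by convention on an empty staple list
        log.info("empty staple list: SP%% reported as 100 by convention")
    return cm, report


def solve(design: Design, params: SolverParams | None = None) -> tuple[ContactMap, SolveReport]:
    """Run the full solver on a design and return (contact map, report).

    Raises :class:`Stage2Error` (E2) or :class:`OverlapError` (E4).
    """
    params = params or SolverParams()
    t0 = time.perf_counter()
    scaffold = design.scaffold
    virtuals = split_virtual(design)
    report = SolveReport(
        solver="revnano",
        params={"mu_min": params.mu_min, "sigma": params.sigma, "beta": params.beta,
                "mode": params.mode.value, "seed": params.seed},
        n_staples=len(design.staples),
        n_virtual=len(virtuals),
    )
    srts = [build_srt(v, scaffold, params.mu_min, params.sigma, params.node_cap)
            for v in virtuals]
    report.stage0 = route_stats(srts).as_dict()

    claims = ClaimState(design, virtuals, srts, params)
    report.stage1_sweeps = stage1_propagate(claims)
    report.stage1_placed = claims.n_placed
    if claims.n_total:
        stage2_check(claims)
    report.stage2_iterations = stage2_place(claims)
    report.stage2_placed = claims.n_placed
    report.omitted_virtual = sorted(
        i for i, st in enumerate(claims.states) if not st.placed
    )

    fixed = stage3_fix_overlaps(claims.placed_routes(), virtuals,
                                scaffold.n, scaffold.circular)
    cm, report = _finalise(design, virtuals, fixed, report)
    report.elapsed_s = round(time.perf_counter() - t0, 3)
    log.info("solved: SP%%=%.1f, %d omitted staples, %.2fs",
             report.sp_percent, len(report.omitted_parents), report.elapsed_s)
    return cm, report


def solve_naive(design: Design, mu_min: int = 6) -> tuple[ContactMap, SolveReport]:
    """The NAIVE baseline: route each staple independently by repeatedly
    committing the longest maximal complementary match (ties to the lowest
    scaffold start) of the remaining staple prefix, then repair overlaps and
    reassemble. A staple that cannot be fully consumed is left unplaced."""
    t0 = time.perf_counter()
    scaffold = design.scaffold
    virtuals = split_virtual(design)
    report = SolveReport(
        solver="naive",
        params={"mu_min": mu_min},
        n_staples=len(design.staples),
        n_virtual=len(virtuals),
    )
    routes: dict[int, Route] = {}
    for vi, vs in enumerate(virtuals):
        seq = vs.sequence
        offset = 0
        used: set[int] = set()
        sections: list[Section] = []
        while offset < len(seq):
            matches = maximal_matches(seq[offset:], scaffold, mu_min, staple_offset=offset)
            matches = [
                m for m in matches
                if not used & set(m.scaffold_bases(scaffold.n, scaffold.circular))
            ]
            if not matches:
                sections = []
                break
            matches.sort(key=lambda m: (-m.mu, m.start))
            best = matches[0]
            sections.append(best)
            used |= set(best.scaffold_bases(scaffold.n, scaffold.circular))
            offset += best.mu
        if sections:
            routes[vi] = tuple(sections)
    report.stage1_placed = len(routes)
    report.omitted_virtual = sorted(set(range(len(virtuals))) - set(routes))

    fixed = stage3_fix_overlaps(routes, virtuals, scaffold.n, scaffold.circular)
    cm, report = _finalise(design, virtuals, fixed, report)
    report.elapsed_s = round(time.perf_counter() - t0, 3)
    return cm, report
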