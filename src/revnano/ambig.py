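"""Junction ambiguity analysis (the AMBIG algorithm).

A junction is the boundary between two adjacent hybridised scaffold domains
belonging to different staple sections (a Holliday junction or a
half-crossover/nick between staples). Because the solver only knows
sequence complementarity, a junction whose surrounding scaffold letters
permit the boundary to slide while both staples remain Watson-Crick paired
is *ambiguous*: its placed position is one of several equally consistent
positions. If every junction is immovable (and every staple is placed), the
contact map is encoded in the sequences without information loss.

Sliding by ``k`` transfers the pairing of ``k`` scaffold bases between the
two flanking staple sections, with both staple sequences fixed;
complementarity is re-tested against the shifted alignment. For a slide of
one base this reduces to the classic letter criterion: the scaffold base
following the crossover must equal the scaffold base on the other side of
the crossover for the junction to move.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .contactmap import UNPAIRED, ContactMap
from .seqio import Design, SegmentKind, wc_partner

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class JunctionReport:
    """Slack of one junction, identified by the scaffold base pair (b, b+1)
    at the boundary. ``ambiguous`` iff the junction can slide at all."""

    junction: tuple[int, int]
    slack_left: int
    slack_right: int
    staple_left: int
    staple_right: int

    @property
    def ambiguous(self) -> bool:
        return self.slack_left + self.slack_right > 0

    @property
    def immovable(self) -> bool:
        return not self.ambiguous


def _section_extent(cm: ContactMap, pos: int, direction: int) -> int:
    """Length of the section run containing ``pos`` walking ``direction``."""
    n = cm.n
    sid, sb = cm.partner(pos)
    length = 1
    p = pos
    while True:
        q = p + direction
        if cm.circular:
            q %= n
        elif not 0 <= q < n:
            break
        nxt = cm.partner(q)
        if nxt is None or nxt[0] != sid or nxt[1] != sb - direction:
            break
        sid, sb = nxt
        p = q
        length += 1
    return length


def find_junctions(cm: ContactMap) -> list[tuple[int, int]]:
    """All boundaries (b, b+1) between adjacent paired scaffold bases that
    belong to different staple sections."""
    n = cm.n
    out = []
    last = n if cm.circular else n - 1
    for b in range(last):
        b2 = (b + 1) % n
        pa, pb = cm.partner(b), cm.partner(b2)
        if pa is None or pb is None:
            continue
        same_section = pa[0] == pb[0] and pb[1] == pa[1] - 1
        if not same_section:
            out.append((b, b2))
    return out


def junction_slack(cm: ContactMap, design: Design, junction: tuple[int, int]) -> JunctionReport:
    """How far the junction can slide in each direction while both flanking
    staples' shifted bases stay complementary to the scaffold.

    ``slack_right``: max k such that scaffold bases b+1..b+k can transfer
    from the right section's pairing to the left staple's preceding bases;
    ``slack_left`` is symmetric. The search is capped at the shorter
    flanking section length minus one.
    """
    scaffold = design.scaffold
    n = cm.n
    b, b2 = junction
    pa, pb = cm.partner(b), cm.partner(b2)
    if pa is None or pb is None or (pa[0] == pb[0] and pb[1] == pa[1] - 1):
        raise ValueError(f"({b}, {b2}) is not a junction")

    sid_l, sb_l = pa  # left section: staple base at scaffold b is its 5'-most
    sid_r, sb_r = pb  # right section: staple base at scaffold b+1 is its 3'-most
    seq_l = design.staples[sid_l].sequence
    seq_r = design.staples[sid_r].sequence
    len_l = _section_extent(cm, b, -1)
    len_r = _section_extent(cm, b2, +1)
    cap = min(len_l, len_r) - 1

    def scaf(i: int) -> str:
        return scaffold.base(i % n if cm.circular else i)

    slack_right = 0
    for k in range(1, cap + 1):
        idx = sb_l - k  # staple base of the LEFT staple that would pair scaffold b+k
        pos = b + k
        if idx < 0 or not (cm.circular or pos < n):
            break
        if seq_l[idx].upper() != wc_partner(scaf(pos), scaffold.material):
            break
        slack_right = k

    slack_left = 0
    for k in range(1, cap + 1):
        idx = sb_r + k  # staple base of the RIGHT staple that would pair scaffold b+1-k
        pos = b2 - k if not cm.circular else (b2 - k) % n
        if idx >= len(seq_r) or not (cm.circular or pos >= 0):
            break
        if seq_r[idx].upper() != wc_partner(scaf(pos), scaffold.material):
            break
        slack_left = k

    return JunctionReport(junction, slack_left, slack_right, sid_l, sid_r)


@dataclass
class AmbigSummary:
    n_junctions: int
    n_immovable: int
    n_ambiguous: int
    all_staples_placed: bool
    i2_zero: bool  # all junctions immovable AND all staples placed

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _all_staples_placed(cm: ContactMap, design: Design) -> bool:
    """True when every hybridising staple base of the design is paired."""
    have: dict[int, set[int]] = {}
    for i in np.flatnonzero(cm.staple_id != UNPAIRED):
        have.setdefault(int(cm.staple_id[i]), set()).add(int(cm.staple_base[i]))
    for staple in design.staples:
        want = {
            j
            for seg in staple.segments
            if seg.kind is SegmentKind.HYBRIDISING
            for j in range(seg.start, seg.end)
        }
        if want - have.get(staple.id, set()):
            return False
    return True


def ambig_all(cm: ContactMap, design: Design) -> tuple[list[JunctionReport], AmbigSummary]:
    """Slack reports for every junction on the contact map plus a summary."""
    reports = [junction_slack(cm, design, j) for j in find_junctions(cm)]
    placed = _all_staples_placed(cm, design)
    n_ambig = sum(1 for r in reports if r.ambiguous)
    summary = AmbigSummary(
        n_junctions=len(reports),
        n_immovable=len(reports) - n_ambig,
        n_ambiguous=n_ambig,
        all_staples_placed=placed,
        i2_zero=(n_ambig == 0 and placed),
    )
    log.info("AMBIG: %d junctions, %d immovable, %d ambiguous (I2==0: %s)",
             summary.n_junctions, summary.n_immovable, summary.n_ambiguous, summary.i2_zero)
    return reports, summary


def write_junction_csv(reports: list[JunctionReport], path: str | Path,
                       comments: list[str] | None = None) -> None:
    lines = [f"# {c}" for c in (comments or [])]
    lines.append("scaffold_base_left,scaffold_base_right,slack_left,slack_right,"
                 "ambiguous,staple_left,staple_right")
    for r in reports:
        lines.append(
            f"{r.junction[0]},{r.junction[1]},{r.slack_left},{r.slack_right},"
            f"{int(r.ambiguous)},{r.staple_left},{r.staple_right}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
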