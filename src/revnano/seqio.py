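"""Sequence input/output and the staple/scaffold domain model.

Conventions used throughout the package:

* All sequences are written 5'->3'.
* Scaffold indexing is 0-based from the scaffold 5' end; on circular
  scaffolds index arithmetic is modulo N, linear scaffolds never wrap.
* Staple markup: uppercase letters are hybridising, lowercase letters mark
  non-hybridising subsequences (end dangles, interior loop-outs) which are
  never routed on the scaffold.
* ``material`` names the scaffold chemistry. ``RNA`` means an RNA scaffold
  folded by DNA staples (hybrid origami); staple alphabets are always
  {A,C,G,T}.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

from .errors import InputError as InputErr

log = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")

_DNA_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_RNA_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
# Staple (DNA) letter that pairs a given scaffold letter, per material.
_PARTNER = {
    "DNA": _DNA_COMPLEMENT,
    "RNA": {"A": "T", "U": "A", "C": "G", "G": "C"},
}


class Material(str, Enum):
    DNA = "DNA"
    RNA = "RNA"


class SegmentKind(str, Enum):
    HYBRIDISING = "hybridising"
    NONHYBRIDISING = "nonhybridising"


def wc_complement(base: str, material: Material | str = Material.DNA) -> str:
    """Watson-Crick complement of ``base`` within one material's alphabet."""
    material = Material(material)
    table = _DNA_COMPLEMENT if material is Material.DNA else _RNA_COMPLEMENT
    try:
        return table[base.upper()]
    except KeyError:
        raise ValueError(f"unknown base {base!r} for material {material.value}") from None


def wc_partner(scaffold_base: str, material: Material | str = Material.DNA) -> str:
    """The staple (DNA) letter that hybridises a given scaffold letter.

    For a DNA scaffold this is the plain complement; for an RNA scaffold the
    staples are DNA, so scaffold U pairs staple A and scaffold A pairs
    staple T.
    """
    material = Material(material)
    try:
        return _PARTNER[material.value][scaffold_base.upper()]
    except KeyError:
        raise ValueError(
            f"unknown scaffold base {scaffold_base!r} for material {material.value}"
        ) from None


def pairs(scaffold_base: str, staple_base: str, material: Material | str = Material.DNA) -> bool:
    """True when a staple base can hybridise a scaffold base."""
    return staple_base.upper() == wc_partner(scaffold_base, material)


def wc_scaffold_letter(staple_base: str, material: Material | str = Material.DNA) -> str:
    """The scaffold letter that hybridises a given staple (DNA) letter:
    the inverse of :func:`wc_partner` within one material."""
    material = Material(material)
    table = _PARTNER[material.value]
    inverse = {v: k for k, v in table.items()}
    try:
        return inverse[staple_base.upper()]
    except KeyError:
        raise ValueError(
            f"unknown staple base {staple_base!r} for material {material.value}"
        ) from None


@dataclass(frozen=True)
class Segment:
    kind: SegmentKind
    start: int  # staple base index of the segment's first base
    length: int

    @property
    def end(self) -> int:  # exclusive
        return self.start + self.length


@dataclass(frozen=True)
class Scaffold:
    """The single long strand of the origami."""

    sequence: str
    circular: bool = True
    material: Material = Material.DNA

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise InputErr("empty scaffold sequence")
        alphabet = DNA_ALPHABET if self.material is Material.DNA else RNA_ALPHABET
        bad = set(seq) - alphabet
        if bad:
            raise InputErr(
                f"illegal scaffold character(s) {sorted(bad)} for material "
                f"{self.material.value}"
            )

    @property
    def n(self) -> int:
        return len(self.sequence)

    def base(self, index: int) -> str:
        """Scaffold letter at ``index`` (modulo N when circular)."""
        if self.circular:
            return self.sequence[index % self.n]
        if not 0 <= index < self.n:
            raise IndexError(f"scaffold index {index} out of range on linear scaffold")
        return self.sequence[index]


@dataclass(frozen=True)
class Staple:
    """A staple oligo with case markup split into segments.

    ``sequence`` keeps the raw case markup; ``segments`` is the run-length
    partition of the markup into hybridising (uppercase) and non-hybridising
    (lowercase) parts. A staple with no markup has one hybridising segment
    covering its whole sequence.
    """

    id: int
    sequence: str
    segments: tuple[Segment, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputErr(f"staple {self.id}: empty sequence")
        bad = set(self.sequence.upper()) - DNA_ALPHABET
        if bad:
            raise InputErr(
                f"staple {self.id}: illegal character(s) {sorted(bad)} "
                "(staples are DNA, alphabet ACGT)"
            )
        if not self.segments:
            object.__setattr__(self, "segments", segments_from_case(self.sequence))
        total = sum(s.length for s in self.segments)
        if total != len(self.sequence) or any(s.length <= 0 for s in self.segments):
            raise InputErr(f"staple {self.id}: segments do not partition the sequence")

    @property
    def hybridising_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind is SegmentKind.HYBRIDISING)


@dataclass(frozen=True)
class VirtualStaple:
    """One hybridising segment of a parent staple, routed independently."""

    parent_id: int
    parent_segment_index: int  # index among the parent's hybridising segments
    sequence: str  # uppercase hybridising subsequence
    offset: int  # staple base index of the segment start within the parent


@dataclass(frozen=True)
class Design:
    scaffold: Scaffold
    staples: tuple[Staple, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "staples", tuple(self.staples))
        ids = [s.id for s in self.staples]
        if ids != list(range(len(ids))):
            raise InputErr("staple ids must be unique and dense from 0 in input order")
        too_long = [s.id for s in self.staples if len(s.sequence) > self.scaffold.n]
        if too_long:
            raise InputErr(f"staple(s) {too_long} longer than the scaffold")


def segments_from_case(sequence: str) -> tuple[Segment, ...]:
    """Run-length encode letter case into hybridising/non-hybridising segments."""
    segs: list[Segment] = []
    start = 0
    for i in range(1, len(sequence) + 1):
        if i == len(sequence) or sequence[i].isupper() != sequence[start].isupper():
            kind = SegmentKind.HYBRIDISING if sequence[start].isupper() else SegmentKind.NONHYBRIDISING
            segs.append(Segment(kind, start, i - start))
            start = i
    return tuple(segs)


def _read_scaffold_text(text: str) -> str:
    lines = [ln.strip() for ln in text.splitlines()]
    if lines and lines[0].startswith(">"):
        # FASTA: first record only
        seq_lines: list[str] = []
        in_first = False
        for ln in lines:
            if ln.startswith(">"):
                if in_first:
                    break
                in_first = True
                continue
            if in_first:
                seq_lines.append(ln)
        return "".join(seq_lines)
    return "".join(ln for ln in lines if ln)


def _read_staple_lines(text: str) -> list[str]:
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if "," in first:
        reader = csv.DictReader(io.StringIO(text))
        if reader.fieldnames and "sequence" in [f.strip().lower() for f in reader.fieldnames]:
            key = next(f for f in reader.fieldnames if f.strip().lower() == "sequence")
            return [row[key].strip() for row in reader if row.get(key, "").strip()]
        # headerless id,sequence CSV: take the last column
        rows = list(csv.reader(io.StringIO(text)))
        return [r[-1].strip() for r in rows if r and r[-1].strip()]
    out = []
    blanks = 0
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln:
            blanks += 1
            continue
        out.append(ln)
    if blanks > 1:
        log.warning("skipped %d blank staple lines", blanks)
    return out


def read_design(
    scaffold_path: str | Path,
    staples_path: str | Path,
    circular: bool = True,
    material: Material | str = Material.DNA,
) -> Design:
    """Read a design from a scaffold file (FASTA or bare sequence) and a
    staple list (one sequence per line, or CSV with a ``sequence`` column).

    Lowercase staple letters mark non-hybridising regions.
    """
    material = Material(material)
    scaffold_seq = _read_scaffold_text(Path(scaffold_path).read_text())
    staple_seqs = _read_staple_lines(Path(staples_path).read_text())
    return make_design(scaffold_seq, staple_seqs, circular=circular, material=material)


def make_design(
    scaffold_seq: str,
    staple_seqs: Sequence[str],
    circular: bool = True,
    material: Material | str = Material.DNA,
) -> Design:
    """Build a validated :class:`Design` from in-memory sequences."""
    scaffold = Scaffold(scaffold_seq, circular=circular, material=Material(material))
    staples = tuple(Staple(i, seq) for i, seq in enumerate(staple_seqs))
    return Design(scaffold, staples)


def write_design(design: Design, scaffold_path: str | Path, staples_path: str | Path) -> None:
    """Echo a design back to disk: scaffold as FASTA, staples one per line.

    Case markup on staples is preserved byte-identically.
    """
    Path(scaffold_path).write_text(
        f">scaffold circular={design.scaffold.circular} "
        f"material={design.scaffold.material.value}\n{design.scaffold.sequence}\n"
    )
    Path(staples_path).write_text("".join(s.sequence + "\n" for s in design.staples))


def split_virtual(design: Design) -> list[VirtualStaple]:
    """One virtual staple per hybridising segment, ordered by
    (parent id, segment index). Deterministic."""
    out: list[VirtualStaple] = []
    for staple in design.staples:
        for k, seg in enumerate(staple.hybridising_segments):
            out.append(
                VirtualStaple(
                    parent_id=staple.id,
                    parent_segment_index=k,
                    sequence=staple.sequence[seg.start : seg.end].upper(),
                    offset=seg.start,
                )
            )
    return out


@dataclass(frozen=True)
class Section:
    """One staple section, candidate or placed.

    Staple base (``staple_offset + j``) pairs scaffold base (``start - j``),
    modulo N on circular scaffolds: sections run toward scaffold 5' because
    staple and scaffold are antiparallel.
    """

    start: int
    mu: int
    staple_offset: int

    def scaffold_bases(self, n: int, circular: bool) -> tuple[int, ...]:
        if circular:
            return tuple((self.start - j) % n for j in range(self.mu))
        return tuple(self.start - j for j in range(self.mu))


@dataclass
class ParentPlacement:
    """Placement of a physical staple after virtual-staple reassembly."""

    staple_id: int
    sections: list[Section]  # staple offsets in PARENT coordinates
    partial: bool  # some hybridising segment was left unrouted


def merge_virtual(
    virtuals: Sequence[VirtualStaple],
    routes: dict[int, Sequence[Section]],
    design: Design,
) -> list[ParentPlacement]:
    """Reassemble routed virtual staples into physical staples.

    ``routes`` maps a virtual-staple index (position in ``virtuals``) to its
    placed sections in virtual-staple coordinates; the virtual offset is
    applied so parent placements use parent staple base indices. A parent
    with any unplaced virtual staple is kept (placed segments only) and
    flagged as partially placed.
    """
    by_parent: dict[int, list[tuple[int, VirtualStaple, Sequence[Section]]]] = {}
    expected: dict[int, int] = {s.id: len(s.hybridising_segments) for s in design.staples}
    for vi, vs in enumerate(virtuals):
        if vi in routes:
            by_parent.setdefault(vs.parent_id, []).append((vs.parent_segment_index, vs, routes[vi]))

    placements: list[ParentPlacement] = []
    for pid in sorted(by_parent):
        entries = sorted(by_parent[pid], key=lambda t: t[0])
        sections = [
            Section(sec.start, sec.mu, vs.offset + sec.staple_offset)
            for _, vs, secs in entries
            for sec in secs
        ]
        partial = len(entries) < expected[pid]
        if partial:
            log.warning("staple %d partially placed: %d/%d segments routed",
                        pid, len(entries), expected[pid])
        placements.append(ParentPlacement(pid, sections, partial))
    return placements
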