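"""Forward design of synthetic raster origamis with known ground truth.

The generator lays a scaffold along a serpentine raster path over a grid of
helix rows, derives Watson-Crick complementary staples from a chosen staple
pattern, and records the exact ground-truth contact map. Scaffold sequences
can be seeded-random, repeat-deficient De Bruijn sequences (every k-mer at
most once, so staple sections of >= k bases have unique binding sites), or
user-supplied. An input-noise model adds per-base substitutions and surplus
random "contaminant" staples, emulating sequence lists imperfectly copied
from a publication.

The generated designs are deliberately small (grids up to a few thousand
bases) so that the full pipeline runs in seconds; they emulate raster
origami connectivity (full staple coverage, inter-row crossovers), not M13
biology or wireframe multi-arm junctions.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from enum import Enum

from .contactmap import ContactMap
from .errors import InputError
from .seqio import Design, Material, Scaffold, Staple, wc_partner, wc_scaffold_letter

log = logging.getLogger(__name__)

_BASES = "ACGT"


class StaplePattern(str, Enum):
    TWO_SECTION_32NT = "two_section_32nt"
    THREE_SECTION = "three_section"
    CUSTOM = "custom"


class ScaffoldKind(str, Enum):
    RANDOM = "random"
    DEBRUIJN = "debruijn"
    PROVIDED = "provided"


@dataclass
class RasterSpec:
    """Specification of a synthetic raster origami.

    ``helix_rows`` x ``columns`` grid; the scaffold runs a serpentine path
    (row 0 left-to-right, row 1 right-to-left, ...), so scaffold length is
    rows * columns.
    """

    helix_rows: int = 4
    columns: int = 64
    staple_pattern: StaplePattern = StaplePattern.TWO_SECTION_32NT
    section_lengths: tuple[int, ...] = ()
    scaffold_kind: ScaffoldKind = ScaffoldKind.DEBRUIJN
    debruijn_order: int = 7
    seed: int = 0
    circular: bool = True
    material: Material = Material.DNA
    provided_scaffold: str = ""
    # Substitute the scaffold letter on each side of every designed staple
    # crossover when it matches the letter on the other side. This removes
    # sequence-matching overshoot and makes every junction immovable, i.e.
    # the design encodes its contact map without ambiguity -- the property a
    # careful origami designer can engineer for. Disable to emulate raw
    # designs where overshoot defects can occur.
    engineer_junctions: bool = True

    def __post_init__(self) -> None:
        self.staple_pattern = StaplePattern(self.staple_pattern)
        self.scaffold_kind = ScaffoldKind(self.scaffold_kind)
        self.material = Material(self.material)
        if self.helix_rows < 1 or self.columns < 1:
            raise InputError("grid must have at least one row and one column")

    @property
    def n(self) -> int:
        return self.helix_rows * self.columns


def debruijn_sequence(k: int, length: int, seed: int = 0) -> str:
    """Prefix of a De Bruijn cycle over {A,C,G,T} of order ``k``: every
    k-mer occurs at most once in the returned sequence.

    ``seed`` permutes the alphabet and rotates the cycle, giving distinct
    repeat-deficient sequences per seed. ``length`` may not exceed
    4**k + k - 1 (the linearised cycle).
    """
    if k < 1:
        raise ValueError("order k must be >= 1")
    limit = 4**k + k - 1
    if length > limit:
        raise ValueError(f"length {length} too large for order {k} (max {limit})")
    rng = random.Random(seed)
    alphabet = list(_BASES)
    rng.shuffle(alphabet)

    # standard Lyndon-word concatenation ("FKM" algorithm) for the cycle
    seq: list[int] = []
    a = [0] * (k + 1)

    def db(t: int, p: int) -> None:
        if t > k:
            if k % p == 0:
                seq.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, 4):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    cycle = "".join(alphabet[i] for i in seq)  # length 4**k
    rot = rng.randrange(len(cycle))
    doubled = cycle[rot:] + cycle + cycle[: k - 1]
    return doubled[:length]


def random_sequence(length: int, seed: int = 0, alphabet: str = _BASES) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice(alphabet) for _ in range(length))


def _scaffold_index(row: int, col: int, columns: int) -> int:
    """Scaffold base index of grid cell (row, col) on the serpentine path."""
    return row * columns + (col if row % 2 == 0 else columns - 1 - col)


def _column_run(row: int, c0: int, width: int, columns: int) -> tuple[int, int]:
    """Scaffold interval (lo, hi) covered by columns [c0, c0+width) on a row."""
    a = _scaffold_index(row, c0, columns)
    b = _scaffold_index(row, c0 + width - 1, columns)
    return (a, b) if a <= b else (b, a)


def _staple_from_sections(
    staple_id: int, scaffold: Scaffold, intervals: list[tuple[int, int]]
) -> tuple[Staple, list[tuple[int, int, int]]]:
    """Build a staple pairing the given scaffold intervals antiparallel.

    Each interval (lo, hi) is traversed hi -> lo (staple 5'->3' against the
    ascending scaffold). Returns the staple and ground-truth triples
    (scaffold_base, staple_id, staple_base).
    """
    letters: list[str] = []
    truth: list[tuple[int, int, int]] = []
    sb = 0
    for lo, hi in intervals:
        for p in range(hi, lo - 1, -1):
            letters.append(wc_partner(scaffold.sequence[p], scaffold.material))
            truth.append((p, staple_id, sb))
            sb += 1
    return Staple(staple_id, "".join(letters)), truth


def _engineer_scaffold(
    seq: str,
    staple_sections: list[list[tuple[int, int]]],
    n: int,
    circular: bool,
    seed: int,
    material: Material = Material.DNA,
) -> str:
    """Mutate scaffold letters so that no designed staple crossover can
    overshoot or slide.

    For each staple's consecutive section pair, intervals (lo1, hi1) then
    (lo2, hi2) in staple 5'->3' order, the complementary run of the first
    section extends one base past lo1 exactly when scaffold[lo1-1] equals
    scaffold[hi2] (the base designed to pair the next staple letter), and the
    junction slides the other way exactly when scaffold[hi2+1] equals
    scaffold[lo1]. Enforcing the two inequalities at every crossover removes
    all overshoot and, because nick sliding between neighbouring staples
    reduces to the same letter comparisons, makes every junction immovable.

    The inequalities form a 4-colouring problem over scaffold positions;
    positions touch few constraints in these patterns, so a greedy seeded
    repair converges immediately.
    """
    chars = list(seq)
    pairs_list: list[tuple[int, int]] = []
    for intervals in staple_sections:
        for (lo1, _hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
            for p, q in ((lo1 - 1, hi2), (hi2 + 1, lo1)):
                if circular:
                    p, q = p % n, q % n
                elif not (0 <= p < n and 0 <= q < n):
                    continue
                if p != q:
                    pairs_list.append((p, q))
    partners: dict[int, set[int]] = {}
    for p, q in pairs_list:
        partners.setdefault(p, set()).add(q)
        partners.setdefault(q, set()).add(p)
    rng = random.Random(seed)
    alphabet = "ACGU" if Material(material) is Material.RNA else _BASES
    for _ in range(10):
        violated = [(p, q) for p, q in pairs_list if chars[p] == chars[q]]
        if not violated:
            break
        for p, q in violated:
            if chars[p] != chars[q]:
                continue  # already repaired via an earlier pair this pass
            options = [b for b in alphabet if b not in {chars[x] for x in partners[p]}]
            if not options:
                log.warning("junction engineering: no admissible letter at base %d", p)
                continue
            chars[p] = rng.choice(options)
    else:
        left = sum(1 for p, q in pairs_list if chars[p] == chars[q])
        if left:
            log.warning("junction engineering: %d constraints unsatisfied", left)
    return "".join(chars)


def forward_design(spec: RasterSpec) -> tuple[Design, ContactMap]:
    """Generate a raster design and its ground-truth contact map.

    Staple patterns:

    * ``two_section_32nt`` -- row pairs; each staple pairs 16 bases on the
      upper row and the same 16 columns on the lower row (one crossover),
      tiling every scaffold base (rows even, columns divisible by 16).
    * ``three_section`` -- row triples; each staple pairs the same column
      block (default width 8) on three adjacent rows (two crossovers);
      rows divisible by 3, columns divisible by the block width.
    * ``custom`` -- row pairs; ``section_lengths`` are laid out on
      alternating rows over advancing column blocks (coverage may be
      partial).
    """
    n = spec.n
    kind = spec.scaffold_kind
    if kind is ScaffoldKind.RANDOM:
        seq = random_sequence(n, spec.seed)
    elif kind is ScaffoldKind.DEBRUIJN:
        seq = debruijn_sequence(spec.debruijn_order, n, spec.seed)
    else:
        seq = spec.provided_scaffold.strip().upper()
        if len(seq) < n:
            raise InputError(
                f"provided scaffold ({len(seq)} nt) shorter than the grid ({n} nt)"
            )
        if len(seq) > n:
            log.info("provided scaffold longer than the grid; using the first %d nt", n)
            seq = seq[:n]
    if spec.material is Material.RNA:
        seq = seq.upper().replace("T", "U")

    cols = spec.columns
    staple_sections: list[list[tuple[int, int]]] = []
    pattern = spec.staple_pattern
    if pattern is StaplePattern.TWO_SECTION_32NT:
        w = 16
        if spec.helix_rows % 2 or cols % w:
            raise InputError("two_section_32nt needs even rows and columns % 16 == 0")
        for r in range(0, spec.helix_rows, 2):
            for c0 in range(0, cols, w):
                staple_sections.append(
                    [_column_run(r, c0, w, cols), _column_run(r + 1, c0, w, cols)]
                )
    elif pattern is StaplePattern.THREE_SECTION:
        w = spec.section_lengths[0] if spec.section_lengths else 8
        if spec.helix_rows % 3 or cols % w:
            raise InputError(f"three_section needs rows % 3 == 0 and columns % {w} == 0")
        for r in range(0, spec.helix_rows, 3):
            for c0 in range(0, cols, w):
                staple_sections.append(
                    [_column_run(r + dr, c0, w, cols) for dr in range(3)]
                )
    else:
        if not spec.section_lengths:
            raise InputError("custom pattern requires section_lengths")
        if spec.helix_rows % 2:
            raise InputError("custom pattern needs an even number of rows")
        per_staple = list(spec.section_lengths)
        for r in range(0, spec.helix_rows, 2):
            c = 0
            while c + sum(per_staple) <= cols:
                secs = []
                cc = c
                for i, ln in enumerate(per_staple):
                    secs.append(_column_run(r + (i % 2), cc, ln, cols))
                    cc += ln
                staple_sections.append(secs)
                c = cc

    if spec.engineer_junctions:
        seq = _engineer_scaffold(seq, staple_sections, n, spec.circular, spec.seed,
                                 spec.material)
    scaffold = Scaffold(seq, circular=spec.circular, material=spec.material)

    staples: list[Staple] = []
    cm = ContactMap.empty(n, spec.circular, spec.material)
    for sid, intervals in enumerate(staple_sections):
        staple, truth = _staple_from_sections(sid, scaffold, intervals)
        staples.append(staple)
        for sb_pos, _, sb in truth:
            if cm.staple_id[sb_pos] != -1:
                raise InputError("inconsistent spec: staple pattern double-covers a base")
            cm.set_pair(sb_pos, sid, sb)

    design = Design(scaffold, tuple(staples))
    return design, cm


def insert_loopout(design: Design, cm: ContactMap, staple_id: int,
                   loop: str = "tttt", after_section: int = 1) -> tuple[Design, ContactMap]:
    """Insert a lowercase non-hybridising loop-out into one staple, between
    hybridising sections, shifting the ground-truth staple base indices."""
    staple = design.staples[staple_id]
    if loop.upper().strip("ACGT"):
        raise InputError("loop must be a DNA sequence")
    # boundary = staple base index where section `after_section` ends
    bounds = _section_boundaries(cm, staple_id)
    if after_section >= len(bounds):
        raise InputError(f"staple {staple_id} has only {len(bounds)} sections")
    cut = bounds[after_section - 1] if after_section >= 1 else 0
    new_seq = staple.sequence[:cut] + loop.lower() + staple.sequence[cut:]
    staples = list(design.staples)
    staples[staple_id] = Staple(staple_id, new_seq)
    new_cm = ContactMap.empty(cm.n, cm.circular, cm.material)
    for i in range(cm.n):
        p = cm.partner(i)
        if p is None:
            continue
        sid, sb = p
        if sid == staple_id and sb >= cut:
            sb += len(loop)
        new_cm.set_pair(i, sid, sb)
    return Design(design.scaffold, tuple(staples)), new_cm


def _section_boundaries(cm: ContactMap, staple_id: int) -> list[int]:
    """Exclusive end staple-base index of each section of a staple, in
    staple 5'->3' order, derived from the ground truth."""
    positions = sorted(
        (int(cm.staple_base[i]), int(i))
        for i in range(cm.n)
        if cm.staple_id[i] == staple_id
    )
    ends: list[int] = []
    for k, (sb, pos) in enumerate(positions):
        nxt = positions[k + 1] if k + 1 < len(positions) else None
        contiguous = (
            nxt is not None
            and nxt[0] == sb + 1
            and (nxt[1] - pos) % cm.n == cm.n - 1  # scaffold descends with staple
        )
        if not contiguous:
            ends.append(sb + 1)
    return ends


def implant_decoy(
    design: Design,
    cm: ContactMap,
    staple_id: int = 0,
    overshoot: int = 1,
    window_start: int | None = None,
) -> tuple[Design, int, int]:
    """Write a lure binding site for one staple into an unpaired scaffold
    window: the complement pattern of the staple's first section plus
    ``overshoot`` extra complementary bases, so the lure run is strictly
    longer than the designed one.

    Only unpaired scaffold bases are rewritten and no staple sequence
    changes, so ``cm`` remains the ground truth of the returned design. A
    greedy longest-match router will commit the staple to the lure; a solver
    that keeps competing routes and weighs their scaffold path lengths will
    not. Returns (new design, lure window start, lure length).
    """
    scaffold = design.scaffold
    n = scaffold.n
    staple = design.staples[staple_id]
    if overshoot < 1:
        raise InputError("overshoot must be >= 1")
    bounds = _section_boundaries(cm, staple_id)
    if len(bounds) < 2:
        raise InputError(f"staple {staple_id} needs >= 2 sections to host a lure")
    m1 = bounds[0]
    lure_len = m1 + overshoot
    if lure_len >= len(staple.sequence):
        raise InputError("overshoot exceeds the staple's remaining bases")

    # unpaired runs (non-wrapping), as (start, length)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if cm.staple_id[i] == -1:
            j = i
            while j < n and cm.staple_id[j] == -1:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    margin = 2  # keep clear of letters engineered for the flanking junctions
    need = lure_len + 2 * margin
    if window_start is not None:
        host = next((r for r in runs if r[0] <= window_start and
                     window_start + lure_len + margin <= r[0] + r[1]), None)
        if host is None or window_start < host[0] + margin:
            raise InputError(f"window {window_start} does not fit an unpaired run")
        y = window_start
    else:
        runs = [r for r in runs if r[1] >= need]
        if not runs:
            raise InputError(f"no unpaired scaffold run of >= {need} bases for the lure")
        start, length = max(runs, key=lambda r: r[1])
        y = start + (length - lure_len) // 2

    chars = list(scaffold.sequence)
    mat = scaffold.material
    for j in range(lure_len):
        pos = y + lure_len - 1 - j  # staple base j pairs here, antiparallel
        if cm.staple_id[pos] != -1:
            raise InputError("lure window overlaps a paired base")
        chars[pos] = wc_scaffold_letter(staple.sequence[j], mat)
    # guard letters: cap the lure run at exactly lure_len on both flanks
    alphabet = "ACGU" if mat is Material.RNA else _BASES
    below = y - 1 if scaffold.circular else max(y - 1, 0)
    if y - 1 >= 0 or scaffold.circular:
        p = below % n
        if wc_partner(chars[p], mat) == staple.sequence[lure_len].upper():
            chars[p] = next(b for b in alphabet
                            if wc_partner(b, mat) != staple.sequence[lure_len].upper())
    if y + lure_len < n or scaffold.circular:
        p = (y + lure_len) % n
        if wc_partner(chars[p], mat) == staple.sequence[0].upper():
            chars[p] = next(b for b in alphabet
                            if wc_partner(b, mat) != staple.sequence[0].upper())
    new_scaffold = Scaffold("".join(chars), circular=scaffold.circular, material=mat)
    log.info("implanted %d nt lure for staple %d at scaffold [%d, %d]",
             lure_len, staple_id, y, y + lure_len - 1)
    return Design(new_scaffold, design.staples), y, lure_len


class NoisePosition(str, Enum):
    END = "end"
    SHUFFLED = "shuffled"


def add_noise(
    design: Design,
    sub_rate: float = 0.0,
    n_contaminants: int = 0,
    contaminant_len: int = 32,
    position: NoisePosition | str = NoisePosition.END,
    seed: int = 0,
) -> Design:
    """Input-noise model: per-base substitutions on staples at ``sub_rate``
    plus ``n_contaminants`` surplus random DNA staples appended at the list
    end or shuffled into it. Seeded and deterministic."""
    if not 0 <= sub_rate <= 1:
        raise InputError("sub_rate must be in [0, 1]")
    position = NoisePosition(position)
    rng = random.Random(seed)
    seqs: list[str] = []
    for staple in design.staples:
        chars = list(staple.sequence)
        for i, ch in enumerate(chars):
            if sub_rate and rng.random() < sub_rate:
                new = rng.choice([b for b in _BASES if b != ch.upper()])
                chars[i] = new if ch.isupper() else new.lower()
        seqs.append("".join(chars))
    contaminants = [
        "".join(rng.choice(_BASES) for _ in range(contaminant_len))
        for _ in range(n_contaminants)
    ]
    if position is NoisePosition.END:
        seqs = seqs + contaminants
    else:
        for c in contaminants:
            seqs.insert(rng.randrange(len(seqs) + 1), c)
    staples = tuple(Staple(i, s) for i, s in enumerate(seqs))
    return Design(design.scaffold, staples)
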