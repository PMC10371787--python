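# Methods

## Model

An origami design is modelled as a circular (or linear) **scaffold** of `n`
bases and a list of **staples**. Hybridisation is strictly antiparallel
Watson–Crick: if staple base `j` pairs scaffold base `b`, staple base `j+1`
pairs scaffold base `b−1` (mod `n`). A maximal complementary run of length μ
starting at scaffold base `start` (pairing staple bases `off … off+μ−1` with
scaffold bases `start … start−μ+1`) is a **section**. The reconstruction
target is the **contact map**: arrays `staple_id[b]`, `staple_base[b]` with
`−1` for unpaired scaffold bases, under the constraint that every
(staple, staple-base) pair claims at most one scaffold base.

Materials: DNA scaffolds pair A·T and C·G with DNA staples; RNA scaffolds
(alphabet ACGU) pair with **DNA** staples via U·A, A·T, C·G, G·C. Staple
letters are always ACGT; lowercase staple letters mark non-hybridising
segments (5′/3′ dangles, interior loop-outs) and are excluded from routing
but carried through to the domain graph.

## Solver stages

**Stage 0 — staple routing trees.** For each contiguous hybridising segment
of a staple (a *virtual staple*), a depth-first tree enumerates all tilings
of the staple sequence by **maximal** matches: at each tree level, all
maximal runs of the remaining staple suffix against the scaffold are found;
runs shorter than `mu_min` are discarded, runs overlapping the route's own
earlier sections are rejected, and among siblings only runs with
μ ≥ (best sibling μ) − `sigma` are kept. Only routes consuming the entire
staple survive. A node cap (10⁶) aborts pathological inputs. Because
matches are *maximal*, a route can overshoot the designed section boundary —
this is a property of the inputs, not a bug, and is handled by Stages 2–3.
Correctness is checked against `enumerate_tilings`, an independent
brute-force oracle that knows nothing of the tree construction.

**Stage 1 — footprint propagation.** Single-route staples are committed.
Each commitment updates per-base claim sets; a candidate route is deleted
when any of its sections has more than a `beta` fraction of its bases
claimed by *other* staples. Staples reduced to one route are committed in
turn (Gauss–Seidel), to a fixed point. Footprints only grow, enforced by a
monotonicity assertion. If the placed fraction is below the 0.65 threshold
the solver raises `Stage2Error` (exit code 2); exactly 0.65 proceeds.

**Stage 2 — clearest shortest path.** The placed structure defines a base
graph `B` (scaffold backbone + placed staple pairings). Each surviving route
is scored by the total shortest-path distance its sections span in `B`; the
staple with the largest margin (second-best cost − best cost) is placed
next, ties broken toward the highest staple index, and distances are
re-propagated (ripple) after each placement. Physically, staples connect
proximal helices, so the compact route is the designed one — this is what
defeats sequence-level decoys that fool a greedy longest-match baseline.

**Stage 3 — overlap trimming.** Overshoot can leave a scaffold base claimed
by two staples. The claim ending at a section 3′ terminus is trimmed first
(5′ fallback; ties broken toward the higher parent id). Three claimants, an
overlap touching no terminus, or a trim that would erase a section raise
`OverlapError` (exit code 4).

**Stage 4 — merge.** Virtual staples are merged back into their parents;
`SP%` is the fraction of parents whose sections were placed consistently.

Defaults (`SolverParams`): `mu_min=6`, `sigma=4`, `beta=0.3`,
deterministic mode, seed 0. Presets: `raster` = (6, 4, 0.3),
`wireframe` = (5, 2, 0.25).

## Ambiguity analysis

For each junction (adjacent scaffold bases paired to different staple
sections), the **slack** in each direction is the largest `k` such that `k`
bases could be transferred across the junction with all transferred
positions still Watson–Crick consistent. Because pairing is positionwise,
this reduces to letter comparisons; slack 0 in both directions means the
junction is immovable. A design is reported `i2_zero` when all staples
placed and every junction is immovable — the condition under which the
contact map is the unique sequence-consistent interpretation. The test
suite and acceptance script validate the slack routine against an
independent brute-force base-transfer oracle.

## Synthetic generator

`RasterSpec` builds a serpentine raster design on a `helix_rows × columns`
grid: the scaffold follows a boustrophedon path, staples tile it with
two-section 32-nt, three-section, or custom patterns whose sections sit on
adjacent rows (one crossover per section boundary). Scaffold sequences are
seeded-random, user-provided, or order-`k` **De Bruijn** prefixes (every
k-mer at most once, via Lyndon-word concatenation with a seeded alphabet
shuffle and rotation), so staple sections of ≥ k bases have unique binding
sites.

**Junction engineering.** Even a repeat-deficient scaffold permits two local
defects: a maximal run can overshoot a crossover by one base, and a junction
can slide. For consecutive sections `(lo1,hi1)`, `(lo2,hi2)` of one staple,
both defects vanish exactly when `seq[lo1−1] ≠ seq[hi2]` and
`seq[hi2+1] ≠ seq[lo1]` (indices mod `n`). Nick sliding between
neighbouring staples reduces algebraically to the same two inequalities, so
enforcing them at every crossover makes *every* junction immovable. The
constraints form a sparse 4-colouring problem solved by seeded greedy
repair (converges in one pass on these patterns). With
`engineer_junctions=False` the raw scaffold is used and overshoot defects
occur at realistic rates — this mode feeds the ambiguity-oracle tests.

**Decoy implant** (`implant_decoy`): the complement of staple 0's first
section plus one overshoot base is written into an unpaired scaffold
window, with guard letters on both flanks capping the spurious run at
exactly that length. The greedy baseline commits the longer spurious match
(hamming 34 = 2 × 17 misassigned bases per fixture); the solver keeps both
candidate routes and Stage 2's path-length criterion selects the designed
one (hamming 0).

**Noise model** (`add_noise`): i.i.d. per-base substitutions to a different
letter at rate `sub_rate`, plus surplus random contaminant staples appended
or shuffled in — emulating sequence lists imperfectly transcribed from a
publication. The generator emulates raster-origami *connectivity* (full
coverage, inter-row crossovers, loop-outs, dangles), **not** M13 sequence
biology, staple melting thermodynamics, or wireframe multi-arm junction
geometry.

## Layout

The contact map and design convert losslessly to a typed multigraph of
domains (`ds_scaffold`, `ss_scaffold`, `scaffold_nick`, `staple_crossover`,
`staple_loopout`, `staple_dangle`); the inverse conversion is tested as an
exact round trip. For drawing, parallel edges collapse to their minimum
target length and each connected component is embedded with Kamada–Kawai
from a circular initialisation ordered by scaffold position (edge weight =
target length in bases; positions rescaled afterwards to physical scale,
since the library normalises its output). A short force refinement
(springs toward target lengths, weak repulsion between close non-adjacent
nodes) is accepted only if it reduces the RMS relative edge-length error.
Reported **stress** is scale-optimal: with optimal scale
`s* = Σ(e/d) / Σ(e/d)²` over edges (target `e`, drawn distance `d`), stress
is the mean of `((s*·e − d)/d)²`. The HTML export is a single
self-contained file (inline SVG + vanilla JavaScript, no external assets)
with staple-colouring, scaffold-domain, and junction-ambiguity views.

## Limitations

- Staples must be DNA (ACGT); pure-RNA staple sets are not supported.
- Stage 3 resolves only two-claimant overlaps that touch a section
  terminus; denser conflicts abort with exit code 4 rather than search.
- The acceptance battery runs entirely on synthetic fixtures, including a
  1024-nt, 32-staple raster standing in for a published design; no external
  downloads are performed, so agreement with any specific published origami
  is not asserted.
- Junction engineering mutates a De Bruijn scaffold, so k-mer uniqueness is
  no longer strictly guaranteed post-repair; the round-trip tests hold
  because the engineered inequalities, not uniqueness alone, pin the map.
- Layout quality is a heuristic 2-D/3-D embedding of graph distances, not a
  physical model of helix packing or electrostatics.
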