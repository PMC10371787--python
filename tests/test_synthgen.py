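"""Synthetic design generator: De Bruijn scaffolds, ground truth, noise."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revnano.contactmap import UNPAIRED
from revnano.errors import InputError
from revnano.seqio import pairs, wc_partner
from revnano.synthgen import (
    NoisePosition,
    RasterSpec,
    add_noise,
    debruijn_sequence,
    forward_design,
    implant_decoy,
    insert_loopout,
    random_sequence,
)


class TestDeBruijn:
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_every_kmer_appears_at_most_once_at_full_length(self, k):
        seq = debruijn_sequence(k, 4**k + k - 1)
        kmers = [seq[i:i + k] for i in range(len(seq) - k + 1)]
        assert len(kmers) == len(set(kmers)) == 4**k

    def test_order7_long_prefix_has_unique_7mers(self):
        seq = debruijn_sequence(7, 7000, seed=11)
        kmers = {seq[i:i + 7] for i in range(len(seq) - 6)}
        assert len(kmers) == 7000 - 6

    def test_seed_changes_the_sequence(self):
        assert debruijn_sequence(4, 200, seed=0) != debruijn_sequence(4, 200, seed=1)

    def test_seeded_repeatability(self):
        assert debruijn_sequence(4, 200, seed=5) == debruijn_sequence(4, 200, seed=5)

    def test_length_cap_enforced(self):
        with pytest.raises(ValueError):
            debruijn_sequence(2, 4**2 + 2)

    def test_alphabet(self):
        assert set(debruijn_sequence(3, 60)) <= set("ACGT")


class TestForwardDesign:
    def test_ground_truth_is_watson_crick_consistent(self, raster):
        design, gt = raster
        for i in range(gt.n):
            p = gt.partner(i)
            if p is None:
                continue
            sid, sb = p
            assert pairs(design.scaffold.sequence[i],
                         design.staples[sid].sequence[sb],
                         design.scaffold.material)

    def test_two_section_pattern_tiling(self, raster):
        design, gt = raster
        assert len(design.staples) == (4 // 2) * (64 // 16)
        assert all(len(s.sequence) == 32 for s in design.staples)
        assert gt.paired_fraction() == 1.0

    def test_staples_rederivable_from_scaffold_and_truth(self, raster):
        # the generator's own staples must equal letters re-derived
        # independently from the scaffold through the ground truth
        design, gt = raster
        rebuilt = {s.id: ["?"] * len(s.sequence) for s in design.staples}
        for i in range(gt.n):
            p = gt.partner(i)
            if p:
                rebuilt[p[0]][p[1]] = wc_partner(design.scaffold.sequence[i])
        for s in design.staples:
            assert "".join(rebuilt[s.id]) == s.sequence

    def test_counting_oracle_every_base_once(self, raster_three_section):
        design, gt = raster_three_section
        # full tiling: each scaffold base paired exactly once; staple bases
        # partition the staple lengths
        assert gt.paired_fraction() == 1.0
        per_staple = {}
        for i in range(gt.n):
            sid, sb = gt.partner(i)
            per_staple.setdefault(sid, set()).add(sb)
        for s in design.staples:
            assert per_staple[s.id] == set(range(len(s.sequence)))

    def test_grid_divisibility_enforced(self):
        with pytest.raises(InputError):
            forward_design(RasterSpec(helix_rows=3, columns=64))  # odd rows
        with pytest.raises(InputError):
            forward_design(RasterSpec(helix_rows=4, columns=60))  # 60 % 16 != 0

    def test_custom_pattern_requires_lengths(self):
        with pytest.raises(InputError):
            forward_design(RasterSpec(staple_pattern="custom"))

    def test_provided_scaffold_too_short_rejected(self):
        with pytest.raises(InputError):
            forward_design(RasterSpec(helix_rows=2, columns=16,
                                      scaffold_kind="provided",
                                      provided_scaffold="ACGT"))

    def test_rna_material_uses_rna_alphabet(self):
        design, _ = forward_design(RasterSpec(seed=1, material="RNA"))
        assert set(design.scaffold.sequence) <= set("ACGU")
        assert all(set(s.sequence) <= set("ACGT") for s in design.staples)

    def test_engineering_enforces_crossover_letter_inequalities(self, raster):
        # for consecutive sections of one staple, the scaffold letter one
        # base past the first section's 5' terminus must differ from the
        # letter at the next section's scaffold-3' end (and symmetrically),
        # which is what forbids overshoot and junction sliding
        design, gt = raster
        seq = design.scaffold.sequence
        n = gt.n
        by_staple: dict[int, list[tuple[int, int]]] = {}
        for i in range(n):
            p = gt.partner(i)
            if p:
                by_staple.setdefault(p[0], []).append((p[1], i))
        for entries in by_staple.values():
            entries.sort()
            # split into sections at staple-base discontinuities in scaffold
            sections: list[list[int]] = [[entries[0][1]]]
            for (sb_prev, pos_prev), (sb, pos) in zip(entries, entries[1:]):
                if sb == sb_prev + 1 and (pos_prev - pos) % n == 1:
                    sections[-1].append(pos)
                else:
                    sections.append([pos])
            for sec1, sec2 in zip(sections, sections[1:]):
                lo1, hi2 = sec1[-1], sec2[0]  # staple 3' end of sec1, entry of sec2
                assert seq[(lo1 - 1) % n] != seq[hi2]
                assert seq[(hi2 + 1) % n] != seq[lo1]

    def test_unengineered_random_scaffolds_can_overshoot(self):
        # with engineering off, at least one seed in a small batch produces a
        # staple whose maximal first run exceeds its designed section
        from revnano.srt import build_srt
        from revnano.seqio import split_virtual

        found = False
        for seed in range(10):
            spec = RasterSpec(seed=seed, scaffold_kind="random",
                              engineer_junctions=False)
            design, _ = forward_design(spec)
            for v in split_virtual(design):
                srt = build_srt(v, design.scaffold, 6, 4)
                if any(r[0].mu != 16 for r in srt.routes):
                    found = True
        assert found


class TestLoopout:
    def test_loop_shifts_staple_bases(self, raster):
        design, gt = raster
        design2, gt2 = insert_loopout(design, gt, staple_id=2, loop="ttt")
        assert design2.staples[2].sequence.count("t") == 3
        moved = [i for i in range(gt.n) if gt.partner(i) != gt2.partner(i)]
        assert all(gt.partner(i)[0] == 2 for i in moved)
        # second section's staple bases shifted by the loop length
        for i in moved:
            assert gt2.partner(i) == (2, gt.partner(i)[1] + 3)

    def test_loop_must_be_dna(self, raster):
        design, gt = raster
        with pytest.raises(InputError):
            insert_loopout(design, gt, staple_id=0, loop="x!")


class TestDecoy:
    def test_lure_longer_than_designed_section_and_truth_unchanged(self, decoy_fixture):
        design, gt, y, L = decoy_fixture
        staple = design.staples[0]
        # lure pairs staple bases 0..L-1 antiparallel at [y, y+L-1]
        for j in range(L):
            assert pairs(design.scaffold.sequence[y + L - 1 - j], staple.sequence[j])
        # window was unpaired: ground truth still consistent with new scaffold
        for i in range(gt.n):
            p = gt.partner(i)
            if p:
                assert pairs(design.scaffold.sequence[i],
                             design.staples[p[0]].sequence[p[1]])
        assert all(gt.staple_id[y + k] == UNPAIRED for k in range(L))

    def test_lure_run_is_capped_by_guard_letters(self, decoy_fixture):
        design, _, y, L = decoy_fixture
        staple = design.staples[0]
        seq = design.scaffold.sequence
        assert not pairs(seq[y - 1], staple.sequence[L])
        assert not pairs(seq[y + L], staple.sequence[0])

    def test_needs_an_unpaired_window(self, raster):
        design, gt = raster  # fully tiled: no room
        with pytest.raises(InputError):
            implant_decoy(design, gt)


class TestNoise:
    def test_zero_noise_is_identity(self, raster):
        design, _ = raster
        noisy = add_noise(design, sub_rate=0.0, n_contaminants=0, seed=9)
        assert [s.sequence for s in noisy.staples] == [s.sequence for s in design.staples]

    def test_contaminants_appended_at_end(self, raster):
        design, _ = raster
        noisy = add_noise(design, n_contaminants=3, contaminant_len=20, seed=1)
        assert len(noisy.staples) == len(design.staples) + 3
        assert all(len(s.sequence) == 20 for s in noisy.staples[-3:])
        assert [s.sequence for s in noisy.staples[:8]] == \
            [s.sequence for s in design.staples]

    def test_shuffled_contaminants_preserve_multiset(self, raster):
        design, _ = raster
        noisy = add_noise(design, n_contaminants=2, seed=4,
                          position=NoisePosition.SHUFFLED)
        originals = {s.sequence for s in design.staples}
        assert originals <= {s.sequence for s in noisy.staples}
        assert len(noisy.staples) == 10

    def test_seeded_repeatability(self, raster):
        design, _ = raster
        a = add_noise(design, sub_rate=0.05, n_contaminants=1, seed=7)
        b = add_noise(design, sub_rate=0.05, n_contaminants=1, seed=7)
        assert [s.sequence for s in a.staples] == [s.sequence for s in b.staples]

    @given(st.integers(0, 1000))
    @settings(max_examples=10)
    def test_substitution_count_positionwise_oracle(self, seed):
        design, _ = forward_design(RasterSpec(seed=0))
        noisy = add_noise(design, sub_rate=0.1, seed=seed)
        changed = sum(
            a != b
            for s0, s1 in zip(design.staples, noisy.staples)
            for a, b in zip(s0.sequence, s1.sequence)
        )
        total = sum(len(s.sequence) for s in design.staples)
        # a substituted base is always a *different* letter, so the count is
        # exactly the number of substitution draws; loose binomial bounds
        assert 0 <= changed <= total
        if changed:
            for s0, s1 in zip(design.staples, noisy.staples):
                for a, b in zip(s0.sequence, s1.sequence):
                    if a != b:
                        assert b in "ACGT" and b != a

    def test_invalid_rate_rejected(self, raster):
        design, _ = raster
        with pytest.raises(InputError):
            add_noise(design, sub_rate=1.5)


class TestRandomSequence:
    def test_seeded_and_alphabet(self):
        assert random_sequence(50, 3) == random_sequence(50, 3)
        assert set(random_sequence(50, 3)) <= set("ACGT")
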