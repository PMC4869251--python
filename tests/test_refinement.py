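"""Refinement subroutines: tandem filtering, widening, extension, boundary
correction, trimming, annotation and long-spacer recovery."""

import pytest

from crisparray.annotation import RepeatBank
from crisparray.model import (
    CrisprArray,
    GenomeRecord,
    ReferenceRepeat,
    RepeatUnit,
    SpacerUnit,
    forward_unit_intervals,
    reconstruct_span,
)
from crisparray.refine import (
    RefinementConfig,
    TANDEM_FLAG,
    annotate_insertions,
    correct_terminal_gaps,
    extend_array,
    extend_repeat_ends,
    filter_tandem_repeats,
    recover_repeats_from_long_spacers,
    refine,
    refine_repeat_boundaries,
    select_representative_repeat,
    trim_array,
)
from crisparray.scenarios import (
    scenario_clean,
    scenario_degenerate_end,
    scenario_fused_spacer,
    scenario_jannaschii_like,
)
from crisparray.seeds import cluster_to_candidate, scan_repeated_words
from crisparray.simulate import (
    PlantSpec,
    _random_seq,
    _rng,
    generate_genome,
    generate_tandem_decoy,
    random_repeat,
)

from conftest import detect, forward_units


def _array_from_units(genome, intervals):
    """intervals: [(start, end, is_repeat), ...] sorted and tiling."""
    units = []
    for s, e, is_rep in intervals:
        text = genome.sequence[s:e]
        units.append(
            RepeatUnit(s, e, text) if is_rep else SpacerUnit(s, e, text, lost=s == e)
        )
    arr = CrisprArray(genome_id=genome.id, units=units)
    arr.check_structure()
    return arr


def _crude_candidate(genome):
    clusters = scan_repeated_words(genome)
    assert clusters, "fixture must be seedable"
    return cluster_to_candidate(clusters[0], genome)


class TestFilterTandemRepeats:
    def _with_spacers(self, spacers):
        rng = _rng([1, 3])
        rep = random_repeat(rng, 25)
        parts, intervals, pos = [], [], 0
        for i, s in enumerate(spacers + [None]):
            parts.append(rep)
            intervals.append((pos, pos + len(rep), True))
            pos += len(rep)
            if s is not None:
                parts.append(s)
                intervals.append((pos, pos + len(s), False))
                pos += len(s)
        genome = GenomeRecord("t", "".join(parts))
        return _array_from_units(genome, intervals)

    def test_identical_spacers_are_tandem(self):
        s = _random_seq(_rng([2, 3]), 30)
        assert filter_tandem_repeats(self._with_spacers([s, s, s])) == "tandem"

    def test_random_spacers_are_kept(self):
        rng = _rng([3, 3])
        spacers = [_random_seq(rng, 32) for _ in range(4)]
        assert filter_tandem_repeats(self._with_spacers(spacers)) == "keep"

    def test_four_varying_columns_is_still_tandem(self):
        base = _random_seq(_rng([4, 3]), 30)
        variants = [base]
        for i, col in enumerate((3, 9, 15, 21)):
            alt = "A" if base[col] != "A" else "C"
            variants.append(base[:col] + alt + base[col + 1 :])
        assert filter_tandem_repeats(self._with_spacers(variants)) == "tandem"

    def test_identical_spacer_run_among_distinct_ones_is_kept(self):
        genome, _ = scenario_jannaschii_like(2)
        result = detect(genome)
        assert len(result.arrays) == 1
        assert result.arrays[0].n_repeats == 24
        assert result.arrays[0].score.category == "good"

    def test_perfect_tandem_decoy_is_rejected_end_to_end(self):
        unit = random_repeat(_rng([5, 3]), 40)
        genome = generate_tandem_decoy(unit, 8, 0.0, seed=5)
        assert detect(genome).arrays == []


class TestExtendRepeatEnds:
    def test_recovers_full_repeat_from_inner_word(self):
        genome, truths = scenario_clean(7, n_repeats=6)
        truth = truths[0]
        arr = extend_repeat_ends(_crude_candidate(genome), genome)
        true_len = len(truth.representative_repeat)
        assert all(len(r) == true_len for r in arr.repeats())
        assert [(r.start, r.end) for r in arr.repeats()] == [
            (r.start, r.end) for r in truth.repeats()
        ]

    def test_weak_column_crossed_when_followed_by_two_strong(self):
        # 10 repeats; first flank column 4/10 identical, next two 9/10
        rng = _rng([8, 3])
        rep = random_repeat(rng, 20)
        cols = ["AAAACGTCGT", "AAAAAAAAAC", "AAAAAAAAAG"]  # per-unit flank bases
        tails = ["".join(c[i] for c in cols) for i in range(10)]
        parts, pos, intervals = [], 0, []
        for i in range(10):
            parts.append(rep)
            intervals.append((pos, pos + len(rep), True))
            pos += len(rep)
            if i < 9:
                filler = _random_seq(rng, 25)
                s = tails[i] + filler
                parts.append(s)
                pos += len(s)
        genome = GenomeRecord("w", "".join(parts) + tails[9] + _random_seq(rng, 30))
        arr = _array_from_units(
            genome,
            [
                iv if iv[2] else iv
                for iv in _tile(intervals, len(genome.sequence))
            ],
        )
        out = extend_repeat_ends(arr, genome)
        assert all(len(r) >= len(rep) + 3 for r in out.repeats())

    def test_three_repeats_require_perfect_identity(self):
        # 3 repeats; flank column 2/3 identical: no extension at all
        rng = _rng([9, 3])
        rep = random_repeat(rng, 22)
        flanks = ["A", "A", "C"]
        parts, pos, intervals = [], 0, []
        for i in range(3):
            parts.append(rep)
            intervals.append((pos, pos + len(rep), True))
            pos += len(rep)
            if i < 2:
                s = flanks[i] + _random_seq(rng, 27)
                parts.append(s)
                pos += len(s)
        genome = GenomeRecord("p", "".join(parts) + flanks[2] + _random_seq(rng, 30))
        arr = _array_from_units(genome, _tile(intervals, len(genome.sequence)))
        out = extend_repeat_ends(arr, genome)
        assert [len(r) for r in out.repeats()] == [22, 22, 22]

    def test_consuming_every_spacer_flags_tandem(self):
        unit = random_repeat(_rng([10, 3]), 36)
        genome = generate_tandem_decoy(unit, 6, 0.0, seed=10)
        arr = refine(_crude_candidate(genome), genome)
        assert TANDEM_FLAG in arr.flags


def _tile(repeat_intervals, genome_length):
    """Fill spacer intervals between repeat intervals."""
    out = []
    for i, (s, e, _) in enumerate(repeat_intervals):
        out.append((s, e, True))
        if i + 1 < len(repeat_intervals):
            out.append((e, repeat_intervals[i + 1][0], False))
    return out


class TestSelectRepresentative:
    def _arr(self, observed):
        pos, units = 0, []
        for i, r in enumerate(observed):
            units.append(RepeatUnit(pos, pos + len(r), r))
            pos += len(r)
            if i + 1 < len(observed):
                units.append(SpacerUnit(pos, pos + 5, "ACGTA"))
                pos += 5
        return CrisprArray(genome_id="x", units=units)

    def test_mode_and_runner_up(self):
        R, Rp = "ACGTACGTACGT", "ACGTACGTACGA"
        arr = self._arr([R, R, R, Rp])
        assert select_representative_repeat(arr) == (R, Rp)

    def test_tie_goes_to_five_prime_most(self):
        R, Rp = "ACGTACGTACGT", "TGCATGCATGCA"
        arr = self._arr([R, Rp])
        assert select_representative_repeat(arr)[0] == R

    def test_all_distinct_takes_leading_two(self):
        reps = ["ACGTACGTACGA", "ACGTACGTACGC", "ACGTACGTACGG"]
        arr = self._arr(reps)
        assert select_representative_repeat(arr) == (reps[0], reps[1])


class TestExtendArray:
    def _planted(self, seed, terminal_mutations):
        rng = _rng([seed, 4])
        spec = PlantSpec(
            repeat=random_repeat(rng, 28),
            n_repeats=7,
            offset=300,
            spacer_length=(26, 38),
            leader_at_fraction=0.72,
            terminal_mutations=terminal_mutations,
            seed=seed,
        )
        return generate_genome([spec], 3500, seed=seed)

    def test_mutated_terminal_repeat_recovered(self):
        # terminal repeat at 75 % identity: above the 67 % extension cutoff
        genome, truths = self._planted(11, 7)
        truth = truths[0]
        arr = _array_from_units(
            genome, [(u.start, u.end, u.is_repeat) for u in truth.units[:-2]]
        )
        select_representative_repeat(arr)
        out = extend_array(arr, genome)
        assert out.n_repeats == truth.n_repeats
        assert out.units[-1].end == truth.units[-1].end

    def test_low_identity_candidate_not_added(self):
        # terminal repeat at ~57 % identity: below the 67 % cutoff
        genome, truths = self._planted(12, 12)
        truth = truths[0]
        arr = _array_from_units(
            genome, [(u.start, u.end, u.is_repeat) for u in truth.units[:-2]]
        )
        select_representative_repeat(arr)
        out = extend_array(arr, genome)
        assert out.n_repeats == truth.n_repeats - 1

    def test_adjacent_arrays_300nt_apart_not_merged(self):
        rng = _rng([13, 4])
        rep = random_repeat(rng, 26)
        specs = [
            PlantSpec(repeat=rep, n_repeats=4, offset=300, leader_length=0, seed=1),
            PlantSpec(repeat=rep, n_repeats=4, offset=860, leader_length=0, seed=2),
        ]
        # arrays end ~offset+4*60; gap between spans > 125
        genome, truths = generate_genome(specs, 2500, seed=13)
        gap = truths[1].units[0].start - truths[0].units[-1].end
        assert gap > 125
        arr = _array_from_units(
            genome, [(u.start, u.end, u.is_repeat) for u in truths[0].units]
        )
        select_representative_repeat(arr)
        out = extend_array(arr, genome)
        assert out.units[-1].end == truths[0].units[-1].end


class TestRefineRepeatBoundaries:
    def test_bank_match_restores_missing_final_base(self):
        rng = _rng([14, 4])
        full = random_repeat(rng, 29)
        bank = RepeatBank([ReferenceRepeat(full, "ref", "I-E")])
        spec = PlantSpec(
            repeat=full[:-1],  # planted without the final base
            n_repeats=5,
            offset=300,
            spacer_sequences=[full[-1] + _random_seq(rng, 30) for _ in range(4)],
            leader_at_fraction=0.72,
            seed=14,
        )
        genome, _ = generate_genome([spec], 3000, seed=14)
        arr = refine(_crude_candidate(genome), genome, bank)
        assert arr.representative_repeat == full

    def test_motif_places_boundary_after_attgaaa_plus_one(self):
        rng = _rng([15, 4])
        spec = PlantSpec(
            repeat=random_repeat(rng, 24) + "ATTGAAA",
            n_repeats=5,
            offset=300,
            spacer_sequences=["C" + _random_seq(rng, 30) for _ in range(4)],
            leader_at_fraction=0.72,
            seed=15,
        )
        genome, _ = generate_genome([spec], 3000, seed=15)
        arr = refine(_crude_candidate(genome), genome, None)
        assert arr.representative_repeat.endswith("ATTGAAAC")

    def test_degenerate_end_columns_trimmed(self):
        rng = _rng([16, 4])
        rep = random_repeat(rng, 30)
        swap = lambda c: "A" if c != "A" else "C"
        spec = PlantSpec(
            repeat=rep,
            n_repeats=5,
            offset=300,
            leader_at_fraction=0.72,
            substitution_events=[
                (1, 29, swap(rep[29])),
                (1, 28, swap(rep[28])),
            ],
            seed=16,
        )
        genome, _ = generate_genome([spec], 3000, seed=16)
        arr = refine(_crude_candidate(genome), genome, None)
        # 1/5 = 20 % mismatch in the last two columns: above the extension
        # threshold (80 % identity) yet at the degeneracy cutoff, so the
        # boundary rule returns both columns to the spacers
        assert arr.representative_repeat == rep[:-2]


class TestTrimArray:
    def test_terminal_repeat_at_45_percent_removed(self):
        genome, truths = scenario_clean(17, n_repeats=6)
        truth = truths[0]
        arr = _array_from_units(
            genome, [(u.start, u.end, u.is_repeat) for u in truth.units]
        )
        select_representative_repeat(arr)
        rep = arr.representative_repeat
        # forge a 45 %-identity terminal repeat by rewriting the observation
        bad = rep[: len(rep) // 2] + _random_seq(_rng([17, 5]), len(rep) - len(rep) // 2)
        arr.units[-1].observed_sequence = bad
        out = trim_array(arr)
        assert out.n_repeats == truth.n_repeats - 1

    def test_high_identity_array_unchanged(self):
        genome, truths = scenario_clean(18, n_repeats=5)
        arr = _array_from_units(
            genome, [(u.start, u.end, u.is_repeat) for u in truths[0].units]
        )
        select_representative_repeat(arr)
        before = [(u.start, u.end) for u in arr.units]
        assert [(u.start, u.end) for u in trim_array(arr).units] == before

    def test_minimum_repeat_floor_respected(self):
        genome, truths = scenario_clean(19, n_repeats=3)
        arr = _array_from_units(
            genome, [(u.start, u.end, u.is_repeat) for u in truths[0].units]
        )
        select_representative_repeat(arr)
        arr.units[-1].observed_sequence = _random_seq(_rng([19, 5]), 24)
        assert trim_array(arr).n_repeats == 3


class TestCorrectTerminalGaps:
    def _clean(self, seed):
        genome, truths = scenario_clean(seed, n_repeats=5)
        arr = _array_from_units(
            genome, [(u.start, u.end, u.is_repeat) for u in truths[0].units]
        )
        select_representative_repeat(arr)
        return genome, arr

    def test_borrows_matching_base_from_spacer(self):
        genome, arr = self._clean(20)
        # mis-place one internal boundary: repeat 2 one base short at 3'
        r = arr.repeats()[2]
        idx = arr.units.index(r)
        spacer = arr.units[idx + 1]
        true_end = r.end
        r.end -= 1
        r.observed_sequence = genome.sequence[r.start : r.end]
        spacer.start -= 1
        spacer.sequence = genome.sequence[spacer.start : spacer.end]
        out = correct_terminal_gaps(arr, genome)
        assert out.repeats()[2].end == true_end
        reconstruct_span(out, genome)

    def test_extra_unmatched_base_recorded_as_insertion(self):
        genome, arr = self._clean(21)
        r = arr.repeats()[1]
        idx = arr.units.index(r)
        spacer = arr.units[idx + 1]
        r.end += 1
        r.observed_sequence = genome.sequence[r.start : r.end]
        spacer.start += 1
        spacer.sequence = genome.sequence[spacer.start : spacer.end]
        out = correct_terminal_gaps(arr, genome)
        target = out.repeats()[1]
        assert target.insertions, "extra terminal base should be labelled"
        reconstruct_span(out, genome)

    def test_clean_array_is_a_no_op(self):
        genome, arr = self._clean(22)
        before = [(u.start, u.end) for u in arr.units]
        out = correct_terminal_gaps(arr, genome)
        assert [(u.start, u.end) for u in out.units] == before


class TestAnnotateInsertions:
    def test_single_insertion_gets_position_notation(self):
        spec = PlantSpec(
            repeat="GTGTTCCCCGCGCCAGCGGGGATAAACCG",
            n_repeats=6,
            offset=300,
            insertion_events=[(2, 14, "C")],
            leader_at_fraction=0.72,
            seed=23,
        )
        genome, truths = generate_genome([spec], 3200, seed=23)
        result = detect(genome)
        assert len(result.arrays) == 1
        arr = result.arrays[0]
        assert arr.representative_repeat == spec.repeat  # gap-free representative
        carrier = [u for u in arr.repeats() if u.insertions]
        assert len(carrier) == 1
        (pos, bases), = carrier[0].insertions
        assert bases == "C"
        # 1-based position points at the inserted base on the forward genome
        assert genome.sequence[pos - 1] == "C"

    def test_clean_array_has_no_edit_annotations(self):
        genome, _ = scenario_clean(24, n_repeats=5)
        arr = detect(genome).arrays[0]
        for u in arr.repeats():
            assert not (u.mismatch_positions or u.insertions or u.deletions)

    def test_shared_insertion_annotated_on_both_carriers(self):
        spec = PlantSpec(
            repeat="GTGTTCCCCGCGCCAGCGGGGATAAACCG",
            n_repeats=8,
            offset=300,
            insertion_events=[(2, 14, "CT"), (5, 14, "CT")],
            leader_at_fraction=0.72,
            seed=25,
        )
        genome, _ = generate_genome([spec], 3800, seed=25)
        arr = detect(genome).arrays[0]
        carriers = [u for u in arr.repeats() if u.insertions]
        assert len(carriers) == 2
        assert all(ins[0][1] == "CT" for ins in [u.insertions for u in carriers])
        assert arr.representative_repeat == spec.repeat


class TestRecoverRepeatsFromLongSpacers:
    def test_fused_spacer_split_restored_with_deletion(self):
        genome, truth = scenario_fused_spacer(3)
        arr = detect(genome).arrays[0]
        assert forward_units(arr, genome) == forward_units(truth, genome)
        carrier = [u for u in arr.repeats() if u.deletions]
        assert len(carrier) == 1
        assert sum(length for _, length in carrier[0].deletions) == 3

    def test_typical_spacers_untouched(self):
        genome, truths = scenario_clean(26, n_repeats=6)
        arr = detect(genome).arrays[0]
        before = [(u.start, u.end) for u in arr.units]
        out = recover_repeats_from_long_spacers(arr, genome)
        assert [(u.start, u.end) for u in out.units] == before


class TestRefineDriver:
    @pytest.mark.parametrize("seed", [27, 28, 29])
    def test_clean_candidate_reaches_exact_truth(self, seed, bank):
        genome, truths = scenario_clean(seed)
        arr = refine(_crude_candidate(genome), genome, bank)
        assert [(u.start, u.end) for u in arr.units] == [
            (u.start, u.end) for u in truths[0].units
        ]

    @pytest.mark.parametrize("seed", [30, 31])
    def test_refine_is_idempotent(self, seed, bank):
        genome, _ = scenario_clean(seed)
        once = refine(_crude_candidate(genome), genome, bank)
        again = refine(once, genome, bank)
        assert [(u.start, u.end) for u in again.units] == [
            (u.start, u.end) for u in once.units
        ]
        assert again.representative_repeat == once.representative_repeat

    def test_every_emitted_array_reconstructs_its_span(self, bank):
        for seed in (32, 33):
            genome, _ = scenario_clean(seed)
            for arr in detect(genome, repeat_bank=bank).arrays:
                reconstruct_span(arr, genome)

    def test_degenerate_last_repeat_retained_with_annotations(self):
        case = scenario_degenerate_end(0)
        # pick a seed whose terminal repeat sits above the trim cutoff
        assert case.should_retain
        arr = detect(case.genome).arrays[0]
        assert arr.n_repeats == case.truth.n_repeats
        last = arr.repeats()[-1]
        assert last.mismatch_positions
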