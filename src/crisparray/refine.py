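"""Iterative refinement of crude seed candidates into finished arrays.

The refinement stage turns a cluster of identical 11-mers into an array
with biologically meaningful boundaries.  It owns:

* tandem-repeat elimination (tandem repeats look like CRISPRs to a word
  scanner but lack the repeat-dissimilar spacer structure);
* symmetric column-wise widening of the repeats;
* representative/alternative repeat selection;
* array extension into the flanks with a lowered identity threshold, to
  pick up degenerate terminal repeats the seed scan missed;
* boundary correction against a reference-repeat bank, the ATTGAAA(N) 3'
  motif, and repeat-end degeneracy;
* trimming of terminal repeats that match the representative poorly;
* per-repeat terminal gap correction and insertion/deletion annotation;
* recovery of mutated repeats hiding inside unusually long spacers.

All operations run before orientation is decided, i.e. on forward-genome
coordinates, and every one of them preserves the invariant that unit
sequences tile the genomic span exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from statistics import median

from .align import (
    GAP,
    align_repeats,
    column_identity,
    fit_align,
    local_align_sweep,
    pairwise_rows,
    repeat_identity,
)
from .model import CrisprArray, GenomeRecord, RepeatUnit, SpacerUnit

TANDEM_FLAG = "tandem_repeat_suspect"


@dataclass
class RefinementConfig:
    """Tunable thresholds of the refinement stage (defaults are the
    pipeline's standard operating point; fractions are in [0, 1])."""

    primary_column_identity: float = 0.75
    alt_column_identity_short: float = 0.50  # arrays with < 7 repeats
    alt_column_identity_long: float = 0.40
    extension_min_identity: float = 0.67
    trim_min_identity: float = 0.66  # strict >: terminal repeats at or below go
    min_repeats_after_trim: int = 3
    max_spacer: int = 125
    end_degeneracy: float = 0.20
    long_spacer_factor: float = 1.2
    extension_low_identity_floor: float = 0.35
    dynamic_adjacent_reference: bool = True
    recover_min_identity: float | None = None  # default: extension_min_identity
    min_repeat_length: int = 11
    max_iterations: int = 10
    tandem_max_unaligned_columns: int = 5
    tandem_spacer_identity: float = 75.0  # median best spacer-pair identity, %
    tandem_repeat_like_identity: float = 80.0  # local spacer-vs-repeat match, %
    tandem_repeat_like_cover: float = 0.6  # fraction of the shorter sequence

    def __post_init__(self) -> None:
        for name in (
            "primary_column_identity",
            "alt_column_identity_short",
            "alt_column_identity_long",
            "extension_min_identity",
            "trim_min_identity",
            "end_degeneracy",
            "extension_low_identity_floor",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.min_repeats_after_trim < 2:
            raise ValueError("min_repeats_after_trim must be >= 2")
        if (
            self.recover_min_identity is not None
            and self.recover_min_identity < self.extension_low_identity_floor
        ):
            raise ValueError(
                "recover_min_identity below the permitted floor "
                f"({self.extension_low_identity_floor})"
            )

    @property
    def recovery_identity(self) -> float:
        return (
            self.recover_min_identity
            if self.recover_min_identity is not None
            else self.extension_min_identity
        )


# ---------------------------------------------------------------------------
# unit-list plumbing


def _build_units(genome: GenomeRecord, intervals: list[tuple[int, int]]) -> list:
    seq = genome.sequence
    units = []
    for i, (s, e) in enumerate(intervals):
        units.append(RepeatUnit(s, e, seq[s:e]))
        if i + 1 < len(intervals):
            ns = intervals[i + 1][0]
            units.append(SpacerUnit(e, ns, seq[e:ns], lost=(e == ns)))
    return units


def _repeat_intervals(array: CrisprArray) -> list[tuple[int, int]]:
    return [(u.start, u.end) for u in array.repeats()]


def _rebuild(array: CrisprArray, genome: GenomeRecord, intervals) -> CrisprArray:
    array.units = _build_units(genome, intervals)
    array.check_structure()
    return array


def _signature(array: CrisprArray):
    return tuple((u.start, u.end, u.is_repeat) for u in array.units)


# ---------------------------------------------------------------------------
# tandem elimination


def filter_tandem_repeats(array: CrisprArray, config: RefinementConfig | None = None) -> str:
    """Classify a candidate as ``keep`` or ``tandem``.

    Two tests: (a) the spacer set aligns with fewer than 5 non-conserved
    columns (near-identical "spacers" are the period of a tandem repeat, not
    acquired sequence); (b) the median over spacers of the best pairwise
    identity to another spacer is >= 75 % — the array lacks a
    repeat-dissimilar spacer structure.  A median keeps genuine arrays with
    a run of recently duplicated identical spacers (a known natural pattern)
    out of the tandem bin.  Candidates with a single usable spacer bypass
    the test with a flag.
    """
    config = config or RefinementConfig()
    all_spacers = array.spacers()
    spacer_seqs = [s.sequence for s in all_spacers if len(s.sequence) > 0]

    # repeat-end extension eating the majority of the "spacers" is the
    # signature of a tandem period, not of (rare) total spacer loss
    if all_spacers and sum(1 for s in all_spacers if len(s) == 0) * 2 > len(all_spacers):
        return "tandem"

    # spacers that resemble the repeat itself: no repeat-dissimilar spacer
    # structure (covers the single-spacer case too).  Containment is tested
    # both ways so period fragments of any length are caught.
    if spacer_seqs:
        observed = [u.observed_sequence for u in array.repeats()]
        counts = Counter(observed)
        top = max(counts.values())
        rep = next(s for s in observed if counts[s] == top)

        def containment(s: str) -> float:
            vals = []
            for fit in (fit_align(rep, s), fit_align(s, rep)):
                if fit is not None:
                    vals.append(fit[2])
            return max(vals) if vals else 0.0

        if median(containment(s) for s in spacer_seqs) >= config.tandem_spacer_identity:
            return "tandem"

        # period fragments at a shifted phase: a spacer is repeat-like when
        # an ungapped local match to the repeat covers most of the shorter
        # of the two at high identity
        def repeat_like(s: str) -> bool:
            if len(s) < 8:
                return True  # a sliver between period copies, not a spacer
            hit = local_align_sweep(rep, s)
            return (
                hit is not None
                and hit.identity >= config.tandem_repeat_like_identity
                and hit.length
                >= config.tandem_repeat_like_cover * min(len(rep), len(s))
            )

        if sum(repeat_like(s) for s in spacer_seqs) * 2 > len(spacer_seqs):
            return "tandem"

    if len(spacer_seqs) < 2:
        array.flags.add("single_spacer_unchecked")
        return "keep"
    aln = align_repeats(spacer_seqs)
    unaligned = sum(1 for cid in aln.column_identities() if cid < 1.0)
    if unaligned < config.tandem_max_unaligned_columns:
        return "tandem"
    best = []
    for i, si in enumerate(spacer_seqs):
        best.append(
            max(repeat_identity(si, sj) for j, sj in enumerate(spacer_seqs) if j != i)
        )
    if median(best) >= config.tandem_spacer_identity:
        return "tandem"
    return "keep"


# ---------------------------------------------------------------------------
# repeat-end extension


def extend_repeat_ends(
    array: CrisprArray, genome: GenomeRecord, config: RefinementConfig | None = None
) -> CrisprArray:
    """Widen all repeats symmetrically while flanking columns stay conserved.

    A column joins the repeat while its identity across repeats is at least
    the primary threshold (75 %), which automatically demands perfect
    identity for two or three repeats, one mismatch for four to seven, and
    so on.  Once per side a weaker column (identity >= 50 % for arrays of
    < 7 repeats, >= 40 % otherwise) may be crossed when the two columns
    beyond it are both above the primary threshold.  If widening consumes
    every spacer the candidate is a tandem repeat and is flagged.
    """
    config = config or RefinementConfig()
    seq = genome.sequence
    reps = _repeat_intervals(array)
    n = len(reps)
    primary = config.primary_column_identity
    alt = (
        config.alt_column_identity_short if n < 7 else config.alt_column_identity_long
    )

    def col_identity(intervals, side: str, k: int) -> float | None:
        bases = []
        for s, e in intervals:
            pos = s - 1 - k if side == "left" else e + k
            if pos < 0 or pos >= len(seq):
                return None
            bases.append(seq[pos])
        return column_identity(bases)

    def room(intervals, side: str, depth: int) -> bool:
        for i, (s, e) in enumerate(intervals):
            if side == "left":
                limit = intervals[i - 1][1] if i > 0 else 0
                if s - depth < limit:
                    return False
            else:
                limit = intervals[i + 1][0] if i < len(intervals) - 1 else len(seq)
                if e + depth > limit:
                    return False
        return True

    def shift(intervals, side: str):
        if side == "left":
            return [(s - 1, e) for s, e in intervals]
        return [(s, e + 1) for s, e in intervals]

    for side in ("left", "right"):
        used_weak = False
        while True:
            if not room(reps, side, 1):
                break
            cid = col_identity(reps, side, 0)
            if cid is None:
                break
            if cid >= primary:
                reps = shift(reps, side)
                continue
            if not used_weak and cid >= alt and room(reps, side, 3):
                c1 = col_identity(reps, side, 1)
                c2 = col_identity(reps, side, 2)
                if c1 is not None and c2 is not None and c1 >= primary and c2 >= primary:
                    reps = shift(reps, side)
                    used_weak = True
                    continue
            break

    _rebuild(array, genome, reps)
    internal = array.spacers()
    if internal and all(len(s) == 0 for s in internal):
        array.flags.add(TANDEM_FLAG)
    return array


# ---------------------------------------------------------------------------
# representative repeat


def select_representative_repeat(array: CrisprArray) -> tuple[str, str]:
    """Modal observed repeat (ties: nearest the 5' end) and the runner-up."""
    observed = [u.observed_sequence for u in array.repeats()]
    if len(observed) < 2:
        raise ValueError("representative selection needs >= 2 repeats")
    counts = Counter(observed)
    top = max(counts.values())
    modal = {s for s, c in counts.items() if c == top}
    representative = next(s for s in observed if s in modal)
    alternative = ""
    rest = {s: c for s, c in counts.items() if s != representative}
    if rest:
        top2 = max(rest.values())
        modal2 = {s for s, c in rest.items() if c == top2}
        alternative = next(s for s in observed if s in modal2)
    array.representative_repeat = representative
    array.alternative_repeat = alternative
    return representative, alternative


# ---------------------------------------------------------------------------
# array extension into the flanks


def _median_spacer(array: CrisprArray) -> float:
    lens = [len(s) for s in array.spacers() if not s.lost]
    return float(median(lens)) if lens else 0.0


def _window_length(rep_len: int, med_spacer: float) -> int:
    if 15 < med_spacer < 70:
        return round(rep_len + 1.33 * med_spacer)
    return round(2.5 * rep_len)


def extend_array(
    array: CrisprArray, genome: GenomeRecord, config: RefinementConfig | None = None
) -> CrisprArray:
    """Add degenerate terminal repeats found in the flanking windows.

    Each side is probed repeatedly: a window one repeat-plus-spacer deep is
    scanned for the best ungapped local match to the reference repeat (the
    adjacent terminal repeat by default), the match is widened to the
    reference length, and accepted as a new repeat when its identity is at
    least ``extension_min_identity`` and the gap to the terminus lies in
    [0, max_spacer] (a zero gap represents total spacer loss).  Never
    removes units.
    """
    config = config or RefinementConfig()
    seq = genome.sequence
    if not array.representative_repeat:
        select_representative_repeat(array)
    min_id = config.extension_min_identity * 100.0

    for side in ("right", "left"):
        while True:
            reps = _repeat_intervals(array)
            rep = array.representative_repeat
            wl = _window_length(len(rep), _median_spacer(array))
            if side == "right":
                ts, te = reps[-1]
                ref = seq[ts:te] if config.dynamic_adjacent_reference else rep
                wstart, wend = te, min(len(seq), te + wl)
            else:
                ts, te = reps[0]
                ref = seq[ts:te] if config.dynamic_adjacent_reference else rep
                wstart, wend = max(0, ts - wl), ts
            if wend - wstart < config.min_repeat_length:
                break
            hit = local_align_sweep(ref, seq[wstart:wend])
            if hit is None:
                break
            cstart = wstart + hit.window_start - hit.query_start
            cend = wstart + hit.window_end + (len(ref) - hit.query_end)
            cstart = max(cstart, 0)
            cend = min(cend, len(seq))
            if side == "right":
                gap = cstart - te
            else:
                gap = ts - cend
            if cend - cstart < config.min_repeat_length:
                break
            if gap < 0 or gap > config.max_spacer:
                break
            if repeat_identity(seq[cstart:cend], ref) < min_id - 1e-9:
                break
            intervals = sorted(reps + [(cstart, cend)])
            _rebuild(array, genome, intervals)
            select_representative_repeat(array)
    return array


# ---------------------------------------------------------------------------
# boundary refinement


def _shift_boundaries(
    array: CrisprArray,
    genome: GenomeRecord,
    left_delta: int,
    right_delta: int,
    config: RefinementConfig,
) -> CrisprArray:
    """Uniformly move every repeat's 5' boundary out by ``left_delta`` bases
    and its 3' boundary by ``right_delta`` (negative = trim).  No-op when the
    move would break containment, spacer non-negativity or the minimum
    repeat length."""
    if left_delta == 0 and right_delta == 0:
        return array
    reps = _repeat_intervals(array)
    new = [(s - left_delta, e + right_delta) for s, e in reps]
    n = len(genome.sequence)
    for i, (s, e) in enumerate(new):
        if s < 0 or e > n or e - s < config.min_repeat_length:
            return array
        if i > 0 and s < new[i - 1][1]:
            return array
    return _rebuild(array, genome, new)


def refine_repeat_boundaries(
    array: CrisprArray,
    genome: GenomeRecord,
    repeat_bank=None,
    config: RefinementConfig | None = None,
) -> CrisprArray:
    """Correct the repeat/spacer boundary, in priority order:

    1. a reference-bank match dictates the exact repeat extent;
    2. an ATTGAAA motif at/near the 3' end places the boundary just after
       the motif plus one base (the "(N)");
    3. otherwise terminal columns whose across-array mismatch fraction is at
       least ``end_degeneracy`` are trimmed back to the first conserved
       column (trimmed bases return to the adjacent spacers).
    """
    config = config or RefinementConfig()
    if not array.representative_repeat:
        select_representative_repeat(array)
    rep = array.representative_repeat

    if repeat_bank is not None:
        m = repeat_bank.match(rep)
        if m is not None:
            arr = _shift_boundaries(array, genome, m.left_delta, m.right_delta, config)
            select_representative_repeat(arr)
            return arr

    i = rep.rfind("ATTGAAA")
    if i >= 0 and i + 7 >= len(rep) - 4:
        desired_len = i + 7 + 1  # motif end + the (N) base
        arr = _shift_boundaries(array, genome, 0, desired_len - len(rep), config)
        select_representative_repeat(arr)
        return arr

    reps = array.repeats()
    if len(reps) >= 2:
        # degeneracy is judged on the repeat alignment, so repeats carrying
        # insertions or deletions do not shift the frame of the end columns;
        # gaps are excluded — a terminal gap is a boundary error for the
        # gap-correction step, not evidence of sequence degeneracy
        aln = align_repeats([r.observed_sequence for r in reps])
        identities = []
        for col in aln.columns():
            bases = [c for c in col if c != GAP]
            identities.append(column_identity(bases) if bases else 1.0)
        rep_row = next(
            row for row in aln.rows if row.replace(GAP, "") == rep
        )
        min_len = min(len(r) for r in reps)
        max_trim = max(0, min_len - config.min_repeat_length)

        def trim_depth(columns) -> int:
            k = 0
            for c in columns:
                if 1.0 - identities[c] < config.end_degeneracy - 1e-9:
                    break
                if rep_row[c] != GAP:  # count representative positions only
                    k += 1
                    if k >= max_trim:
                        break
            return min(k, max_trim)

        n_cols = len(identities)
        kl = trim_depth(range(n_cols))
        kr = trim_depth(range(n_cols - 1, -1, -1))
        if kl or kr:
            arr = _shift_boundaries(array, genome, -kl, -kr, config)
            select_representative_repeat(arr)
            return arr
    return array


# ---------------------------------------------------------------------------
# trimming


def trim_array(array: CrisprArray, config: RefinementConfig | None = None) -> CrisprArray:
    """Drop terminal repeats that match the representative poorly.

    From each end inward, a terminal repeat whose identity to the
    representative is not strictly above the cutoff (66 %) is removed along
    with its flanking spacer; trimming stops at the cutoff or at the
    minimum repeat count (3).
    """
    config = config or RefinementConfig()
    cutoff = config.trim_min_identity * 100.0
    while array.n_repeats > config.min_repeats_after_trim:
        rep = array.representative_repeat or select_representative_repeat(array)[0]
        first = array.units[0]
        last = array.units[-1]
        if repeat_identity(first.observed_sequence, rep) <= cutoff + 1e-9:
            array.units = array.units[2:]
            select_representative_repeat(array)
            continue
        if repeat_identity(last.observed_sequence, rep) <= cutoff + 1e-9:
            array.units = array.units[:-2]
            select_representative_repeat(array)
            continue
        break
    array.check_structure()
    return array


def fuse_low_identity_internal_repeats(
    array: CrisprArray, config: RefinementConfig | None = None
) -> int:
    """Dissolve internal repeats that match the representative no better
    than the trim cutoff back into one spacer.

    Word seeding occasionally chains a chance word occurrence inside a
    spacer into the candidate; such a unit is a random sequence wearing a
    repeat label.  Terminal cases are handled by trimming; internal ones
    are fused with their two flanking spacers.  Genuine degenerate repeats
    recovered from long spacers always sit at or above the recovery
    threshold (>= 67 %) and are never touched.  Returns the number fused.
    """
    config = config or RefinementConfig()
    cutoff = config.trim_min_identity * 100.0
    fused = 0
    while True:
        rep = array.representative_repeat or select_representative_repeat(array)[0]
        target = None
        for i in range(2, len(array.units) - 2, 2):  # internal repeats only
            u = array.units[i]
            if repeat_identity(u.observed_sequence, rep) <= cutoff + 1e-9:
                target = i
                break
        if target is None:
            return fused
        prev_spacer = array.units[target - 1]
        next_spacer = array.units[target + 1]
        merged = SpacerUnit(
            prev_spacer.start,
            next_spacer.end,
            prev_spacer.sequence
            + array.units[target].observed_sequence
            + next_spacer.sequence,
            lost=prev_spacer.start == next_spacer.end,
        )
        array.units[target - 1 : target + 2] = [merged]
        array.check_structure()
        select_representative_repeat(array)
        fused += 1


# ---------------------------------------------------------------------------
# terminal gap correction


def correct_terminal_gaps(array: CrisprArray, genome: GenomeRecord) -> CrisprArray:
    """Resolve per-repeat terminal gaps against the representative.

    A repeat missing bases at one end borrows them from the adjacent spacer
    when the spacer boundary bases match the representative; extra terminal
    bases that the representative lacks are recorded as insertions on that
    repeat.  Coordinates stay tiling throughout.
    """
    rep = array.representative_repeat or select_representative_repeat(array)[0]
    changed = False
    for i, u in enumerate(array.units):
        if not u.is_repeat or u.observed_sequence == rep:
            continue
        rrow, orow = pairwise_rows(rep, u.observed_sequence)
        # missing 5' prefix: leading gaps in the observed row
        g5 = 0
        for rch, och in zip(rrow, orow):
            if och == GAP and rch != GAP:
                g5 += 1
            else:
                break
        if g5 and i > 0:
            prev = array.units[i - 1]
            for k in range(min(g5, len(prev.sequence)), 0, -1):
                if prev.sequence[-k:] == rep[g5 - k : g5]:
                    u.start -= k
                    prev.end -= k
                    changed = True
                    break
        # missing 3' suffix: trailing gaps in the observed row
        g3 = 0
        for rch, och in zip(reversed(rrow), reversed(orow)):
            if och == GAP and rch != GAP:
                g3 += 1
            else:
                break
        if g3 and i + 1 < len(array.units):
            nxt = array.units[i + 1]
            for k in range(min(g3, len(nxt.sequence)), 0, -1):
                if nxt.sequence[:k] == rep[len(rep) - g3 : len(rep) - g3 + k]:
                    u.end += k
                    nxt.start += k
                    changed = True
                    break
    if changed:
        seq = genome.sequence
        for u in array.units:
            if u.is_repeat:
                u.observed_sequence = seq[u.start : u.end]
            else:
                u.sequence = seq[u.start : u.end]
                u.lost = u.lost and u.start == u.end
        array.check_structure()
        select_representative_repeat(array)
    # extra terminal bases (and any other edits) -> annotation labels
    annotate_insertions(array, genome)
    return array


# ---------------------------------------------------------------------------
# insertion / mismatch / deletion annotation


def annotate_insertions(array: CrisprArray, genome: GenomeRecord) -> CrisprArray:
    """Annotate each repeat's edits relative to the representative.

    Substitutions become (representative column, base) records, runs of
    extra bases become (1-based forward-genome position, bases) insertion
    records — keeping the representative itself gap-free — and missing runs
    become (representative column, length) deletion records.
    """
    rep = array.representative_repeat or select_representative_repeat(array)[0]
    n = len(genome.sequence)
    for u in array.units:
        if not u.is_repeat:
            continue
        u.mismatch_positions = []
        u.insertions = []
        u.deletions = []
        obs = u.observed_sequence
        if obs == rep:
            continue
        rrow, orow = pairwise_rows(rep, obs)
        col = 0  # representative column
        opos = 0  # offset within the observed repeat, reported strand
        i = 0
        m = len(rrow)
        while i < m:
            rch, och = rrow[i], orow[i]
            if rch != GAP and och != GAP:
                if rch != och:
                    u.mismatch_positions.append((col, och))
                col += 1
                opos += 1
                i += 1
            elif rch == GAP:
                j = i
                while j < m and rrow[j] == GAP:
                    j += 1
                bases = orow[i:j]
                if array.was_reversed:
                    pos_fwd = n - (u.start + opos)
                else:
                    pos_fwd = u.start + opos + 1
                u.insertions.append((pos_fwd, bases))
                opos += j - i
                i = j
            else:  # deletion in the observed repeat
                j = i
                while j < m and orow[j] == GAP and rrow[j] != GAP:
                    j += 1
                u.deletions.append((col, j - i))
                col += j - i
                i = j
    return array


# ---------------------------------------------------------------------------
# recovery of repeats from long spacers


def recover_repeats_from_long_spacers(
    array: CrisprArray, genome: GenomeRecord, config: RefinementConfig | None = None
) -> CrisprArray:
    """Split unusually long spacers that hide a degenerate repeat.

    Spacers longer than ``long_spacer_factor`` x the median are scanned for
    an ungapped local match to the representative; a hit passing the
    recovery identity threshold splits the spacer into spacer / degenerate
    repeat / spacer, with empty flanks recorded as lost spacers.  Partial
    repeat deletions surface later as deletion annotations.
    """
    config = config or RefinementConfig()
    rep0 = array.representative_repeat or select_representative_repeat(array)[0]
    threshold = config.recovery_identity * 100.0
    seq = genome.sequence
    changed = True
    while changed:
        changed = False
        spacers = [u for u in array.units if not u.is_repeat and not u.lost]
        if len(spacers) < 3:
            break
        med = median(len(s) for s in spacers)
        rep = array.representative_repeat
        for idx, u in enumerate(array.units):
            if u.is_repeat or u.lost:
                continue
            if len(u) <= config.long_spacer_factor * med:
                continue
            # gaps allowed here: a repeat with an internal deletion spans two
            # ungapped blocks, so the whole representative is fitted into the
            # spacer under the same unit-cost scheme as the identity metric
            hit = fit_align(rep, u.sequence)
            if hit is None:
                continue
            ws, we, identity = hit
            cstart, cend = u.start + ws, u.start + we
            if cend - cstart < config.min_repeat_length:
                continue
            if identity < threshold - 1e-9:
                continue
            left = SpacerUnit(u.start, cstart, seq[u.start:cstart], lost=(u.start == cstart))
            new_rep = RepeatUnit(cstart, cend, seq[cstart:cend])
            right = SpacerUnit(cend, u.end, seq[cend : u.end], lost=(cend == u.end))
            array.units[idx : idx + 1] = [left, new_rep, right]
            array.check_structure()
            select_representative_repeat(array)
            changed = True
            break
    return array


# ---------------------------------------------------------------------------
# the full refinement driver


def refine(
    candidate: CrisprArray,
    genome: GenomeRecord,
    repeat_bank=None,
    config: RefinementConfig | None = None,
) -> CrisprArray:
    """Run the full refinement cascade on a crude seed candidate.

    Repeat-end extension and the tandem filter run first (tandem
    classification is terminal); the extend / boundary-refine / trim trio
    then iterates to a fixed point (bounded), and terminal-gap correction,
    long-spacer recovery and edit annotation finish the array.
    """
    config = config or RefinementConfig()
    array = candidate

    for _outer in range(3):
        array = extend_repeat_ends(array, genome, config)
        if TANDEM_FLAG in array.flags:
            return array
        if filter_tandem_repeats(array, config) == "tandem":
            array.flags.add(TANDEM_FLAG)
            return array
        select_representative_repeat(array)

        for _ in range(config.max_iterations):
            before = _signature(array)
            array = extend_array(array, genome, config)
            array = refine_repeat_boundaries(array, genome, repeat_bank, config)
            array = trim_array(array, config)
            if _signature(array) == before:
                break

        # a seeding artifact fused away re-opens the widening question
        if fuse_low_identity_internal_repeats(array, config) == 0:
            break
        if array.n_repeats < 2:
            return array

    array = correct_terminal_gaps(array, genome)
    array = recover_repeats_from_long_spacers(array, genome, config)
    array = annotate_insertions(array, genome)

    if filter_tandem_repeats(array, config) == "tandem":
        array.flags.add(TANDEM_FLAG)
    return array
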