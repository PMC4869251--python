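"""Alignment kernels for repeat refinement.

Three tools, all tuned for short (<~60 nt) near-identical nucleotide
sequences:

* :func:`align_repeats` — a light star multiple alignment of the repeat (or
  spacer) set, sufficient for columns-of-near-identical-rows bookkeeping;
* :func:`repeat_identity` — the percent-identity metric used throughout
  refinement, with matches and gaps weighted +1/−1 against the reference
  length;
* :func:`local_align_sweep` — a Smith–Waterman search over an increasing
  gap-penalty ladder that returns the best *ungapped* local alignment.

The pairwise dynamic programming itself is Biopython's PairwiseAligner; the
scoring conventions, sweep logic and star-merge are defined here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import islice

from Bio import Align

GAP = "-"

# Penalty ladder for the best-ungapped-alignment search.
SWEEP_PENALTIES = [5.5 + 0.5 * i for i in range(10)]  # 5.5 .. 10.0

_MAX_ALTERNATIVES = 64  # cap on co-optimal alignments examined per call


def _unit_cost_aligner() -> Align.PairwiseAligner:
    # match +1, mismatch 0, any gap −1: the global score is exactly
    # (#matches − #gap columns).
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = 0
    a.open_gap_score = -1
    a.extend_gap_score = -1
    return a


def _local_aligner(gap_penalty: float) -> Align.PairwiseAligner:
    # EMBOSS water nucleotide defaults (+5/−4) with a linear gap penalty.
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 5
    a.mismatch_score = -4
    a.open_gap_score = -gap_penalty
    a.extend_gap_score = -gap_penalty
    return a


_UNIT = _unit_cost_aligner()


def pairwise_rows(a: str, b: str) -> tuple[str, str]:
    """Gapped rows of one optimal global unit-cost alignment of a vs b."""
    aln = _UNIT.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def repeat_identity(observed: str, reference: str) -> float:
    """Percent identity of ``observed`` against ``reference``.

    max(0, matches − gap columns) / len(reference) × 100 under the optimal
    global alignment with unit costs (gaps, insertions and deletions all
    penalised −1).  repeat_identity(x, x) == 100 for every x.
    """
    if not observed or not reference:
        raise ValueError("repeat_identity requires two non-empty sequences")
    score = _UNIT.score(observed, reference)
    return max(0.0, score) / len(reference) * 100.0


def column_identity(column: list[str]) -> float:
    """Modal non-gap base count over the number of rows (gaps never match)."""
    if not column:
        raise ValueError("empty column")
    counts = Counter(c for c in column if c not in (GAP, "N"))
    top = max(counts.values()) if counts else 0
    return top / len(column)


@dataclass
class RepeatAlignment:
    """A gapped multiple alignment; ungapping row i returns input i exactly."""

    rows: list[str]
    consensus: str

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def columns(self) -> list[list[str]]:
        return [[r[i] for r in self.rows] for i in range(self.n_columns)]

    def column_identities(self) -> list[float]:
        return [column_identity(col) for col in self.columns()]


def align_repeats(sequences: list[str]) -> RepeatAlignment:
    """Star multiple alignment against the longest input sequence.

    Adequate for the near-identical case this package deals in: identical
    inputs align gap-free, and a single insertion in one sequence yields one
    gap column in all others.  Consensus ties break alphabetically; columns
    where gaps are in the majority are dropped from the consensus.
    """
    if len(sequences) < 2 or any(not s for s in sequences):
        raise ValueError("align_repeats needs >= 2 non-empty sequences")
    center = max(sequences, key=len)
    lc = len(center)

    # Pairwise-align every row to the center and note, for each center
    # position, how many inserted bases precede it in that row.
    parsed = []  # per row: (ins_before: list[str] of len lc+1, at: list[str] of len lc)
    max_ins = [0] * (lc + 1)
    for seq in sequences:
        crow, srow = pairwise_rows(center, seq)
        ins_before = [""] * (lc + 1)
        at = [""] * lc
        ci = 0
        for cch, sch in zip(crow, srow):
            if cch == GAP:
                ins_before[ci] += sch
            else:
                at[ci] = sch
                ci += 1
        parsed.append((ins_before, at))
        for i in range(lc + 1):
            max_ins[i] = max(max_ins[i], len(ins_before[i]))

    rows = []
    for ins_before, at in parsed:
        out = []
        for i in range(lc + 1):
            block = ins_before[i]
            out.append(block + GAP * (max_ins[i] - len(block)))
            if i < lc:
                out.append(at[i])
        rows.append("".join(out))

    consensus = []
    for i in range(len(rows[0])):
        col = [r[i] for r in rows]
        gaps = col.count(GAP)
        if gaps * 2 > len(col):
            continue
        counts = Counter(c for c in col if c != GAP)
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        consensus.append(best)
    return RepeatAlignment(rows=rows, consensus="".join(consensus))


@dataclass(frozen=True)
class LocalHit:
    """An ungapped local alignment of a query inside a window."""

    query_start: int
    query_end: int
    window_start: int
    window_end: int
    identity: float  # percent over the matched length
    score: float

    @property
    def length(self) -> int:
        return self.query_end - self.query_start


def _hit_from_block(query: str, window: str, qs: int, qe: int, ws: int) -> LocalHit:
    matches = sum(1 for a, b in zip(query[qs:qe], window[ws : ws + (qe - qs)]) if a == b)
    length = qe - qs
    mism = length - matches
    return LocalHit(
        query_start=qs,
        query_end=qe,
        window_start=ws,
        window_end=ws + length,
        identity=matches / length * 100.0,
        score=5.0 * matches - 4.0 * mism,
    )


def local_align_sweep(query: str, window: str) -> LocalHit | None:
    """Best non-gapped local alignment of ``query`` inside ``window``.

    Runs Smith–Waterman (+5 match / −4 mismatch) at each gap penalty of the
    5.5→10 (step 0.5) ladder and returns the first gap-free optimum; if every
    level still gaps, the highest-penalty alignment is stripped to its
    longest contiguous block.  Ties break toward the longer alignment, then
    the leftmost window position.  Returns None when nothing scores > 0.
    """
    if len(query) < 5:
        raise ValueError("query must be >= 5 nt")
    if not window:
        return None

    last_blocks: list[tuple[int, int, int]] | None = None
    for penalty in SWEEP_PENALTIES:
        aligner = _local_aligner(penalty)
        try:
            alignments = aligner.align(query, window)
        except (OverflowError, MemoryError):  # pragma: no cover - giant inputs
            continue
        if alignments.score <= 0:
            break
        best = None
        best_key = None
        for aln in islice(alignments, _MAX_ALTERNATIVES):
            qblocks, wblocks = aln.aligned
            gapped = len(qblocks) > 1
            length = sum(int(e) - int(s) for s, e in qblocks)
            key = (0 if not gapped else 1, -length, int(wblocks[0][0]))
            if best_key is None or key < best_key:
                best_key = key
                best = (qblocks, wblocks, gapped)
        qblocks, wblocks, gapped = best
        if not gapped:
            qs, qe = int(qblocks[0][0]), int(qblocks[0][1])
            ws = int(wblocks[0][0])
            return _hit_from_block(query, window, qs, qe, ws)
        last_blocks = [
            (int(qs), int(qe), int(ws))
            for (qs, qe), (ws, _we) in zip(qblocks, wblocks)
        ]

    if last_blocks is None:
        return None
    # Every positive-scoring penalty level gapped: take the longest
    # contiguous block of the highest such level.
    qs, qe, ws = max(last_blocks, key=lambda blk: (blk[1] - blk[0], -blk[2]))
    hit = _hit_from_block(query, window, qs, qe, ws)
    return hit if hit.score > 0 else None


@dataclass(frozen=True)
class GappedHit:
    """Full span of the best local alignment, gaps allowed (used to locate
    repeats carrying internal deletions, which no ungapped block can span)."""

    query_start: int
    query_end: int
    window_start: int
    window_end: int
    score: float


def local_align_gapped(query: str, window: str, gap_penalty: float = 5.5) -> GappedHit | None:
    """Smith–Waterman span of query vs window at the lowest sweep penalty."""
    if len(query) < 5 or not window:
        return None
    aligner = _local_aligner(gap_penalty)
    alignments = aligner.align(query, window)
    if alignments.score <= 0:
        return None
    best = None
    best_key = None
    for aln in islice(alignments, _MAX_ALTERNATIVES):
        qblocks, wblocks = aln.aligned
        qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
        ws, we = int(wblocks[0][0]), int(wblocks[-1][1])
        key = (-(qe - qs), ws)
        if best_key is None or key < best_key:
            best_key = key
            best = GappedHit(qs, qe, ws, we, float(alignments.score))
    return best


def fit_align(reference: str, window: str) -> tuple[int, int, float] | None:
    """Best window subregion matching the *whole* reference.

    Global unit-cost alignment of the reference against the window with
    free end gaps on the window side, so the returned subregion is the one
    maximising :func:`repeat_identity` against the reference.  Returns
    (window start, window end, identity %) or None for an empty fit.
    """
    if not reference or not window:
        return None
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = 0
    a.open_gap_score = -1
    a.extend_gap_score = -1
    # unmatched window ends are free (attribute renamed across Biopython versions)
    if hasattr(a, "end_insertion_score"):
        a.end_insertion_score = 0
    else:  # pragma: no cover - older Biopython
        a.target_end_gap_score = 0
    alignments = a.align(reference, window)
    best = None
    for aln in islice(alignments, _MAX_ALTERNATIVES):
        _rblocks, wblocks = aln.aligned
        if len(wblocks) == 0:
            continue
        ws, we = int(wblocks[0][0]), int(wblocks[-1][1])
        if we <= ws:
            continue
        key = (we - ws, ws)  # co-optimal fits: shortest, then leftmost region
        if best is None or key < best[0]:
            best = (key, ws, we)
    if best is None:
        return None
    _, ws, we = best
    return ws, we, repeat_identity(window[ws:we], reference)
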