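"""Seed detection: putative CRISPRs as clusters of a repeated word.

An array betrays itself as two or more identical short words separated by
bounded gaps (the candidate spacers).  The word length trades sensitivity
for speed: the shortest experimentally verified repeats are ~23 nt, so the
default 11-mer word still hits every repeat even with several mutations.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .model import CrisprArray, GenomeRecord, RepeatUnit, SpacerUnit


@dataclass(frozen=True)
class SeedCluster:
    """Occurrences of one repeated word whose successive gaps are spacer-sized."""

    word: str
    occurrences: tuple[int, ...]
    genome_id: str

    @property
    def span(self) -> tuple[int, int]:
        return self.occurrences[0], self.occurrences[-1] + len(self.word)


def compute_space_bounds(word_length: int) -> tuple[int, int]:
    """Permitted gap (candidate spacer length) between repeated words.

    min = max(0, 30 - word_length); max = 125 + word_length.  The minimum is
    clamped at 0 for words >= 30 nt, where the raw formula goes negative.
    """
    if word_length <= 5:
        raise ValueError("word sizes must be >5")
    return max(0, 30 - word_length), 125 + word_length


def scan_repeated_words(
    genome: GenomeRecord, word_length: int = 11, min_occurrences: int = 3
) -> list[SeedCluster]:
    """Find maximal runs of an identical word with spacer-sized gaps.

    Words containing N never match.  Runs with fewer than ``min_occurrences``
    occurrences are dropped; clusters whose genomic spans overlap (shifted
    copies of the same repeat region) are merged into the single cluster
    with the most occurrences.
    """
    if min_occurrences < 2:
        raise ValueError("min_occurrences must be >= 2")
    min_space, max_space = compute_space_bounds(word_length)
    seq = genome.sequence
    if len(seq) < word_length:
        return []

    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - word_length + 1):
        w = seq[i : i + word_length]
        if "N" not in w:
            positions[w].append(i)

    clusters: list[SeedCluster] = []
    for word, occ in positions.items():
        if len(occ) < 2:
            continue
        run = [occ[0]]
        for p in occ[1:]:
            gap = p - (run[-1] + word_length)
            if min_space <= gap <= max_space:
                run.append(p)
            else:
                if len(run) >= min_occurrences:
                    clusters.append(SeedCluster(word, tuple(run), genome.id))
                run = [p]
        if len(run) >= min_occurrences:
            clusters.append(SeedCluster(word, tuple(run), genome.id))

    return _merge_overlapping(clusters)


def _merge_overlapping(clusters: list[SeedCluster]) -> list[SeedCluster]:
    """Group clusters with overlapping spans; keep the best per group.

    Best = most occurrences, then widest span, then leftmost, then
    lexicographically smallest word (full determinism).
    """
    if not clusters:
        return []
    clusters = sorted(clusters, key=lambda c: c.span)
    groups: list[list[SeedCluster]] = []
    cur = [clusters[0]]
    cur_end = clusters[0].span[1]
    for c in clusters[1:]:
        s, e = c.span
        if s < cur_end:
            cur.append(c)
            cur_end = max(cur_end, e)
        else:
            groups.append(cur)
            cur = [c]
            cur_end = e
    groups.append(cur)

    best = []
    for g in groups:
        best.append(
            min(
                g,
                key=lambda c: (
                    -len(c.occurrences),
                    -(c.span[1] - c.span[0]),
                    c.span[0],
                    c.word,
                ),
            )
        )
    return sorted(best, key=lambda c: c.span)


def cluster_to_candidate(cluster: SeedCluster, genome: GenomeRecord) -> CrisprArray:
    """Crude array: repeats are the word occurrences, spacers the gaps.

    Downstream refinement widens the repeats to their true extent.
    """
    w = len(cluster.word)
    seq = genome.sequence
    units = []
    occ = cluster.occurrences
    for i, p in enumerate(occ):
        units.append(RepeatUnit(p, p + w, seq[p : p + w]))
        if i + 1 < len(occ):
            q = occ[i + 1]
            units.append(SpacerUnit(p + w, q, seq[p + w : q], lost=(p + w == q)))
    arr = CrisprArray(genome_id=genome.id, units=units)
    arr.check_structure()
    return arr
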