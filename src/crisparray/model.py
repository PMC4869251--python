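"""Core data types and coordinate conventions for CRISPR array analysis.

A CRISPR array is an alternating run of near-identical direct repeats and
unique spacers.  Every interval in this package is 0-based half-open and
lives on the *reported* strand of its genome: a freshly detected array uses
forward-genome coordinates; after reverse complementation (when the array is
transcribed from the minus strand) coordinates are remapped onto the reverse
strand axis, so that ``revcomp(genome)[start:end]`` is always the unit
sequence.  Conversion to the 1-based inclusive coordinates used in text
reports and GFF3 happens only at the output layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


class CoordinateError(ValueError):
    """A unit interval falls outside its genome."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open ``[start, end)`` -> 1-based inclusive ``(first, last)``."""
    return start + 1, end


def from_one_based(first: int, last: int) -> tuple[int, int]:
    """Inverse of :func:`to_one_based`."""
    return first - 1, last


@dataclass(frozen=True)
class AnnotationFeature:
    """A gene/CDS-level feature from a GenBank record.

    ``start``/``end`` are 0-based half-open forward-genome coordinates.
    """

    kind: str
    start: int
    end: int
    strand: str  # '+' or '-'
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"feature {self.kind}: invalid interval [{self.start}, {self.end})"
            )


@dataclass
class GenomeRecord:
    """A named nucleotide sequence with optional annotation features."""

    id: str
    sequence: str
    features: list[AnnotationFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"genome {self.id!r}: unsupported characters {sorted(bad)}; "
                "only A/C/G/T/N are accepted (IUPAC ambiguity codes are rejected)"
            )
        self.sequence = seq
        for f in self.features:
            if f.end > len(seq):
                raise CoordinateError(
                    f"feature {f.kind} [{f.start}, {f.end}) exceeds genome length {len(seq)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RepeatUnit:
    """One direct-repeat instance.

    Edit annotations are relative to the array's representative repeat:
    ``mismatch_positions`` are (representative column, observed base),
    ``deletions`` are (representative column, length) and ``insertions`` are
    (1-based forward-genome position, inserted bases as read on the reported
    strand).
    """

    start: int
    end: int
    observed_sequence: str
    mismatch_positions: list[tuple[int, str]] = field(default_factory=list)
    insertions: list[tuple[int, str]] = field(default_factory=list)
    deletions: list[tuple[int, int]] = field(default_factory=list)

    is_repeat = True

    @property
    def sequence(self) -> str:
        return self.observed_sequence

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SpacerUnit:
    """One spacer instance; ``lost`` marks a fully deleted spacer (length 0)."""

    start: int
    end: int
    sequence: str
    lost: bool = False

    is_repeat = False

    def __post_init__(self) -> None:
        if self.lost and self.start != self.end:
            raise ValueError("lost spacer must have zero length")

    def __len__(self) -> int:
        return self.end - self.start


Unit = RepeatUnit | SpacerUnit


@dataclass
class ScoreBreakdown:
    """The nine named quality-score components, their sum and the category."""

    components: dict[str, float]
    total: float
    category: str  # good | questionable | discarded

    @classmethod
    def from_components(
        cls, components: dict[str, float], good_cutoff: float = 4.0
    ) -> "ScoreBreakdown":
        total = sum(components.values())
        if total < 0:
            category = "discarded"
        elif total >= good_cutoff:
            category = "good"
        else:
            category = "questionable"
        return cls(dict(components), total, category)


@dataclass(frozen=True)
class ReferenceRepeat:
    """A known direct repeat in validated 5'->3' orientation."""

    sequence: str
    family: str
    cas_type: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) < 20:
            raise ValueError(
                f"reference repeat {self.family!r}: length {len(self.sequence)} < 20"
            )


@dataclass
class CrisprArray:
    """An ordered alternating repeat/spacer structure on one genome."""

    genome_id: str
    units: list[Unit]
    orientation: str = "unknown"  # forward | reverse | unknown
    was_reversed: bool = False
    representative_repeat: str = ""
    alternative_repeat: str = ""
    score: ScoreBreakdown | None = None
    type_hints: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)
    direction_confidence: str = ""

    # -- structure -----------------------------------------------------
    def repeats(self) -> list[RepeatUnit]:
        return [u for u in self.units if u.is_repeat]

    def spacers(self) -> list[SpacerUnit]:
        return [u for u in self.units if not u.is_repeat]

    @property
    def n_repeats(self) -> int:
        return len(self.repeats())

    @property
    def start(self) -> int:
        return self.units[0].start

    @property
    def end(self) -> int:
        return self.units[-1].end

    def check_structure(self) -> None:
        """Raise if the alternating repeat/spacer invariants are broken."""
        units = self.units
        if len(units) < 3 or len(units) % 2 == 0:
            raise ValueError("array must be R,S,R,...,R with >= 2 repeats")
        for i, u in enumerate(units):
            if u.is_repeat != (i % 2 == 0):
                raise ValueError(f"unit {i} breaks repeat/spacer alternation")
        for a, b in zip(units, units[1:]):
            if a.end != b.start:
                raise ValueError(
                    f"units not contiguous at [{a.start},{a.end}) -> [{b.start},{b.end})"
                )

    def iter_units(self) -> Iterator[Unit]:
        return iter(self.units)


def reconstruct_span(array: CrisprArray, genome: GenomeRecord) -> str:
    """Genome substring covered by the array, on the reported strand.

    Equals the in-order concatenation of all unit sequences; a mismatch
    indicates corrupted coordinates and raises.
    """
    seq = revcomp(genome.sequence) if array.was_reversed else genome.sequence
    n = len(seq)
    for i, u in enumerate(array.units):
        kind = "repeat" if u.is_repeat else "spacer"
        if not (0 <= u.start <= u.end <= n):
            raise CoordinateError(
                f"{kind} unit {i} [{u.start}, {u.end}) outside genome of length {n}"
            )
    span = seq[array.units[0].start : array.units[-1].end]
    concat = "".join(u.sequence for u in array.units)
    if span != concat:
        raise CoordinateError(
            f"array on {array.genome_id}: unit sequences do not tile the span"
        )
    return span


def reverse_complement_array(array: CrisprArray, genome: GenomeRecord) -> CrisprArray:
    """Remap an array onto the opposite strand (an involution).

    New coordinates are ``L - old_end`` .. ``L - old_start`` on the reverse
    strand axis (L = genome length), unit order is reversed and unit
    sequences are reverse complemented, so the reported array always reads
    5'->3' on its strand.  Per-repeat edit annotations are remapped exactly:
    representative columns mirror, inserted bases are complemented while
    keeping their absolute forward-genome position.
    """
    n = len(genome.sequence)
    rep_len = len(array.representative_repeat)
    new_units: list[Unit] = []
    for u in reversed(array.units):
        ns, ne = n - u.end, n - u.start
        if u.is_repeat:
            new_units.append(
                RepeatUnit(
                    ns,
                    ne,
                    revcomp(u.observed_sequence),
                    mismatch_positions=[
                        (rep_len - 1 - c, b.translate(_COMPLEMENT))
                        for c, b in reversed(u.mismatch_positions)
                    ],
                    insertions=[(pos, revcomp(b)) for pos, b in reversed(u.insertions)],
                    deletions=[
                        (rep_len - c - ln, ln) for c, ln in reversed(u.deletions)
                    ],
                )
            )
        else:
            new_units.append(SpacerUnit(ns, ne, revcomp(u.sequence), lost=u.lost))
    flipped = {"forward": "reverse", "reverse": "forward"}.get(
        array.orientation, array.orientation
    )
    return replace(
        array,
        units=new_units,
        was_reversed=not array.was_reversed,
        orientation=flipped,
        representative_repeat=revcomp(array.representative_repeat),
        alternative_repeat=revcomp(array.alternative_repeat),
        type_hints=list(array.type_hints),
        flags=set(array.flags),
    )


def forward_interval(array: CrisprArray, start: int, end: int, genome_length: int) -> tuple[int, int]:
    """Map a reported-strand interval back to forward-genome coordinates."""
    if array.was_reversed:
        return genome_length - end, genome_length - start
    return start, end


def forward_unit_intervals(
    array: CrisprArray, genome_length: int
) -> list[tuple[int, int, bool]]:
    """All unit intervals in forward-genome coordinates, position-sorted —
    the orientation-agnostic shape of an array, for truth comparisons."""
    out = []
    for u in array.units:
        fs, fe = forward_interval(array, u.start, u.end, genome_length)
        out.append((fs, fe, u.is_repeat))
    return sorted(out)
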