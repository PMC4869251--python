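"""Deterministic synthetic genomes with planted CRISPR arrays.

The generator emulates the sequence phenomena the detector is built for:
AT-rich leaders, a 3' (leader-distal) gradient of repeat degeneration,
insertions and deletions in individual repeats, total spacer loss, the
ATTGAAA(N) boundary motif, and minus-strand arrays.  Every fixture carries
an exact truth array, so recovery can be measured boundary-for-boundary.

Two deliberate design points:

* mutations never touch the first ``protected_prefix`` bases of a repeat,
  so the word-level seed scan sees every planted unit and the *refinement*
  stages are what the fixtures exercise;
* the bases immediately flanking each repeat are forced to vary across
  units (a cycling pattern).  Without this the planted boundary is not
  identifiable: a column of identical spacer-start bases is
  indistinguishable from one more repeat column, and the truth would not
  be the unique maximum-likelihood boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CrisprArray, GenomeRecord, RepeatUnit, SpacerUnit, revcomp

BASES = np.array(list("ACGT"))
_CYCLE = "ACGT"


def _rng(seed_parts) -> np.random.Generator:
    return np.random.default_rng([int(p) & 0x7FFFFFFF for p in seed_parts])


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p)) if n > 0 else ""


def random_repeat(
    rng: np.random.Generator, length: int, forbid_motif: bool = True
) -> str:
    """A random repeat sequence; by default re-sampled until it carries no
    ATTGAAA on either strand, so orientation/boundary signals stay under
    the fixture's explicit control."""
    while True:
        r = _random_seq(rng, length)
        if not forbid_motif:
            return r
        if "ATTGAAA" not in r and "TTTCAAT" not in r:
            return r


def _mutate(
    seq: str, rng: np.random.Generator, n_mut: int, protected_prefix: int
) -> str:
    if n_mut <= 0:
        return seq
    positions = np.arange(protected_prefix, len(seq))
    if len(positions) < n_mut:
        n_mut = len(positions)
    chosen = rng.choice(positions, size=n_mut, replace=False)
    out = list(seq)
    for p in chosen:
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[rng.integers(0, 3)]
    return "".join(out)


@dataclass
class PlantSpec:
    """Recipe for one planted array.

    ``offset`` positions the cassette (leader + units) in the final genome;
    ``per_repeat_mutation_rate`` is the substitution rate of repeat copy i
    multiplied by ``three_prime_gradient ** i`` (rank from the leader);
    ``insertion_events``/``deletion_events`` are explicit
    (repeat index, offset within repeat, bases / length) edits;
    ``spacer_sequences`` overrides the uniform length sampler.
    """

    repeat: str
    n_repeats: int
    offset: int
    spacer_length: tuple[int, int] = (25, 45)
    per_repeat_mutation_rate: float = 0.0
    three_prime_gradient: float = 1.0
    terminal_mutations: int = 0  # extra substitutions in the last repeat only
    substitution_events: list[tuple[int, int, str]] = field(default_factory=list)
    insertion_events: list[tuple[int, int, str]] = field(default_factory=list)
    deletion_events: list[tuple[int, int, int]] = field(default_factory=list)
    spacer_loss_indices: list[int] = field(default_factory=list)
    spacer_sequences: list[str] | None = None
    leader_length: int = 200
    leader_at_fraction: float = 0.5
    motif_suffix: str = ""
    strand: str = "+"
    protected_prefix: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.repeat) + len(self.motif_suffix) < 11:
            raise ValueError("repeat must be >= 11 nt")
        if not 0.0 <= self.per_repeat_mutation_rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")


@dataclass
class PlantedCassette:
    """Internal: a realised cassette, in cassette-local 5'->3' coordinates."""

    sequence: str
    unit_bounds: list[tuple[int, int, bool, bool]]  # start, end, is_repeat, lost
    representative: str


def _realise(spec: PlantSpec, index: int, seed: int) -> PlantedCassette:
    rng = _rng([seed, spec.seed, index, 0xC5])
    base_repeat = spec.repeat + spec.motif_suffix
    L = len(base_repeat)
    n = spec.n_repeats

    # spacers
    if spec.spacer_sequences is not None:
        spacers = list(spec.spacer_sequences)
        if len(spacers) != n - 1:
            raise ValueError("need n_repeats - 1 spacer sequences")
    else:
        lo, hi = spec.spacer_length
        spacers = [
            _random_seq(rng, int(rng.integers(lo, hi + 1))) for _ in range(n - 1)
        ]
    for i in spec.spacer_loss_indices:
        spacers[i] = ""

    # repeat copies with the 3' degeneration gradient
    copies = []
    for i in range(n):
        rate = spec.per_repeat_mutation_rate * (spec.three_prime_gradient**i)
        n_mut = round(min(rate, 1.0) * L)
        copies.append(_mutate(base_repeat, rng, n_mut, spec.protected_prefix))
    if spec.terminal_mutations:
        copies[-1] = _mutate(
            copies[-1], rng, spec.terminal_mutations, spec.protected_prefix
        )
    for rep_idx, off, base in spec.substitution_events:
        c = copies[rep_idx]
        copies[rep_idx] = c[:off] + base.upper() + c[off + 1 :]
    for rep_idx, off, bases in spec.insertion_events:
        c = copies[rep_idx]
        copies[rep_idx] = c[:off] + bases.upper() + c[off:]
    for rep_idx, off, length in spec.deletion_events:
        c = copies[rep_idx]
        copies[rep_idx] = c[:off] + c[off + length :]

    # boundary identifiability: cycle the two bases at each end of every
    # spacer so neither the primary nor the one-weak-column extension rule
    # can ever carry a repeat boundary into a spacer
    if spec.spacer_sequences is None:
        for i, s in enumerate(spacers):
            if not s:
                continue
            pre = _CYCLE[i % 4] + _CYCLE[(i + 1) % 4]
            post = _CYCLE[(i + 2) % 4] + _CYCLE[(i + 3) % 4]
            if len(s) >= 4:
                spacers[i] = pre + s[2:-2] + post
            elif len(s) >= 2:
                spacers[i] = pre[:1] + s[1:-1] + post[-1:]
            else:
                spacers[i] = pre[:1]

    # leader: AT-rich 5' flank
    lead_rng = _rng([seed, spec.seed, index, 0x1EAD])
    at = spec.leader_at_fraction
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    leader = (
        "".join(lead_rng.choice(BASES, size=spec.leader_length, p=p))
        if spec.leader_length
        else ""
    )

    parts = [leader]
    bounds: list[tuple[int, int, bool, bool]] = []
    pos = len(leader)
    for i, c in enumerate(copies):
        parts.append(c)
        bounds.append((pos, pos + len(c), True, False))
        pos += len(c)
        if i < n - 1:
            s = spacers[i]
            parts.append(s)
            bounds.append((pos, pos + len(s), False, len(s) == 0))
            pos += len(s)
    return PlantedCassette("".join(parts), bounds, base_repeat)


def generate_genome(
    specs: list[PlantSpec],
    background_length: int,
    gc: float = 0.5,
    seed: int = 0,
    genome_id: str = "synthetic",
) -> tuple[GenomeRecord, list[CrisprArray]]:
    """Background sequence with each spec's cassette written in at its
    offset.  Returns the genome and one truth array per spec, in the
    reported-strand convention the pipeline itself emits (minus-strand
    truths carry reverse-axis coordinates and ``was_reversed=True``).
    """
    bg_rng = _rng([seed, 0xB6])
    genome_seq = list(_random_seq(bg_rng, background_length, gc))
    n = background_length

    placed: list[tuple[int, int]] = []
    realised = []
    for index, spec in enumerate(specs):
        cassette = _realise(spec, index, seed)
        span = (spec.offset, spec.offset + len(cassette.sequence))
        if span[1] > n or span[0] < 0:
            raise ValueError(f"cassette {index} exceeds the genome: {span}")
        for o in placed:
            if span[0] < o[1] and o[0] < span[1]:
                raise ValueError(f"cassette {index} overlaps another planted span")
        placed.append(span)
        realised.append((spec, cassette))
        text = (
            cassette.sequence if spec.strand == "+" else revcomp(cassette.sequence)
        )
        genome_seq[span[0] : span[1]] = list(text)

    genome = GenomeRecord(genome_id, "".join(genome_seq))

    truths = []
    for (spec, cassette), span in zip(realised, placed):
        clen = len(cassette.sequence)
        units = []
        for s, e, is_rep, lost in cassette.unit_bounds:
            if spec.strand == "+":
                gs, ge = span[0] + s, span[0] + e
            else:
                # cassette-local 5'->3' maps onto the reverse strand axis
                gs = (n - span[0] - clen) + s
                ge = (n - span[0] - clen) + e
            seq_axis = genome.sequence if spec.strand == "+" else revcomp(genome.sequence)
            text = seq_axis[gs:ge]
            if is_rep:
                units.append(RepeatUnit(gs, ge, text))
            else:
                units.append(SpacerUnit(gs, ge, text, lost=lost))
        truth = CrisprArray(
            genome_id=genome_id,
            units=units,
            orientation="forward" if spec.strand == "+" else "reverse",
            was_reversed=(spec.strand == "-"),
            representative_repeat=cassette.representative,
        )
        truths.append(truth)
    return genome, truths


def generate_tandem_decoy(
    period_unit: str,
    n_copies: int,
    divergence: float,
    seed: int = 0,
    flank: int = 400,
    genome_id: str = "tandem_decoy",
) -> GenomeRecord:
    """A tandem-repeat decoy: adjacent copies of one unit with per-copy
    divergence, embedded in random flanks.  A correct pipeline rejects it
    at default settings."""
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = _rng([seed, 0x7A2D])
    copies = []
    for _ in range(n_copies):
        n_mut = round(divergence * len(period_unit))
        copies.append(_mutate(period_unit.upper(), rng, n_mut, 0))
    seq = _random_seq(rng, flank) + "".join(copies) + _random_seq(rng, flank)
    return GenomeRecord(genome_id, seq)
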