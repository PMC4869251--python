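"""Ready-made fixture scenarios for benchmarking the pipeline.

Each scenario realises one of the sequence phenomena the detector is
designed around, at the package's standard study conditions (repeats
23-48 nt, spacers 25-45 nt, 3-30 repeats, AT-rich leaders), and returns
the genome together with its exact truth.  Scenarios that plant edits
verify, and if necessary re-sample, until the planted truth is the unique
optimum of the detection objective (no shared seed word for a copy meant
to hide in a spacer; no coincidental flank match outscoring the planted
extent) — otherwise "recovery" would be ill-posed rather than hard.

All scenarios are bit-reproducible from their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import fit_align, repeat_identity
from .model import AnnotationFeature, CrisprArray, GenomeRecord, ReferenceRepeat
from .simulate import PlantSpec, _rng, generate_genome, random_repeat

LEADER_AT = 0.72  # AT fraction of planted leaders (vs. 0.50 background)


def _background_for(spec: PlantSpec, margin: int = 400) -> int:
    lo, hi = spec.spacer_length
    unit = len(spec.repeat) + len(spec.motif_suffix) + hi
    return spec.offset + spec.leader_length + spec.n_repeats * unit + margin


def scenario_clean(seed: int, n_repeats: int | None = None, strand: str = "+"):
    """A clean planted array: no mutations, boundaries exactly plantable."""
    rng = _rng([seed, 0xC1])
    length = int(rng.integers(23, 49))
    n = n_repeats if n_repeats is not None else int(rng.integers(3, 31))
    spec = PlantSpec(
        repeat=random_repeat(rng, length),
        n_repeats=n,
        offset=300,
        spacer_length=(25, 45),
        leader_at_fraction=LEADER_AT,
        strand=strand,
        seed=seed,
    )
    return generate_genome([spec], _background_for(spec), seed=seed)


def scenario_oriented(
    seed: int, strand: str | None = None, mutation_rate: float = 0.008
):
    """An array with full orientation signal: AT leader, 3' ATTGAAA(N)
    motif and (optionally) a mild leader-distal degeneration gradient.

    ``mutation_rate=0`` gives the clean variant used for the strand-symmetry
    suite, where planted boundaries admit exactly one interpretation."""
    rng = _rng([seed, 0xD1])
    if strand is None:
        strand = "+" if rng.integers(0, 2) == 0 else "-"
    length = int(rng.integers(24, 40))
    spec = PlantSpec(
        repeat=random_repeat(rng, length),
        n_repeats=int(rng.integers(6, 12)),
        offset=300,
        spacer_length=(26, 40),
        leader_at_fraction=0.75,
        motif_suffix="ATTGAAAC",
        per_repeat_mutation_rate=mutation_rate,
        three_prime_gradient=1.35 if mutation_rate else 1.0,
        strand=strand,
        seed=seed,
    )
    return generate_genome([spec], _background_for(spec), seed=seed)


@dataclass
class DegenerateEndCase:
    genome: GenomeRecord
    truth: CrisprArray
    terminal_identity: float  # percent, planted terminal repeat vs clean repeat
    should_retain: bool  # identity strictly above the 66 % trim cutoff


def scenario_degenerate_end(seed: int) -> DegenerateEndCase:
    """An 8-repeat array whose last repeat carries a planted substitution
    load between ~5 % and ~45 %, straddling the 66 % trim cutoff."""
    rng = _rng([seed, 0xDE])
    length = int(rng.integers(28, 41))
    max_mut = length - 11  # mutations stay clear of the seed prefix
    n_mut = int(rng.integers(2, min(max_mut, round(0.45 * length)) + 1))
    spec = PlantSpec(
        repeat=random_repeat(rng, length),
        n_repeats=8,
        offset=300,
        spacer_length=(26, 40),
        leader_at_fraction=LEADER_AT,
        terminal_mutations=n_mut,
        seed=seed,
    )
    genome, truths = generate_genome([spec], _background_for(spec), seed=seed)
    truth = truths[0]
    # label with the same unit-cost identity the trim rule applies (a gapped
    # alignment can score above the naive substitution count)
    identity = repeat_identity(
        truth.repeats()[-1].observed_sequence, truth.representative_repeat
    )
    return DegenerateEndCase(genome, truth, identity, identity > 66.0)


def scenario_fused_spacer(seed: int):
    """A 9-repeat array whose 5th repeat lost 3 mid-repeat bases and gained
    a substitution, leaving no intact seed word: the copy is invisible to
    word seeding and fuses its two spacers, exercising long-spacer repeat
    recovery.  Re-samples until the planted copy is the unique optimum of
    the recovery fit."""
    attempt = 0
    while True:
        sub_seed = (seed * 131 + attempt) & 0x3FFFFFFF
        rng = _rng([sub_seed, 0xF5])
        rep = random_repeat(rng, 29)
        obs = rep[:10] + rep[13:]
        swap = "A" if obs[18] != "A" else "G"
        obs = obs[:18] + swap + obs[19:]
        attempt += 1
        if any(obs[i : i + 11] in rep for i in range(len(obs) - 10)):
            continue
        spec = PlantSpec(
            repeat=rep,
            n_repeats=9,
            offset=300,
            spacer_length=(28, 34),
            leader_at_fraction=0.75,
            deletion_events=[(4, 10, 3)],
            substitution_events=[(4, 21, swap)],
            seed=sub_seed,
        )
        genome, truths = generate_genome([spec], _background_for(spec), seed=sub_seed)
        truth = truths[0]
        # the recovery objective must point exactly at the planted copy
        units = truth.units
        fused_start, fused_end = units[7].start, units[9].end
        degenerate = units[8]
        fit = fit_align(rep, genome.sequence[fused_start:fused_end])
        if fit is None:
            continue
        ws, we, _ = fit
        if (fused_start + ws, fused_start + we) != (degenerate.start, degenerate.end):
            continue
        return genome, truth


def scenario_max_score(seed: int):
    """The all-maxima fixture: a clean in-range array whose repeat is a
    known (synthetic bank) repeat ending in the ATTGAAA(N) motif, in a
    genome annotated with cas1/cas2/cas3 genes.  Every score component is
    at its maximum, so the total is exactly 13."""
    rng = _rng([seed, 0x13])
    core = random_repeat(rng, 22)
    repeat = core + "ATTGAAAC"  # 30 nt, motif at the 3' end
    spec = PlantSpec(
        repeat=repeat,
        n_repeats=8,
        offset=300,
        spacer_length=(28, 42),
        leader_at_fraction=0.75,
        seed=seed,
    )
    genome, truths = generate_genome([spec], _background_for(spec), seed=seed)
    for i, gene in enumerate(("cas1", "cas2", "cas3")):
        genome.features.append(
            AnnotationFeature(
                "gene", 10 + 100 * i, 100 + 100 * i, "+", {"gene": gene}
            )
        )
    # synthetic bank entry: the planted repeat itself (labelled synthetic)
    from .annotation import RepeatBank

    bank = RepeatBank([ReferenceRepeat(repeat, "synthetic-max", "I-E")])
    return genome, truths[0], bank


def scenario_jannaschii_like(seed: int):
    """A genuine array with a run of 7 identical spacers followed by
    distinct ones — a natural duplication pattern a tandem filter must not
    reject."""
    rng = _rng([seed, 0x3A])
    rep = random_repeat(rng, 30)
    dup = random_repeat(rng, 32, forbid_motif=False)
    spacers = [dup] * 7 + [random_repeat(rng, 32, forbid_motif=False) for _ in range(16)]
    spec = PlantSpec(
        repeat=rep,
        n_repeats=24,
        offset=300,
        spacer_sequences=spacers,
        leader_at_fraction=LEADER_AT,
        seed=seed,
    )
    return generate_genome([spec], _background_for(spec), seed=seed)
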