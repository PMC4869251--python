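"""Nine-component quality score for predicted arrays.

Each component captures a biological property of genuine CRISPR arrays
(cas genes nearby, a known repeat family, the 3' boundary motif, internal
repeat homogeneity, canonical repeat and spacer lengths, spacer
uniqueness) and contributes a bounded positive or negative value; the
array's score is their sum.  Arrays scoring >= 4.0 are "good", in [0, 4)
"questionable", and below 0 discarded.  The component ranges are fixed by
the method's published description; the linear maps inside those ranges
are this package's own calibration and are fully overridable through
:class:`ScoringConfig`.  The maximum attainable total is 13.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

from .align import repeat_identity
from .annotation import BankMatch, CasGeneHit
from .model import CrisprArray, GenomeRecord, ScoreBreakdown

COMPONENT_NAMES = [
    "cas_gene_bonus",
    "known_repeat_bonus",
    "motif_bonus",
    "repeat_identity_metric",
    "repeat_dissimilarity_penalty",
    "repeat_length_metric",
    "spacer_length_metric",
    "spacer_identity_metric",
    "repeat_mismatch_metric",
]

COMPONENT_RANGES = {
    "cas_gene_bonus": (0.0, 1.0),
    "known_repeat_bonus": (0.0, 3.0),
    "motif_bonus": (0.0, 3.0),
    "repeat_identity_metric": (0.0, 3.0),
    "repeat_dissimilarity_penalty": (-1.5, 0.0),
    "repeat_length_metric": (-3.0, 1.0),
    "spacer_length_metric": (-3.0, 0.0),
    "spacer_identity_metric": (-3.0, 1.0),
    "repeat_mismatch_metric": (-1.0, 1.0),
}


@dataclass
class ScoringConfig:
    good_cutoff: float = 4.0
    report_all_above: float = 0.0
    bank_min_identity: float = 90.0
    # component 4: mean repeat identity mapped linearly [0.80, 1.00] -> [0, 3]
    identity_lo: float = 0.80
    # component 6: repeat length sweet spot and hard edges
    repeat_len_good: tuple[int, int] = (23, 47)
    repeat_len_bad: tuple[int, int] = (17, 55)
    # component 7: median spacer length sweet spot and hard edges
    spacer_len_good: tuple[int, int] = (25, 50)
    spacer_len_bad: tuple[int, int] = (15, 70)

    def __post_init__(self) -> None:
        if self.good_cutoff < 0:
            raise ValueError("good_cutoff must be >= 0")


def _clamp(x: float, lo: float, hi: float) -> float:
    return max(lo, min(hi, x))


def _linear(x: float, x0: float, y0: float, x1: float, y1: float) -> float:
    if x1 == x0:
        return y0
    return y0 + (y1 - y0) * (x - x0) / (x1 - x0)


def _repeat_length_metric(length: int, cfg: ScoringConfig) -> float:
    g0, g1 = cfg.repeat_len_good
    b0, b1 = cfg.repeat_len_bad
    if g0 <= length <= g1:
        return 1.0
    if length < g0:
        return _clamp(_linear(length, b0, -3.0, g0, 1.0), -3.0, 1.0)
    return _clamp(_linear(length, g1, 1.0, b1, -3.0), -3.0, 1.0)


def _spacer_length_metric(med: float, cfg: ScoringConfig) -> float:
    g0, g1 = cfg.spacer_len_good
    b0, b1 = cfg.spacer_len_bad
    if g0 <= med <= g1:
        return 0.0
    if med < g0:
        return _clamp(_linear(med, b0, -3.0, g0, 0.0), -3.0, 0.0)
    return _clamp(_linear(med, g1, 0.0, b1, -3.0), -3.0, 0.0)


def _spacer_identity_metric(spacers: list[str]) -> float:
    """+1 when all spacers are mutually < 50 % identical; otherwise graded
    down on the mean per-spacer best pairwise identity, reaching -3 at full
    duplication (every spacer a copy of another).  A single spacer carries
    no uniqueness evidence and earns nothing."""
    if len(spacers) < 2:
        return 0.0
    best = []
    for i, si in enumerate(spacers):
        best.append(
            max(repeat_identity(si, sj) for j, sj in enumerate(spacers) if j != i)
        )
    mean_best = sum(best) / len(best)
    if mean_best < 50.0:
        return 1.0
    return _clamp(_linear(mean_best, 50.0, 1.0, 100.0, -3.0), -3.0, 1.0)


def _repeat_mismatch_metric(identities: list[float]) -> float:
    """+1 when every repeat is >= 90 % identical to the representative;
    otherwise graded on the mean identity, -1 at <= 70 %."""
    if min(identities) >= 90.0:
        return 1.0
    mean_id = sum(identities) / len(identities)
    return _clamp(_linear(mean_id, 70.0, -1.0, 90.0, 1.0), -1.0, 1.0)


def _motif_at_3prime(rep: str) -> bool:
    i = rep.rfind("ATTGAAA")
    return i >= 0 and i + 7 >= len(rep) - 1  # motif, optionally one (N) base


def score_array(
    array: CrisprArray,
    genome: GenomeRecord,
    cas_hits: list[CasGeneHit] | None = None,
    bank_match: BankMatch | None = None,
    config: ScoringConfig | None = None,
) -> ScoreBreakdown:
    """Compute the nine components and their sum for a refined array."""
    cfg = config or ScoringConfig()
    cas_hits = cas_hits or []
    rep = array.representative_repeat
    if not rep:
        raise ValueError("score_array requires a representative repeat")
    repeats = [u.observed_sequence for u in array.repeats()]
    spacers = [s.sequence for s in array.spacers() if not s.lost]
    identities = [repeat_identity(r, rep) for r in repeats]
    mean_identity = sum(identities) / len(identities) / 100.0

    from collections import Counter

    variant_counts = Counter(repeats)
    recurrent_variants = sum(1 for c in variant_counts.values() if c >= 2)

    components = {
        "cas_gene_bonus": 1.0
        if any(h.gene_name in ("cas1", "cas2") for h in cas_hits)
        else 0.0,
        "known_repeat_bonus": 3.0
        if bank_match is not None and bank_match.identity >= cfg.bank_min_identity
        else 0.0,
        "motif_bonus": 3.0 if _motif_at_3prime(rep) else 0.0,
        # internal repeat consistency means little for tiny arrays: scale by
        # repeat count (0 at 2 repeats, full weight from 4 up)
        "repeat_identity_metric": _clamp(
            _linear(mean_identity, cfg.identity_lo, 0.0, 1.0, 3.0), 0.0, 3.0
        )
        * _clamp((len(repeats) - 2) / 2.0, 0.0, 1.0),
        "repeat_dissimilarity_penalty": -1.5 if recurrent_variants >= 2 else 0.0,
        "repeat_length_metric": _repeat_length_metric(len(rep), cfg),
        "spacer_length_metric": _spacer_length_metric(
            float(median([len(s) for s in spacers])) if spacers else 0.0, cfg
        ),
        "spacer_identity_metric": _spacer_identity_metric(spacers),
        "repeat_mismatch_metric": _repeat_mismatch_metric(identities),
    }
    breakdown = ScoreBreakdown.from_components(components, cfg.good_cutoff)
    array.score = breakdown
    return breakdown


def categorise_and_filter(
    arrays: list[CrisprArray],
    config: ScoringConfig | None = None,
    genome_lengths: dict[str, int] | None = None,
) -> list[CrisprArray]:
    """Drop discarded (total < 0) arrays; sort the rest by genome position.

    Questionable arrays keep a flag so reports can label them.  Reversed
    arrays sort by their forward-genome start when ``genome_lengths`` is
    provided (reported-strand coordinates otherwise).
    """
    cfg = config or ScoringConfig()

    def forward_start(a: CrisprArray) -> int:
        if a.was_reversed and genome_lengths and a.genome_id in genome_lengths:
            return genome_lengths[a.genome_id] - a.end
        return a.start

    kept = []
    for a in arrays:
        if a.score is None:
            raise ValueError("arrays must be scored before filtering")
        if a.score.total < 0:
            continue
        if a.score.total < cfg.good_cutoff:
            a.flags.add("questionable")
        kept.append(a)
    kept.sort(key=lambda a: (a.genome_id, forward_start(a)))
    return kept
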