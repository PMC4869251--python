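"""Array orientation prediction.

CRISPR arrays are transcribed from the leader end; reporting an array
5'->3' on the transcribed strand is what makes spacer ends, seed regions
and PAM positions meaningful downstream.  This module combines four
sequence-level orientation signals into a majority vote:

1. a reference-bank match on the plus or minus strand;
2. the ATTGAAA(N) motif at the repeat 3' end (a conserved transcription
   direction indicator) on either strand;
3. A/T richness of the flanks — the leader containing the promoter is
   AT-rich and sits 5' of the array;
4. the repeat degeneracy gradient — mutations accumulate at the
   leader-distal (3') end.

This is a deliberately simplified predictor built only from these
documented signals; the fully fledged published orientation method uses
additional predictors (including RNA secondary structure) that are out of
scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import repeat_identity
from .annotation import RepeatBank
from .model import CrisprArray, GenomeRecord, reverse_complement_array, revcomp

MOTIF = "ATTGAAA"

FLANK_WINDOW = 200  # nt examined on each side for leader AT-richness
AT_MARGIN = 0.05  # minimum AT-fraction difference to cast a vote
GRADIENT_MARGIN = 5.0  # percentage points of mean terminal-repeat identity


@dataclass(frozen=True)
class DirectionCall:
    orientation: str  # forward | reverse | unknown
    confidence: str  # HIGH | MEDIUM | LOW
    votes: dict

    def __post_init__(self) -> None:
        if self.orientation == "unknown" and self.confidence != "LOW":
            raise ValueError("unknown orientation must have LOW confidence")


def _at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("A") + seq.count("T")) / len(seq)


def _vote_bank(rep: str, bank: RepeatBank | None) -> int:
    if bank is None or len(rep) < 11:
        return 0
    m = bank.match(rep)
    if m is None:
        return 0
    return 1 if m.strand == "+" else -1


def _vote_motif(rep: str) -> int:
    """ATTGAAA at the 3' end as-is votes forward; its reverse complement at
    the 5' end votes reverse; both or neither abstains."""
    fwd = rep.rfind(MOTIF) >= 0 and rep.rfind(MOTIF) + len(MOTIF) >= len(rep) - 4
    rc = revcomp(MOTIF)
    rev = rep.find(rc) >= 0 and rep.find(rc) <= 4
    if fwd and not rev:
        return 1
    if rev and not fwd:
        return -1
    return 0


def _vote_at_flank(array: CrisprArray, genome: GenomeRecord) -> int:
    seq = revcomp(genome.sequence) if array.was_reversed else genome.sequence
    up = seq[max(0, array.start - FLANK_WINDOW) : array.start]
    down = seq[array.end : array.end + FLANK_WINDOW]
    if len(up) < 20 or len(down) < 20:
        return 0
    diff = _at_fraction(up) - _at_fraction(down)
    if diff >= AT_MARGIN:
        return 1  # AT-rich leader upstream: array already points forward
    if diff <= -AT_MARGIN:
        return -1
    return 0


def _vote_gradient(array: CrisprArray) -> int:
    reps = array.repeats()
    if len(reps) < 4 or not array.representative_repeat:
        return 0
    k = min(3, len(reps) // 2)
    rep = array.representative_repeat
    head = sum(repeat_identity(r.observed_sequence, rep) for r in reps[:k]) / k
    tail = sum(repeat_identity(r.observed_sequence, rep) for r in reps[-k:]) / k
    if head - tail >= GRADIENT_MARGIN:
        return 1  # degeneracy at the trailing end = leader-distal 3': forward
    if tail - head >= GRADIENT_MARGIN:
        return -1
    return 0


def predict_direction(
    array: CrisprArray, genome: GenomeRecord, repeat_bank: RepeatBank | None = None
) -> DirectionCall:
    """Majority vote of the four orientation predictors.

    Confidence is HIGH when at least two predictors agree and none opposes,
    MEDIUM on a one-vote margin, LOW (orientation unknown) on ties or when
    every predictor abstains.
    """
    rep = array.representative_repeat
    votes = {
        "bank_match": _vote_bank(rep, repeat_bank),
        "motif": _vote_motif(rep) if rep else 0,
        "at_flank": _vote_at_flank(array, genome),
        "degeneracy_gradient": _vote_gradient(array),
    }
    pro = sum(1 for v in votes.values() if v > 0)
    con = sum(1 for v in votes.values() if v < 0)
    total = pro - con
    if total == 0:
        return DirectionCall("unknown", "LOW", votes)
    orientation = "forward" if total > 0 else "reverse"
    winner, loser = max(pro, con), min(pro, con)
    if winner >= 2 and loser == 0:
        confidence = "HIGH"
    else:
        confidence = "MEDIUM"
    return DirectionCall(orientation, confidence, votes)


def apply_direction(
    array: CrisprArray, call: DirectionCall, genome: GenomeRecord
) -> CrisprArray:
    """Reverse complement reverse-called arrays; label the rest.

    Unknown calls leave the array forward-as-found with a flag that
    surfaces in the report.
    """
    if call.orientation == "reverse":
        array = reverse_complement_array(array, genome)
        array.orientation = "reverse"
        return array
    if call.orientation == "forward":
        array.orientation = "forward"
    else:
        array.orientation = "unknown"
        array.flags.add("orientation_unresolved")
    return array
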