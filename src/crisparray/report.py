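"""Text report, GFF3 output and the end-to-end pipeline driver.

The text report renders each array in dot notation against its
representative repeat: matching bases print as '.', substitutions print
the base, deleted columns print '-', and inserted bases are listed to the
right of the unit as ``BASES [position]`` with their 1-based forward
genome position.  The GFF3 output nests direct_repeat and spacer children
under a repeat_region parent, in forward-genome coordinates, ready for
genome browsers and annotation pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import repeat_identity
from .annotation import RepeatBank, assign_type_hints, find_cas_genes
from .direction import apply_direction, predict_direction
from .model import CrisprArray, GenomeRecord, forward_interval, reconstruct_span
from .refine import (
    TANDEM_FLAG,
    RefinementConfig,
    annotate_insertions,
    refine,
    select_representative_repeat,
)
from .scoring import ScoringConfig, categorise_and_filter, score_array
from .seeds import cluster_to_candidate, scan_repeated_words


@dataclass
class ReportOptions:
    min_score_to_report: float = 0.0
    show_components: bool = True
    spacer_feature_type: str = "sequence_feature"  # or literal "spacer"

    def __post_init__(self) -> None:
        if self.min_score_to_report < 0:
            raise ValueError("min_score_to_report must be >= 0 (negative-score arrays are never reported)")


# ---------------------------------------------------------------------------
# dot notation


def render_repeat_dots(unit, representative: str) -> str:
    """Dot-notation rendering of one repeat against the representative."""
    out = ["."] * len(representative)
    for col, length in unit.deletions:
        for c in range(col, min(col + length, len(representative))):
            out[c] = "-"
    for col, base in unit.mismatch_positions:
        if 0 <= col < len(out):
            out[col] = base
    return "".join(out)


def format_insertions(unit) -> str:
    return " ".join(f"{bases} [{pos}]" for pos, bases in unit.insertions)


def _unit_position(unit, array: CrisprArray, genome_length: int) -> int:
    """1-based forward-genome position of the unit's first reported base."""
    if array.was_reversed:
        return genome_length - unit.start
    return unit.start + 1


def render_text_report(
    arrays: list[CrisprArray],
    genome: GenomeRecord,
    options: ReportOptions | None = None,
) -> str:
    options = options or ReportOptions()
    n = len(genome.sequence)
    lines: list[str] = []
    lines.append(f"CRISPR arrays on {genome.id} ({n} bp): {len(arrays)} reported")
    if not genome.features:
        lines.append(
            "NOTE: no annotation supplied; the lack of annotated cas genes in"
            " this output does not mean they are absent."
        )
    for idx, array in enumerate(arrays, start=1):
        fs, fe = forward_interval(array, array.start, array.end, n)
        strand = "-" if array.was_reversed else "+"
        cat = array.score.category if array.score else "unscored"
        lines.append("")
        lines.append(
            f"Array {idx}  {genome.id}:{fs + 1}-{fe}  strand {strand}"
            + ("  (reversed: reported 5'->3' on the minus strand)" if array.was_reversed else "")
            + f"  score {array.score.total:.2f} ({cat})"
            if array.score
            else f"Array {idx}  {genome.id}:{fs + 1}-{fe}  strand {strand}"
        )
        rep = array.representative_repeat
        lines.append(
            f"{'Position':>10}  {'Length':>6}  {'Identity':>8}  {'SpLen':>5}  "
            f"{'Repeat':<{max(6, len(rep))}}  Spacer"
        )
        units = array.units
        for i in range(0, len(units), 2):
            u = units[i]
            spacer = units[i + 1] if i + 1 < len(units) else None
            dots = render_repeat_dots(u, rep)
            ident = repeat_identity(u.observed_sequence, rep)
            sp_len = f"{len(spacer)}" if spacer is not None else "-"
            sp_seq = (
                (spacer.sequence if not spacer.lost else "(spacer lost)")
                if spacer is not None
                else "|"
            )
            notes = format_insertions(u)
            lines.append(
                f"{_unit_position(u, array, n):>10}  {len(u):>6}  {ident:>7.1f}%  "
                f"{sp_len:>5}  {dots:<{max(6, len(rep))}}  {sp_seq}"
                + (f"  {notes}" if notes else "")
            )
        lines.append(f"Representative repeat : {rep}")
        if array.alternative_repeat:
            lines.append(f"Alternative repeat    : {array.alternative_repeat}")
        if array.score and options.show_components:
            lines.append("Score components:")
            for name, value in array.score.components.items():
                lines.append(f"  {name:<28} {value:+.2f}")
            lines.append(f"  {'total':<28} {array.score.total:+.2f}")
        if array.direction_confidence:
            lines.append(
                f"Direction             : {array.orientation}"
                f" (confidence {array.direction_confidence})"
            )
        if array.type_hints:
            lines.append("CRISPR-Cas type(s)    : " + "; ".join(array.type_hints))
        if "questionable" in array.flags:
            lines.append("Flag                  : questionable")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# GFF3


def _gff_escape(value: str) -> str:
    for ch, rep in [("%", "%25"), (";", "%3B"), ("=", "%3D"), ("&", "%26"), (",", "%2C")]:
        value = value.replace(ch, rep)
    return value


def render_gff(
    arrays: list[CrisprArray],
    genome: GenomeRecord,
    options: ReportOptions | None = None,
) -> str:
    options = options or ReportOptions()
    n = len(genome.sequence)
    out = ["##gff-version 3", f"##sequence-region {genome.id} 1 {n}"]
    for idx, array in enumerate(arrays, start=1):
        aid = f"crispr_{idx}"
        fs, fe = forward_interval(array, array.start, array.end, n)
        strand = "-" if array.was_reversed else "+"
        score = f"{array.score.total:.2f}" if array.score else "."
        notes = [f"orientation {array.orientation or 'unknown'}"]
        notes.extend(array.type_hints)
        attrs = (
            f"ID={aid};rpt_family=CRISPR;"
            f"note={_gff_escape('; '.join(notes))}"
        )
        out.append(
            f"{genome.id}\tcrisparray\trepeat_region\t{fs + 1}\t{fe}\t{score}\t{strand}\t.\t{attrs}"
        )
        children = []
        rep_i = sp_i = 0
        for u in array.units:
            us, ue = forward_interval(array, u.start, u.end, n)
            if u.is_repeat:
                rep_i += 1
                children.append(
                    (us, f"direct_repeat", f"ID={aid}_repeat_{rep_i};Parent={aid}", ue)
                )
            else:
                if u.lost:
                    continue
                sp_i += 1
                ftype = options.spacer_feature_type
                attr = f"ID={aid}_spacer_{sp_i};Parent={aid}"
                if ftype != "spacer":
                    attr += ";note=CRISPR_spacer"
                children.append((us, ftype, attr, ue))
        for us, ftype, attr, ue in sorted(children):
            out.append(
                f"{genome.id}\tcrisparray\t{ftype}\t{us + 1}\t{ue}\t.\t{strand}\t.\t{attr}"
            )
    out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    genome: GenomeRecord
    arrays: list[CrisprArray] = field(default_factory=list)
    cas_hits: list = field(default_factory=list)
    report: str = ""
    gff: str = ""


def _dedupe(arrays: list[CrisprArray], genome_length: int) -> list[CrisprArray]:
    """Drop refined arrays whose forward spans overlap a better one
    (more repeats, then wider, then leftmost)."""
    spans = []
    for a in arrays:
        fs, fe = forward_interval(a, a.start, a.end, genome_length)
        spans.append((fs, fe, a))
    spans.sort(key=lambda t: (-t[2].n_repeats, -(t[1] - t[0]), t[0]))
    kept: list[tuple[int, int, CrisprArray]] = []
    for fs, fe, a in spans:
        if any(fs < ke and ks < fe for ks, ke, _ in kept):
            continue
        kept.append((fs, fe, a))
    kept.sort(key=lambda t: t[0])
    return [a for _, _, a in kept]


def run_pipeline(
    genome: GenomeRecord,
    repeat_bank: RepeatBank | None = None,
    refinement: RefinementConfig | None = None,
    scoring: ScoringConfig | None = None,
    options: ReportOptions | None = None,
    word_length: int = 11,
    min_repeats: int = 3,
    orientation_mode: str = "auto",
) -> PipelineResult:
    """Seed -> refine -> orient -> annotate -> score -> filter -> render.

    Fully deterministic: identical inputs and configuration give
    byte-identical report and GFF text.
    """
    refinement = refinement or RefinementConfig()
    scoring = scoring or ScoringConfig()
    options = options or ReportOptions()
    n = len(genome.sequence)

    clusters = scan_repeated_words(genome, word_length, min_occurrences=min_repeats)
    refined: list[CrisprArray] = []
    for cluster in clusters:
        candidate = cluster_to_candidate(cluster, genome)
        array = refine(candidate, genome, repeat_bank, refinement)
        if TANDEM_FLAG in array.flags:
            continue
        if array.n_repeats < 2:
            continue
        refined.append(array)
    refined = _dedupe(refined, n)

    cas_hits = find_cas_genes(genome)

    final: list[CrisprArray] = []
    for array in refined:
        if orientation_mode == "forward":
            array.orientation = "forward"
        else:
            call = predict_direction(array, genome, repeat_bank)
            array.direction_confidence = call.confidence
            if orientation_mode == "auto":
                array = apply_direction(array, call, genome)
                if array.was_reversed:
                    # the 5' end is only now known: re-resolve the
                    # representative tie-break and the edit annotations
                    # in the reported frame
                    select_representative_repeat(array)
                    annotate_insertions(array, genome)
            else:  # as-found: the call is noted but never applied
                array.orientation = call.orientation
        bank_match = (
            repeat_bank.match(array.representative_repeat) if repeat_bank else None
        )
        array.type_hints = assign_type_hints(array, cas_hits, bank_match)
        score_array(array, genome, cas_hits, bank_match, scoring)
        reconstruct_span(array, genome)  # hard invariant on every emitted array
        final.append(array)

    final = categorise_and_filter(final, scoring, {genome.id: n})
    final = [
        a for a in final if a.score.total >= options.min_score_to_report
    ]

    result = PipelineResult(genome=genome, arrays=final, cas_hits=cas_hits)
    result.report = render_text_report(final, genome, options)
    result.gff = render_gff(final, genome, options)
    return result
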