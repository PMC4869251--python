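"""Reference-repeat bank lookup and cas-gene based typing.

Two independent evidence sources hint at the CRISPR-Cas type of an array:
a match of its representative repeat to a library of validated repeats
(which also pins down the correct repeat extent), and signature cas genes
annotated in the input GenBank record (cas3 -> Type I, cas9 -> II,
cas10 -> III, csf1 -> IV, cas12/cpf1 -> V).  Only annotation text is used
for the gene scan — no sequence-based gene search — so an empty result
never means the genes are absent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from .align import GAP, pairwise_rows
from .model import AnnotationFeature, GenomeRecord, ReferenceRepeat, revcomp

SIGNATURE_TYPES = {
    "cas3": "I",
    "cas9": "II",
    "cas10": "III",
    "csf1": "IV",
    "cas12": "V",
}

# lower-case word -> canonical gene label
_SYNONYMS = {
    "cpf1": "cas12",
    "csn1": "cas9",
    "csx12": "cas10",
    "cmr2": "cas10",
    "csf1": "csf1",
}

_CAS_WORD = re.compile(r"\bcas(\d+)[a-z]?\b")
_WORD = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class CasGeneHit:
    gene_name: str
    feature: AnnotationFeature
    signature_for: frozenset[str]


@dataclass(frozen=True)
class BankMatch:
    entry: ReferenceRepeat
    strand: str  # '+' if the repeat matches the entry as stored, '-' otherwise
    left_delta: int  # bases to add (+) or trim (-) at the repeat 5' end
    right_delta: int  # likewise at the 3' end
    identity: float  # percent, over the bank entry length


def _overlap_stats(query: str, target: str) -> tuple[float, int, int]:
    """Identity of query vs target plus the boundary deltas that would give
    the query the target's extent (positive delta = extend the query)."""
    qrow, trow = pairwise_rows(query, target)
    matches = sum(1 for a, b in zip(qrow, trow) if a == b and a != GAP)
    gaps = sum(1 for a, b in zip(qrow, trow) if a == GAP or b == GAP)
    identity = max(0.0, matches - gaps) / len(target) * 100.0

    def edge(rowpair) -> int:
        qch, tch = rowpair
        if qch == GAP and tch != GAP:
            return 1  # target overhang: extend query
        if tch == GAP and qch != GAP:
            return -1  # query overhang: trim query
        return 0

    left = 0
    for pair in zip(qrow, trow):
        d = edge(pair)
        if d == 0:
            break
        left += d
    right = 0
    for pair in zip(reversed(qrow), reversed(trow)):
        d = edge(pair)
        if d == 0:
            break
        right += d
    return identity, left, right


class RepeatBank:
    """A set of known repeats with exact and near-exact lookup.

    Entries are stored upper-case in their validated 5'->3' orientation;
    duplicate (sequence, family) pairs are rejected.
    """

    def __init__(self, entries: list[ReferenceRepeat], min_identity: float = 90.0):
        seen = set()
        for e in entries:
            key = (e.sequence, e.family)
            if key in seen:
                raise ValueError(f"duplicate bank entry {key}")
            seen.add(key)
        self.entries = list(entries)
        self.min_identity = min_identity

    def __len__(self) -> int:
        return len(self.entries)

    def match(self, repeat: str) -> BankMatch | None:
        """Best bank entry matching ``repeat`` on either strand, or None.

        A hit requires an exact substring relationship or an alignment
        identity of at least ``min_identity`` percent of the entry length;
        ties resolve to the highest identity, then the longest entry.
        """
        repeat = repeat.upper()
        if len(repeat) < 11:
            raise ValueError("bank lookup requires a repeat of >= 11 nt")
        best: BankMatch | None = None
        for entry in self.entries:
            for strand in ("+", "-"):
                target = entry.sequence if strand == "+" else revcomp(entry.sequence)
                exact = repeat in target or target in repeat
                identity, left, right = _overlap_stats(repeat, target)
                if not exact and identity < self.min_identity:
                    continue
                cand = BankMatch(entry, strand, left, right, identity)
                if (
                    best is None
                    or (cand.identity, len(cand.entry.sequence))
                    > (best.identity, len(best.entry.sequence))
                ):
                    best = cand
        return best


def load_repeat_bank(path=None, min_identity: float = 90.0) -> RepeatBank:
    """Load a bank from a TSV (sequence, family, cas_type, source; '#'
    comments).  Without a path the small bundled literature-derived bank is
    used."""
    if path is None:
        text = (
            resources.files("crisparray").joinpath("data/repeat_bank.tsv").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    entries = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed bank line: {line!r}")
        seq, family = parts[0], parts[1]
        cas_type = parts[2] if len(parts) > 2 else ""
        entries.append(ReferenceRepeat(seq, family, cas_type))
    return RepeatBank(entries, min_identity=min_identity)


def match_reference_repeat(repeat: str, bank: RepeatBank) -> BankMatch | None:
    """Functional alias for :meth:`RepeatBank.match`."""
    return bank.match(repeat)


def _canonical_genes(text: str) -> set[str]:
    text = text.lower()
    hits = {f"cas{m.group(1)}" for m in _CAS_WORD.finditer(text)}
    for word in _WORD.findall(text):
        if word in _SYNONYMS:
            hits.add(_SYNONYMS[word])
    return hits


def find_cas_genes(genome: GenomeRecord) -> list[CasGeneHit]:
    """Scan gene/CDS annotation for cas genes (and synonyms).

    Matches are case-insensitive word matches against the ``gene`` and
    ``product`` qualifiers; names are canonicalised (cpf1 -> cas12,
    csn1 -> cas9).  FASTA-only input yields an empty list — the report
    notes that absence of annotation is not absence of the genes.
    """
    hits: list[CasGeneHit] = []
    for feature in genome.features:
        if feature.kind not in ("gene", "CDS"):
            continue
        text = " ".join(
            str(feature.qualifiers.get(k, "")) for k in ("gene", "product")
        )
        for name in sorted(_canonical_genes(text)):
            sig = frozenset(
                {SIGNATURE_TYPES[name]} if name in SIGNATURE_TYPES else set()
            )
            hits.append(CasGeneHit(name, feature, sig))
    return hits


def assign_type_hints(
    array, cas_hits: list[CasGeneHit], bank_match: BankMatch | None
) -> list[str]:
    """Union of bank-derived and cas-gene-derived type labels, each tagged
    with its evidence source; conflicts are listed, never arbitrated."""
    hints: list[str] = []
    if bank_match is not None and bank_match.entry.cas_type:
        hints.append(f"{bank_match.entry.cas_type} (repeat match)")
    sig_types = sorted({t for h in cas_hits for t in h.signature_for})
    for t in sig_types:
        hints.append(f"{t} (cas genes)")
    return hints
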