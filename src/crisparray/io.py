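"""FASTA / GenBank input and FASTA output via Biopython."""

from __future__ import annotations

from Bio import SeqIO

from .model import AnnotationFeature, GenomeRecord


def _features_from_seqrecord(record) -> list[AnnotationFeature]:
    feats = []
    for f in record.features:
        if f.type not in ("gene", "CDS"):
            continue
        quals = {}
        for key in ("gene", "product", "locus_tag", "note"):
            if key in f.qualifiers:
                quals[key] = str(f.qualifiers[key][0])
        try:
            start, end = int(f.location.start), int(f.location.end)
        except (TypeError, AttributeError):  # fuzzy/compound locations
            continue
        if start >= end:
            continue
        strand = "-" if f.location.strand == -1 else "+"
        feats.append(AnnotationFeature(f.type, start, end, strand, quals))
    return feats


def read_fasta(path) -> list[GenomeRecord]:
    return [
        GenomeRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_genbank(path) -> list[GenomeRecord]:
    return [
        GenomeRecord(rec.id, str(rec.seq), _features_from_seqrecord(rec))
        for rec in SeqIO.parse(str(path), "genbank")
    ]


def read_genome(path, fmt: str | None = None) -> list[GenomeRecord]:
    """Read FASTA or GenBank, sniffing the format from the first byte when
    not given ('>' opens a FASTA; GenBank flat files open with LOCUS)."""
    if fmt is None:
        with open(path) as fh:
            first = fh.read(1)
        fmt = "fasta" if first == ">" else "genbank"
    if fmt == "fasta":
        return read_fasta(path)
    if fmt == "genbank":
        return read_genbank(path)
    raise ValueError(f"unsupported format {fmt!r}")


def write_fasta(genomes: list[GenomeRecord], path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), 70):
                fh.write(g.sequence[i : i + 70] + "\n")
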