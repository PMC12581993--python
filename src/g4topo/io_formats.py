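"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open; the GFF3 1-based inclusive
convention is converted at the parsing boundary and restored on output.
Sequences are uppercased on input; IUPAC ambiguity letters are retained and
treated as neutral by downstream scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from gffutils.iterators import DataIterator

logger = logging.getLogger(__name__)

IUPAC_LETTERS = frozenset("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHV",
    "TGCANYRSWMKVHDB",
)


def revcomp(sequence: str) -> str:
    """Reverse complement of an uppercased IUPAC nucleotide string."""
    return sequence.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class SequenceRecord:
    """A genome contig: id, uppercased sequence, and topology."""

    contig_id: str
    sequence: str
    topology: str = "linear"  # {linear, circular}

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureRecord:
    """A gene-derived annotation in 0-based half-open coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str  # {+,-}
    kind: str  # {gene, exon, CDS, intron}
    gene_id: str
    biotype: str = "unknown"  # {protein_coding, noncoding, unknown}

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start},{self.end})")


@dataclass(frozen=True)
class Interval:
    """A BED-style half-open span, optionally named/scored/stranded."""

    contig_id: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"invalid span [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA


def parse_fasta(path: str | Path, topology: str = "linear") -> list[SequenceRecord]:
    """Parse a (multi-record) FASTA file into SequenceRecords.

    Sequences are uppercased and the record order of the file is preserved.
    Raises :class:`FormatError` (naming the offending line) for a sequence
    before any header, a header with no sequence lines, a duplicated contig
    id, or characters outside the IUPAC alphabet.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: header at line {header_line} has no sequence")
        bad = set(seq) - IUPAC_LETTERS
        if bad:
            raise FormatError(
                f"{path}: non-IUPAC characters {sorted(bad)} under header at line {header_line}"
            )
        records.append(SequenceRecord(header, seq, topology))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}: malformed header at line {lineno}")
                if name in seen:
                    raise FormatError(f"{path}: duplicate contig id {name!r} at line {lineno}")
                seen.add(name)
                header, header_line, chunks = name, lineno, []
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence before any header at line {lineno}")
                chunks.append(line.upper())
    flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _biotype_from_attributes(attributes) -> str:
    for key in ("gene_biotype", "biotype", "gene_type"):
        if key in attributes:
            value = attributes[key][0]
            return "protein_coding" if value == "protein_coding" else "noncoding"
    return "unknown"


def _gene_id_from_attributes(attributes) -> str:
    for key in ("gene_id", "ID", "Parent"):
        if key in attributes:
            return attributes[key][0]
    return ""


def parse_gff_features(path: str | Path, kinds: Sequence[str]) -> list[FeatureRecord]:
    """Extract features of the requested kinds from a GFF3 file.

    GFF 1-based inclusive coordinates become 0-based half-open.  Records with
    end < start or with an undefined strand are skipped with a logged warning
    rather than aborting the parse.
    """
    wanted = set(kinds)
    if not wanted:
        raise ValueError("kinds must be nonempty")
    out: list[FeatureRecord] = []
    for feat in DataIterator(str(path)):
        if feat.featuretype not in wanted:
            continue
        if feat.end < feat.start:
            logger.warning(
                "%s: skipping %s with end < start (%d < %d)",
                path, feat.featuretype, feat.end, feat.start,
            )
            continue
        if feat.strand not in ("+", "-"):
            logger.warning(
                "%s: skipping %s at %s:%d-%d with undefined strand",
                path, feat.featuretype, feat.seqid, feat.start, feat.end,
            )
            continue
        out.append(
            FeatureRecord(
                contig_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                kind=feat.featuretype,
                gene_id=_gene_id_from_attributes(feat.attributes),
                biotype=_biotype_from_attributes(feat.attributes),
            )
        )
    return out


def write_gff3(features: Iterable[FeatureRecord], path: str | Path, source: str = "g4topo") -> None:
    """Write FeatureRecords as GFF3 (coordinates restored to 1-based inclusive)."""
    feats = sorted(features, key=lambda f: (f.contig_id, f.start, f.end, f.kind))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            attrs = f"ID={f.gene_id}.{f.kind}.{f.start}" if f.kind != "gene" else f"ID={f.gene_id}"
            attrs += f";gene_id={f.gene_id}"
            if f.biotype != "unknown":
                attrs += f";gene_biotype={f.biotype}"
            fh.write(
                f"{f.contig_id}\t{source}\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open spans (overlapping spans merged; abutting kept separate
    only if they share no base, i.e. [a,b) and [b,c) stay separate)."""
    ordered = sorted(spans)
    merged: list[list[int]] = []
    for s, e in ordered:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def derive_introns(exons: Sequence[FeatureRecord]) -> list[FeatureRecord]:
    """Introns are the gaps between coordinate-sorted exons of each gene.

    Exons of a gene are unioned first (multi-transcript annotations collapse
    to one exon chain); overlapping exons trigger a logged warning.  Abutting
    exons produce no intron.
    """
    by_gene: dict[str, list[FeatureRecord]] = {}
    for ex in exons:
        by_gene.setdefault(ex.gene_id, []).append(ex)

    introns: list[FeatureRecord] = []
    for gene_id, group in by_gene.items():
        contigs = {g.contig_id for g in group}
        strands = {g.strand for g in group}
        if len(contigs) > 1 or len(strands) > 1:
            raise ValueError(f"gene {gene_id}: exons span multiple contigs or strands")
        spans = [(g.start, g.end) for g in group]
        merged = merge_spans(spans)
        if len(merged) < len(spans):
            logger.warning("gene %s: overlapping exons merged before intron derivation", gene_id)
        proto = group[0]
        for (_, left_end), (right_start, _) in zip(merged, merged[1:]):
            if right_start > left_end:
                introns.append(
                    replace(proto, start=left_end, end=right_start, kind="intron")
                )
    introns.sort(key=lambda f: (f.contig_id, f.start, f.end))
    return introns


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3/BED6 into Intervals; start >= end is a format error."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: fewer than 3 BED columns at line {lineno}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer coordinate at line {lineno}") from exc
            if start >= end:
                raise FormatError(f"{path}: start >= end at line {lineno}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            out.append(Interval(fields[0], start, end, strand, name, score))
    return out


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return format(score, "g")


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write BED6, deterministically sorted by (contig, start, end, strand)."""
    ordered = sorted(intervals, key=lambda i: (i.contig_id, i.start, i.end, i.strand))
    with open(path, "w") as fh:
        for iv in ordered:
            fh.write(
                f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{_fmt_score(iv.score)}\t{iv.strand}\n"
            )
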