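"""Reconciliation of the two call sets and density/overlap statistics.

Cross-method agreement uses the fractional-overlap rule: two spans match
when their overlap reaches the required fraction of *either* span
(equivalently, of the shorter one).  The default fractions are 0.5 for
cross-method reconciliation and 0.1 for mapping onto external reference
interval sets.  Densities are reported both as G4 base pairs per megabase
and as G4 counts per megabase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .detect import G4Hit
from .io_formats import FeatureRecord, Interval, merge_spans

Span = tuple[int, int]


def _span(x) -> Span:
    return (x.start, x.end)


def _overlap_bp(a: Span, b: Span) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


@dataclass(frozen=True)
class VennCounts:
    """Tally of a two-set reconciliation at a fractional-overlap rule."""

    only_a: int
    only_b: int
    common: int  # matched pairs
    matched_a: int
    matched_b: int


@dataclass(frozen=True)
class DensityReport:
    region_label: str
    g4_bp: int
    g4_count: int
    region_bp: int
    density_bp_per_mb: float
    density_count_per_mb: float


def _fractional_matches(a: Sequence, b: Sequence, min_frac: float) -> list[tuple[int, int]]:
    """Index pairs (i, j) where overlap >= min_frac of either span.

    Sorted sweep per contig; the all-pairs equivalent is the oracle in the
    test suite.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    by_contig_b: dict[str, list[tuple[Span, int]]] = {}
    for j, y in enumerate(b):
        by_contig_b.setdefault(y.contig_id, []).append((_span(y), j))
    for lst in by_contig_b.values():
        lst.sort()

    pairs: list[tuple[int, int]] = []
    order_a = sorted(range(len(a)), key=lambda i: (a[i].contig_id, a[i].start, a[i].end))
    for i in order_a:
        x = a[i]
        xs = _span(x)
        for ys, j in by_contig_b.get(x.contig_id, ()):
            if ys[0] >= xs[1]:
                break
            ov = _overlap_bp(xs, ys)
            if ov <= 0:
                continue
            if ov >= min_frac * min(xs[1] - xs[0], ys[1] - ys[0]):
                pairs.append((i, j))
    return pairs


def common_hits(a: Sequence[G4Hit], b: Sequence[G4Hit],
                min_frac: float = 0.5) -> tuple[VennCounts, list[tuple[G4Hit, G4Hit]]]:
    """Cross-method reconciliation: the overlap rule satisfied by either span.

    Returns the Venn tally (both the matched-pair count and the per-set
    matched-hit counts) plus the matched pairs themselves.
    """
    pairs = _fractional_matches(a, b, min_frac)
    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}
    counts = VennCounts(
        only_a=len(a) - len(matched_a),
        only_b=len(b) - len(matched_b),
        common=len(pairs),
        matched_a=len(matched_a),
        matched_b=len(matched_b),
    )
    return counts, [(a[i], b[j]) for i, j in pairs]


def map_to_reference(hits: Sequence[G4Hit], reference: Sequence[Interval],
                     min_frac: float = 0.1) -> list[G4Hit]:
    """Hits overlapping some reference interval by >= min_frac of either span."""
    matched = {i for i, _ in _fractional_matches(hits, reference, min_frac)}
    return [hits[i] for i in sorted(matched)]


def _merged_hit_spans(hits: Iterable) -> dict[str, list[Span]]:
    by_contig: dict[str, list[Span]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(_span(h))
    return {c: merge_spans(s) for c, s in by_contig.items()}


def _intersect_bp(a: list[Span], b: list[Span]) -> int:
    """Total overlap bp between two sorted merged span lists (two-pointer)."""
    total = i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def genome_density(hits: Sequence[G4Hit], genome_bp: int,
                   label: str = "genome") -> DensityReport:
    """Genome-wide density: G4 bp (of merged hits) and counts per megabase."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be > 0")
    spans = _merged_hit_spans(hits)
    g4_bp = sum(e - s for sl in spans.values() for s, e in sl)
    return DensityReport(
        region_label=label,
        g4_bp=g4_bp,
        g4_count=len(hits),
        region_bp=genome_bp,
        density_bp_per_mb=g4_bp / genome_bp * 1e6,
        density_count_per_mb=len(hits) / genome_bp * 1e6,
    )


def compartment_density(hits: Sequence[G4Hit], features: Sequence[FeatureRecord],
                        label: str | None = None) -> DensityReport:
    """Density within one annotation compartment (gene/exon/CDS/intron).

    Features are merged per contig first; g4_bp is the overlap of merged
    hits with merged features and region_bp the merged feature footprint.
    """
    if not features:
        raise ValueError("no annotated compartment")
    kinds = {f.kind for f in features}
    label = label or "/".join(sorted(kinds))
    feat_spans = {c: merge_spans(s) for c, s in _group_spans(features).items()}
    hit_spans = _merged_hit_spans(hits)
    g4_bp = sum(
        _intersect_bp(hit_spans.get(c, []), sl) for c, sl in feat_spans.items()
    )
    region_bp = sum(e - s for sl in feat_spans.values() for s, e in sl)
    count = sum(
        1 for h in hits
        if _intersect_bp([_span(h)], feat_spans.get(h.contig_id, []))
    )
    return DensityReport(
        region_label=label,
        g4_bp=g4_bp,
        g4_count=count,
        region_bp=region_bp,
        density_bp_per_mb=(g4_bp / region_bp * 1e6) if region_bp else 0.0,
        density_count_per_mb=(count / region_bp * 1e6) if region_bp else 0.0,
    )


def _group_spans(items: Iterable) -> dict[str, list[Span]]:
    by_contig: dict[str, list[Span]] = {}
    for it in items:
        by_contig.setdefault(it.contig_id, []).append(_span(it))
    return by_contig


def gene_overlap_fraction(hits: Sequence[G4Hit], genes: Sequence[FeatureRecord],
                          partition_by_biotype: bool = False):
    """Fraction of genes overlapped (>= 1 shared bp) by at least one hit.

    With ``partition_by_biotype`` the fraction is reported separately for
    protein_coding and noncoding genes (unknown biotypes grouped with
    noncoding, mirroring a two-way partition).
    """
    if not genes:
        raise ValueError("genes must be nonempty")
    hit_spans = _merged_hit_spans(hits)

    def covered(g: FeatureRecord) -> bool:
        return _intersect_bp([_span(g)], hit_spans.get(g.contig_id, [])) > 0

    if not partition_by_biotype:
        return sum(covered(g) for g in genes) / len(genes)
    out: dict[str, float] = {}
    for bucket in ("protein_coding", "noncoding"):
        members = [
            g for g in genes
            if (g.biotype == "protein_coding") == (bucket == "protein_coding")
        ]
        if members:
            out[bucket] = sum(covered(g) for g in members) / len(members)
    return out
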