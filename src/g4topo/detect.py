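"""Dual-method putative G-quadruplex detection.

Two detectors are implemented, matching the two call sets the catalog
reconciles:

* ``scan_regex`` — the consensus motif G>=3 N1-7 G>=3 N1-7 G>=3 N1-7 G>=3,
  applied to both strands with standard left-to-right, non-overlapping,
  greedy regular-expression semantics.

* ``call_hunter`` — a windowed per-base G-richness score: each base in a
  maximal run of k guanines scores +min(k, cap), cytosines score the
  negative, everything else 0; windows of length w whose mean score
  reaches |s| seed candidate regions, overlapping same-sign windows are
  merged, and each region is trimmed to start and end on its majority
  letter (G for "+", C for "-").  Defaults w=25, s=1.5, cap=4.

Hit coordinates are 0-based half-open on the forward reference strand;
minus-strand hits describe a structure on the reverse complement.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Interval, SequenceRecord, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectParams:
    """Parameters shared by the two detectors.

    min_run/loop_min/loop_max/n_runs define the consensus grammar;
    window/threshold/score_cap define the windowed G-richness scorer.
    """

    min_run: int = 3
    loop_min: int = 1
    loop_max: int = 7
    n_runs: int = 4
    window: int = 25
    threshold: float = 1.5
    score_cap: int = 4

    def __post_init__(self) -> None:
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")
        if not (1 <= self.loop_min <= self.loop_max):
            raise ValueError("need 1 <= loop_min <= loop_max")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")

    @property
    def min_motif_length(self) -> int:
        return self.n_runs * self.min_run + (self.n_runs - 1) * self.loop_min

    def motif_pattern(self, base: str = "G") -> re.Pattern[str]:
        run = f"{base}{{{self.min_run},}}"
        loop = f"[ACGT]{{{self.loop_min},{self.loop_max}}}"
        return re.compile(run + (loop + run) * (self.n_runs - 1))


@dataclass(frozen=True)
class G4Hit:
    """A located putative G4 on the forward reference coordinate system."""

    contig_id: str
    start: int
    end: int
    strand: str  # {+,-}
    method: str  # {regex, hunter, merged}
    score: float | None = None
    sequence: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def as_interval(self) -> Interval:
        return Interval(self.contig_id, self.start, self.end, self.strand,
                        name=self.method, score=self.score)


@dataclass(frozen=True)
class ScoreTrack:
    """Per-base G/C run scores for one contig (G runs positive, C negative)."""

    contig_id: str
    per_base_scores: np.ndarray


DEFAULT_PARAMS = DetectParams()


def scan_regex(record: SequenceRecord, params: DetectParams = DEFAULT_PARAMS) -> list[G4Hit]:
    """Consensus-motif hits on both strands.

    The forward strand is scanned directly; the reverse strand is scanned on
    the reverse complement and match spans are mapped back, so within each
    strand matches are non-overlapping, found left-to-right in that strand's
    reading direction with greedy run quantifiers.
    """
    seq = record.sequence
    length = len(seq)
    pattern = params.motif_pattern("G")
    hits = [
        G4Hit(record.contig_id, m.start(), m.end(), "+", "regex",
              sequence=m.group(0))
        for m in pattern.finditer(seq)
    ]
    for m in pattern.finditer(revcomp(seq)):
        start, end = length - m.end(), length - m.start()
        hits.append(
            G4Hit(record.contig_id, start, end, "-", "regex",
                  sequence=seq[start:end])
        )
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def base_scores(record: SequenceRecord, params: DetectParams = DEFAULT_PARAMS) -> ScoreTrack:
    """Run-length G/C scores: base in a maximal run of k G scores +min(k,cap),
    k C scores -min(k,cap); any other letter scores 0 and breaks runs."""
    arr = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
    scores = np.zeros(len(arr), dtype=np.int64)
    cap = params.score_cap
    for letter, sign in ((ord("G"), 1), (ord("C"), -1)):
        mask = arr == letter
        if not mask.any():
            continue
        # run-length decode: boundaries of maximal runs of `letter`
        padded = np.concatenate(([False], mask, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            scores[s:e] = sign * min(e - s, cap)
    return ScoreTrack(record.contig_id, scores)


def window_means(track: ScoreTrack, window: int) -> np.ndarray:
    """Mean of per-base scores over every window [i, i+window)."""
    scores = track.per_base_scores
    if len(scores) < window:
        return np.empty(0, dtype=float)
    csum = np.concatenate(([0], np.cumsum(scores)))
    return (csum[window:] - csum[:-window]) / float(window)


def _regions_from_windows(starts: np.ndarray, window: int) -> list[tuple[int, int, int, int]]:
    """Merge overlapping candidate windows; return (start, end, wfirst, wlast)."""
    regions = []
    run_start = prev = int(starts[0])
    for s in starts[1:]:
        s = int(s)
        if s < prev + window:  # windows [prev,prev+w) and [s,s+w) share >= 1 bp
            prev = s
        else:
            regions.append((run_start, prev + window, run_start, prev))
            run_start = prev = s
    regions.append((run_start, prev + window, run_start, prev))
    return regions


def call_hunter(record: SequenceRecord, params: DetectParams = DEFAULT_PARAMS) -> list[G4Hit]:
    """Windowed-score hits: qualifying windows merged per sign and trimmed.

    A window with mean >= threshold seeds a "+" (G-rich) region; mean <=
    -threshold a "-" (C-rich) region.  The recorded score is the
    maximum-magnitude window mean inside the region (signed).
    """
    seq = record.sequence
    w = params.window
    if len(seq) < w:
        logger.info("%s: contig shorter than window (%d < %d); no hunter calls",
                    record.contig_id, len(seq), w)
        return []
    means = window_means(base_scores(record, params), w)
    hits: list[G4Hit] = []
    for strand, letter in (("+", "G"), ("-", "C")):
        qual = means >= params.threshold if strand == "+" else means <= -params.threshold
        starts = np.flatnonzero(qual)
        if starts.size == 0:
            continue
        for rstart, rend, wfirst, wlast in _regions_from_windows(starts, w):
            # trim to first/last majority letter inside the merged span
            first = seq.find(letter, rstart, rend)
            last = seq.rfind(letter, rstart, rend)
            if first == -1:  # cannot happen for |mean| >= threshold > 0
                continue
            inside = means[wfirst : wlast + 1]
            inside = inside[qual[wfirst : wlast + 1]]
            score = float(inside.max() if strand == "+" else inside.min())
            hits.append(
                G4Hit(record.contig_id, first, last + 1, strand, "hunter",
                      score=score, sequence=seq[first : last + 1])
            )
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def merge_hits(hits: list[G4Hit], per_strand: bool = True,
               record: SequenceRecord | None = None) -> list[G4Hit]:
    """Replace overlapping hits (sharing >= 1 bp) by their union span.

    By default hits are merged within each strand; ``per_strand=False``
    merges across strands and records strand "." when constituents disagree.
    Method becomes "merged" when constituent methods differ.  If ``record``
    is given, merged hits carry the reference slice as sequence.
    """
    if not hits:
        return []
    contigs = {h.contig_id for h in hits}
    if len(contigs) > 1:
        raise ValueError("merge_hits expects hits on a single contig")

    def key(h: G4Hit):
        return (h.strand,) if per_strand else ()

    groups: dict[tuple, list[G4Hit]] = {}
    for h in hits:
        groups.setdefault(key(h), []).append(h)

    out: list[G4Hit] = []
    for group in groups.values():
        group.sort(key=lambda h: (h.start, h.end))
        cluster: list[G4Hit] = []
        clusters: list[list[G4Hit]] = []
        end = -1
        for h in group:
            if cluster and h.start < end:
                cluster.append(h)
                end = max(end, h.end)
            else:
                if cluster:
                    clusters.append(cluster)
                cluster, end = [h], h.end
        clusters.append(cluster)
        for cl in clusters:
            start = min(h.start for h in cl)
            end = max(h.end for h in cl)
            methods = {h.method for h in cl}
            strands = {h.strand for h in cl}
            scores = [h.score for h in cl if h.score is not None]
            seq = None
            if record is not None:
                seq = record.sequence[start:end]
            elif len(cl) == 1:
                seq = cl[0].sequence
            out.append(
                G4Hit(
                    cl[0].contig_id, start, end,
                    strand=cl[0].strand if len(strands) == 1 else ".",
                    method=cl[0].method if len(methods) == 1 else "merged",
                    score=max(scores, key=abs) if scores else None,
                    sequence=seq,
                )
            )
    out.sort(key=lambda h: (h.start, h.end, h.strand))
    return out
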