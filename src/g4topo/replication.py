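"""Replication-origin analyses: circular binning, strand asymmetry, GC skew.

A circular bacterial chromosome with a single origin (oriC) is replicated
by two forks diverging toward the terminus.  Positions are expressed as
signed offsets from the oriC midpoint in (-L/2, L/2]; the chromosome is
discretized into an odd number of bins (default 1001) whose center bin is
oriC and whose extreme bins meet at the terminus.  G4 hits are tallied per
bin separately for the forward and reverse strands and normalized by the
per-strand bin mean.  GC skew, (G - C)/(G + C) in 25-bp windows averaged
per bin, is carried alongside as the canonical strand-asymmetry co-track:
its sign, not a hard-wired convention, links bins to the biological
leading/lagging labels.

Linear (e.g. human) origin sets are profiled with a fixed half-window
around each origin midpoint instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detect import G4Hit
from .io_formats import Interval, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OriginSpec:
    """Origin of replication: oriC midpoint on a chromosome of known length."""

    contig_id: str
    ori_mid: int
    chrom_len: int
    topology: str = "circular"

    def __post_init__(self) -> None:
        if not (0 <= self.ori_mid < self.chrom_len):
            raise ValueError("ori_mid must lie within the chromosome")

    @staticmethod
    def from_annotation(contig_id: str, start: int, end: int, chrom_len: int,
                        topology: str = "circular") -> "OriginSpec":
        """Midpoint (start+end)//2 of an annotated oriC span."""
        return OriginSpec(contig_id, ((start + end) // 2) % chrom_len,
                          chrom_len, topology)


@dataclass(frozen=True)
class SkewParams:
    window: int = 25

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class CircularProfile:
    """Per-bin strand-split counts, enrichments, and GC skew around oriC."""

    n_bins: int
    counts_fwd: np.ndarray
    counts_rev: np.ndarray
    enrichment_fwd: np.ndarray | None = None
    enrichment_rev: np.ndarray | None = None
    gc_skew: np.ndarray | None = None
    n_genomes: int = 1

    @property
    def center_bin(self) -> int:
        return (self.n_bins - 1) // 2


def circ_distance(p: int, q: int, chrom_len: int) -> int:
    """min(|P - Q|, L - |P - Q|): shortest way around the circle."""
    if not (0 <= p < chrom_len and 0 <= q < chrom_len):
        raise ValueError("positions must lie in [0, chrom_len)")
    d = abs(p - q)
    return min(d, chrom_len - d)


def signed_offset(p: int, ori: OriginSpec) -> int:
    """Signed circular offset from oriC, mapped to (-L/2, L/2].

    The antipode (terminus) maps to the positive boundary +L/2.
    """
    if ori.topology != "circular":
        raise ValueError("signed offsets are defined for circular topology only")
    L = ori.chrom_len
    off = (p - ori.ori_mid) % L  # in [0, L)
    if off * 2 > L:
        off -= L
    return off


def _bin_of_offset(off: float, chrom_len: int, n_bins: int) -> int:
    # offset in (-L/2, L/2] -> bin in [0, n_bins); center bin holds offset 0
    idx = int((off + chrom_len / 2) * n_bins // chrom_len)
    return min(max(idx, 0), n_bins - 1)


def bin_circular(hits: Sequence[G4Hit], ori: OriginSpec,
                 n_bins: int = 1001) -> CircularProfile:
    """Tally hits into oriC-centered circular bins, split by strand.

    A hit is assigned to the bin of its midpoint; a hit long enough to touch
    several bins is counted in every bin its span touches.
    """
    counts_fwd = np.zeros(n_bins, dtype=np.int64)
    counts_rev = np.zeros(n_bins, dtype=np.int64)
    L = ori.chrom_len
    bin_width = L / n_bins
    step = max(1, int(bin_width // 2))
    for h in hits:
        positions = list(range(h.start, h.end, step))
        if (h.end - 1) not in positions:
            positions.append(h.end - 1)
        bins = {_bin_of_offset(signed_offset(p % L, ori), L, n_bins)
                for p in positions}
        dest = counts_rev if h.strand == "-" else counts_fwd
        for b in bins:
            dest[b] += 1
    return CircularProfile(n_bins, counts_fwd, counts_rev)


def bin_enrichment(profile: CircularProfile) -> CircularProfile:
    """Per-strand enrichment: counts over the per-strand bin mean.

    A strand with zero total is reported as missing (None), not as zeros.
    """
    for attr, counts in (("enrichment_fwd", profile.counts_fwd),
                         ("enrichment_rev", profile.counts_rev)):
        total = counts.sum()
        setattr(profile, attr, counts / counts.mean() if total > 0 else None)
    return profile


def gc_skew_windows(sequence: str, window: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """GC skew (G-C)/(G+C) per tiling window; windows with G+C=0 are dropped.

    Returns (window midpoints, skew values).  A trailing partial window is
    ignored.
    """
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    n_win = len(arr) // window
    if n_win == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    trimmed = arr[: n_win * window].reshape(n_win, window)
    g = (trimmed == ord("G")).sum(axis=1)
    c = (trimmed == ord("C")).sum(axis=1)
    gc = g + c
    keep = gc > 0
    if (~keep).any():
        logger.info("%d of %d skew windows had G+C=0 and were skipped",
                    int((~keep).sum()), n_win)
    mids = np.arange(n_win) * window + window // 2
    skew = (g[keep] - c[keep]) / gc[keep]
    return mids[keep], skew


def gc_skew_binned(record: SequenceRecord, ori: OriginSpec,
                   skew: SkewParams = SkewParams(), n_bins: int = 1001) -> np.ndarray:
    """Mean GC skew of the 25-bp windows falling in each circular bin.

    Bins receiving no window are NaN.
    """
    mids, values = gc_skew_windows(record.sequence, skew.window)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    L = ori.chrom_len
    for mid, val in zip(mids, values):
        b = _bin_of_offset(signed_offset(int(mid), ori), L, n_bins)
        sums[b] += val
        counts[b] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def leading_fraction(hits: Sequence[G4Hit], ori: OriginSpec,
                     invert: bool = False) -> float:
    """Fraction of hits oriented with the leading strand.

    Under the default convention the fork on the positive-offset replichore
    moves toward increasing coordinates, so a "+" hit at positive offset
    (or a "-" hit at negative offset) is leading-oriented; ``invert`` flips
    the convention.  Hits whose midpoint offset is exactly 0 are ignored.
    """
    if not hits:
        raise ValueError("no hits")
    leading = lagging = 0
    for h in hits:
        off = signed_offset(((h.start + h.end) // 2) % ori.chrom_len, ori)
        if off == 0:
            continue
        is_leading = (h.strand == "+") == (off > 0)
        if invert:
            is_leading = not is_leading
        if is_leading:
            leading += 1
        else:
            lagging += 1
    if leading + lagging == 0:
        raise ValueError("no hits off the origin")
    return leading / (leading + lagging)


@dataclass
class LinearOriginProfile:
    halfwin: int
    counts_fwd: np.ndarray
    counts_rev: np.ndarray
    enrichment_fwd: np.ndarray | None = None
    enrichment_rev: np.ndarray | None = None
    n_origins: int = 0

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.halfwin, self.halfwin)


def linear_origin_profile(hits: Sequence[G4Hit], origins: Sequence[Interval],
                          halfwin: int = 2000) -> LinearOriginProfile:
    """Per-strand G4 coverage and enrichment around origin midpoints.

    Origin intervals contribute their midpoints; offsets are genomic
    (origins carry no orientation).  Enrichment divides each strand's
    counts by that strand's window mean; a strand with no coverage is
    reported as missing.
    """
    width = 2 * halfwin
    counts = {"+": np.zeros(width, dtype=np.int64),
              "-": np.zeros(width, dtype=np.int64)}
    by_contig: dict[str, list[G4Hit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    for o in origins:
        mid = (o.start + o.end) // 2
        lo, hi = mid - halfwin, mid + halfwin
        for h in by_contig.get(o.contig_id, ()):
            if h.end <= lo or h.start >= hi:
                continue
            a, b = max(h.start, lo), min(h.end, hi)
            counts[h.strand if h.strand in counts else "+"][a - lo : b - lo] += 1
    prof = LinearOriginProfile(halfwin, counts["+"], counts["-"],
                               n_origins=len(origins))
    for attr, c in (("enrichment_fwd", counts["+"]), ("enrichment_rev", counts["-"])):
        total = c.sum()
        setattr(prof, attr, c / c.mean() if total > 0 else None)
    return prof


def origins_with_hit_fraction(origins: Sequence[Interval], hits: Sequence[G4Hit],
                              halfwin: int = 2000) -> float:
    """Fraction of origins with >= 1 hit within +-halfwin of their midpoint.

    With halfwin=0 an origin counts only if a hit covers the midpoint base.
    """
    if not origins:
        raise ValueError("origins must be nonempty")
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append((h.start, h.end))
    n_with = 0
    for o in origins:
        mid = (o.start + o.end) // 2
        lo, hi = mid - halfwin, mid + halfwin + 1
        if any(s < hi and e > lo for s, e in by_contig.get(o.contig_id, ())):
            n_with += 1
    return n_with / len(origins)
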