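"""G-run / loop decomposition of G4 sequences and length distributions.

A G-run is a maximal stretch of at least ``min_run`` consecutive guanines;
loops are the stretches between consecutive G-runs.  Sequence before the
first run or after the last (possible for windowed-score hits, which may be
trimmed mid-loop) is recorded as flanks, never as loops, so that
``left_flank + runs/loops + right_flank`` reconstructs the input exactly.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .detect import G4Hit


@dataclass(frozen=True)
class G4Decomposition:
    g_run_lengths: tuple[int, ...]
    loop_sequences: tuple[str, ...]
    left_flank: str
    right_flank: str
    total_length: int
    gc_fraction: float
    canonical: bool  # >= 2 G-runs present

    @property
    def loop_lengths(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.loop_sequences)


def gc_fraction(sequence: str) -> float:
    """(G + C) / (A + C + G + T); ambiguity letters excluded from both sides."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = Counter(sequence)
    acgt = sum(counts[b] for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / acgt


def decompose(sequence: str, min_run: int = 3) -> G4Decomposition:
    """Split a sequence into flanks, maximal G-runs, and intervening loops.

    Sequences with fewer than two G-runs are flagged non-canonical and have
    an empty loop list.
    """
    if not sequence:
        raise ValueError("empty sequence")
    try:
        gc = gc_fraction(sequence)
    except ValueError:  # fully ambiguous input still decomposes
        gc = float("nan")
    runs = [(m.start(), m.end()) for m in re.finditer(f"G{{{min_run},}}", sequence)]
    if not runs:
        return G4Decomposition((), (), sequence, "", len(sequence),
                               gc, canonical=False)
    loops = tuple(
        sequence[prev_end:next_start]
        for (_, prev_end), (next_start, _) in zip(runs, runs[1:])
    )
    return G4Decomposition(
        g_run_lengths=tuple(e - s for s, e in runs),
        loop_sequences=loops,
        left_flank=sequence[: runs[0][0]],
        right_flank=sequence[runs[-1][1]:],
        total_length=len(sequence),
        gc_fraction=gc,
        canonical=len(runs) >= 2,
    )


def reconstruct(d: G4Decomposition) -> str:
    """Inverse of :func:`decompose`: flanks + runs + loops in order."""
    parts = [d.left_flank]
    for i, run_len in enumerate(d.g_run_lengths):
        parts.append("G" * run_len)
        if i < len(d.loop_sequences):
            parts.append(d.loop_sequences[i])
    parts.append(d.right_flank)
    return "".join(parts)


def length_distributions(hits: Sequence[G4Hit], min_run: int = 3) -> dict[str, dict[int, int]]:
    """Empirical (value -> count) tables of G4 total, G-run, and loop lengths.

    Minus-strand hits are decomposed on their own strand (the reverse
    complement of the stored forward-reference sequence).
    """
    from .io_formats import revcomp

    totals: Counter = Counter()
    run_lengths: Counter = Counter()
    loop_lengths: Counter = Counter()
    for h in hits:
        if h.sequence is None:
            raise ValueError("hits must carry sequences")
        seq = revcomp(h.sequence) if h.strand == "-" else h.sequence
        d = decompose(seq, min_run=min_run)
        totals[d.total_length] += 1
        run_lengths.update(d.g_run_lengths)
        loop_lengths.update(d.loop_lengths)
    return {
        "total_length": dict(sorted(totals.items())),
        "g_run_length": dict(sorted(run_lengths.items())),
        "loop_length": dict(sorted(loop_lengths.items())),
    }
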