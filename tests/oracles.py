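"""Independent brute-force oracles used to validate the implementation.

Everything here deliberately avoids the code paths (and the `re` module
semantics) of the package: the motif matcher is a recursive-descent search
with explicit greedy preference order, window means are recomputed from
scratch per window, and interval statistics use all-pairs scans or per-base
bitmaps.
"""

from __future__ import annotations

ACGT = set("ACGT")


def _maximal_g_run(seq: str, i: int) -> int:
    k = i
    n = len(seq)
    while k < n and seq[k] == "G":
        k += 1
    return k - i


def _match_end(seq: str, i: int, runs_left: int,
               min_run: int, loop_min: int, loop_max: int) -> int | None:
    """End of the greedy match of the motif grammar starting at i, if any.

    Preference order mirrors greedy regex backtracking: longest run first,
    then longest loop, deeper choices revised before shallower ones.
    """
    m = _maximal_g_run(seq, i)
    if m < min_run:
        return None
    if runs_left == 1:
        return i + m
    for r in range(m, min_run - 1, -1):
        for l in range(loop_max, loop_min - 1, -1):
            j = i + r + l
            if j + min_run * (runs_left - 1) + loop_min * (runs_left - 2) > len(seq):
                continue
            if any(ch not in ACGT for ch in seq[i + r : j]):
                continue
            e = _match_end(seq, j, runs_left - 1, min_run, loop_min, loop_max)
            if e is not None:
                return e
    return None


def brute_regex_spans(seq: str, min_run: int = 3, loop_min: int = 1,
                      loop_max: int = 7, n_runs: int = 4) -> list[tuple[int, int]]:
    """Left-to-right non-overlapping greedy matches of the consensus grammar."""
    spans = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "G":
            e = _match_end(seq, i, n_runs, min_run, loop_min, loop_max)
            if e is not None:
                spans.append((i, e))
                i = e
                continue
        i += 1
    return spans


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def brute_regex_hits(seq: str, **kw) -> set[tuple[int, int, str]]:
    """Both-strand grammar hits as (start, end, strand) on forward coords."""
    n = len(seq)
    hits = {(s, e, "+") for s, e in brute_regex_spans(seq, **kw)}
    hits |= {(n - e, n - s, "-") for s, e in brute_regex_spans(revcomp(seq), **kw)}
    return hits


def naive_base_scores(seq: str, cap: int = 4) -> list[int]:
    """Char-by-char run scoring, no vectorization."""
    n = len(seq)
    scores = [0] * n
    i = 0
    while i < n:
        ch = seq[i]
        if ch in "GC":
            j = i
            while j < n and seq[j] == ch:
                j += 1
            value = min(j - i, cap) * (1 if ch == "G" else -1)
            for k in range(i, j):
                scores[k] = value
            i = j
        else:
            i += 1
    return scores


def naive_window_means(seq: str, w: int, cap: int = 4) -> list[float]:
    """Every window mean recomputed from scratch (O(n*w))."""
    scores = naive_base_scores(seq, cap)
    return [sum(scores[i : i + w]) / w for i in range(len(scores) - w + 1)]


def allpairs_fractional(a: list[tuple[int, int]], b: list[tuple[int, int]],
                        min_frac: float) -> set[tuple[int, int]]:
    """All (i, j) pairs matching the either-span fractional-overlap rule."""
    pairs = set()
    for i, (s1, e1) in enumerate(a):
        for j, (s2, e2) in enumerate(b):
            ov = min(e1, e2) - max(s1, s2)
            if ov <= 0:
                continue
            if ov >= min_frac * (e1 - s1) or ov >= min_frac * (e2 - s2):
                pairs.add((i, j))
    return pairs


def bitmap_overlap_bp(a: list[tuple[int, int]], b: list[tuple[int, int]],
                      length: int) -> int:
    """Per-base membership count of positions covered by both span sets."""
    in_a = bytearray(length)
    in_b = bytearray(length)
    for s, e in a:
        for p in range(max(s, 0), min(e, length)):
            in_a[p] = 1
    for s, e in b:
        for p in range(max(s, 0), min(e, length)):
            in_b[p] = 1
    return sum(1 for x, y in zip(in_a, in_b) if x and y)


def naive_merge(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """O(n^2) pairwise merging until fixpoint."""
    spans = [list(s) for s in spans]
    changed = True
    while changed:
        changed = False
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                a, b = spans[i], spans[j]
                if a[0] < b[1] and b[0] < a[1]:
                    spans[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    del spans[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((s, e) for s, e in spans)


def random_sequence(rng, length: int, gc: float) -> str:
    import numpy as np

    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))
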