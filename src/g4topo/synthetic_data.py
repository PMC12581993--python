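"""Synthetic genomes with planted G4 structure and ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so every stage of the pipeline can be exercised end to end without
downloading data:

* an i.i.d. background sequence of configurable GC content; on circular
  chromosomes the G/C balance of the forward strand is tilted in opposite
  directions on the two replichores to realize a planted GC skew;
* non-overlapping gene models (exons separated by introns) with promoter,
  TES-downstream, and intronic splice-flank regions;
* consensus-grammar G4s planted at a baseline Poisson rate, multiplied by
  configurable factors inside the special regions, with strands drawn
  uniformly (linear) or with a leading-strand bias (circular);
* a truth set of planted spans; the genome is re-scanned after planting so
  motifs that arise by chance in the background are tallied (labelled
  separately), never scrubbed.

Each planted motif is flanked by short sanitized guard zones (no G/C run of
three or more, A/T at the immediately adjacent base) so the consensus
scanner recovers exactly the planted coordinates; guards also enforce the
spacing that keeps planted spans from merging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .detect import DetectParams, scan_regex
from .io_formats import FeatureRecord, Interval, SequenceRecord, revcomp

GUARD = 10  # bp sanitized on each side of a planted span


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated species.

    Rates are in planted G4s per megabase; factors multiply the baseline
    rate inside their region class (1.0 = no enrichment).  ``leading_bias``
    is the probability that a planted G4 on a circular chromosome is
    oriented with the leading strand; ``skew_amp`` is the planted
    per-replichore GC skew of the forward strand.
    """

    genome_length: int = 200_000
    gc: float = 0.40
    topology: str = "linear"
    ori_mid: int | None = None
    skew_amp: float = 0.0
    n_genes: int = 50
    exons_per_gene: int = 3
    gene_len: int = 2000
    exon_len: int = 300
    baseline_g4_rate: float = 100.0
    promoter_factor: float = 1.0
    tes_factor: float = 1.0
    splice_factor: float = 1.0
    promoter_len: int = 500
    tes_len: int = 500
    splice_len: int = 250
    leading_bias: float = 0.5
    run_len_range: tuple[int, int] = (3, 5)
    loop_len_range: tuple[int, int] = (1, 7)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0,1)")
        if self.topology not in ("linear", "circular"):
            raise ValueError("topology must be linear or circular")
        if not (-1 <= self.skew_amp <= 1):
            raise ValueError("skew_amp must be in [-1,1]")
        if not (0 <= self.leading_bias <= 1):
            raise ValueError("leading_bias must be in [0,1]")
        for name in ("baseline_g4_rate", "promoter_factor", "tes_factor",
                     "splice_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def origin(self) -> int:
        return self.genome_length // 2 if self.ori_mid is None else self.ori_mid


@dataclass
class TruthSet:
    """Planted spans with their region class, plus background-arising motifs."""

    planted: list[Interval] = field(default_factory=list)
    background_motifs: list[Interval] = field(default_factory=list)

    def assignments(self) -> dict[Interval, str]:
        return {iv: iv.name or "background" for iv in self.planted}


@dataclass
class SpeciesData:
    name: str
    record: SequenceRecord
    features: list[FeatureRecord]
    truth: TruthSet
    spec: SyntheticSpec


def sample_g4(rng: np.random.Generator,
              run_len_range: tuple[int, int] = (3, 5),
              loop_len_range: tuple[int, int] = (1, 7),
              n_runs: int = 4) -> str:
    """One consensus-grammar instance; loop bases are drawn from {A,C,T}
    so runs are never accidentally extended."""
    rlo, rhi = run_len_range
    llo, lhi = loop_len_range
    if rlo < 2 or llo < 1 or rhi < rlo or lhi < llo:
        raise ValueError("invalid run/loop length ranges")
    parts = []
    for i in range(n_runs):
        parts.append("G" * int(rng.integers(rlo, rhi + 1)))
        if i < n_runs - 1:
            loop_len = int(rng.integers(llo, lhi + 1))
            parts.append("".join(rng.choice(list("ACT"), size=loop_len)))
    return "".join(parts)


def _background_bases(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. background; circular genomes tilt G vs C per replichore."""
    L = spec.genome_length
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    half_at, half_gc = (1 - spec.gc) / 2, spec.gc / 2
    if spec.topology == "linear" or spec.skew_amp == 0:
        p = [half_at, half_gc, half_gc, half_at]
        return rng.choice(bases, size=L, p=p)
    # signed offsets from the origin; positive replichore gets +skew_amp
    pos = np.arange(L)
    off = (pos - spec.origin) % L
    off = np.where(off * 2 > L, off - L, off)
    seq = np.empty(L, dtype=np.uint8)
    for mask, amp in ((off > 0, spec.skew_amp), (off <= 0, -spec.skew_amp)):
        n = int(mask.sum())
        p = [half_at, half_gc * (1 - amp), half_gc * (1 + amp), half_at]
        seq[mask] = rng.choice(bases, size=n, p=p)
    return seq


def _place_genes(spec: SyntheticSpec, rng: np.random.Generator) -> list[FeatureRecord]:
    if spec.n_genes == 0:
        return []
    margin = spec.promoter_len + 100
    usable = spec.genome_length - 2 * margin
    slot = usable // spec.n_genes
    clearance = max(spec.promoter_len, spec.tes_len)
    if slot < spec.gene_len + 2 * clearance + 1:
        raise ValueError(
            f"infeasible packing: {spec.n_genes} genes of {spec.gene_len} bp "
            f"plus flanking regions do not fit in {spec.genome_length} bp"
        )
    n_ex = spec.exons_per_gene
    intron_len = 0
    if n_ex > 1:
        intron_len = max((spec.gene_len - n_ex * spec.exon_len) // (n_ex - 1), 0)
    gene_span = n_ex * spec.exon_len + (n_ex - 1) * intron_len
    features: list[FeatureRecord] = []
    for g in range(spec.n_genes):
        slack = slot - gene_span - 2 * clearance
        start = margin + g * slot + clearance + int(rng.integers(0, slack + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{g:04d}"
        features.append(FeatureRecord("chr1", start, start + gene_span, strand,
                                      "gene", gid, "protein_coding"))
        for e in range(n_ex):
            ex_start = start + e * (spec.exon_len + intron_len)
            features.append(FeatureRecord("chr1", ex_start, ex_start + spec.exon_len,
                                          strand, "exon", gid, "protein_coding"))
    return features


def _special_regions(spec: SyntheticSpec,
                     features: Sequence[FeatureRecord]) -> dict[str, list[tuple[int, int]]]:
    """Disjoint planting regions: promoter/tes flanks and intronic splice flanks."""
    regions: dict[str, list[tuple[int, int]]] = {"promoter": [], "tes": [], "splice": []}
    genes = [f for f in features if f.kind == "gene"]
    exons = [f for f in features if f.kind == "exon"]
    for g in genes:
        if g.strand == "+":
            regions["promoter"].append((g.start - spec.promoter_len, g.start))
            regions["tes"].append((g.end, g.end + spec.tes_len))
        else:
            regions["promoter"].append((g.end, g.end + spec.promoter_len))
            regions["tes"].append((g.start - spec.tes_len, g.start))
    from .io_formats import derive_introns

    for intron in derive_introns(exons):
        half = (intron.end - intron.start) // 2
        flank = min(spec.splice_len, half)
        if flank > 0:
            regions["splice"].append((intron.start, intron.start + flank))
            regions["splice"].append((intron.end - flank, intron.end))
    for lst in regions.values():
        lst.sort()
    return regions


def _overlaps_any(span: tuple[int, int], spans: list[tuple[int, int]]) -> bool:
    return any(s < span[1] and e > span[0] for s, e in spans)


def _sanitize_guard(seq: np.ndarray, lo: int, hi: int, adjacent: list[int],
                    rng: np.random.Generator) -> None:
    """Break any G/C run of >=3 inside [lo,hi) and force A/T at the bases
    immediately adjacent to the planted span."""
    G, C = ord("G"), ord("C")
    at = np.frombuffer(b"AT", dtype=np.uint8)
    for p in adjacent:
        if 0 <= p < len(seq) and seq[p] in (G, C):
            seq[p] = rng.choice(at)
    for i in range(max(lo, 2), min(hi, len(seq))):
        b = seq[i]
        if b in (G, C) and seq[i - 1] == b and seq[i - 2] == b:
            seq[i] = rng.choice(at)


def generate_genome(spec: SyntheticSpec, name: str = "chr1") -> SpeciesData:
    """Simulate one species: sequence, gene annotation, planted truth.

    The genome is re-scanned with the consensus detector after planting, so
    the truth set reflects realized motif instances: every planted span plus
    any motif that arose by chance in the background (labelled separately).
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    seq = _background_bases(spec, rng)
    features = _place_genes(spec, rng)
    for i, f in enumerate(features):
        features[i] = replace(f, contig_id=name)
    regions = _special_regions(spec, features)

    L = spec.genome_length
    rate_bp = spec.baseline_g4_rate / 1e6
    special_len = {k: sum(e - s for s, e in v) for k, v in regions.items()}
    background_len = L - sum(special_len.values())
    plan = [
        ("background", 1.0, background_len, None),
        ("promoter", spec.promoter_factor, special_len["promoter"], regions["promoter"]),
        ("tes", spec.tes_factor, special_len["tes"], regions["tes"]),
        ("splice", spec.splice_factor, special_len["splice"], regions["splice"]),
    ]
    all_special = sorted(s for v in regions.values() for s in v)

    occupied: list[tuple[int, int]] = []
    planted: list[Interval] = []
    ori = None
    if spec.topology == "circular":
        from .replication import OriginSpec, signed_offset

        ori = OriginSpec(name, spec.origin, L)

    for label, factor, region_len, region_list in plan:
        if region_len <= 0 or factor == 0 or rate_bp == 0:
            continue
        n = int(rng.poisson(rate_bp * factor * region_len))
        for _ in range(n):
            motif = sample_g4(rng, spec.run_len_range, spec.loop_len_range)
            m = len(motif)
            placed = False
            for _attempt in range(200):
                if region_list is None:
                    start = int(rng.integers(GUARD, L - GUARD - m))
                else:
                    weights = np.array([e - s for s, e in region_list], dtype=float)
                    ridx = int(rng.choice(len(region_list), p=weights / weights.sum()))
                    rs, re_ = region_list[ridx]
                    if re_ - rs < m:
                        continue
                    start = int(rng.integers(rs, re_ - m + 1))
                    if start < GUARD or start + m > L - GUARD:
                        continue
                span = (start - GUARD, start + m + GUARD)
                if _overlaps_any(span, occupied):
                    continue
                if region_list is None and _overlaps_any((start, start + m), all_special):
                    continue
                placed = True
                break
            if not placed:
                continue
            if spec.topology == "circular":
                mid_off = signed_offset((start + m // 2) % L, ori)
                leading = rng.random() < spec.leading_bias
                if mid_off > 0:
                    strand = "+" if leading else "-"
                else:
                    strand = "-" if leading else "+"
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            payload = motif if strand == "+" else revcomp(motif)
            seq[start : start + m] = np.frombuffer(payload.encode(), dtype=np.uint8)
            occupied.append((start - GUARD, start + m + GUARD))
            planted.append(Interval(name, start, start + m, strand, name=label))

    for s, e in occupied:
        _sanitize_guard(seq, s, min(s + GUARD, e), [s + GUARD - 1], rng)
        _sanitize_guard(seq, max(e - GUARD, s), e, [e - GUARD], rng)

    record = SequenceRecord(name, seq.tobytes().decode("ascii"), spec.topology)
    truth = TruthSet(planted=sorted(planted, key=lambda i: (i.start, i.end)))
    planted_keys = {(p.start, p.end, p.strand) for p in truth.planted}
    params = DetectParams(min_run=spec.run_len_range[0],
                          loop_min=spec.loop_len_range[0],
                          loop_max=spec.loop_len_range[1])
    for h in scan_regex(record, params):
        if (h.start, h.end, h.strand) not in planted_keys:
            truth.background_motifs.append(
                Interval(name, h.start, h.end, h.strand, name="background_motif")
            )
    return SpeciesData(name, record, features, truth, spec)


def generate_cohort(n_species: int, spec: SyntheticSpec,
                    between_species_jitter: float = 0.1,
                    seed: int = 0) -> list[SpeciesData]:
    """Independent species with jittered baseline rates.

    Species s derives its generator seed from substream s of ``seed``; the
    baseline rate is multiplied by a lognormal factor with the given
    log-scale sd.  Deterministic given (seed, n_species, spec).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    out = []
    for s, child in enumerate(np.random.SeedSequence(seed).spawn(n_species)):
        state = child.generate_state(2)
        sub_seed = int(state[0])
        jitter_rng = np.random.Generator(np.random.PCG64(int(state[1])))
        factor = float(jitter_rng.lognormal(0.0, between_species_jitter)) \
            if between_species_jitter > 0 else 1.0
        sp = replace(spec, seed=sub_seed,
                     baseline_g4_rate=spec.baseline_g4_rate * factor)
        out.append(generate_genome(sp, name=f"sp{s:03d}"))
    return out
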