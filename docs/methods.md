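# Methods

This note documents the models and procedures g4topo implements, the
parameters that matter, the synthetic world the tests rely on, and the
numerical choices made where the design was genuinely open.

## Coordinate and strand conventions

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted at the parse/write boundary only. Overlap always
means "shares ≥ 1 bp", so abutting spans never merge and never match.
Minus-strand hits are stored on forward-reference coordinates with the
forward-strand slice as their sequence; strand-aware analyses reverse
complement on demand. A hit on a gene's annotated strand is *nontemplate*
(sense, mRNA-like); the opposite strand is *template*.

## Detection

### Consensus motif

The grammar G≥3 N1–7 G≥3 N1–7 G≥3 N1–7 G≥3 is compiled to a regular
expression with loop alphabet {A,C,G,T}; N and other IUPAC ambiguity
letters match neither runs nor loops (an ambiguous base cannot be asserted
to take part in a quartet or loop). Matching is left-to-right,
non-overlapping, with greedy quantifiers — standard regex semantics.
Because overlap handling within one method is absorbed by downstream
merging anyway, this choice only fixes which of several overlapping
parsings is reported. All grammar parameters (min run 3, loops 1–7,
4 runs) are exposed in `DetectParams`.

### Windowed G-richness score

Per-base scores: a base inside a maximal run of k identical G (C) scores
+min(k, 4) (−min(k, 4)); everything else scores 0 and terminates runs.
Window means (w = 25) at or beyond the threshold (s = 1.5, chosen upstream
for < 10 % FDR) seed candidate regions per sign; overlapping same-sign
windows merge; each region is trimmed to begin and end on its majority
letter. The region score is the maximum-magnitude qualifying window mean
(a region-wide mean is available via the same data). Two consequences of
trimming worth knowing: a trimmed region can be shorter than one window,
and the guarantee that survives trimming is that each region *derives
from* (overlaps) at least one qualifying window — the tests check exactly
that. Contigs shorter than w produce an empty call set with a logged
notice, not an error.

### Merging and reconciliation

Overlapping hits are replaced by their union span; merging is per strand
by default (the source study's merge statement is strand-silent), with a
flag for strand-agnostic merging that records "." when constituents
disagree. Cross-method agreement uses the fractional rule satisfied by
*either* span (≥ 0.5 of the shorter, ties count); reference mapping uses
0.1. Venn output reports both the matched-pair count and per-set
matched-hit counts, since a hit can match several partners.

## Densities

Both flavours are always computed — G4 bp per Mb (overlap of merged hits)
and G4 count per Mb — because published figures use both and they diverge
for long or merged hits. Compartment densities merge the compartment's
annotations per contig first; an empty compartment raises a labelled error
rather than returning 0, mirroring the exclusion of unannotated species.

## Metaprofiles

Occupancy counts per-bp coverage (a hit increments every offset it
covers); a count-at-start mode exists behind a flag. Offsets use the
half-open window [−F, F) with F = 500 by default (also reused for splice
sites, configurable); offset 0 is the anchor base; anchors near contig
edges contribute truncated windows while the enrichment divisor remains
the full offset set (global-mean normalization). Species are pooled by
summing counts before normalizing (the study's wording supports pooling);
per-species averaging would weight small genomes up and is not the
default.

Monte-Carlo bands resample species with replacement (N = 1000, 2.5/97.5
percentiles); replicate r draws from substream r of one seeded RNG family,
so results are independent of execution order. Two band flavours exist:
per-offset bands (`mc_confidence`) and bands of a regional mean fold
(`mc_region_band`). Quote the regional band for regional claims — the
per-offset bands also carry per-position counting noise and are much
wider.

A structural caveat on fold enrichment: because the normalizer is the
window-wide mean, a region occupying fraction q of the window with rate
ratio f over the rest has mean enrichment f/(q·f + 1 − q) — bounded by
1/q. For an enriched half-window (q = ½) the fold can never exceed 2
however strong the planting; recovering the underlying rate ratio
requires comparing the enriched region against a far-field region, which
is what the recovery tests do.

## Replication origins

Circular positions are reduced to signed offsets from the oriC midpoint in
(−L/2, L/2] (antipode mapped to +L/2); 1001 bins put oriC in center bin
500 with the terminus at both extremes. (The source text is
self-contradictory about whether bin 500 is oriC or the terminus; the
oriC-centered reading matches the figure and is adopted.) A hit occupies
the bin of its midpoint and additionally every bin its span touches.
Per-strand enrichment divides counts by the per-strand bin mean; a strand
with zero total is reported missing, not zero. GC skew is (G−C)/(G+C) in
25-bp tiling windows assigned to the bin of their midpoint and averaged;
windows with G+C = 0 are skipped (the statistic is a ratio) and logged.

Leading/lagging is a *convention*, not a measurement: by default the fork
on the positive-offset replichore moves toward increasing coordinates, so
a "+" hit at positive offset is leading-oriented; an `invert` flag flips
it. The GC-skew track is reported alongside so the biological label can be
anchored to the skew sign rather than hard-wired.

## Synthetic world

`SyntheticSpec` defaults define the stated world: GC 0.40 (a typical
genome-wide value for many eukaryotes and a mid-range prokaryote),
baseline 100 planted G4s/Mb (between typical bacterial and G4-dense
eukaryotic values; ~20 per 200-kb genome), 50 genes of 2 kb (three 300-bp
exons, two 550-bp introns), planted motifs with runs of 3–5 and loops of
1–7 drawn from {A,C,T}, neutral region factors 1.0, leading bias 0.5 and
skew 0. Region classes partition the genome: promoter [−500, 0) upstream
of the TSS, TES-downstream [0, 500), intronic splice flanks of up to
250 bp per junction, and background (everything else); each class receives
a Poisson number of motifs at baseline × factor and background placement
rejects positions inside special regions, so a factor is an absolute rate
multiplier for its class.

Each planted span is flanked by 10-bp sanitized guards (no G/C run ≥ 3,
A/T at the adjacent base) — enough to make it impossible for any grammar
parse to extend across the boundary (a run would need 3 consecutive G in
the guard; a loop cannot bridge 10 bp) — so the consensus scanner recovers
exactly the planted coordinates. Spans-plus-guards are kept disjoint,
which also enforces the > loop-max separation that prevents planted
super-motifs. The genome is re-scanned after planting; chance
background-arising motifs are kept and labelled, never scrubbed (scrubbing
would distort composition). Circular skew is realized by shifting
probability gc·amp/2 from C to G on the positive replichore (and the
reverse on the other), giving expected forward-strand skew ±amp exactly.

What the generator does **not** emulate: repeat landscapes, codon
structure, phylogenetic correlation between species, chromatin context,
multi-origin chromosomes, and planting across the circular origin of
coordinates (spans stay within [0, L)). A green recovery test therefore
establishes correctness of the statistics on i.i.d.-background genomes
with planted structure — not detector performance on real genomes.

One quantitative consequence of the planting design: because each motif is
placed wholly inside its (short) region, per-offset coverage is
concentrated in region interiors by a factor W/(W − ℓ + 1) (≈ 1.10 for
250–500-bp regions and ≈ 28-bp motifs), with tapered edges. Recovery
tests therefore expect the upstream/downstream rate ratio near
f / 1.1 rather than exactly f.

## Determinism

All randomness flows from `numpy.random.SeedSequence`: cohorts spawn one
substream per species, Monte-Carlo replicates one per replicate. The
orchestrated `run-all` writes a manifest without timestamps; a rerun with
the same config and seed is byte-identical, and the test suite asserts
this at the output-tree level.

## Known limitations

* The windowed scorer follows the published algorithm's parameters but the
  exact trimming of the original implementation is not fully specified
  upstream; the trimming here (to majority-letter boundaries) is the
  documented reading and is parameterized.
* Venn counting of "common" calls is reported both as matched pairs and as
  matched hits because the upstream figure is ambiguous between the two.
* RNA G4s, machine-learned propensity scores, and thermodynamic stability
  are out of scope.
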