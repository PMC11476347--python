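# Methods

## Coordinate frame and replichore geometry

Chromosomes are circular; sequences are stored linearly and every interval
operation accepts wrap-around intervals (`start_bp > end_bp`). All base-pair
coordinates are 1-based inclusive; degree coordinates are half-open
[0°, 360°), with `C° = C_bp · 360 / L_bp` reduced mod 360 so position 1 (the
first base of the oriC region) is 0°.

**oriC anchoring.** The origin is located by semi-global alignment of a
supplied probe (477 bp by default) against both strands with edlib; the
anchor is the first bp of the matched region on the plus strand. A match must
reach 90% identity and 80% probe coverage (semi-global alignment covers the
whole probe by construction); otherwise a not-found error is raised rather
than guessing. Identity is `(probe_len − edit_distance) / max(aln_len,
probe_len)`.

**terC calling.** Two windowed strand-asymmetry profiles are computed after
rotation to oriC, with window = step = 0.1% of the chromosome length
(rounded, floor 100 bp; windows tile the circle, the last window wrapping):

* GC skew: per-window `(G−C)/(G+C)` on the plus strand (windows with no G/C
  contribute 0; N bases are never counted);
* octamer asymmetry: per-window (forward occurrences − reverse-complement
  occurrences) of GGGCAGGG, overlapping occurrences counted.

Sign convention: with oriC at 0° and the leading strands G-rich and
forward-motif-rich, both cumulative profiles attain their global **maximum**
near terC. The octamer extremum is the primary call; the GC-skew extremum is
reported as agreement (`agreement_deg`). Because the octamer cumulative curve
is flat between the last forward and first reverse occurrence, the call is
the midpoint of the maximal plateau, which is unbiased when occurrences
approach terC from both sides. A call is refused (low-confidence error) when
the cumulative range does not exceed `3 · sd(window values) · √n_windows` —
three standard deviations of the endpoint of a random walk with the observed
per-window noise; a plain 3·sd floor would never trigger, since even a
signal-free cumulative walk grows like √n.

terC is reported as a point; delimiting a terC *region* is out of scope (no
defining algorithm exists for it here).

## tRNA catalog

Genes are numbered 001 upward by increasing rotated plus-strand coordinate,
one single pass 0°→360° through terC — the numbering that makes the reference
layout's hot-spot genes come out as 010 (Thr/GGT), 030 (Asn/GTT) and
039 (Lys/CTT). Ties on start position are broken by strand (+ first) then
anticodon, so numbering is stable under permutation of the input. Chromosome
quarters are fixed at 0/90/180/270° regardless of the called terC angle. The
strand-asymmetry test is a Pearson chi-square against a uniform expectation,
offered for both a 2-category (strand) and an 8-category (strand × quarter)
grouping; the published statistic's grouping is not recoverable (its printed
statistic and p-value are mutually inconsistent for df = 1), so neither is
asserted as canonical.

## att-site detection and classification

Candidate direct repeats are maximal ungapped matches seeded by exact
`min_len`-mers (12 by default) between two windows: one copy must end within
150 bp of the element's left boundary, the other start within 150 bp of its
right boundary. Extension proceeds through mismatches while the mismatch
fraction stays ≤ 5% (configurable; planted/real recombinant sites are exact),
and matches must start and end on agreeing columns. Candidates are ranked by
length, then proximity to the annotated boundaries. Lengths outside
12–98 bp are rejected — the empirical size range of these recombinant sites.

Classification: the copy overlapping a tRNA gene is attR, the distal copy
attL. The anchor is `three_prime`/`five_prime` when attR reaches the
strand-aware terminal base of the gene; `central` (gene disrupted) when the
element interval lies inside the gene locus, or when the attR overlap sits
entirely inside the middle 40% of the gene. `in_gene_bp + spacer_bp = att
length` always. An attR overlapping two distinct tRNA genes is an ambiguity
error. Minus-strand genes are evaluated in gene-local 5′→3′ coordinates so
"3′ end" is biological.

A disrupted gene's annotation spans its whole locus including the inserted
element; consequently element-inside-gene containment is the disruption
signal, and in-silico excision of the element restores the intact gene span.

**Nested integrations.** The element interior is scanned for near-copies of
the flanking repeat. A match counts only when its agreeing columns cover
≥ 90% of the *full flank length*: a chance ≥ 12 bp match to a sub-segment of
the flank is not a copy of the repeat (in an 80 kb interior such chance
seeds are expected at an appreciable rate, and treating them as copies would
fabricate sub-element splits). Each internal copy splits the element into
sequential sub-elements recorded as (offset, length).

**Excision.** Removing the element plus exactly one repeat copy is the
inverse of the integration model; since the copies are identical, removing
either copy yields the same sequence. Excision refuses att pairs that are
unequal beyond the configured mismatch tolerance (exact by default). For a
nested pair, excising the inner element (between the gene-side flank's
matching segment and the internal copy) and then the outer one restores the
pre-integration genome; this is exercised in the tests.

## Hot-spot statistics

Per-gene integration frequencies are shares of all calls across the cohort.
The uniformity test is a Pearson chi-square over the genes with ≥ 1
integration (uniform null, df = k − 1, no continuity correction); the
survival function is the regularized upper incomplete gamma
(via `scipy.stats.chi2.sf`), cross-checked in tests against
`scipy.special.gammaincc` and the df = 2 closed form `e^(−x/2)`. Tiers are
the exact contiguous minimum-variance partition of the sorted frequencies
(Fisher–Jenks dynamic program, O(k·n²)), k = 3 by default, verified against
exhaustive enumeration for small n. Shannon diversity uses natural log over
categories with positive count. The geometric-progression summary of
pair-class counts is the mean and SEM of successive ratios.

## Synteny blocks

One block per unordered element pair: the single highest-scoring local
alignment (ties: longer block, then lexicographic coordinates), both strands
considered. Scoring: match +1, mismatch −2, gap −5 − 2·length. For pairs with
`len_a · len_b ≤ 4·10⁵` the block is the exact affine-gap Smith–Waterman
(Gotoh) optimum with traceback — tested to equal an independent
implementation's optimal score. Longer pairs use exact 15-mer seeds, ungapped
x-drop extension (x-drop 50), and greedy chaining of colinear segments with
gaps ≤ 200 bp bridged by an exact global alignment (computed in a canonical
argument order so results are symmetric in the input pair). Identity =
matching columns / alignment columns. Retention filter: > 8000 columns and
> 90% identity, applied strictly. The retained blocks export to a
pydantic-validated JSON document (elements with class-based colors, links
with coordinates) in deterministic order.

## Synthetic-data generator

The generator emulates, at desk scale, the features the pipeline must
recover; its defaults are the package's study conditions:

* **400 kb** chromosome (degree-based logic is length-invariant; desk-scale
  tests use 250–300 kb), GC fraction 0.62 (alphaproteobacterial),
* oriC probe verbatim at position 1; a fixed default 477 bp probe,
* (G−C) composition bias ±0.04 switching sign at terC (170° by default),
* GGGCAGGG planted forward-only before terC and reverse-complement-only
  after, at 2.0/kb. The density is set by a localization argument: the call
  sits mid-way between the last forward and first reverse occurrence, so the
  mean inter-occurrence gap (0.5 kb = 0.45° at 400 kb) must be well inside
  the ±2° recovery tolerance. A real megabase chromosome carries the same
  cumulative contrast at lower density simply by being longer,
* 52 tRNA genes (76 bp canonical bodies, anticodon at offset 34,
  deterministic per isotype/anticodon) in the reference ordinal layout,
  evenly spaced, 39 on the plus and 13 on the minus strand (13/12 among the
  25 integration-site genes),
* integrations per the duplication model: the att segment (gene end or
  interior + spacer) is copied and the payload inserted between the copies on
  the far side of the gene body, for either gene strand and all three anchor
  classes; nested specs insert an inner element against an internal repeat
  copy; disrupting integrations can carry a replacement tRNA whose body is
  diverged to ~80% identity (substitution every 5th position, anticodon
  preserved) — both realistic for phage-borne tRNA genes and guaranteeing the
  imported copy is never mistaken for an internal att repeat,
* six forced-mismatch columns flank every planted repeat copy, making the
  planted repeat *maximal*: without this, chance matches at the boundaries
  would legitimately extend the detected repeat past the planted coordinates
  and boundary-exact recovery would not be a well-posed expectation,
* cohorts: per strain (seed = base seed + strain index, one generator stream
  per genome), each tRNA gene independently receives ≤ 1 integration with
  probability `min(1, 9 × tier probability)`. Per-gene *shares* of
  integrations are invariant to the multiplicity scale (9) and match the
  planted tiers 0.02/0.05/0.11 in expectation; the scale itself is set by a
  power analysis — with 27 strains the three-gene top tier is reliably
  separable from the six mid-tier genes only when hot-spot genes recruit in
  nearly every strain. Element classes, integrase-origin labels and
  phage-fragment flags are drawn with frequencies mirroring the observed
  composition of tRNA-anchored elements.

What the generator does **not** emulate: phage gene content, integrase
sequences, sequence evolution between strains, annotation error in element
boundaries beyond the ±150 bp search window, multi-replicon genomes, and
degenerate/partial repeats. Passing tests therefore demonstrate correctness
of the geometry, detection, classification and statistics on clean planted
truth — not robustness to noisy real-world annotations.

## Numerical choices and degenerate inputs

Windows with zero G+C contribute 0 skew. `argmax` plateaus are resolved at
the plateau midpoint. The tier dynamic program breaks SSE ties toward the
earlier split (1e−15 slack). Empty frequency tables, single categories,
all-zero counts, k > n tiers, zero expected counts, unequal aligned lengths
and empty FASTA records all raise explicit errors. Report output is
deterministic: sorted table names, fixed column order, sorted JSON keys.

## Known limitations

* The repeat finder reports ungapped repeats only; recombinant sites with
  internal indels between attL and attR would be truncated at the indel.
* For very long elements the synteny aligner is heuristic; exactness is
  guaranteed (and tested) only at the exact-DP size threshold.
* The octamer terminus method assumes the motif's strand asymmetry flips at
  terC, the documented alphaproteobacterial pattern; it is interpreted here
  as a cumulative strand-difference extremum.
* `excise` on an element spanning the linear origin returns the genome
  re-linearized at the junction.
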