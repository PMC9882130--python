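# Methods

## Signal model

All signal is histone modification density (HMD): the calibrated estimate
of the percent of nucleosomes at a locus bearing a given H3K4 methylform
(me0/me1/me2/me3). HMD is non-negative but deliberately *not* clamped at
100% — calibrated tracks can exceed 100% through noise, and thresholding
operates on raw values. Tracks are piecewise-constant segments on 0-based
half-open coordinates (BED/bedGraph native); gaps between segments read as
HMD 0, absence of signal being the only defensible interpretation in the
absence of an imputation rule. Intervals that share only a boundary point
never overlap, everywhere in the package.

## Broad H3K4me3 domain (BH4D) calling

A BH4D is a maximal run of consecutive `bin_bp` windows (default 50 bp),
each with HMD ≥ `min_hmd` (default 25%), whose total length is ≥
`min_len_bp` (default 2000 bp) and which contains at least one annotated
TSS point. Both thresholds are inclusive: exactly 2000 bp at exactly
25.0% qualifies. Choices made where the procedure was genuinely open:

* **Bin grid** is anchored at coordinate 0 of each chromosome
  (deterministic; a `grid_offset_bp` parameter exposes phase-sensitivity
  checks). Each bin's value is the coverage-weighted mean of overlapping
  segments.
* **TSS intersection** is evaluated against TSS *points* (the start
  coordinate of a 1 bp record), not promoter windows.
* **Counting is TSS-level**: a domain spanning k TSSs contributes k, and
  several domains over one TSS contribute 1. This makes comparisons
  between antibodies well-defined; domain-level calls are also returned.
* Two call sets are compared by partitioning the union of their hit TSSs
  into shared / a-only / b-only.

## Antibody cross-reactivity mixing

An antibody's specificity profile is its relative capture fraction over
the four methylforms, stored un-normalized and row-normalized on use. The
apparent track is the per-bin convex combination of the true tracks with
those weights. The literature states cross-reactivity percentages but no
mixing equation; the convex combination is this package's own reading —
it preserves the HMD scale under perfect specificity and lets a
"50% cross-reactive with me2" figure be used directly as a weight. An
optional per-methylform abundance multiplier (default 1.0), applied
before normalization, emulates abundance-driven capture (H3K4me2 being
globally more abundant than H3K4me3) without hard-coding abundance
values. The unmodified form (me0) contributes zero signal by definition.

The mechanism this encodes: H3K4me2 flanks the central promoter H3K4me3
peak, so any me2 weight ≥ `min_hmd / flank_level` pushes the flanks over
the calling threshold and fuses plateau + flanks into one broad apparent
domain — false-positive BH4Ds at promoters whose true me3 plateau is too
short to qualify.

## Bidirectional CAGE TSS regions

Two opposite-strand CAGE peaks pair when they overlap or when the gap
between their original coordinates is ≤ `max_gap` (default 400 bp). The
literal recipe of extending *both* strand files by 400 bp and
intersecting would accept pairs up to 800 bp apart; the contract here is
anchored on the stated "within 400 bp", with the extension trick retained
only as an internal candidate-generation device. The emitted region is
the full span of both peaks plus the gap — guaranteed non-empty and
containing both TSSs for downstream intersection (an inner-gap-only
variant is available via a flag). All in-range partners are paired by
default (`nearest_only` restricts to the closest), no divergent-vs-
convergent orientation requirement is imposed, and overlapping output
regions are merged.

## Enhancer filter cascades

The **loose definition** keeps DNase HS sites that overlap an H3K4me1
peak and no annotated promoter. The **stringent cascade** applies, in
canonical order: remove Refseq-promoter overlaps; require overlap with
TFBS, GRO-Cap TSS, ATAC, H3K27ac, FAIRE, DNase and P300; require a pol II
ChIA-PET interaction one anchor of which overlaps the candidate while the
partner anchor overlaps a promoter (either orientation). All predicates
are conjunctive, so the final set is order-independent; the per-step
survivor counts follow the canonical order. Candidate identity is
preserved throughout (no re-merging), so counts always refer to input
candidates. The **refinement** removes candidates on unannotated lncRNA
promoters first, then requires FANTOM5 validated-enhancer support.

Knobs that materially affect counts and are therefore explicit
parameters: the promoter window when only TSS points are available
(TSS ± 1000 bp default — survivor counts are known to be sensitive to the
promoter annotation release and window), the 1 bp minimum-overlap default
(BEDTools convention), and an optional minimum TSS distance (default
2000 bp, applied only on request) for a stricter reading of "distal".

## Metagene profiles and heatmaps

Loci are anchored at TSS points or interval midpoints (integer floor);
each locus samples the track in `bin_bp` bins across
[anchor − flank, anchor + flank), with minus-strand flipping optional.
The heatmap matrix is the per-locus version; the metagene profile is
defined as its column means, so the two are exactly consistent by
construction. Bins falling before coordinate 0 contribute 0 and are
counted in `n_out_of_bounds` rather than silently truncated. No
smoothing and no per-locus normalization are applied.

## Synthetic genome generator

The generator emulates the locus archetypes the analyses assume, on toy
chromosomes (default two of 1 Mb):

* **Promoters** (default 30): a central me3 plateau (1000 bp at 90% —
  near the ~100% seen at highly transcribed promoters) flanked by me2
  (1500 bp per side at a level drawn per-promoter from 45–63%, i.e.
  50–70% of the apex) and low broad me1 (10%), with a divergent CAGE
  peak pair (20 bp peaks, 360 bp apart) at the TSS.
* **Enhancers** (default 30): 1000 bp of high me1 (60%), moderate me2
  (30%) and me3 drawn uniformly from 1–5%; half carry CAGE pairs.
* **Unannotated promoters** (default 5): promoter-shaped but absent from
  the TSS annotation — the contaminant class for loose enhancer
  definitions; their windows populate the lncRNA-promoter set.

Defaults not fixed by the study conditions (locus counts, chromosome
size, background me1/me2 levels, CAGE geometry, subset fractions) were
chosen once as representative of a desk-scale calibrated K562-like
experiment and documented here. Feature-library sets are planted from a
per-enhancer "first failing step" label (survival probability 0.25,
otherwise uniform over the steps), so the expected survivor count after
every cascade step is exact ground truth; contaminant candidates on real
promoter plateaus exercise the promoter-removal step. Validation truth
sets are random enhancer subsets of recorded size.

Profiles are piecewise-constant plateaus aligned to the 50 bp track grid
(widths must be multiples of `bin_bp`), which makes apparent breadth
under any mixing weight exactly computable: plateau = (1−x)·apex, flanks
= x·flank_level, and a TSS gains a BH4D iff the plateau clears the
threshold and the run containing the TSS (plateau, or plateau + both
flanks) reaches the minimum length. `plant_specificity_scenario` uses
this closed form as an oracle independent of the domain caller; with
noise it is approximate, so the cross-check tests run noise-free.

Noise, when enabled, is additive Gaussian per bin truncated at 0
(preserving HMD non-negativity). Determinism is by seed plus a documented
draw order on a single numpy `default_rng` stream: locus shuffle and
placement jitter; per-locus levels and strands; cascade labels; me3-peak,
FANTOM5, validation and CAGE subsets; then per-bin noise. Loci are placed
non-overlapping with 5–10 kb spacing (aligned to the bin grid); requests
that do not fit raise an error suggesting a larger chromosome.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level sampling noise and coverage
dependence, irregular peak shapes, overlapping/nested regulatory
elements, chromosome-scale heterogeneity, realistic locus density, and
correlated errors between methylform tracks. Tests against this generator
establish the correctness of the algorithms at exact ground truth, not
field performance on experimental tracks.

## Problem sizes and numerics

Tests and the acceptance script use desk-scale genomes (tens of loci on
0.3–1.5 Mb chromosomes), chosen so the whole suite verifies exact
planted-truth recovery in seconds. Oracle-equivalence checks run the
domain caller against an O(n) rescan on 200 random tracks (≤ 1000 bins)
and CAGE pairing against an all-pairs scan on 100 random peak sets
(≤ 100 peaks). Threshold comparisons are plain `>=` on float64; bin means
are computed from an exact prefix-integral of the piecewise-constant
track, so grid-aligned plateaus reproduce their planted values without
rounding. Ties in pairing (`nearest_only`) break toward the smaller gap,
then the leftmost partner.

## Known limitations

* The headline counts of the motivating analyses depend on specific
  GEO/ENCODE accessions and an unpinned Gencode promoter annotation;
  they are reproducible with those downloads via the same operations but
  are not shipped as tests.
* Metagene output is a faithful reimplementation of TSS-anchored
  averaging, not a bit-exact reproduction of any external profiler's
  normalizations.
* The convex-combination mixing model is a stated interpretation of
  published cross-reactivity percentages (which do not define their
  denominator); IP saturation and epitope masking are out of scope.
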