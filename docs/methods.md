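# Methods

## Coverage model and conventions

All analysis operates on binned coverage tracks: mean per-base read
depth in fixed 100 bp bins (the last, partial bin averaged over its true
width), 0-based half-open coordinates, one track per contig per sample.
100 bp keeps multi-hundred-kbp contigs tractable while resolving the
~500 bp edge windows the detector uses; re-binning by averaging is exact
(binning at 25 bp and averaging to 100 bp equals direct 100 bp binning),
so finer inputs lose nothing. Contigs shorter than 40 kbp are discarded
(inclusive boundary: exactly 40 kbp is kept) — the signatures of
interest span tens to hundreds of kbp and cannot be recognized on
shorter sequence.

Reads with mapping quality 0 are counted by default (ambiguous reads
placed randomly contribute exactly once); `min_mapq` switches this off.
Zero-coverage contigs get explicit all-zero tracks so that the rank
screen's denominators are complete.

Normalization attaches depth per million mapped reads:
`norm = depth * 1e6 / total_mapped`. Alignments supply `total_mapped`
by counting; depth-file inputs (TSV/bedGraph) carry no library size and
default to an identity denominator of 1e6 (norm == raw). Every
classification decision is a *ratio* of normalized depths, so this
default changes nothing; only users comparing absolute normalized depth
across samples need to pass the true totals.

## Packaging simulator

The simulator draws individual packaged fragments from a particle-type
mixture. Channel weights (induction, lateral, per-pac-site, GTA rates)
are normalized into a distribution and `n_particles` fragments drawn
multinomially. Per channel:

* **Induced element** — the exact element interval. With probability
  `specialized_rate` the particle is instead an imprecise-excision
  particle: one capsid-capacity (`G`) fragment spanning a randomly
  chosen edge (`side_bias` = probability of the left edge), host-flank
  extent uniform on `[0, max_flank)`. The uniform extent law is a
  deliberate least-informative choice: the data constrain only the
  finite flank span and its decline, not the law, and uniform reproduces
  both (expected flank coverage falls linearly to zero at `max_flank`).
* **Headful packaging** (lateral and generalized) — a particle carries
  the k-th headful `[s + (k-1)H, s + kH)` downstream of the initiation
  point, `P(k) = q^(k-1)(1-q)` (first headful always possible, memoryless
  continuation with probability `q`). Expected coverage at distance `d`
  is `n_ch * q^floor(d/H) * (1-q)`: a staircase that is constant within
  each headful window and decays by `q` per window. Lateral transduction
  reuses this machinery with the initiation point pinned to one prophage
  edge, strictly unidirectional, on top of the element's induction
  plateau. Note the normalization: with `r` *initiation series* each
  producing every headful until dissociation, coverage is
  `r * q^floor(d/H)`; the two parameterizations are identical in shape
  with `r = n_ch (1-q)` (the first-headful rate).
* **GTA-like** — fixed-size (`fragment_size`, default 13 kbp) fragments
  whose start density follows a smooth positive bias field (log-scaled,
  Gaussian-correlated, min-max calibrated so the field's max/min ratio
  equals the configured fold exactly, including any self-exclusion dip
  over the element's own gene cluster).

Circular genomes wrap fragments across the origin; linear contigs
truncate them at the ends — the detector must and does tolerate
truncated staircases. Closed-form expected coverage mirrors the sampling
laws exactly (verified: at 100,000 particles the per-bin deviation stays
below 5 standard errors for all modes simultaneously).

Whole-community tracks are even with an optional log-linear
origin-of-replication gradient (the ori/terminus depth ratio equals the
configured fold exactly) and per-bin Poisson noise applied at depth
level, so the per-bin variance equals the mean. Read-level shot noise,
GC bias, mappability structure and strain mixtures are *not* modeled —
passing tests demonstrate correct recovery of the assumed packaging
process, not robustness to every artifact of real libraries (the
whole-community evenness check exists precisely because real assemblies
violate evenness).

### Fixtures

Named fixtures encode the magnitudes of the classical model systems in
versioned YAML: `lambda_like` (48.5 kbp prophage, per-side specialized
fraction 1e-4, 25 kbp maximum flanks → plateau:flank ratio 1:10,000),
`p22_like` (six pac sites, 44 kbp headful, q = 0.7 → staircases over
several hundred kbp), `p1_like` (many weak low-processivity sites whose
overlapping staircases blur into < 10-fold unevenness with no sharp
edges), `pbsx_like` (13 kbp GTA fragments, 30-fold smooth bias,
self-exclusion over the element), `faecalis_like` (two lateral
prophages at frequency ratios 1:500 and 1:240 plus a high-output
phage-hijacking island), and `community_like`: 60 contigs (40–800 kbp)
mixing 20 standard, 8 induction, 8 specialized, 6 lateral,
6 generalized, 6 GTA-like and 6 seeded contamination contigs whose VLP
signal is a scaled-down copy of their whole-community profile. Element
positions and rates are drawn per seed within the ranges coded in the
generator. Whole-community abundances of transduced contigs are
assigned monotonically in their VLP coverage — genuine carriage is
VLP-enriched by construction, which is exactly the biological assumption
the rank screen tests, while the seeded contaminants violate it.

## Detector

All decisions run on the normalized VLP track; the whole-community
track contributes only an assembly-evenness check (CV of the 10 kbp
smoothed track; fail above 0.5 flags the contig, processing continues).

**Baseline.** Median of the bins at or below the 90th percentile —
robust to one large induced prophage. For flank walks the reference is
`min(baseline, 10%-quantile, minimum of the 10 kbp smoothed track)`,
because a lateral staircase can cover most of a contig and drag the
median up to a staircase-tail level, clipping measured flank extents.

**Segmentation.** Penalized binary segmentation of
`log2(norm + pseudocount)` under a piecewise-constant least-squares
model. A split is accepted when its SSE gain exceeds
`penalty × sigma²`, with `sigma²` estimated robustly as half the median
squared successive difference (floored at 0.01); penalty default 30,
minimum segment 3 bins, ties resolved toward fewer segments because a
split must strictly beat the penalty. The pseudocount of 1 normalized
unit applies to every log transform.

**Classification cascade.** Adjacent segments whose means stay within
one sharp-edge fold (5×) of each other are grouped; a group is a plateau
candidate if its mean is ≥ 10× over baseline and its length is
5–200 kbp. A candidate is confirmed when both boundary folds over
500 bp windows reach 5× (a boundary at a contig end counts but sets
`truncated_at_end`) and the interior is level (|slope| ≤ 0.05
log2-fold / 10 kbp — a truncated decaying staircase is not a plateau).
For each confirmed plateau the detector walks outward while coverage
stays ≥ 3× over the flank reference: a one-sided flank ≥ 100 kbp with
negative decay makes the element **lateral**; a shorter flank (≥ 1 kbp,
≤ plateau/10) makes it **specialized**; otherwise it is **induction**
(prophage vs. chromosomal island cannot be separated without gene
annotation, so both map to induction). Frequency is
`N = plateau mean / flank maximum` (lightly smoothed flank, 2
significant figures, reported as 1:N).

Without a plateau: pac sites are boundaries where the directional edge
fold reaches 5× (local maxima, both orientations, deduplicated within
one headful scale, candidates within 2.5 kbp of a contig end discarded
as end-ramp artifacts) whose downstream 2-headful window decays; pac
calls with contig unevenness ≥ 5 give **generalized**. Unevenness ≥ 2
with *no* sharp interior edge and no pac call gives **gta_like**
(unevenness is max/min of the 10 kbp smoothed, pseudocount-floored
track; no upper unevenness bound — GTA bias can reach 30-fold, and the
presence of pac edges, not an unevenness ceiling, separates generalized
from GTA-like). Flat tracks are **standard**; the remainder is
**unknown**, the deliberate residual class. Contig-level mode is the
highest-precedence element call
(specialized > lateral > induction > generalized > gta_like > unknown > standard).

**Headful size** comes from the autocorrelation of the first difference
of log2 coverage over a staircase interval: processive packaging leaves
equally spaced, equally sized (in log space) downward steps, so the
difference signal is an impulse train whose autocorrelation peaks at the
headful. The interval is truncated once coverage falls into the noise
floor, a peak must exceed the lag-window median by 5 robust SDs (else
the estimate is undefined and flagged), and a sub-multiple lag carrying
≥ 50% of the peak is preferred to avoid harmonic (octave) errors.

**Scale invariance and coverage gates.** Mode decisions use only
normalized fold ratios, so multiplying a sample's depths and
`total_mapped` by any constant changes no call. Absolute read-coverage
gates — plateau ≥ 20×, flank maximum ≥ 150× raw — control only the
`confident` flag (`low_coverage`, `flank_below_gate`): below a gate the
detector still emits the pattern as a flagged candidate rather than a
confident call. Under read downsampling this yields the expected
ordering: the specialized flank call is lost first, induction survives
to ~20× plateau coverage, and deeper sampling never loses a call a
shallower sample has.

## Rank screen

Per contig and sample, the share of total mean normalized coverage is
ranked (rank 1 = highest). Ranking is ordinal on (share descending,
contig id ascending), making ranks an exact permutation of 1..n with a
deterministic tie policy; zero-coverage contigs take the worst ranks. A
candidate contig is `contamination_suspect` iff its VLP rank is
numerically higher (worse) than its whole-community rank; equal rank is
consistent with carriage. Flags are invariant under rescaling either
sample and are advisory — they annotate calls, never delete them, since
a worsened rank can also reflect genuinely inefficient mobilization.

## Parameter defaults

| parameter | default | rationale |
| --- | --- | --- |
| bin size | 100 bp | resolves 500 bp edges; keeps 800 kbp contigs at 8,000 bins |
| min contig length | 40 kbp | patterns span tens–hundreds of kbp |
| induction fold | 10× over baseline | induced elements sit orders of magnitude above baseline |
| edge fold / window | 5× over 500 bp | "vertical" rises vs. ramps |
| flank fold | 3× over flank reference | flanks are weak but clearly above background |
| lateral minimum extent | 100 kbp | lateral decay spans several hundred kbp; specialized flanks tens |
| unevenness fold (generalized) | 5× | strong staircase unevenness; weak generalized signals peak near 10-fold |
| plateau length | 5–200 kbp | phage genome to island/prophage-cluster scale |
| coverage gates | 20× plateau, 150× flank | depths at which the respective patterns remain recognizable |
| pseudocount | 1 normalized unit | stabilizes logs and folds near zero |
| segmentation penalty | 30 × noise variance | no spurious splits on Poisson-level noise at ≥ 40 kbp contigs |

## Problem sizes

The test suite and the acceptance script run entirely on simulated
data: single-contig fixtures of 0.3–2 Mbp, particle pools of 1e5–3e6
fragments, and a 60-contig community (~15 Mbp total). These sizes give
sub-percent sampling error on every recovered quantity while the whole
suite completes in well under a minute.

## Known limitations

* Coverage-only evidence: retrotransposons/transposases and novel
  particle types surface as `unknown`; prophages and pirating islands
  are indistinguishable without annotation.
* Per-particle fragment sampling abstracts away read length, paired-end
  structure and mapping ambiguity; detection limits measured here are
  therefore slightly optimistic relative to real libraries.
* The headful estimator needs ≥ 3 visible steps; single-headful or very
  low-processivity systems return an undefined (flagged) estimate.
* pac sites within ~2.5 kbp of a contig end are suppressed as
  indistinguishable from end ramps.
* The rank screen is a directional consistency check, not a
  contamination-fraction estimate.
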