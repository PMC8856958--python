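# Methods

`shmirkit` implements two pipelines around a common set of sequence and
statistics primitives: design of shRNAmir guide duplexes against a target
mRNA, and quantification of the co-expression between an RNAi target
protein (ChAT in the motivating application) and a co-expressed viral
reporter, both at the ordinal-category level and at the per-cell
intensity level.  A synthetic-data module generates inputs with the
statistical structure the analyses assume, so every stage can be tested
at desk scale without external data.

## Guide design

**Model of an admissible guide.** A guide is a 21-nt siRNA-style sense
window on a reference isoform of the target (the longest isoform, by
default), extended to a fully overlapping 22-nt duplex: the sense strand
drops one 3' base and gains the two bases of upstream target context
(`target[start-2, start+20)`, 0-based half-open), and the antisense
(guide) strand is its exact reverse complement.  The first sense base is
then edited (C/G→A, A/T→C) to re-create the bulge of the endogenous
miR-30A hairpin; the guide strand stays perfectly complementary to the
target.  Because the two added 5' bases must come from somewhere and the
duplex is specified to be fully overlapping, target-context extension is
the only consistent reading; it is an inference and is documented as
such.

**Filters.**

* *Isoform coverage*: the 22-nt pre-mismatch window must occur verbatim
  in every known isoform of the target gene.  "Complementary to all
  isoforms" is evaluated on the sense window, which is equivalent to
  checking the antisense guide by definition of the reverse complement.
* *Off-target*: a guide is rejected if its 22-nt pre-mismatch window has
  more than 15 nt of contiguous exact complementarity to any non-target
  transcript.  The screen is a 16-mer membership query against an index
  of the background transcriptome — a window exceeds 15 nt of contiguous
  complementarity iff it shares a 16-mer with some transcript — and is
  validated in the test suite against a longest-common-substring dynamic
  program on planted-run fixtures (runs of 14, 15, 16, 17 nt).
  Whether "15 nt complementarity" tolerates interruptions is not
  specified anywhere we could anchor it; contiguous matching is
  implemented and is the assumption throughout.  Only the sense (mRNA)
  strand of transcripts is scanned, since RNAi acts on mRNA, and the
  scan uses the pre-mismatch window because the mismatch position does
  not pair with the target.

**Ranking.** External tools (e.g. the DSIR web tool) performed ranking in
the motivating study, and their regression models are not reproduced
here.  Ranking is a pluggable strategy: externally supplied scores can
be injected per candidate start, and the built-in default is a
transparent heuristic — +1 if GC fraction of the 21-mer lies in
[0.30, 0.65], plus the A/T-fraction difference between the last and
first four sense bases (a proxy for the 5'-antisense thermodynamic
asymmetry that biases RISC loading toward the guide strand).  Ties break
deterministically by (smaller start, lexicographic sequence).

**Scaffolds and assembly.** Templates are data, not code: an ordered
alternation of fixed blocks and labelled 22-nt slots, YAML-loadable.
The shipped mirE template uses the field-standard miR-E/miR-30a context
(5' lower stem `TGCTGTTGACAGTGAGCG`, loop `TAGTGAAGCCACAGATGTA`, 3'
lower stem `TGCCTACTGCCTCGGA…`); the shipped four-hairpin mir17-19b-like
polycistron uses synthetic stand-in arms, because the real cluster arms
were not available to transcribe — users cloning for real should load
their own template.  Construct assembly concatenates promoter, ORF,
BsrGI+AscI 5' flanks, the scaffold insert, a SalI 3' flank and any
remainder, and validates that each declared recognition sequence
(defaults BsrGI `TGTACA`, AscI `GGCGCGCC`, SalI `GTCGAC`, all
configurable) occurs exactly once and that the insert lies strictly 3'
of the ORF stop codon.  Guides can re-create a site by chance (roughly
1 in 2 kb per 6-mer site for random sequence); validation rejects these
with positions listed, and the worked example shows the fallback to the
next-ranked guide.

## Categorical co-expression statistics

Cells carry an ordinal marker level (strong=1, medium=2, weak=3) and an
ordinal reporter level (RU=1 untreated, then RN, RW, RM, RS=5).  With
this orientation an inverse marker/reporter relation — stronger reporter,
weaker marker — produces a positive trend statistic; when comparing to
published values whose score convention is unstated, |Z| is the
comparable quantity.

* **Goodness of fit.** Treated-region counts over the three marker
  categories are tested against the untreated category ratio:
  X² = Σ (O_c − n·p_c)²/(n·p_c), df = 2, asymptotic upper tail.
  Reference ratios are pooled over untreated cells per construct by
  default.
* **Linear-by-linear association.** For an ordered r×c table with
  integer scores u, v, the score statistic T = Σ u_i v_j n_ij is
  standardised as Z = r_uv·√(n−1), where r_uv is the score correlation
  over the n cells; two-sided p from the standard normal.  This is a
  1-df trend test; the (r−1)(c−1) table df (8 for a 3×5 table) is
  reported as metadata only, and the equivalent 1-df chi-square Z² is
  exposed alongside Z.  The asymptotic p is validated against a
  column-label permutation oracle in the test suite; at ~400 cells per
  table the two agree to ~0.013 at 10⁵ permutations.
* **Ordered-proportion trends.** Pearson correlation of a strong- or
  weak-category proportion profile against rank 1..k over RU..RS.
* **Densities.** Per-region marker-positive cells/mm², treated vs
  untreated, compared by Wilcoxon–Mann–Whitney: full enumeration of all
  C(n₁+n₂, n₁) group assignments when both groups have ≤ 8 regions
  (ties handled by midranks), otherwise the tie-corrected normal
  approximation without continuity correction.
* **Penetrance.** Fraction of marker-positive cells in treated regions
  with reporter level ≥ RW; RN ("reporter not detected") counts as
  negative.

No continuity corrections are applied to the chi-square or trend tests
(both asymptotic), and no multiple-testing correction is applied across
constructs, matching the analysis conventions of the motivating study.
The Bonferroni family size for the KS intensity test is an explicit,
required argument — there is no defensible hidden default.

## Intensity quantification

Images are 8-bit (0–255).  Background normalisation rescales all pixels
by target/background so the mean over the background mask reaches the
channel target (≈100 for the marker compartment, ≈10 for the reporter
measured away from the injection site); results are rounded and clamped
to 255 with the clamp count reported.  Per-cell measurement is the mask
mean minus background, floored at 0 (negative brightness is physically
meaningless on this scale), plus the pixel area; masks outlined on the
marker channel transfer unchanged to the reporter channel.  Distribution
shifts use the asymptotic two-sample Kolmogorov–Smirnov test with
explicit Bonferroni correction; intensity co-variation uses Pearson
correlation with the least-squares line for plotting.

Segmentation evaluation is intersection-over-union with greedy
descending-overlap matching (each predicted and truth object used at
most once; unmatched truth objects score 0; mean over truth objects).
The matching rule is a design choice — no published rule was available —
and the assignment is returned so alternative matchers can be compared.
The segmenter itself is pluggable; the built-in `naive_segment`
(8-connected supra-threshold components with a minimum area) is a
baseline for synthetic renders, not a substitute for a trained model.

## Synthetic data

**Transcriptome fixtures.** Four isoforms share a 600-nt CDS verbatim
and differ in random UTRs (the first isoform is longest, hence the
reference).  Decoys are uniform random DNA; planted off-target runs copy
a k-nt substring of a chosen candidate window into a decoy with forced
mismatches at both flanks, so the true maximal shared run equals k
exactly (verified by the LCS oracle).  At the fixture scale used
(40 decoys × 400 nt vs 22-nt windows) chance 16-mer collisions are
negligible (4¹⁶ ≈ 4·10⁹).

**Cell tables.** Per region (default 6 treated + 6 untreated, areas
3–8 mm²), cell count ~ Poisson(density × area) with density uniform in
8–15 cells/mm².  Baseline marker intensity is a three-component
truncated-normal mixture, one component per category band (weak
(5,50), medium (50,100), strong (100,150) gray levels), with component
weights 0.30/0.60/0.10, so thresholding at 50/100 reproduces the
baseline proportions in expectation; additive N(0, 5²) measurement
noise perturbs these slightly at the band edges.  Treated cells are
penetrant with probability 0.80; penetrant cells draw a reporter dose
R ~ Beta(2, 2) (the dose-response form is unconstrained by any source,
so it is explicit configuration), and

    marker   C' = C·(1 − β·R) + ε,          β ∈ [0, 1] knockdown slope
    reporter Y  = 180·R + λ·C' + ε,         λ ≥ 0 channel leakage

with ordinal reporter levels from thresholds 15/60/120 and untreated
cells always RU.  Intensities are clipped to [0, 255]; the floor at 0
censors the weakest reporter signals, which mildly attenuates small
leakage estimates (observed ≈0.04 recovered for a planted 0.05).  The
generator does **not** remove severely knocked-down cells, so treated
and untreated densities match by construction — the density reduction
seen in real mirE1 tissue (undetectable cells dropping out of counting)
is deliberately not modelled.  Category thresholds are generator
configuration, not estimated: the visual thresholds of human annotators
are unknowable, and all quantitative checks use proportions, not
threshold values.

**Images.** Cells render as filled ellipses (semi-axes 4–8 px, random
orientation) with Poisson pixel noise at background + amplitude
(marker background 100, reporter background 10), placed by rejection
sampling with a minimum centre separation (30 px default), so the
default renders are well-separated; truth masks are the drawn pixel
sets.

**Parameter recovery.** β̂ = −slope/intercept of the regression of
treated-cell marker intensity on dose (E[C'|R] = E[C](1 − βR)), with a
delta-method CI that ignores the slope–intercept covariance; λ̂ is the
untreated reporter-on-marker regression slope with its standard CI.
Across 50 seeds at ~5000 cells, the mean β̂ lands within ±0.05 of a
planted β = 0.5.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure the analyses
assume — ordinal mixtures, Poisson counts, linear knockdown and leakage,
Beta doses, shot-noise imaging — but not real histology: no anatomy, no
section-to-section variation, no annotator disagreement, no soft cell
edges or overlapping somata beyond the optional overlap flag, and no
drop-out of suppressed cells.  Passing tests therefore demonstrate that
the statistics and pipelines are implemented correctly and are calibrated
(type-I error 0.04–0.06 at α = 0.05 under matched nulls), not that any
biological conclusion transfers to real tissue.  The published headline
trend values (|Z| ≈ 18.1, 18.5, 8.7, 8.0, 13.1 and the null 0.48/0.31)
are functions of per-region raw counts available only in the study's
supplementary tables; `load_category_table` + `linear_by_linear_test`
recompute such statistics from a transcribed count CSV in well under a
second, but the counts themselves are not bundled here.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make Monte-Carlo
error small relative to the tolerances: ≥500 candidate windows for the
off-target/LCS equivalence, 20 tables × 10⁵ permutations for the trend
oracle, 10⁴ replicates for type-I calibration, 50 seeds × ~5000 cells
for recovery, 25 rendered cells for segmentation.  Degenerate inputs
fail loudly rather than silently: empty margins, zero variance, zero
background, empty masks, and zero reference ratios with observed counts
all raise errors naming the offending input.  All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; fixed seeds
give byte-identical generator outputs.
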