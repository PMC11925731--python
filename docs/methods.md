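# Methods

This note documents the models, conventions and numerical choices behind
`modcal`, and what the synthetic benchmark does and does not establish.

## Data model and conventions

- **Coordinates** are 1-based inclusive on the molecule throughout the
  package (matching modification-catalogue conventions); BED input/output is
  converted from/to 0-based half-open at the boundary.  Duplicate
  (molecule, position) rows in a site table are rejected — inputs are
  assumed deduplicated (one representative copy per duplicated tRNA/rRNA
  gene).
- **ESB scale.**  ESB values are fractions in [0, 1] internally.  Caller
  output is mapped through named dialects that declare their column layout
  and scale (`modcal`, `eligos`, `eligos_percent`); percent-scaled columns
  are divided by 100 on input.  This avoids silent 100× errors between the
  two scales that appear in the field's literature.
- **Detectability.**  A built-in table maps MODOMICS-style one-character
  symbols to (modification name, detectable-by-error-based-calling).  Types
  that leave basecalling essentially unperturbed (s⁴U, s²C, m⁵C, mnm⁵U,
  lysidine, m⁶t⁶A, i⁶A, m⁴Cm) are flagged not detectable.  Unknown symbols
  are kept with unknown detectability and a logged warning.

## Threshold calibration

Calling rule: ESB_test ≥ a ∧ ESB_control ≤ b ∧ OddR ≥ c ∧ p_adj ≤ d, all
comparisons inclusive.  Calibration scores every combination of a candidate
grid against the known tRNA/rRNA catalogue:

- **Precision** is region-tolerant.  Called positions are merged into
  maximal runs of adjacent positions; a region is true when any of its
  positions lies within ±`tolerance` (default 10) nt of a known site on the
  same molecule.  Rationale: one modification produces signal over a
  neighbourhood, so counting each smeared position as an independent false
  positive would be wrong.
- **Recall** counts known sites called at the exact position; a
  `recall_window` switch widens the match, and `detectable_only` optionally
  removes never-detectable types from the recall counts (default off; the
  full catalogue is counted).
- **Selection**: highest recall subject to precision ≥ `precision_floor`
  (default 0.85).  Among recall ties the search starts from the
  highest-precision, most restrictive combination and then relaxes each
  parameter independently to its least restrictive value that leaves
  precision and recall unchanged, in the fixed order p_adj, ESB control,
  OddR, ESB test.  Re-evaluation after every relaxation makes the rule
  insensitive to non-monotone stretches of the landscape.
- **Default grid**: ESB test 0.01–0.20 (step 0.01), ESB control 0.005–0.10
  (step 0.005), OddR 0.5–10 (step 0.5), p_adj {1e−5, 1e−3, 0.01, 0.05} —
  20·20·20·4 = 32,000 combinations on the fraction scale.  Grids are fully
  configurable; thresholds quoted on the percent scale in the literature can
  be expressed with a custom grid.

Five-way classification of known sites applies the precedence: type not
detectable → depth insufficient (< 20 reads on the molecule) → detected →
detected with offset signal (nearest call within ±10 nt; distance ties go
upstream) → not detected.  The precedence mirrors how benchmark figures in
this field are drawn; it matters only for sites qualifying for several
categories.  Detection percentages count exact and offset detections
together, are rounded half-up to one decimal, and are reported alongside a
truncated variant and the raw fraction so any printed-value convention can
be audited.

## Regions and annotation

Region biotype is decided by the region midpoint with fixed precedence
tRNA > rRNA > CDS > 5′UTR > 3′UTR > ncRNA > intergenic (tmRNA and pseudogene
features fall in the non-coding bucket).  A midpoint rule is needed because
regions can straddle segment boundaries; precedence makes straddles
deterministic.

Metagene positions use a [0, 3] scale with unit bands per segment.  Within a
segment the coordinate is the fractional distance from the first to the last
nucleotide in transcript orientation: position p in segment [s, e] maps to
band + (p − s)/(e − s) on the plus strand and band + (e − p)/(e − s) on the
minus strand, so 0 is always the transcript 5′ end, the first nucleotide of
a segment maps to the band start and the CDS midpoint maps to exactly 1.5.
A segment's final nucleotide maps to the band boundary; single-nucleotide
segments cannot be normalized and raise an error.  One point per region
midpoint is emitted by default; a per-position mode carries the reference
base for base-resolved distributions.

## Differential analysis

ΔESB = ESB_test − ESB_control within one condition.  For each position in
the union of the two conditions' called sets a record is emitted; a position
not detected in a condition (not called there, or absent from that
condition's table) gets ΔESB 0 for that condition.  This set-to-0 rule makes
the comparison total.  Change labels use an equality band ε = 1e−6 on the
fraction scale.  The per-site ratio ΔESB_b/ΔESB_a is undefined (NaN) when
ΔESB_a = 0; such records are excluded from the MS correlation, which
otherwise compares, per modification type, mean ΔESB_b / mean ΔESB_a against
mean MS abundance_b / mean MS abundance_a (Pearson, two-sided p).  At least
three paired types are required.  Only types detectable by error-based
calling belong in the pairing — the caller cannot quantify the others.  A
value-vs-value switch and a log-scale switch are provided.

Between-condition sharing: a position called in both conditions is shared;
called in one only, it is a "modification in a unique RNA" when its molecule
has < 20 reads in the other condition, else a "unique modification".

When replicate-level ESB columns are available, per-site condition
differences can be tested with an unpaired two-sample t-test
(`differential.delta_ttest`); with the single combined value per condition
that callers emit, the analysis is descriptive.

## SELECT classification

ΔCT = CT(target) − CT(A control) is computed per replicate and averaged
arithmetically per sample type (replicate SD reported); ΔΔCT = ΔCT(WT) −
ΔCT(reference), where the reference is IVT RNA or a writer-deletion mutant.
Classification is modified iff ΔΔCT ≤ −1 (inclusive).  The sign convention
follows the assay's readout, in which a modified target makes ΔΔCT
negative; the generator plants CT offsets on the same scale, so a planted
effect of 2.5 cycles yields ΔΔCT = −2.5 in expectation.

## Synthetic data generator

The generator emulates the statistical structure of error-based caller
output on a bacterial transcriptome; it is the package's test bed, not a
read-level simulator (no squiggles, no basecalling error model).

- **Molecules**: 40 tRNAs (74–90 nt), 16S/23S-sized rRNAs (1542/2904 nt),
  120 mRNAs with 5′UTR/CDS/3′UTR plus unannotated 30-nt flanks (intergenic
  positions) on alternating strands, 10 ncRNAs.  Desk scale: generation
  takes a few seconds.
- **Signal model**: background ESB ~ Gamma(2, 0.002) capped at 0.0199
  (systemic noise floor); a modified position adds effect × stoichiometry
  (effect 0.45 at stoichiometry 1, per-site multiplicative noise sd 0.08);
  neighbours within ±10 nt receive geometrically decayed elevation
  (factor 0.5/nt).  OddR is the ESB quotient with a floor of 1e−3; p_adj is
  a deterministic monotone transform exp(−15 · ΔESB · √depth) — sufficient
  to exercise the threshold logic without simulating read-level tests.
- **Depths**: log-normal per molecule (median 120, σ 1); 12% of tRNAs and a
  configurable set of mRNAs sit below the 20-read floor (those molecules
  produce no modification signal).  rRNA depth is fixed at 800.
- **Catalogue**: canonical tRNA positions (D16/17/20, Gm18, anticodon
  cluster 32–40, m⁷G46, acp³U47, T-loop 54/55) and spaced rRNA sites,
  symbols drawn from realistic pools including non-detectable types; two
  known sites carry a displaced signal (−5 nt) and no signal at the
  catalogued position itself, reproducing offset detections.
  Non-detectable types are planted only at positions isolated from other
  modifications (e.g. s⁴U at tRNA position 8), so benchmark recall reflects
  genuine on-site signals rather than neighbour bleed-through at catalogued
  positions.
- **Threshold identifiability**: the planted cutoff set
  (ESB_test 0.05, ESB_control 0.02, OddR 3, p 0.05) is pinned from the
  inside by four sentinel known sites that hug one threshold each
  (low-elevation signal just above the ESB-test cutoff; elevated control
  ESB just under the control cutoff; quotient just above OddR 3; p = 0.03),
  and from the outside by decoy systemic-noise positions just beyond each
  cutoff (marginal ESB-test values 0.012–0.048; control-noisy positions
  with control ESB 0.024–0.098; low-OddR positions 0.6–2.9).  One grid step
  looser in any parameter admits decoy false regions; one step tighter
  loses sentinel recall.  Decoy OddR values are set directly rather than as
  the ESB quotient — real callers derive OddR from read-level error counts,
  which can diverge from the ESB ratio.  Sentinels carry fixed common
  detectable types whose condition-b multipliers keep them callable in both
  conditions.
- **Condition b**: per-type stoichiometry multipliers (defaults span
  0.72–1.18, e.g. Um down ~28%, m⁶⁶A up ~18%, anticodon Ψ down ~22%); 60%
  of CDS sites increase; a few sites exist in one condition only, and a few
  molecules are under-covered in exactly one condition.  The MS table is
  mean planted stoichiometry × scale with 5% multiplicative noise over
  three replicates, so its ratios track the planted multipliers.  SELECT
  CT tables plant a −2.5-cycle ΔΔCT at modified targets with 0.05-cycle
  replicate noise.

**What passing tests show — and do not show.**  The synthetic profile
establishes that the machinery is correct: thresholding matches a naive
filter, region merging and precision/recall match brute-force enumeration,
the grid search equals exhaustive search with the stated tie-breaks, the
planted cutoffs are recovered on the default profile, and planted
stoichiometry shifts are recovered with high MS correlation (ρ ≥ 0.8 in
≥ 90% of seeds at 5% MS noise).  It does not establish performance on real
nanopore data: real ESB distributions are heavier-tailed and
sequence-context dependent, real smear is not geometric, caller p-values
are not a deterministic transform of effect size, and real catalogues
contain errors.  Quantities that depend on a specific organism's data
(full-transcriptome site counts, the exact selected thresholds, a study's
precision/recall) are properties of that data, not of this package.

## Known limitations

- The grid search is exhaustive by design (the landscape is part of the
  output); very large custom grids scale linearly in combinations.
- Metagene normalization requires host genes with annotated segments;
  regions on molecules without models are skipped.
- Caller p-values are assumed pre-adjusted; no multiple-testing correction
  is applied.
- The ELIGOS-style column dialects are best-effort mappings; the exact
  layout of a given caller version may need a custom dialect.
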