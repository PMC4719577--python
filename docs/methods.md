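# Methods

## Statistical primitives

All screens reduce to four primitives, centralized in
`tfcircuits.stats` and verified against brute-force oracles in the test
suite.

**Fisher's exact test.**  Exact hypergeometric p on a 2×2 table.  The
two-sided value follows the *point-probability rule*: the sum of the
probabilities of all tables with the observed margins whose probability
does not exceed that of the observed table.  Stated explicitly because
two-sided conventions differ between implementations; the test suite
checks agreement with an exact rational enumeration for every table
with N ≤ 12 to |Δp| < 10⁻¹².  Degenerate all-zero tables are rejected
as input errors; callers that can legitimately produce an empty margin
(a gene with no counted mutations) handle that case before the test and
report p = 1.

**Mann–Whitney U.**  Exact permutation null when the pooled sample is
tie-free and of size ≤ 16, tie-corrected normal approximation with
continuity correction otherwise; the path taken is recorded on the
result.  Cohort-scale comparisons always take the asymptotic path; the
exact path exists so small cases are oracle-testable (it reproduces the
enumerated two-sided p = 0.1 for the fully separated 3-vs-3 input).
A pooled sample in which every value is tied has sd(U) = 0 and is
reported as p = 1 (no evidence).

**Benjamini–Hochberg.**  Step-up adjusted q-values in input order,
q ∈ [p, 1], monotone in rank.  Applied only where the pipeline corrects:
overlap families (cross-stratum and circuit overlaps).  Target-level
p-values are deliberately *not* corrected — the significant-target rule
thresholds the raw p at 0.05 jointly with the fold-change; the
fold-change filter makes the joint rule conservative in practice (the
null calibration below measures ≈ 0 joint calls per cohort).

**Set overlap.**  Jaccard index (0 for two empty sets) and a one-sided
Fisher overlap test on
[[|A∩B|, |A\B|], [|B\A|, |U\(A∪B)|]] with a finite universe U.
Overlap tests are one-sided (greater) everywhere: enrichment is the
only hypothesis of interest for an overlap.  All other tests default to
two-sided (cohort enrichment can show depletion as well as enrichment;
targets can move either way; neither mutation class is privileged in
the truncating-vs-missense contrast).

## Alteration model

Mutation rules by mode of action: loss-of-function (LoF) drivers count
truncating (stop gained/lost, frameshift, splice donor/acceptor) and
missense mutations; activating (Act) drivers count missense only;
Undetermined drivers follow the Act rule.  Copy-number bounds are read
literally: deletion strictly below −0.75, amplification strictly above
1.0, copy-neutral the closed interval [−0.75, 1.0].  CNA calls pass
through a concordance gate on the driver's own transcript: a two-sided
Mann–Whitney between CNA-altered and copy-neutral samples must reach
p < 0.05 *and* the group medians must shift in the direction the event
implies (deletion → lower, amplification → higher).  Both groups must
hold at least `min_group_size` (default 5) samples, otherwise
concordance is unestablished and no CNA calls are made.  Mutation calls
are independent of the gate; the two streams are merged, so the altered
set is monotone under added evidence.

## Target misregulation

Per target: two-sided Mann–Whitney of expression in TF-altered vs
unaltered samples, excluding — per target — samples whose copy number
of that target is outside the neutral interval, so target CNAs cannot
masquerade as transcriptional misregulation.  The fold-change estimator
is `log2((median_alt + 1)/(median_unalt + 1))` in RPKM units: medians
for robustness to the heavy right tail of RPKM data, pseudocount 1 so
the ratio is defined at zero expression (both configurable).  A target
is significant when p < 0.05 and |log₂FC| > 1.  The unaltered reference
group ignores partner status at this stage; consequently samples
altered for a connected partner can dilute the reference and cost some
significant targets — a known property of the design, quantified in the
generator notes below.

The background comparison draws `n_random_sets` random same-size gene
sets from the expressed genes outside the TF's annotated targets and
reports the empirical mid-rank percentile of the observed
significant-target count.

## Circuits

Partner eligibility: adjacency to the TF in the edge-type-filtered
functional-interaction network; not itself a TF; at least one altered
sample; altered-sample overlap with the TF at most `partner_overlap_max`
(default 0.5).  The overlap denominator is the smaller of the two
altered sets — the strictest reading, chosen so a rare partner nested
inside a frequent TF's samples is still excluded.  Partner target
effects are measured against samples where *neither* the TF nor the
partner is altered.  Overlap p-values (up-sets and down-sets
separately) use the TF's full annotated-target list as the universe —
the same universe as the cross-stratum overlap, for consistency — and
are BH-corrected per direction across all TF–partner pairs of one
tumor type.  Correcting per tumor type (rather than per TF or globally)
matches how the circuit search is run and keeps q-values comparable
within one cohort's report.

## SLEA

Expression is mean-centered per gene across samples; a sample's score
for a gene set is the mean (optionally median) centered value over the
set; the null is the same statistic over `slea_n_perm` (default 1000)
random same-size gene sets drawn from all matrix genes, shared across
samples; z = (observed − mean(null)) / sd(null) with the sample
standard deviation.  Random index draws are sorted before summarizing
so identical sets summarize bitwise-identically; a null whose spread is
at floating-point rounding level (e.g. the gene set is the whole
matrix) is degenerate and yields z = 0 when the observed value sits on
the null and a flagged NaN otherwise.

## Synthetic cohorts

The generator (`tfcircuits.simulate`) emulates the statistical
structure the analysis assumes, with one integer seed feeding
per-component `SeedSequence` streams (adding a component never perturbs
the others; output is bit-reproducible).

* **Expression** is multiplicative log-normal: per-gene baseline
  `exp(N(2.0, 1.0))` (median ≈ 7 RPKM, heavy right tail), per-cell
  noise `exp(N(0, 0.5))`.  Planted targets multiply by `2**±effect_log2`
  (default effect 2) in altered samples, so the pipeline's median-ratio
  fold-change has a known expectation.
* **Alterations**: each TF is altered in a Bernoulli `alt_fraction`
  (default 0.3) share of samples; `cna_fraction` (default 0.3) of those
  by CNA (±1.5, with the TF's own expression shifted concordantly so
  the gate passes when effects are planted), the rest by mode-consistent
  mutations.  Partner drivers use their own `partner_alt_fraction`
  (default 0.15, a typical driver alteration frequency) and are drawn
  preferring samples not altered for the paired TF so the eligibility
  overlap stays below half.  The reference-group dilution that partner
  alterations cause in the TF's own target screen is therefore present
  (~20 % of the reference in a planted circuit) but not maximal.
* **Targets**: disjoint annotated sets of `targets_per_tf` (default 50)
  genes per TF; `planted_fraction` (default 0.6) of each set carries
  planted effects with random directions; the rest are true negatives,
  making false-positive rates among annotated targets measurable.  The
  50/30 sizing is deliberate: an overlap of two ~5-gene direction sets
  in a universe of 20 cannot reach q < 10⁻³ even when perfect, so
  meaningful circuit power requires universes of this order.
* **Domains and variants**: two domains per TF (positions 100–200 and
  300–350 of a 500-aa protein); `plant_domain_hotspot` re-draws somatic
  mutation positions with within-domain density `multiplier ×` the
  outside density; germline variants are uniform over the protein with
  log-uniform allele frequencies spanning the 10⁻⁴ common-variant
  cutoff.
* **Circuits**: `plant_circuit` wires a partner to a TF with a retained
  edge type and applies the TF's planted shifts to `shared_fraction` of
  its planted targets in partner-altered samples; `shared_fraction = 0`
  plants a connected decoy with no downstream effect.
* **Truth manifest**: every planted signal (targets with directions and
  effects, circuits with shared targets, hotspot multipliers, altered
  sample sets) is recorded in `truth.json` for exact scoring.

What the generator does *not* emulate: mutational signatures, genome
coordinates, segment-level CNA, tumor purity and subclonality,
batch/covariate structure, and correlated co-expression beyond the
planted shifts.  Passing tests therefore demonstrate the pipeline's
correctness and calibration under its own model assumptions, not
performance on real tumor data.

## Problem sizes and calibration runs

The test suite and `scripts/acceptance.py` use cohorts of 60–120
samples and 120–300 genes with 2–3 TFs: large enough that every group
comparison clears the minimum group size with the asymptotic
Mann–Whitney path, small enough that 20–50-seed calibration sweeps run
in tens of seconds.  Measured under those conditions (acceptance
script, seed 1): null cohorts yield a significant-target fraction of
0.0 (the joint rule is strongly conservative) and no significant
circuits; planted targets (effect 2, ~30 vs 30 samples, noise 0.5) are
recovered at ~95 % with 100 % direction accuracy and 0 % false
positives among unplanted annotated targets; shared-fraction-0.8
circuits are detected in 100 % of seeds and decoys in 0 %;
multiplier-10 hotspots are detected at p < 0.01 in 100 % of seeds while
neutral domains exceed p = 0.05 at ~93 % (the discrete one-sided Fisher
test is conservative at the nominal 95 %).

## Numerical and degenerate-input choices

* Germline allele-frequency filter keeps the boundary (AF ≥ 10⁻⁴).
* A mutation inside two overlapping domains counts once per domain;
  a variant is inside a domain iff its single reported position is.
* A gene with no counted mutations (or no retained variants) gets
  p = 1 and a NaN fraction in the domain contrast.
* Direction ties (log₂FC exactly 0) are labelled "up" but can never be
  significant.
* The plotting export of the domain contrast caps −log₁₀p at 10;
  stored p-values are never truncated.
* Cohort mutation enrichment counts mutation *events*, not mutated
  samples, and requires at least two cohorts; the reference margin is
  the pooled mutations of the other driver TFs.
* The TF over-representation test takes the gene-universe size as an
  explicit argument; no default is applied silently.

## Known limitations

Raw-p thresholding at the target level is a fidelity choice, not an FDR
guarantee; the circuit q-value family is per tumor type, so q-values
are not comparable across cohorts analyzed separately; the
segment-to-gene CNA mapping is a preprocessing responsibility of the
caller; and mutual-exclusivity analysis of circuit members is out of
scope (external tools exist for it).
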