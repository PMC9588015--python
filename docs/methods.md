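# Methods

This note documents the models, rules and numerical choices the package
implements, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the procedure was genuinely open.

## Monitoring model

Each patient contributes a micro-panel of 1–6 somatic variants and a
timeline of blood draws labeled T0 (baseline), T1 (Cycle 1 Day 3), T2
(surgery), T3.k (serial follow-up) and T4 (relapse draw).  A draw is
**positive** when at least `min_positive_variants` (default 1)
probe-passing panel variants have VAF strictly above `vaf_threshold`
(default 5 × 10⁻⁵, i.e. 0.005%).  **Molecular relapse** is the earliest
positive draw at or after surgery; T4 is excluded because a draw taken at
documented relapse cannot predict it.  **Lead time** is clinical minus
molecular relapse month; negative values (molecular call after clinical
documentation) are flagged, not discarded.

Patients are triaged before monitoring, in fixed precedence:

1. `germline_artifact` — any panel variant at blood VAF ≥ 0.90 at any draw
   (somatic panels should never approach 100% in plasma; such variants are
   almost certainly germline contamination of the panel);
2. `insufficient_data` — no baseline draw, or no draw at/after surgery;
3. `low_baseline_signal` — every baseline VAF below 5 × 10⁻⁴ (0.05%), i.e.
   the panel was never detectable in blood to begin with;
4. `evaluable` otherwise.

Detection **sensitivity** is computed over relapsed patients with at least
one non-T4 draw within `relapse_window_months` (default 6) before clinical
relapse; relapses whose last draw is older than the window are not failures
of the assay and are excluded from the denominator.  The mean lead time is
rounded half-up to one decimal (so 4.25 reports as 4.3).

Note on specificity: at consensus depths below 20,000 molecules a single
alt molecule already exceeds the 0.005% threshold, so the probe-coverage
rule and (optionally) `min_positive_variants = 2` carry the specificity
burden; the default of 1 follows the monitoring rule as stated, and
single-variant positives in non-relapsing patients are an expected artifact
(the generator reproduces them as transient positives).

## UMI consensus

The UMI is the first 10 bp of read 2; read 1 spans the full amplicon and is
the consensus template.  Reads are assigned to amplicons by matching their
5' prefix against each amplicon's 20-bp anchor within one mismatch;
ambiguous or failed matches are counted and set aside, never silently
dropped.  Grouping is directional adjacency: within an amplicon, UMIs at
Hamming distance ≤ 1 merge when the smaller count is at most half the
larger plus one — the standard guard that separates true UMI collisions
from PCR/sequencing errors on an abundant UMI.  N is an ordinary fifth
symbol: it mismatches every base, so UMIs are never merged across differing
N positions, and distance 0 gives exact grouping.

Consensus is count-based: per position, the strict majority among non-N
member bases (ties → N); the per-position error is the fraction of non-N
member bases disagreeing with the consensus, and the read error rate is
total disagreements over total non-N bases.  A base-quality-weighted
consensus was deliberately not used: the filtering rules are expressed as
error-rate thresholds, and count-based majority expresses them exactly and
reproducibly.

Filters apply in a fixed order, because order changes outcomes:
(1) drop the consensus read if its read error rate **exceeds** 5%;
(2) mask every base whose position error **exceeds** 10% to N;
(3) drop the read if the resulting no-call fraction **exceeds** 50%.
All three are strict inequalities ("exceeds"); the sample-level QC —
mean unique (consensus) coverage over panel loci — passes at **≥ 500**
inclusive ("minimum of 500").  Coverage ambiguity: the QC is implemented
as the per-sample mean across panel loci, not a per-locus minimum; both
raw and consensus depth are recorded per locus so the rule can be
re-targeted.

## VAF quantification

Each passing consensus molecule contributes exactly once at a panel locus:
ref, alt, other, or no-call (N at any relevant base).  VAF = alt /
(ref + alt + other); no-calls are excluded from the denominator, since a
masked base carries no allele information; VAF is undefined (not zero) at
zero evaluable depth.  Alleles are matched by full allele string at the
locus offset; length-changing alleles whose context matches neither string
count as other.  The low-performing-probe rule uses **raw** assigned-read
coverage (< 1,000× fails): consensus coverage is already bounded by the
500× sample QC, so the raw count is the meaningful per-probe performance
signal; the threshold and the choice of raw vs consensus coverage are both
configurable.

## Statistics

The pCR association uses the uncorrected Pearson chi-square on the 2×2
table of pCR against ever-positive-during-remission, with p from the
chi-square distribution at 1 df.  No continuity correction by default: on
the 1/8 vs 8/17 table the uncorrected statistic is 2.820 (p = 0.093),
consistent with the reported trend, whereas the Yates correction roughly
doubles the p-value; the correction is exposed as a flag.

Sensitivity bounds are exact Clopper–Pearson intervals computed by
bisection on the binomial tail sums to |Δp| < 10⁻⁹ (lower bound: smallest
p with P(Bin(n, p) ≥ x) ≥ α/2; 0 at x = 0; upper bound symmetric).
Bisection on the defining equations, rather than the equivalent
beta-quantile identity, keeps the implementation self-contained and lets
tests verify the bounds by direct binomial summation; the beta identity is
used as an independent cross-check in the test suite.  At 9/10 observed
the 95% lower bound is 0.5550 → 55%.

Percentages are rendered round-half-up to the nearest integer, keeping one
decimal only for exact non-integer tenths (12.5%, but 47% and 82%).

## Synthetic cohort generator

The generator encodes the study conditions the package targets; its
defaults are those conditions, not tuning knobs.

| parameter | default | basis |
|---|---|---|
| variant count law | log-normal, median 77.5, σ_log 1.1, clip [1, 1970] | observed median/range; heavy right tail (two tumors > 750 variants) |
| TP53 prevalence | 0.86 | observed prevalence of non-silent TP53 |
| tissue VAF | Beta, mean 0.329, concentration 8 | observed tissue mean 32.9% |
| baseline blood VAF | log-normal, mean 0.0033, σ_log 0.8 | observed blood mean 0.33% |
| C1D3 multiplier | 1.5 | free parameter: baseline-to-C1D3 kinetics under one cycle of chemotherapy are not established, only that an early increase is seen; exposed in config, not inferred |
| schedule | T0, T1 (0.1 mo), T2 (month 5), then every 6 months to month 48 | 6 × 21-day cycles + 3–5 weeks to surgery ≈ month 5; ~6-month follow-up intervals |
| relapse rate / pCR rate | 0.14 / 0.34 | 7/50 relapses, 17/50 pCR |
| lead time | Uniform[2, 7] months | observed molecular-to-clinical leads of 2–7 months |
| relapse signal | exponential rise from 5 × 10⁻⁴ at onset to 0.02 at relapse | onset at 10× the positivity threshold; spike-like courses |
| draw compliance | 0.8 | roughly half the cohort missing protocol-critical draws |
| low-baseline / germline-artifact probabilities | 0.08 / 0.04 | 4/50 and 2/50 patients |
| transient positive probability (pCR / non-pCR) | 0.10 / 0.35 | single-variant transient positives during remission, more common without pCR |
| family size | 1 + Poisson(3) | PCR duplication structure unstated; every template yields ≥ 1 read pair |
| templates per amplicon | 5,000 (desk scale) | production depth (~6M read pairs/library) scaled down; configurable up |

The tumor-signal trajectory is zero from surgery onward for every
non-relapsing patient (pCR or not); transient single-variant positives are
modeled as locus-level artifacts on one post-surgery draw, separate from
the tumor trajectory, mirroring their interpretation as potential false
positives.  Relapse onset is clinical relapse minus the lead time, clamped
to the surgery month (the residual-disease course) with the clamp logged.

Simulated UMIs are drawn without replacement from a parity-check code (the
last base balances the base-sum mod 4), so distinct templates differ in at
least two UMI positions: error-free reads are never merged across
templates, while single UMI sequencing errors remain correctable by
directional grouping.  This mirrors error-distinguishable vendor UMI sets
and makes the zero-error round trip exact: reads → consensus → allele
counts reproduces the recorded alt-template counts identically, which is a
tested invariant.

Two fidelity levels exist deliberately.  Full read simulation exercises
UMI extraction, grouping, consensus and filtering; count-level simulation
draws alt consensus molecules directly as Binomial(templates, true VAF) —
exactly the quantity the zero-error read path recovers — and is what makes
cohort-scale end-to-end runs (50 patients × ~9 draws × 4 loci at 20,000
templates) run in seconds.  The equality of the two paths at zero error is
itself tested, so the count-level path is a verified shortcut, not an
approximation of unknown quality.

What the generator does **not** emulate: exome sequencing and somatic
calling (variant tables are generated, not called), copy-number and
strand-bias artifacts, indel realignment, context-dependent error spectra,
base-quality variation (qualities are constant Q30), clonal heterogeneity
between panel variants beyond a static per-variant multiplier, and any
clinical covariates beyond pCR/relapse/draw structure.  Passing tests
therefore demonstrate the correctness of the pipeline's logic under the
stated error model, not assay-level analytical validity on real plasma.

## Numerical and interface choices

- Internal coordinates are 0-based half-open; every exported TSV/VCF
  position is 1-based, converted only in the I/O layer; position 0 on
  input is rejected as a schema error.
- Amplicons are fixed ±75 bp around each selected locus: primer design is
  out of scope, but coordinates must be concrete for read assignment and
  allele counting.
- Panel selection ties (equal VAF) break by higher depth, then ascending
  (chromosome, position), making the design a deterministic, order-independent
  function of the variant table.  If non-silent TP53 variants alone ever
  exceeded the six-amplicon cap, the top-VAF six are kept.
- Pooling is greedy first-fit over patients in input order with all of a
  patient's primer pairs kept in one pool — deterministic and sufficient
  for the ~100-pair cap.
- The filter thresholds (population AF 0.001, MQ0 fraction 0.10, depth 20)
  are conventional somatic-filtering defaults, fully configurable; the
  filtering criteria themselves (known variants, population frequency, MQ0,
  depth, confidence) are fixed.
- Read error rates are defined against member bases (disagreeing non-N
  member bases over total non-N member bases); the alternative — rates
  against stored consensus tags — is not reconstructible and the chosen
  definition is fixed and documented.
- Means reported to one decimal round half-up via `decimal.Decimal`,
  avoiding banker's-rounding surprises at exact quarters.

## Problem sizes used in tests and the acceptance script

Cohort-level checks run 50–200 patients at count-level quantification with
20,000 templates per amplicon; read-level checks run single patients at
300–5,000 templates per amplicon and ~2,000–8,000 read families; the error-
suppression property uses 700 families of size 5 at 150 bp (≥ 10⁵ member
bases); generator calibration uses 500 variant profiles and 1,000 baseline
draws.  These sizes keep the full suite under a minute while leaving every
statistical check at least 3σ of headroom.

## Known limitations

- Positivity at default settings is a single-threshold rule; no background
  error model or per-locus noise calibration is applied beyond consensus
  filtering, so specificity at very high depth depends on probe QC and the
  `min_positive_variants` setting.
- The evaluability triage uses measured VAFs; patients whose true baseline
  signal sits near the 0.05% detectability boundary can flip categories
  under sampling noise, exactly as they would in practice.
- BAM/CRAM input and genome alignment are out of scope: the pipeline is
  amplicon-anchored end to end.
- Duplex (double-strand) consensus is not implemented; families are
  single-strand as defined by one UMI.
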