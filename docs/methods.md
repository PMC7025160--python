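# Methods

## Criteria model

Each diagnostic criteria set is a declarative rule with four conjunctive
clauses evaluated per respondent:

1. **Core**: at least `min_core` (default 1) of the core symptoms
   (yearning/longing, preoccupation with the deceased) present.
2. **Associated**: at least `min_associated` = k of the m associated
   symptoms present (PCBD 6/12, PGD_PLOS 5/9, CG 2/8, ICD11_PGD 1/7).
3. **Impairment**: grief reactions interfering with life at least weekly.
   The impairment probe is frequency-worded, so it is carried as a
   separate ordinal code (0 = never, 1 = less than monthly, 2 = monthly,
   3 = weekly, 4 = daily) rather than as a CGQ intensity item; the clause
   requires code ≥ 3 (configurable) and is shared across all four sets.
4. **Duration**: strictly more than `min_months_since_death` (default 12)
   months since the death. The boundary 12.0 is excluded ("more than one
   year"), and a failed duration clause is always decidable.

A symptom is *present* when any of its mapped CGQ items is endorsed at or
above the endorsement cutoff (default 3, "often", on the 0–4 scale —
anchors never/rarely/sometimes/often/very often). Endorsement dominates
missingness; a symptom is *absent* when at least one mapped item is
answered below cutoff and none is endorsed; it is *unknown* only when all
mapped items are unanswered.

### Missing data

Scoring is complete-case: an instrument total exists only when every item
is answered, and a respondent with a missing ICG or WSAS total is
*indeterminate* for caseness. Diagnoses never raise on missing data.
Instead each result carries `data_sufficient`: a respondent is
insufficient for a criteria set exactly when the observed responses leave
the diagnosis undecidable — the observed data fail some clause, but
setting every unknown symptom present (and the unanswered impairment
probe to its maximum) would satisfy all clauses. Because the criteria
logic is monotone in symptom states, this single maximal completion
decides reachability, which the test suite verifies against brute-force
truth-table enumeration. Every report (performance rows, κ, Venn,
run log) states the analyzed n after these exclusions.

### The default symptom-to-item mapping is a reconstruction

The published item-matching tables for the four criteria sets are not
reproduced in this repository, so the shipped mapping
(`data/default_criteria.json`) is built from the public structure: the
k-of-m counts, the shared core symptoms, and the observed strict nesting
of the diagnosed groups. Concretely, PCBD's 12 associated symptoms map
to one CGQ item each (cgq_03..cgq_14); the broader sets define coarser
symptom categories whose item sets union the items of the finer symptoms
they subsume (PGD_PLOS's 9 categories absorb the three rarest PCBD items;
CG merges two PGD_PLOS categories into one; ICD11_PGD merges two of CG's).
Under this construction the nesting

PCBD ⊆ PGD_PLOS ⊆ CG ⊆ ICD11_PGD

is a combinatorial consequence of the rule structure, not a statistical
tendency: for the only non-trivial link, any 6 endorsed items among
PCBD's 12 must cover at least 5 of PGD_PLOS's 9 union-mapped categories
(a covering argument over the three shared multi-category items), and the
remaining links drop k by at least the number of merged categories. Any
study-specific mapping can replace the default via the JSON config, in
which case nesting becomes an empirical question again.

## Comparison statistics

- **Conditional performance.** inclusion% = 100·P(diagnosed | case),
  exclusion% = 100·P(¬diagnosed | subthreshold), against the
  multidimensional caseness rule ICG ≥ 30 ∧ WSAS ≥ 20. Confidence
  intervals are Wilson score intervals (95%), chosen for good behaviour
  at the proportions near 0.9 seen here; rows with zero cases or zero
  subthreshold respondents are flagged undefined rather than dividing by
  zero. A cutoff grid (ICG ∈ {20,25,30} × WSAS ∈ {15,20}) is available to
  probe threshold sensitivity.
- **Agreement.** Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from the
  marginal products, computed on the full decidable sample without regard
  to ICG/WSAS scores, for all unordered pairs. When both classifications
  are constant and equal (p_o = p_e = 1) the limit κ = 1 is returned.
  Bands: poor < 0.20 ≤ fair < 0.40 ≤ moderate < 0.60 ≤ good < 0.80 ≤
  very good ≤ 1.
- **Membership partition.** Respondents decidable under all four sets are
  assigned to exactly one of the 16 diagnosis patterns; the rest are
  excluded and tallied, so cell counts conserve n.
- **Restrictiveness sweep.** Each set is re-evaluated with
  `min_associated` forced to k = 0..6 (points with k > m are omitted and
  logged). The operating point is the argmax of the Youden index
  J = inclusion% + exclusion% − 100; the selection rule is this package's
  choice, with exact ties broken toward smaller k because at equal
  accuracy the less restrictive rule is clinically preferable.

## Synthetic cohort generator

The generator emulates a community sample of adults bereaved more than a
year (n = 1732 by default):

- **Latent structure.** Grief severity θ is a two-class Gaussian mixture:
  a resilient class N(−0.55, 0.85²) and a persistent-grief class
  N(1.42, 0.75²) with mixture weight 0.31. Per instrument, θ is perturbed
  by independent Gaussian noise (sd 0.35 CGQ, 0.25 ICG, 0.60 WSAS) so
  instruments correlate strongly but imperfectly.
- **Items.** Each ordinal item follows a graded-response mechanism,
  P(X ≥ c | θ) = expit(a(θ − b_c)), discrimination a = 1.7 throughout and
  strictly increasing per-item thresholds: an item location plus
  symmetric level offsets (step 0.7 on the 0–4 scales, 0.35 on WSAS's
  0–8). Locations spread core CGQ items easiest (0.0–0.2), shared
  associated items 0.7–1.5, the three rarest associated items 1.8–2.0,
  ICG 0.0–1.6, WSAS 1.2–1.8. One uniform draw per (respondent, item)
  passes through the cumulative curves, which guarantees the generator's
  monotonicity: a higher trait stochastically raises every response.
- **Impairment and timing.** The impairment code is an ordered-logistic
  draw from θ (thresholds −0.8, −0.2, 0.6, 1.4); months since death is
  uniform on (13, 120), so every simulated respondent meets the duration
  clause, as in a more-than-one-year study sample. Missingness is
  missing-completely-at-random per item, default rate 0.
- **Calibration.** `calibrate` holds the item parameters fixed and
  searches the mixture weight (bisection against the ICG ≥ 30 marginal,
  which is monotone in the weight) over a coarse grid of persistent-class
  means, using Monte-Carlo evaluation at n = 20 000 with a fixed seed, so
  the search is deterministic. Targets are the two published marginals,
  ±2 percentage points: 37% ICG ≥ 30 and 16% joint caseness. The shipped
  defaults were produced by this procedure and are a fixed point of it.
- **Parameter recovery.** As a test surface, `recover_parameters` fits a
  two-component Gaussian mixture to ICG totals. Because totals from a
  single latent class are skewed and bounded, a second component always
  improves the likelihood, so single-class detection uses bimodality
  rather than BIC: Ashman's D = |μ₂ − μ₁|/√((σ₁² + σ₂²)/2) < 2.5 declares
  one class. Class means are reported on the total-score scale.

### What passing tests do and do not show

The generator reproduces the two published marginal prevalences, strong
cross-instrument rank correlation, and the structural findings (nesting,
sweep monotonicity, agreement improving when k is held constant). It does
not emulate demographics, relationship-to-deceased or cause-of-death
strata, item-level residual correlations beyond the single trait,
informative missingness, or the real instruments' exact item difficulty
profile — so quantitative agreement with the published per-set
percentages, κ values and Venn counts is approximate (the qualitative
ordering reproduces; exact values would require the non-public data).
Default problem sizes (20 cohorts of 1732 for calibration checks, 100
cohorts of 60 for the nesting property, n = 10 000 for recovery) keep the
full suite under a minute of simulation while leaving Monte-Carlo error
well inside the stated tolerances.

## Numerical notes

- Percentages are reported to one decimal in CSV outputs; counts exact.
- κ on empty input and performance rows without both groups return
  explicit undefined flags, never exceptions or silent NaN arithmetic.
- The pipeline re-reads the cohort CSV it writes, so a `run` is
  byte-identical to chaining `simulate`/`score`/`diagnose` by hand, and
  (manifest, seed) fully determines all outputs.
- Item identifiers (cgq_01.., icg_01.., wsas_01..) are stable strings;
  column order in files is not semantic.

## Known limitations

- The default mapping is a reconstruction (above); analyses of real CGQ
  data should supply the study's own item-matching table.
- PGD_PLOS is modelled as k-of-m plus the shared gates only; any
  additional non-symptom qualifiers in the original proposal are not
  modelled, as only the counts are public.
- The impairment probe is treated as distinct from the CGQ items; if a
  study's probe doubles as a symptom item, the mapping must say so.
- Conditional inclusion/exclusion probabilities are not sensitivity or
  specificity and should not be read against a population prevalence.
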