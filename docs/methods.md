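# Methods

This note records the statistical model, the generator's scope and
parameters, the numerical conventions fixed throughout the package, and the
known limitations. Everything here is implemented in `src/haiburden/` and
exercised by the test suite; the `manifest.json` written by `haiburden run`
repeats the conventions in force for a given bundle.

## 1. Study design

The analysis treats a hospitalization episode as the unit. An episode carries
demographics (age, sex), a DIP category, ICD-10 secondary diagnoses, surgery
and invasive-device flags, a surgical wound class, hospitalization and
diagnostic costs (CNY), a DIP standard payment, a payment type (DIP vs other
settlement), and a length of stay (LOS). Hospital-acquired infection (HAI)
events attach to episodes with an onset day (day 0 = admission; onset ≥ 2
encodes the ≥ 48 h definition), a site (SSI, CLABSI, VAP, CAUTI, other),
organisms and multidrug-resistant organism (MDRO) types.

Four settlement indicators are compared between infected and uninfected
episodes: hospitalization cost, diagnostic cost, LOS, and the **DIP payment
differential** = standard payment − hospitalization cost (positive = surplus,
negative = hospital loss). Currency indicators are reported in USD at
7.12 CNY/USD; arithmetic stays in CNY at full precision and conversion and
rounding happen only at the reporting boundary.

## 2. Synthetic cohort generator

The generator is the package's data source; its defaults *are* the reference
scenario and are never tuned per analysis.

**Sampling model, per episode**

- DIP category: categorical by catalogue weights (six default categories,
  weights 395 / 746 / 452 / 286 / 580 / 203,110; the last is a low-risk
  "general oncology" remainder).
- Age: normal(56, 12²) truncated to [18, 90], rounded; sex: male with
  probability 0.55; payment type: DIP with probability 0.597.
- Cost: lognormal with category median (`exp(μ)` = the catalogue median,
  σ per category, 0.30–0.55). Diagnostic cost = cost × Beta(2.5, 12)
  fraction (a sub-ledger of the total). Standard payment = category cost
  median, so uninfected differentials center near zero.
- LOS: lognormal around the category median rounded to whole days (minimum
  1); σ = 0 gives fixed stays (used in tests).
- Surgery per category probability; surgical episodes draw a wound class
  0/I/II/III from the category distribution, recorded with probability 0.9
  (unrecorded classes show as "none", which keeps the surgery flag and the
  wound dummies from being perfectly collinear in the GLM).
- Comorbidities: independent Bernoulli draws over a fixed ICD-10 code list
  (metastases, diabetes, hypertension, heart failure, COPD, etc.), plus the
  category's principal diagnosis.

**Infection process.** Days 2..LOS are at-risk days. The first onset follows
a truncated geometric law with per-day hazard `h × m_c`, where
`h = 7.22e-4` cohort-wide and `m_c` is the category's hazard multiplier
(8.37 / 6.30 / 6.51 / 10.06 / 4.61 / 1.0). Multipliers were calibrated by
root-finding so category-level incidences land at several percent in the
surgical categories while the cohort-wide incidence stays near 0.39%.
Subsequent events may occur over the extended stay (LOS +
`los_extension_days`). Each event draws a site (surgical vs medical site
distributions; catheter-site events force the device flag), organisms, and
the episode draws its distinct-MDRO-type count from
P(0,1,2,≥3) = (0.7456, 0.2157, 0.0237, 0.0150).

**Injected effects (ground truth).** After baseline sampling,
`inject_effects` modifies infected episodes only:

- cost += `cost_inflation × mdro_escalation^max(k−1,0)` (+
  `wound_class_escalation × wound_level` for SSI episodes), k = distinct
  MDRO types;
- diagnostic cost += `diagnostic_inflation` under the same MDRO multiplier;
- LOS += `los_extension_days`;
- standard payment += `payment_uplift_cny`, modelling partial regrouping of
  complicated stays into higher-paying DIP groups; it decouples the cost
  effect from the (smaller) differential deficit.

Defaults: +35,820.79 CNY cost, +5,687.53 CNY diagnostic, +9 days,
escalation 1.5, +2,500 CNY per wound level, +25,594.55 CNY payment uplift —
i.e., at MDRO count 0, +$5,031.01 cost, +$798.81 diagnostic and a −$1,436.27
differential effect in USD. Uninfected episodes are bit-identical between a
run with effects and a run with null effects, which the tests use to verify
the injected deltas exactly.

Reproducibility: six independent RNG streams are spawned from a single
`SeedSequence`, so the same configuration yields bit-identical tables.

## 3. Comorbidity scoring (CACI)

Charlson comorbidity index with the Quan-2005 ICD-10 coding algorithm and
original weights (17 categories, packaged as a TSV resource), plus age
points: 50–59 → 1, 60–69 → 2, 70–79 → 3, ≥ 80 → 4. Hierarchies apply
(metastatic disease supersedes malignancy; severe supersedes mild liver
disease; complicated supersedes uncomplicated diabetes). Codes are
normalized (uppercase, dots stripped) and matched by 4-character then
3-character prefix probes; unparseable codes warn and are ignored. High-risk
stratum when the combined score is **strictly greater than 3**.

## 4. Matching designs

All designs match 1:1 without replacement on: same DIP category, same sex,
same CACI stratum, |Δage| ≤ 5 years; nearest age breaks ties, then smallest
episode id (full determinism).

- **Exact matching**: cases = infected episodes, controls = never-infected;
  cases processed in episode-id order.
- **Propensity-score matching**: logit model of case status on age, sex and
  CACI stratum; DIP category remains an exact constraint; caliper = 0.2 × SD
  of the logit propensity in the pooled sample; case order is a seeded
  random permutation. Degenerate fits (perfect separation, exploding
  coefficients) raise a `MatchingError` advising exact matching.
- **Risk-set matching**: cases sorted by ascending onset day T1 (ties by
  id). A candidate control must still be hospitalized at T1 (LOS ≥ T1) and
  not yet infected at T1 (first onset strictly > T1; onset = T1 excludes).
  Later-infected patients are eligible controls before their own onset;
  first assignment wins, and a case consumed as a control is dropped from
  the case list (counted as "retained as control"). This design removes the
  time-dependent bias of naive matching, where long uninfected stays are
  compared against cases whose exposure time is guaranteed by their own
  infection.

## 5. Inference

Groups are summarised as median (P25, P75) with quartiles by linear
interpolation. Tests: Mann-Whitney U for two groups, Kruskal-Wallis for
more, chi-square (no continuity correction) for categorical contrasts.
Mann-Whitney uses exact enumeration when both samples have ≤ 20 observations
and no ties, otherwise the tie-corrected normal approximation **without**
continuity correction — chosen so the two-group Kruskal-Wallis identity
H = Z² holds exactly.

Effect sizes are Hodges-Lehmann median differences (median of all pairwise
case-minus-control differences) with the Moses rank-based interval: the
order statistics at cut `K = floor(N/2 − z·sqrt(n_x n_y (n_x+n_y+1)/12))`
from each end, clamped at the extremes, no interpolation (conservative for
tiny samples). Two-sided α = 0.05 throughout.

## 6. GLM of the payment differential

On the risk-set-matched sample, the DIP differential (USD) is regressed with
a Gaussian family and identity link — point estimates are OLS — and the HC1
heteroskedasticity-consistent sandwich covariance, appropriate for skewed
cost residuals. Confidence intervals are B ± 1.96 × robust SE (normal
reference; a t reference is available behind a flag).

Design matrix (reference level in parentheses): intercept, sex (male),
payment type (non-DIP), age (continuous), CACI stratum (≤ 3), invasive
device (no), surgery (no), wound class dummies 0/I/II/III (no surgery /
unrecorded), HAI (no), catheter-associated infection (no), distinct MDRO
types 1/2/3+ (0) — 15 non-reference terms plus the intercept. Levels absent
from the data are dropped with a warning; a rank-deficient design raises an
error naming the collinear columns (found via the SVD null vector). The
matched-pair structure is deliberately not modelled with a random effect.

## 7. Numerical conventions

- Half-up decimal rounding (`Decimal ROUND_HALF_UP`) at the reporting
  boundary only; incidence = cases / patients × 100, reported to 2 decimals.
- Currency conversion at 7.12 CNY/USD, applied to report values, never to
  intermediate arithmetic.
- Seeds are plain integers < 2³¹; every stochastic routine takes an explicit
  seed and identical configurations produce byte-identical output bundles
  (no timestamps in any artifact).

## 8. Validation summary

The acceptance layer of the test suite checks, against independent oracles:
Hodges-Lehmann ≡ brute-force pairwise median up to 200×200; Mann-Whitney
exact enumeration (x=[1,2], y=[3,4] → p = 1/3); type-I error of the matched
comparison in [0.04, 0.06] over 5,000 null replicates; the risk-set matcher
≡ a loop-based eligibility oracle on 50-episode sets; risk-set LOS MD ≤
naive exact-match LOS MD in ≥ 95% of 200 replicates (bias direction); HL CIs
covering all four injected truths in ≥ 90% of 100 registry-style replicates
(n = 20,000); and a mean GLM HAI coefficient within 3 Monte-Carlo standard
errors of an injected −2,000 USD effect over 200 replicates (observed mean
−1999.93, SE 7.8).

## 9. Limitations

- **Independence of cost and LOS.** Baseline cost and LOS are drawn
  independently within a category; real claims correlate them. Matched
  contrasts and GLM coefficients are unaffected (effects are injected
  directly), but joint cost-LOS statistics are not realistic.
- **Repeat-infection frequency.** Subsequent events are drawn over the
  extended stay with the same hazard; the resulting share of multi-infection
  episodes (~2% of cases) is lower than the several percent typical of
  registry data. Frequency-stratified contrasts therefore rest on few
  episodes at registry scale.
- **Constant payment within category.** The DIP standard payment is the
  category cost median plus the infected uplift; real settlements vary with
  annual point values and institution coefficients.
- **Homogeneous hazard within category.** The per-day hazard does not depend
  on age, comorbidity or device use, so infection risk confounding is milder
  than in real data; matching covariates still shift the matched pool, but
  estimated effects are dominated by the injected deltas by construction.
- **No admission-present infections, transfers or deaths**; every episode
  ends in discharge at its sampled LOS.
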