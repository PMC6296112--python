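# Methods

## Data model

A spontaneous-reporting database is four relational tables keyed by
`report_id` — demographics (age description, sex), drugs (generic
name, causality role), adverse events (MedDRA PT code + name), and
patient history (comorbidity terms) — joined into one `CaseReport`
per demographics row. The canonical on-disk dialect is UTF-8 CSV with
a header row and long-format child tables; translating a real agency
download (Japanese headers, agency-specific encodings) is an adapter
concern deliberately left outside the package.

**Age stratification.** Reports are stratified onto the 10-year grid
≤19, 20–29, …, 80–89, ≥90. Any description containing a parseable
integer age is banded, including suffixed years ("75歳") and decade
forms ("70歳代" → 70–79). Categorical descriptions (young adults,
adults, elderly, pregnancy trimesters, unknown) and anything
non-numeric are `excluded` — they cannot be placed on the grid.
Design choices on points the banding convention leaves open: ages
≥100 fall into the ≥90 band (the grid's rule is "≥ 90", so they are
banded, not excluded), and the last band carries the display alias
"90–99". The mapping is total: every string yields a band or
`excluded`, and every retained report occupies exactly one band.

**Drug classes.** The packaged map holds the 98 generics of the eight
ATC classes used in fall-risk screening (α-blockers C02CA; loop-type
diuretics C03CA/C03CC; calcium channel blockers C08; opioids N02A;
benzodiazepine derivatives and related drugs N05CD/N05CF;
barbiturates, aldehydes, melatonin receptor agonists and other
hypnotics/sedatives N05CA/N05CC/N05CH/N05CM; non-selective monoamine
reuptake inhibitors N06AA; SSRIs N06AB). The composite *CNS-active*
group is the union of the last five classes. Matching is exact,
case-insensitive, whitespace-trimmed — no fuzzy matching, for
determinism. The packaged list is kept verbatim, including three
source-list transcription spellings (*triazoram*, *frosemide*,
*lefepramine*); a small alias table resolves the common international
spellings (triazolam, furosemide, lofepramine) onto those entries so
either form classifies identically. Drug counts (`n_cns`, `n_ccb`)
are **distinct substances**: duplicate listings of one generic under
several roles count once. All three role codes (suspected,
concomitant, interacting) are included everywhere.

**Outcome.** A report is fall-related iff any of its event PTs is in
the outcome definition — by default fall (10016173), dizziness
(10013573), orthostatic hypotension (10031127); the set is
configurable. The flag is monotone under event-set union.

## Disproportionality

Crude ROR = (a/c)/(b/d) on the report-level 2×2 table, with the Woolf
log-normal 95% CI, exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)). This CI
method is the SRS-literature standard and reproduces the published
worked-example intervals to two decimals, which fixes the choice.
Signal criterion: lower CI bound > 1 **and** ≥ 2 cases. Zero cells
get the Haldane–Anscombe +0.5 correction on all four cells with an
explicit `corrected` flag (the case-count filter still uses the
uncorrected count). The reporting-ratio column is 100·a/(a+b).
Contingency building counts each report exactly once; class
membership means any drug in the report maps to the class, which the
worked-example arithmetic confirms is report-level (not
drug-report-pair) counting.

## Rule mining

Transactions are sets of namespaced items; `n_cns:k`/`n_ccb:k` are
emitted only for k ≥ 1, at most one `age:` item per report, and the
consequent `ev:fall_related` exactly when the outcome flag is true.
Reports mapping to no items still count in D.

Apriori is level-wise: frequent 1-itemsets, then candidate k-itemsets
joined from (k−1)-itemsets sharing a (k−2)-prefix with subset
pruning; counting is vectorised over a boolean transaction × item
matrix. `min_support` is inclusive (support ≥ threshold, implemented
as count ≥ ⌈min_support·D − ε⌉ with ε = 1e-12 guarding exact
boundaries); `maxlen` bounds the itemset size *including* the
consequent, matching the semantics of the standard R implementation.
Correctness is checked against an exhaustive-enumeration oracle on
small random databases, and support anti-monotonicity is asserted on
mined output.

Rules are generated only for the fixed fall-related consequent — a
post-filter over frequent itemsets, equivalent to an appearance
constraint — with confidence ≥ min_confidence, and sorted by lift
descending with deterministic tie-breaks (support descending, then
lexicographic antecedent).

The chi-squared interest statistic uses the
support/confidence/lift form

    chi² = D·(lift−1)²·(support·confidence) / ((confidence−support)·(lift−confidence))

which is algebraically Pearson's 2×2 chi-squared (verified
numerically to 1e-6 relative in the property suite); chi² ≥ 4
(≈ p < 0.05 at 1 df) flags significance. At exact independence
(lift = 1) chi² = 0 by definition. Degenerate margins — an antecedent
or consequent present in every transaction — make the denominator
vanish: the statistic is returned as NaN with a reason rather than a
crash or a silent 0.

**Subgroup denominators.** A subgroup run (e.g. age ≥ 60) uses D =
size of the analysed subset by default, the principled choice. A
compatibility switch (`support_denominator: full`) scores supports
against the full-database denominator instead, because published
subgroup tables in this literature sometimes print supports on the
full-database scale; joint counts and confidences are identical
either way.

**A known non-reproducible column.** In the published ≥60 subgroup
table, the printed chi-squared values are not consistent with the
printed support/confidence/lift under the formula above (e.g. the
single-item SSRI rule: printed inputs give ≈ 236, printed chi² is
135.59), while the demographic-items table reproduces within input
rounding. The package computes the formula; it does not emulate the
inconsistent column. Likewise, full reconstruction of a published
58-rule table from its marginal rows alone is an under-determined
inversion (antecedent strata overlap), so worked-example checks use
the rows whose antecedent totals are uniquely recoverable from case
count and confidence, plus exact disjoint-strata fixtures.

## Synthetic databases

The generator emulates the statistical skeleton the analysis assumes,
not reporting sociology: independent per-class Bernoulli exposures,
an age mix on the 10-year grid, per-report drug counts, independent
comorbidity flags, and an outcome with multiplicative risk

    P(fall-related) = clip( baseline · Π multiplier(item present) ), in (0, 1).

Multiplicative-on-probability (rather than logistic) is deliberate:
at the rare rates used, risk ratio ≈ odds ratio ≈ lift, so a planted
multiplier is the value every downstream statistic should recover,
making recovery tests directly interpretable.

Defaults are chosen once to mirror a large real SRS snapshot: the age
mix reconstructed from published band totals (mode at 70–79, ~11% of
reports with non-bandable age), class exposure prevalences equal to
the published class report frequencies (e.g. benzodiazepines ≈ 8.9%,
CCBs ≈ 12%), baseline fall probability 0.008 giving an overall
fall-related rate near the observed ~0.9%, and risk multipliers set
to the published class- and age-association sizes (e.g.
benzodiazepines 1.83, SSRIs 2.86, diuretics 0.74, band 80–89 1.59)
with modest comorbidity effects. Counts of concomitant drugs follow
configurable distributions (`cns_count_dist` over 1–6 given CNS
exposure, mostly 1; `ccb_count_dist` over 1–3): the total CNS count
is drawn truncated to at least the number of exposed CNS classes and
each exposed class contributes at least one distinct substance, which
keeps per-class exposure marginals exactly calibrated while honouring
the count distribution. An optional shared latent log-odds factor
(`polypharmacy_sd`) induces positive exposure correlation for stress
tests; exposures are independent by default.

Two layers serve different scales. The vectorised
`SyntheticDatabase` (numpy arrays of exposures, counts, outcome
flags) supports calibration studies — its `contingency()` produces
the same 2×2 counts as building the table from materialised reports,
an equivalence asserted by a dedicated test, and it is what the
1,000-database null-calibration run uses. Materialisation to
`CaseReport` objects draws concrete generic names from the packaged
class lists plus inert filler drugs and guarantees a non-empty event
set per report (a filler PT when the outcome is absent). Both layers
are deterministic: the same seed yields byte-identical CSVs
(materialisation uses a child RNG stream independent of any array
computation order).

Exact fixtures: `fixture_from_strata` builds a database from disjoint
strata (exposure items, stratum size, fall count), and
`fixture_from_counts` specialises it to a 2×2 table that
`build_contingency` reproduces cell-exactly — so published counts run
through the same code paths as simulated data.

**What passing does and does not show.** The generator omits
duplicate reports, notoriety and stimulated-reporting waves,
within-report exposure–age confounding beyond the planted
multipliers, and missingness other than the non-bandable-age
fraction. Passing recovery and calibration tests therefore
demonstrates correctness of the statistical machinery under the
stated generative assumptions, not robustness of SRS signal detection
to real-world reporting biases.

## Problem sizes and numerical choices

Default validation scales, chosen as the package's own test budget:
planted-effect recovery at 200,000 reports (one seed), null
calibration over 1,000 databases of 20,000 reports via the vectorised
path, apriori-versus-enumeration on 200 random databases of ≤ 12
items × ≤ 200 transactions, and a 10,000-report write→load round
trip. The analysis drivers use a 100,000-report snapshot. Thresholds
mirror the published parameterisation: demographic rules at min
support 1e-6, min confidence 0.001, maxlen 3; history × class rules
in the ≥60 subgroup at min confidence 0.01, maxlen 4.

Floating-point policy: full precision internally, 2-decimal rounding
only at the display/assertion boundary; CI z-value fixed at 1.96; rule
tables written with `%.10g` so runs are byte-reproducible.

## Limitations

- Crude ROR only — no stratified/adjusted ROR, PRR, IC/BCPNN or
  EBGM; confounding by age or indication is not adjusted for.
- MedDRA PTs are opaque strings; no SOC/HLT hierarchy traversal.
- The drug map covers exactly the 98 packaged generics; unlisted
  drugs are simply unclassified (never an error).
- Apriori only (as named in this literature); no FP-growth or
  closed/maximal itemset mining. With item counts in the dozens this
  is not a practical constraint.
- Rule-graph visualisation is out of scope.
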