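# fallmine

Pharmacovigilance analysis of **fall-related adverse events** in
spontaneous-reporting-system (SRS) databases: reporting-odds-ratio
disproportionality per drug class, and association-rule mining over
report-level risk items (age band, number of concomitant CNS-active
drugs, drug classes, comorbidities).

Falls in older adults are driven simultaneously by medication, age and
comorbid disease. SRS databases such as JADER or FAERS — four linked
tables of demographics, drugs, adverse events and patient history —
record these factors per report and support two complementary
analyses, both implemented here for anyone studying drug-related fall
risk at database scale:

1. **Disproportionality (ROR).** For an index drug class and the
   fall-related outcome (MedDRA PTs *fall* 10016173, *dizziness*
   10013573, *orthostatic hypotension* 10031127), reports are
   collapsed to a 2×2 table (a = event & class, b = other events &
   class, c = event & other drugs, d = neither) and

   ROR = (a/c) / (b/d),  95% CI = exp( ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d) )

   A class is a **signal** when the lower CI bound exceeds 1 with at
   least two cases. Drug classes follow the ATC hierarchy (8 classes,
   98 generics, packaged); *CNS-active drugs* are the union of
   opioids, benzodiazepines and related drugs, hypnotics/sedatives,
   non-selective monoamine reuptake inhibitors and SSRIs, per the AGS
   2015 Beers Criteria.

2. **Association rules.** Each report becomes a transaction of
   namespaced items (`age:70-79`, `n_cns:4`, `class:benzodiazepines`,
   `hist:dementia`, …); a from-scratch level-wise **apriori** mines
   frequent itemsets, and rules X → {fall-related} are scored with

   support = P(X∩Y),  confidence = P(Y|X),  lift = P(X∩Y)/(P(X)·P(Y)),
   chi² = D·(lift−1)²·(support·confidence) / ((confidence−support)·(lift−confidence))

   where D is the transaction count; chi² equals Pearson's 2×2
   chi-squared, and chi² ≥ 4 flags a rule as significant. Output is
   sorted by lift.

Because real SRS downloads are licensed/external, the package ships a
**synthetic database generator** with planted multiplicative risk
effects (at rare outcome rates, risk ratio ≈ odds ratio ≈ lift), so
every stage is validated end to end against known ground truth, plus
exact fixture builders that rebuild databases from published 2×2
counts.

## Worked example

```sh
python analysis/01_simulate.py    # 100,000-report synthetic database
python analysis/02_signals.py    # ROR signal tables
python analysis/03_mine_rules.py # association rules
```

The second driver also routes the published worked-example counts
(3,715 fall-related reports of 430,587; 8 ATC classes) through the
pipeline and prints, among others:

```
                                   label  case_n  class_total  ror  ci_low  ci_high  is_signal
        Alpha-adrenoreceptor antagonists      64         4600 1.63    1.27     2.09       True
Benzodiazepine derivatives/Benzodiazepine
                           related drugs     561        38300 1.83    1.68     2.01       True
 Selective serotonin reuptake inhibitors     212         9058 2.86    2.49     3.29       True
```

i.e. α-blockers reported with fall-related events 1.63× (95% CI
1.27–2.09) as often as expected under independence — a signal, since
the CI excludes 1 with ≥2 cases. On the synthetic database the third
driver prints the lift of the single-item CNS-drug-count rules, which
climbs with the number of concomitant CNS-active drugs (1.24 for one
drug to 3.57 for six in the run above; the sparsest strata are noisy)
— the planted interaction between CNS polypharmacy and fall risk,
recovered by the miner.

Equivalent shell entry points: `fallmine simulate | signals | rules |
full` (see `fallmine --help`; `full` takes a YAML config and writes
`signals.csv`, `rules_demographic.csv`, `rules_history.csv`,
`run_log.json`).

## Layout

- `src/fallmine/` — library: `schema` (reports, age bands, event
  definition), `drug_classes` (ATC map), `io` (four-table CSV
  dialect), `simulate` (generator + fixtures), `disproportionality`
  (ROR), `rules` (apriori + scoring), `pipeline`/`cli` (orchestration).
- `analysis/` — numbered narrative drivers writing under `results/`.
- `docs/methods.md` — models, parameter choices, numerical decisions,
  limitations.
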