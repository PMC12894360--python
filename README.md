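# pvsignal

Pharmacovigilance signal detection on spontaneous adverse-event report
databases, built around the drug-induced male infertility screening
problem: which drugs are reported with male reproductive-toxicity
events (azoospermia, oligospermia, male infertility, …) far more often
than the reporting background predicts?

The package is aimed at pharmacoepidemiologists and drug-safety
analysts. It ingests two database dialects — FAERS-style quarterly
ASCII packages and EudraVigilance-style consolidated master-case
listings — and runs the full screening workflow:

1. **Ingest & clean** — parse the `$`-delimited DEMO/DRUG/REAC/THER/OUTC
   tables, collapse report versions to one per case (max `FDA_DT`, ties
   broken by max `PRIMARYID`), drop cases on the quarterly deletion lists.
2. **Case definition** — male sex, a reaction exactly matching a MedDRA
   Preferred Term screening list (a 13-term reproductive-toxicity list
   ships as the default), and a suspect-role drug (`PS` in FAERS,
   "Suspected" in EV), with user-supplied synonym-table drug-name
   standardization.
3. **Disproportionality screening** — for each drug a 2×2 table of
   counting units (unique case–drug pairs) against the male background,
   and four statistics with a conjunctive positive-signal criterion:

   | statistic | form | condition |
   |---|---|---|
   | ROR | ad/bc, CI `exp(ln ROR ± 1.96·s)`, `s=√(1/a+1/b+1/c+1/d)` | lower CI > 1, a ≥ 3 |
   | PRR | [a/(a+b)]/[c/(c+d)] | PRR ≥ 2 and χ² ≥ 4 |
   | IC (BCPNN) | log₂ RRR, RRR = aN/((a+b)(a+c)) | IC025 > 0 |
   | EBGM (MGPS) | RRR with log-normal bound EBGM·e^(−1.96·s) | EBGM05 > 2 |

4. **Stratified analyses** — dechallenge/rechallenge `= Y` subsets
   (screened against their own background), consumer vs. healthcare
   professional reporter strata, and ATC first-level drug classes.
5. **Time-to-onset** — days from first suspect-drug administration to the
   event (full dates only), segment distribution, Kaplan–Meier cumulative
   onset curve, Wilcoxon comparison across seriousness strata.
6. **Cross-database validation** — drugs positive in both databases
   independently are designated high-confidence signals.

A calibrated synthetic report generator (`pvsignal.synth`) emulates both
dialects — duplicate report versions, deletion lists, occupation codes,
partial dates, dechallenge/rechallenge flags, seriousness outcomes — and
plants drug–event associations of known relative reporting ratio, so the
whole pipeline is testable without access to the real databases.

## Worked example

Generate a 50,000-case synthetic database with a planted RRR=20 signal
on (finasteride, azoospermia) and a weaker RRR=8 signal on
(testosterone, male infertility), then screen it:

```python
import pvsignal as pv
from pvsignal.synth import SyntheticConfig, PlantedSignal

cfg = SyntheticConfig(seed=1, n_cases=50000, planted_associations=[
    PlantedSignal("FINASTERIDE", "10003883", 20.0),
    PlantedSignal("TESTOSTERONE", "10021929", 8.0)])
listing, manifest = pv.generate_ev_listing(cfg)
units = pv.screening_units(pv.from_ev(listing))
print(pv.screen(units).head(5).round(2).to_string(index=False))
```

```
            drug  n   ror  ror_low  ror_high   prr  prr_low  prr_high   chi2   ic  ic025  ebgm  ebgm05  positive
     FINASTERIDE 43 29.89    20.78     42.98 25.63    18.59     35.34 767.99 4.32   3.79 19.91   13.84      True
    TESTOSTERONE 15  9.60     5.57     16.55  9.07     5.43     15.14  92.29 3.07   2.29  8.41    4.88      True
HYDROXYCARBAMIDE  3  1.76     0.56      5.56  1.75     0.56      5.45   0.36 0.80  -0.86  1.74    0.55     False
      PAROXETINE  3  1.70     0.54      5.37  1.69     0.55      5.26   0.29 0.75  -0.91  1.68    0.53     False
     LEUPRORELIN  3  1.63     0.52      5.15  1.63     0.52      5.05   0.23 0.69  -0.96  1.62    0.51     False
```

Reading the first row: finasteride appears in 43 of the 25,010 male
case–drug units with a target event; its EBGM of 19.91 recovers the
planted reporting-rate ratio of 20, and every criterion condition holds,
so the drug is flagged positive. The two planted drugs — and only they —
are flagged; the decoy drugs stay at the null.

The full pipeline (both databases, all strata, time course,
cross-validation, CSV export with a seeded run log) is one call or one
shell command:

```sh
pvsignal report --seed 7 --out results/
pvsignal --help          # simulate / screen / strata / temporal / crossval / report
```

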