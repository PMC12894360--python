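# Methods

## Screening model

Spontaneous reporting systems have no exposure denominator, so
association is measured by disproportionality: does the target
drug–event combination account for a larger share of the drug's
reports than the same event does among all other drugs? All
screening statistics derive from the 2×2 table of counting units
within one stratum,

```
              target event   other events
target drug        a              b
other drugs        c              d          N = a+b+c+d
```

The counting unit is the unique (case, suspect drug) pair; a unit is a
target-event unit when its case carries at least one reaction matching
the Preferred Term screening list. A case with two suspect drugs
contributes two units; a case with two matched PTs on one drug
contributes one unit (the drug–event *record* convention, where each
matched PT counts separately, is available via
`screening_units(..., events_as_records=True)` and is the default
counting basis for the ATC class analysis, whose published pair counts
follow records).

Closed forms:

- **ROR** = ad/bc with 95% CI `exp(ln ROR ± 1.96·s)`,
  `s = √(1/a+1/b+1/c+1/d)`.
- **PRR** = [a/(a+b)] / [c/(c+d)] with
  `s_PRR = √(1/a − 1/(a+b) + 1/c − 1/(c+d))`.
- **χ²**: Pearson on the 2×2, Yates-corrected by default (the classical
  companion to the PRR ≥ 2 rule); the uncorrected statistic is a
  config switch and both variants are tested. Undefined (NaN) when a
  table margin is zero.
- **EBGM** is the simplified, unshrunk relative reporting ratio
  RRR = aN/((a+b)(a+c)), with log-normal lower bound
  `EBGM05 = EBGM·exp(−1.96·s)` sharing the ROR's log-SE. Full
  DuMouchel hyperprior fitting is deliberately out of scope: the
  unshrunk form is what makes the published table internally
  consistent (log₂ EBGM reproduces the printed IC to 2 dp, and
  EBGM05/EBGM equals ROR_low/ROR), and those two relations are
  regression-tested.
- **IC** = log₂ RRR. The IC025 lower bound has no single canonical
  form in the applied literature, so it is configurable:
  `"normal"` (default) IC − 1.96·s/ln 2; `"bate"`, the closed-form
  posterior moment approximation of the BCPNN with the standard
  hyperparameters (α₁=β₁=1, α=β=2, prior IC expectation 0);
  `"mc"`, a seeded Monte-Carlo 2.5th percentile of the posterior RRR
  under a Jeffreys Dirichlet(½,…) prior on the four cell
  probabilities. The variants are sanity-checked against each other
  but no external printed IC025 value is asserted.

**Zero cells.** A zero in any cell triggers the Haldane–Anscombe +0.5
correction on all four cells for the ROR/PRR points, intervals and the
shared log-SE; EBGM/IC points use the raw cells (finite whenever both
margins are positive). With the correction disabled, a zero in b or c
raises an error rather than returning infinities.

**Positive signal.** The conjunction a ≥ 3, ROR_low > 1, PRR ≥ 2,
χ² ≥ 4, IC025 > 0, EBGM05 > 2 (all thresholds configurable; the
inequalities on IC025 and EBGM05 are strict). The conjunction is
deliberately conservative; its empirical false-positive rate on
planted-null synthetic databases is well under 5% of drugs screened.

## Cleaning conventions

Report versions sharing a CASEID collapse to the one with maximum
FDA_DT, ties broken by maximum PRIMARYID — numerically when both ids
parse as integers (FAERS ids are numeric strings of varying length),
lexicographically otherwise. Deletion lists apply after deduplication.
DEMO rows lacking a caseid or a parseable 8-digit FDA_DT are
quarantined to a rejects table, never guessed. Files are read as UTF-8
with per-line Latin-1 fallback; malformed lines are counted and logged,
and the read fails only when their fraction exceeds a tolerance
(default 1%).

Age conversion to years: DEC×10, YR×1, MON÷12, WK÷52.18, DY÷365.25,
HR÷8766; a value without a unit is taken as years. Age groups
[0,18), [18,45), [45,65), [65,∞). Reporter classes: occupation codes
CN and LW → consumer; MD, PH, OT, HP → healthcare professional;
anything else → unspecified (excluded from both reporter strata). The
descriptive cohort table additionally keeps the raw occupation
category, since published baseline tables report consumers and lawyers
separately.

## Time-to-onset

TTO = event date − earliest full start date over the case's qualifying
suspect-drug rows, from full 8-digit dates only; partial dates and
negative intervals are excluded and itemised in a completeness report
(negative intervals are excluded, not clamped — an event reported
before therapy start is evidence of a date error, not a zero-day
onset). All observations are treated as events (spontaneous reports
record occurred reactions), so the Kaplan–Meier CDF coincides with the
empirical CDF; the KM machinery is kept so censored extensions remain
possible. Quantiles are the smallest times at which the CDF reaches
the level, with a 1e-9 tolerance absorbing product-form rounding in
the KM estimate. The seriousness comparison uses the Wilcoxon rank-sum
(Mann–Whitney) test: exact enumeration when both strata have ≤ 20
observations, tie-corrected normal approximation otherwise.

## Synthetic generator

`synth.SyntheticConfig` defines the study conditions; its defaults are
fixed once and shared by all tests:

- **Vocabulary**: 39 drugs (the 19 screened drugs at marginal
  probability 0.01 each, 20 common decoys at 0.0405) and 37 events
  (the 13 target PTs at 4×10⁻⁴ each — a target-set share of ~0.5% of
  reports, the realistic order for a niche event set — against 24
  common background reactions at 0.04). Marginals summing below 1 are
  renormalised.
- **Joint model**: each case draws one suspect drug and one reaction
  from q(i,j) ∝ λ_ij·p_i·p_j with λ = 1 off the planted cells.
- **Planted-signal calibration**: the statistics tabulate a drug
  against the whole 13-term set, so a raw cell multiplier is both
  diluted by the unboosted set members and attenuated by the marginal
  inflation it causes; the attained set-level RRR is unimodal in λ
  with a finite ceiling. The generator solves λ numerically (1-D root
  find on the rising branch, with a fixed-point pass for interacting
  plants) so the attained set-level RRR equals the requested target —
  this is what makes the recovered EBGM an asymptotically unbiased
  estimate of the planted value, which the consistency tests check at
  three database sizes. Plants restricted to an occupation or
  seriousness stratum multiply the cell only within that stratum.
  The calibration is exact for plants on distinct drugs and events
  and approximate (normaliser-only coupling) otherwise.
- **Demographics**: male fraction 0.5; age a two-component truncated
  normal mixture (0.8·N(35,10) + 0.2·N(60,12) on [0,95]) with 44%
  missing, matching the published cohort's age structure and
  missingness; occupation probabilities matching the published
  reporter mix (MD .29, PH .07, OT .13, CN .43, LW .02, missing .06);
  seriousness rate 0.4.
- **Time-to-onset**: per-drug families (log-normal default,
  μ = ln 132 ≈ 4.883, σ = 2.0 — median at the published 132 days with
  a heavy upper tail spanning the published IQR), clipped at 7300 days
  (therapy never predates the reporting window by more than ~20
  years). Onset timing is drawn independently of seriousness.
- **Dates**: receipt dates uniform over eight configured quarters;
  event = receipt − U(0,365) days; start = event − TTO. Each of the
  start/event dates is full 8-digit with probability 0.45, else
  truncated to YYYYMM or YYYY — leaving ~20% of cases with a
  computable TTO, the documented completeness of real spontaneous
  reports.
- **Duplicates & deletions**: 10% of cases emit a second version with
  the same CASEID, a later FDA_DT, a distinct PRIMARYID, and age as
  the only perturbed non-key field (so dedup correctness is checkable
  field-by-field); 2% of caseids go on deletion lists.
  Dechallenge/rechallenge codes are drawn from separate distributions
  for planted-cell and background cases (Y-rate 0.35 vs 0.05).

The truth manifest records the planted associations (target RRR and
solved raw multiplier), the surviving caseids, the emitted version
count, and the male case-drug unit tabulation per drug, from which the
expected 2×2 cells of any drug are reconstructed exactly.

**What the generator does not emulate** — correlated drug
co-prescription, indication channeling (confounding by indication),
notoriety/Weber reporting dynamics, free-text drug-name noise beyond
the synonym mechanism, MedDRA version drift, and geography. Tests
passing on synthetic data therefore validate the pipeline's mechanics
and its statistical calibration under independent reporting, not
robustness to those real-data biases.

## Pipeline conventions

Both databases are screened with the same criterion after applying one
synonym table to both sources; the cross-database intersection refuses
to run when one drug appears under two spellings. Ranking is by ROR
descending with lexicographic tie-break. Annual counts use the FDA
receipt year for FAERS and the listing's receive year for EV. The EV
background is the whole listing (no region restriction). The export is
a fixed file set (header-only when a table is empty) plus a
`run_log.json` holding the seed, config snapshot and per-stage counts —
no timestamps, so identical inputs give byte-identical outputs. The
synthetic end-to-end run in the tests uses 20,000 cases per database,
and the Monte-Carlo calibration suites use 20 databases of 50,000
(recovery) and 20,000 (null) cases.

## Known limitations

- The unshrunk EBGM is not strictly monotone in a when the drug's own
  margin dominates the background (it tends to 1 as a → ∞); the
  monotonicity property is only asserted, and only holds, in the
  background-dominated screening regime.
- WHO-DD and the MedDRA hierarchy are licensed; standardization is
  exact-match plus a user synonym table, and event matching is exact
  PT code/name equality — no hierarchy traversal, no fuzzy matching.
- Real FAERS quarterly layouts older than 2012 (LAERS), INDI/RPSR
  tables, and automatic download are out of scope.
- Dechallenge/rechallenge and time-to-onset analyses are FAERS-only;
  the EV listing schema carries neither drug-level codes nor therapy
  dates.
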