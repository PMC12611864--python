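# Methods

## Setting and scope

The package analyses spontaneous adverse-event-following-immunization (AEFI)
reports for two infant combination vaccines — pentavalent DTaP-IPV-Hib and
hexavalent DTaP-IPV-Hib-HepB — in the VAERS public-extract file dialect.
Passive reporting systems carry no denominator, so every output is a
*reporting* quantity: disproportionality statistics compare an event's share
of reports between the two vaccine classes, and the logistic model estimates
the odds that a *report* is classified as death, not mortality risk.

## Cohort construction

A report enters the cohort when it satisfies all of:

1. at least one vaccine row whose name matches a combination-vaccine pattern
   (`DTAP + IPV + HIB` for pentavalent, `DTAP + IPV + HEPB + HIB` for
   hexavalent). A report matching both patterns resolves to hexavalent: the
   hexavalent pattern is the stricter superset, so a dual match means the
   name carried the HepB component.
2. age within 42 days to 730 days. Boundaries in years use 365.25 days/year
   and 30.44 days/month; age groups are half-open — G1 [42 d, 4 mo),
   G2 [4 mo, 8 mo), G3 [8 mo, 730 d] — with both outer endpoints included.
   The group labels ("6 weeks to 4 months" etc.) do not themselves fix
   open/closed ends; this convention is ours and is applied consistently.
3. first occurrence of its report id (file order); later duplicates are
   dropped. Same-day/same-age/same-sex/same-PT-set near-duplicates are only
   logged, since the duplicate rule in the source material is stated at the
   id level.
4. at least one PT outside the configurable vaccination-error list (default:
   the procedural-complication block of the toy vocabulary). Error PTs on
   otherwise-clinical reports are retained.

`serious` is the five-flag composite (death, life-threatening,
hospitalization, prolonged hospitalization, disability); emergency-room-only
visits do not count. Percentages in the summary table are rounded half-up to
one decimal, the convention of the published table the fixture reproduces.

## Disproportionality statistics

All four methods consume the same report-level 2×2 table; a report
mentioning an event through several PTs counts once. Events with a = 0 in
the target class are not scored — no threshold can flag them.

**Comparator.** The default comparator is the other vaccine class's cohort
(`other_class`), matching the two-vaccine comparative design. Classical
pharmacovigilance practice instead uses all other reports in the database as
background; an `external_background` mode accepts user-supplied (c, d)
counts for that purpose. Results depend on this choice; it is surfaced in
every API.

**Formulations.** ROR and PRR are the classical estimators with a
Haldane–Anscombe +0.5 on all four cells applied *only* when some cell is
zero. The ROR interval is the log-normal Wald CI. PRR is accompanied by the
Yates-corrected Pearson chi-square (reference only; it enters no threshold).
The BCPNN information component is the shrinkage form
IC = log₂((a+0.5)/(E+0.5)) with expected count E = (a+b)(a+c)/N; its
credible bound IC025 is exact, the 2.5% gamma-posterior quantile, not a
normal approximation. MGPS follows DuMouchel's two-component gamma-Poisson
mixture: the marginal likelihood of a count given E is a two-component
negative binomial, the five hyperparameters (α₁, β₁, α₂, β₂, w) are fit by
multi-start L-BFGS-B on log/logit-transformed parameters (five documented
starting points, best optimum kept, convergence metadata attached), and the
posterior is again a gamma mixture with updated weights. EBGM uses the
digamma closed form for E[ln λ]; EB05 is found by bracketed Brent root
finding on the posterior mixture CDF (absolute tolerance below 1e-6,
bracket guaranteed by component-wise quantiles). An unstratified E is the
default; a stratified variant (summing per-stratum products over age × sex)
can be assembled from the subgroup module but is not switched on anywhere.

**Thresholds and consensus.** ROR ≥ 3 with CI lower bound > 1; PRR ≥ 2 with
a ≥ 3 (reading "N" as the target-class event count, the EMA convention);
IC025 > 0; EB05 > 2. Ties use exactly these inequalities. An event is a
consensus signal when at least two methods flag it. No further
multiple-testing adjustment is applied — a deliberate mirror of standard
signal-detection practice and a documented limitation: the consensus rule
controls false positives empirically (the null calibration test measures
the per-PT consensus false-flag rate at well under 0.05) but offers no
formal error-rate guarantee.

**Prior-fit floor.** Fitting five hyperparameters to fewer than 20 events is
not meaningfully identified, so `fit_mgps_prior` refuses; the scoring
convenience layer then falls back to the canonical prior
(0.2, 0.1, 2.0, 4.0, w = 1/3) with a warning, so SOC-level analyses of small
vocabularies still run.

## Death-classification model

Per vaccine class, logistic regression of the death flag on age group
(reference G1), sex (reference male; unknown-sex reports excluded and
counted — the published-style table has no unknown row), and
co-administration (reference vaccine-alone). Newton/IRLS maximum likelihood
(statsmodels), intervals and p-values are Wald; non-convergence raises, and
perfect separation — which genuinely occurs in the deterministic fixture,
whose flags occupy contiguous index ranges — is reported rather than
papered over with penalization. The pipeline records a skipped model in the
manifest instead of aborting the run.

## Synthetic cohort generator

The generator emulates the structure the analysis needs, with known ground
truth; it is not a model of real reporting behaviour.

- **PT occurrences** are conditionally independent Bernoulli given vaccine
  class: P(PT on report) = min(1, baseline × rr(PT, class)). Products above
  1 are clamped with a warning. A report that would carry no clinical PT
  receives the benign fallback PT (Pyrexia), keeping report counts exact and
  every generated report inside the cohort rules — so the
  write-dialect → ingest round trip is the identity.
- **Ages** are drawn uniformly on a 0.01-year grid inside the sampled age
  group (VAERS stores AGE_YRS with two decimals); the stored age always
  determines the group, so rounding can never contradict the grouping.
- **Death** follows the configured logistic model on age group, sex and
  co-administration; unknown-sex reports use the male reference in the
  linear predictor. Other seriousness flags are drawn independently given
  death status, and death forces the serious composite. Died reports are
  coded recovered = no.
- **Defaults** are the study conditions of the real cohort: 3,259 + 1,720
  reports; P(female) = 0.455, P(unknown sex) = 0.06; co-administration 0.68
  (pentavalent) and 0.88 (hexavalent); per-class seriousness probabilities at
  the published proportions; death coefficients at the published pentavalent
  odds ratios (0.212, 0.170, 0.440, 6.694) with intercept −5.0, giving ≈2%
  death classification overall; age distributions (0.55, 0.25, 0.20) and
  (0.60, 0.25, 0.15) with the youngest group largest, as reported.
- **Not emulated:** dependence among PTs, reporting delays and stimulated
  reporting, geography beyond a categorical region, MedDRA's real size and
  hierarchy (the toy vocabulary has ~50 PTs in 13 SOCs), and any link
  between seriousness and which PTs are reported. Tests passing on this
  generator therefore validate the *pipeline's arithmetic and operating
  characteristics under independence*, not its behaviour on real VAERS data.

The deterministic fixture is a separate object: its per-class margins equal
the published summary table exactly, with flags laid out over contiguous
index ranges so the five-flag union hits the printed serious count. Its
joint structure is arbitrary (the table prints only margins) — which is why
it exhibits separation in the death model.

## Numerical and testing choices

- Random tables for the statistic oracles draw all four cells from
  {0, …, 50}, discarding only empty target or comparator margins.
- The Monte-Carlo IC025 oracle uses 2×10⁵ gamma draws. An empirical 2.5%
  quantile at that size has sampling error ≈ √(p(1−p)/n)/f(q), which exceeds
  0.02 bits when the posterior shape a + 0.5 is small (≈0.04 bits at a = 0).
  The comparison tolerance is therefore max(0.02, 4 × that analytic SE) per
  table — the slack term comes from the oracle's own sampling theory, and
  for a ≥ 2 the tolerance is simply 0.02 bits.
- The EB05 oracle is an independent path: posterior weights via scipy's
  negative-binomial pmf and the quantile via plain interval bisection,
  compared at 1e-6.
- Null Wald coverage is pooled across the four non-intercept terms
  (2,000 intervals over 500 fits): per-term coverage at 500 replicates has
  ≈1% binomial noise, too coarse for a [93%, 97%] band.
- Problem sizes: the test suite runs the full designs (100-seed calibration
  and power, 10-seed prior recovery at 5,000 events, 500-fit coverage,
  200-fit OR recovery); `scripts/acceptance.py` re-runs the same
  computations at lighter sizes (50 seeds, 3 recovery seeds, 100/50 fits) —
  its JSON records the size next to each value.
- Determinism: a single run seed is split with numpy `SeedSequence`
  spawning; identical configuration and seed give byte-identical pipeline
  outputs (fixed float formatting, sorted orderings, documented tie-breaks —
  events by descending count then label).

## Known limitations

Beyond the generator simplifications above: the comparator question (other
class vs external background) materially changes E and all four statistics;
the toy vocabulary cannot reproduce real MedDRA granularity effects (one
clinical phenomenon splitting across many PTs); and the death model
deliberately omits interactions and pooling across classes, matching the
two-column published layout.
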