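# Methods

## Data model

The unit of observation is the **company-year**: one manufacturer's public
disclosures for one calendar year. The packaged panel covers the four HTP
manufacturers of material global scale (PMI, KT&G, BAT, JT) over 2014–2024 —
44 cells. Each cell holds up to two quantities: a user count (input unit:
millions of persons) and an annual heated-stick shipment volume (input unit:
billions of sticks). `N/A` means *not disclosed*; an explicit `0.0` is a
reported zero and counts as data. Internally everything is canonicalized to
persons and stick units; display units exist only at I/O, which removes a
whole class of scale bugs from mixed formulas.

Where a company published several figures for the same year (revisions in
later reports), the latest **report vintage** wins; undated records lose to
any dated one, and two latest-vintage records that disagree are an error
rather than a silent pick, because "most recent wins" offers no tiebreak.

Of the 44 cells, 25 have reported user counts, 14 have shipments only, and 5
have neither (pre-launch or pre-disclosure years); classification keys on
provenance flags, so an inventory taken after imputation still describes the
raw disclosures.

## Shipment-to-user conversion

The core estimator converts a shipment volume to an implied user count:

    users = sticks / (c × 365)

with `c` the brand's mean sticks per user per day. The year length is fixed
at 365; leap years are ignored (the error this introduces, <0.3% on one year
in four, is far below the consumption uncertainty).

**Calibration.** `c` is estimated from a donor company's dual-disclosure
years as the arithmetic mean of per-year implied ratios
`sticks/(users × 365)`, then rounded to the parameter's published precision.
Mean-of-ratios weights each disclosure year equally; a pooled
ratio-of-sums would weight recent high-volume years and gives a visibly
different answer on the BAT donor (7.43 vs 7.64). On the packaged panel:

* PMI donor, nine dual years (2016–2024), unrounded mean 11.989 → **12
  sticks/day**, applied to KT&G (which reports no user counts at all — the
  donor choice follows the published analysis; both brands' devices serve
  similar markets but this is an assumption, not an estimate);
* BAT donor, six dual years (2019–2024), unrounded mean 7.638 → **7.6
  sticks/day**, applied to BAT and JT.

Rounding precision is part of the parameter definition (integer for the
PMI-derived value, one decimal for BAT's) and is supplied by the assumptions
config rather than hard-coded.

## Uncertainty bounds

Two bounding modes are implemented:

* **User-space ±50%** (`multiplicative_user_bounds`): the converted user
  count is multiplied by 0.5 and 1.5. This is the primary series' mode. The
  alternative parameter-space reading of "±50% on the consumption
  assumption" would give asymmetric user bounds (×2/3, ×2), which cannot
  reproduce the near-symmetric published range around the 2024 central;
  user-space perturbation can, so the pipeline treats the sensitivity as a
  statement about users. Both modes remain available.
* **Parameter-CI** (`parameter_ci_bounds`): users are recomputed at the CI
  endpoints of the consumption parameter; since users ∝ 1/c, the upper
  endpoint yields the lower user bound. The alternative series uses this
  with 7.3 (6.33–8.27) sticks/day.

Directly reported user counts carry no sensitivity: lower = central = upper.
Yearly bounds are sums of component bounds, which treats component errors as
perfectly correlated — deliberately conservative for a deterministic
sensitivity design, not a confidence interval.

## Imputation and reconciliation

Five cells have neither value and are resolved by documented rules, applied
before either series is built; every action is tagged on the cell and logged:

* **Launch zeros** — PMI 2014 (IQOS launched in 2014; Japanese prevalence
  was 0.2% in 2015, so the launch year is taken as zero), BAT 2016 (glo
  launched in December 2016). PMI 2015 is likewise zeroed: no published
  assumption covers it, but it predates PMI's first user disclosure and any
  non-negligible uptake, and a zero keeps the series defined over all 44
  cells rather than failing coverage. This is the one gap-filling choice
  made here beyond the published rule list.
* **Share carry** — JT's missing 2019–2020 shipments are filled from its
  assumed 2.5% global stick share (its 2019 level): with share *s*, missing
  volume = s/(1−s) × (other companies' combined volume), i.e. the share is
  of the global total including JT. The published assumption text speaks of
  2017–2018, but the disclosure table prints explicit zeros there and gaps
  in 2019–2020; the pipeline follows the table and surfaces the conflict in
  its log.
* **Split carry** — a mechanism for scaling a total-market stick figure to
  its domestic component using a source year's domestic proportion. The
  packaged panel records KT&G's 2021+ volumes as already domestic-only, so
  the default config ships no active split rule; the mechanism is
  implemented and tested for panels that supply a 2020 global total plus a
  2021 domestic share. Whether KT&G's printed 2020 figure is global or
  domestic is genuinely unstated; treating it as domestic-consistent is the
  conservative reading.
* **Reconciliation** — PMI commercializes KT&G's products outside South
  Korea from December 2020 and its user totals from 2021 include those
  users. From 2021 the KT&G cells are flagged domestic-only and any user
  count KT&G might report is dropped rather than added on top of PMI's;
  KT&G's contribution is its domestic shipments converted at 12 sticks/day.
  The operation is idempotent.

Company-years that resolve to none of reported / converted / rule-imputed
raise a coverage error naming the cells — a silently dropped or zeroed cell
would bias the global total invisibly.

## Survey series

Per country: `users = round(prevalence/100 × population)`, population being
the survey cohort's size (input unit: thousands) for the survey year; ties
round half away from zero. No age standardization or survey-year alignment
is attempted — the surveys span 2019–2025, cohorts 15+/16–74/18+/19+, and
heterogeneous instruments; they are carried as metadata. The aggregate sums
the *printed* user column of the source table (35 countries, 21,782,246
persons; the top five — Japan, South Korea, Italy, Ukraine, Germany — hold
78.5%). Recomputed `prevalence × population` values are kept as a
cross-check column: most cells agree within ±5 persons (denominator display
rounding), but Uzbekistan's printed count was evidently computed from an
unrounded prevalence (0.235% vs the printed 0.24%) and recomputes 1,075
persons high — one reason the printed column, not the recomputation, is
authoritative for the aggregate.

## Synthetic markets

The generator emulates the structure, not the history, of the disclosure
panel: per-company users follow a logistic curve K/(1+e^(−r(t−t0))) from a
launch year (zero before it), shipments are users × c × 365 with optional
multiplicative lognormal noise (σ defaults to 0.05 — a mild reporting/timing
jitter; user counts are definitional truth and carry none), a per-cell mask
reproduces the four disclosure patterns (both / users-only / sticks-only /
none), and masked values get the display rounding of published figures (0.1
million users, 0.1 billion sticks; the rounding arithmetic matches the CSV
reload path bit-for-bit so synthetic panels survive a write/read cycle
unchanged). Logistic growth was chosen as the simplest monotone curve with
saturation matching the observed uptake shape; any monotone curve would do.
Generation is a pure function of the scenario including its seed.

What passing synthetic tests show: calibration recovers a known consumption
parameter from dual-disclosure years; noiseless correctly-specified runs
recover true global users to display-rounding precision; mis-specifying
consumption by factor f shifts converted estimates by exactly 1/f; ±50%
user-space bounds cover truth whenever the true consumption is within
[2/3, 2]× the assumed one. What they do not show: robustness to real-world
features the generator omits — definitional drift in "user", user churn and
dual use, within-year consumption heterogeneity, geographic reallocation,
or correlated revisions across years.

## Numerical and reporting choices

All arithmetic is unrounded float64; rounding happens only at calibration
(published parameter precision) and display (totals to 0.1 million).
Published inputs being display-rounded themselves, recomputed headline
totals differ from originally published ones by up to ~1.5% (e.g. 49.38 vs
48.9 million for the 2024 primary central) — the original analysis evidently
carried unrounded internal figures. The packaged tests therefore compare
headline totals at 3% relative tolerance and structural quantities exactly.

## Known limitations

* Manufacturer "user" definitions differ (PMI: past-7-day use; BAT:
  undefined; JT and KT&G: none) and the primary series inherits that
  heterogeneity; the alternative series trades it for a uniform but
  literature-derived consumption assumption.
* Bounds are deterministic sensitivity ranges, not confidence intervals.
* No country-level allocation of disclosure-based users, no exclusive-use
  vs dual-use decomposition, no forecasting, and Imperial Brands (late,
  non-disclosing entrant) is out of scope.
* The survey aggregate is a lower bound: 35 countries, mostly 2022–2023
  survey years, under partial market coverage.
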