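# Default analysis assumptions for the manufacturer-disclosure pipeline.
#
# Conversion: sticks-per-day parameters used to turn shipment volumes into
# implied user counts. KT&G's parameter is calibrated from PMI's dual-disclosure
# years (KT&G itself reports no user counts); BAT's is calibrated from its own
# dual years and shared with JT (neither Ploom user counts nor JT-specific
# consumption data are published).
conversion:
  KT&G:
    central: 12
    donor: PMI
    rounding: 0
    bound_mode: multiplicative_user_bounds
  BAT:
    central: 7.6
    donor: BAT
    rounding: 1
    bound_mode: multiplicative_user_bounds
  JT:
    central: 7.6
    donor: BAT
    rounding: 1
    bound_mode: multiplicative_user_bounds

# Literature consumption parameter for the shipment-only series
# (survey evidence: mean 7.3 sticks/day, 95% CI 6.33-8.27).
literature:
  central: 7.3
  ci: [6.33, 8.27]

# Imputation rules for company-years with neither users nor sticks.
imputation:
  launch_zero:
    - [PMI, 2014]   # pre-launch-scale year; national prevalence 0.2% in 2015
    - [PMI, 2015]   # pre-disclosure year, negligible uptake
    - [BAT, 2016]   # glo launched December 2016
  share_carry:
    - company: JT
      source_year: 2019
      target_years: [2019, 2020]
      share: 0.025  # JT's global heated-stick share at its 2019 level

# Double-counting reconciliation: PMI's published user totals from 2021 onward
# already include licensed KT&G products outside South Korea; KT&G contributes
# only its domestic (South Korea) shipments from that year.
reconciliation:
  absorbing: PMI
  absorbed: KT&G
  effective_from: 2021
  domestic_market_retained: true
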