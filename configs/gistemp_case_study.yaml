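# Global-mean temperature case study: GISTEMP monthly anomalies
# (units 0.01 degC), one variable per calendar month, yearly time steps,
# 40-year window advanced 1 year at a time.
#
# The size-of-state vector below is the published per-month uncertainty for
# this analysis (Jan..Dec). The stable period that produced it was not
# recorded, so it is supplied explicitly rather than re-estimated.
#
# The GISTEMP table itself is not shipped (it is distributed by NASA GISS
# and revised retroactively); see scripts/gistemp_case_study.py for a
# documented download-and-run attempt.
input:
  path: scratch/gistemp_monthly.csv   # place the downloaded table here
  format: gistemp
size_of_state:
  mode: explicit
  values: [35.96, 39.21, 34.14, 31.17, 32.94, 24.68, 24.14, 31.28, 25.87,
           36.43, 27.25, 40.81]
window:
  width: 40
  increment: 1
tightening:
  mode: strict
smoothing:
  block: 1
summary:
  periods:
    - [1919, 1978]
    - [1979, 2015]
output:
  fi: scratch/gistemp_fi.csv
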