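# SYNTHETIC placeholder morphometrics config.
#
# The otolith-length -> fish-length coefficients and age-group length cutoffs
# below are round-number stand-ins of realistic magnitude, NOT literature
# values.  They exist so the pipeline runs end to end on simulated data.
# Replace every number with species- and region-appropriate published
# regressions before analysing real samples.
#
# fish_length_mm = (intercept_mm + slope * otolith_mm) * shrinkage_factor
# shrinkage_factor in [1.00, 1.04] optionally corrects for freezing shrinkage.

regressions:
  polar cod:
    intercept_mm: 10.0
    slope: 20.0
    otolith_min_mm: 0.8
    otolith_max_mm: 10.0
    shrinkage_factor: 1.0
  capelin:
    intercept_mm: 5.0
    slope: 35.0
    otolith_min_mm: 0.6
    otolith_max_mm: 5.0
    shrinkage_factor: 1.0
  Atlantic herring:
    intercept_mm: 0.0
    slope: 55.0
    otolith_min_mm: 0.5
    otolith_max_mm: 4.5
    shrinkage_factor: 1.0
  Atlantic cod:
    intercept_mm: -5.0
    slope: 28.0
    otolith_min_mm: 1.0
    otolith_max_mm: 12.0
    shrinkage_factor: 1.0
  glacier lanternfish:
    intercept_mm: 8.0
    slope: 18.0
    otolith_min_mm: 0.5
    otolith_max_mm: 4.0
    shrinkage_factor: 1.0

# Length (mm) upper bounds for age classes 0+, 1, 2, 3, 4; above the last
# cutoff a fish is classed ">4".
age_cutoffs_mm:
  polar cod: [90, 130, 160, 185, 210]
  capelin: [100, 130, 155, 175, 190]
  Atlantic herring: [110, 180, 230, 270, 300]
  Atlantic cod: [160, 280, 380, 470, 550]
  glacier lanternfish: [35, 50, 60, 68, 75]
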