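# Single-outcome logistic carrier-risk model, MMRpredict-style structure
# (clinical, pre-tumour-testing stage): applies to CRC probands only, and —
# unlike the multinomial model above — includes tumour side (proximal CRC)
# as a covariate.
#
# SYNTHETIC COEFFICIENTS: structure follows the published model family; the
# numeric values are synthetic stand-ins, not the published equation.
model_name: mmrpredict_synthetic
outcomes: [carrier]
encoding:
  male: {kind: indicator, field: sex, equals: male}
  age_crc: {kind: age, field: age_first_crc, shift: 50, scale: 10}
  proximal: {kind: indicator, field: any_proximal_crc}
  crc_two_plus: {kind: indicator, field: num_crc, equals: "2+"}
  fdr_crc: {kind: count, field: fdr_crc_n, cap: 2}
  fdr_crc_age: {kind: age, field: fdr_crc_youngest_age, shift: 60, scale: 10, default: 0}
  fdr_ec: {kind: count, field: fdr_ec_n, cap: 2}
model:
  carrier:
    intercept: -2.7
    coefficients:
      male: -0.20
      age_crc: -0.55
      proximal: 1.10
      crc_two_plus: 1.00
      fdr_crc: 0.65
      fdr_crc_age: -0.35
      fdr_ec: 0.70
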