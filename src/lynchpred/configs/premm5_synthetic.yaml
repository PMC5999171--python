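# Four-gene multinomial carrier-risk model, PREMM5-style structure.
#
# SYNTHETIC COEFFICIENTS: the covariate set, encodings and multinomial
# structure follow the published model family, but the numeric values here
# are synthetic stand-ins chosen to be clinically plausible (young ages,
# multiple tumours and affected relatives raise risk; tumour side is NOT a
# covariate). They are not the published equation. Replace this file with a
# transcription of the published coefficients for clinical use.
model_name: premm5_synthetic
outcomes: [MLH1, MSH2, MSH6, PMS2]
encoding:
  male: {kind: indicator, field: sex, equals: male}
  crc_two_plus: {kind: indicator, field: num_crc, equals: "2+"}
  age_crc: {kind: age, field: age_first_crc, shift: 50, scale: 10, default: 0}
  ec: {kind: indicator, field: ec}
  other_ls: {kind: indicator, field: other_ls_cancer}
  fdr_crc: {kind: count, field: fdr_crc_n, cap: 2}
  fdr_crc_age: {kind: age, field: fdr_crc_youngest_age, shift: 60, scale: 10, default: 0}
  fdr_ec: {kind: count, field: fdr_ec_n, cap: 2}
  fdr_other: {kind: count, field: fdr_other_ls_n, cap: 2}
  sdr_crc: {kind: count, field: sdr_crc_n, cap: 2}
  sdr_ec: {kind: count, field: sdr_ec_n, cap: 2}
model:
  MLH1:
    intercept: -3.7
    coefficients:
      male: 0.30
      crc_two_plus: 0.90
      age_crc: -0.45
      ec: 1.60
      other_ls: 0.60
      fdr_crc: 0.55
      fdr_crc_age: -0.55
      fdr_ec: 1.00
      fdr_other: 0.20
      sdr_crc: 0.25
      sdr_ec: 0.40
  MSH2:
    intercept: -3.9
    coefficients:
      male: 0.35
      crc_two_plus: 0.90
      age_crc: -0.40
      ec: 1.50
      other_ls: 0.80
      fdr_crc: 0.50
      fdr_crc_age: -0.50
      fdr_ec: 1.00
      fdr_other: 0.35
      sdr_crc: 0.25
      sdr_ec: 0.45
  MSH6:
    intercept: -3.4
    coefficients:
      male: 0.25
      # estimated on development data with no eligible carriers; the
      # updating procedure re-estimates this term (delta)
      crc_two_plus: 1.20
      age_crc: -0.30
      ec: 1.70
      other_ls: 0.50
      fdr_crc: 0.35
      fdr_crc_age: -0.35
      fdr_ec: 1.10
      fdr_other: 0.25
      sdr_crc: 0.20
      sdr_ec: 0.50
  PMS2:
    intercept: -4.0
    coefficients:
      male: 0.15
      crc_two_plus: 0.40
      age_crc: -0.35
      ec: 0.60
      other_ls: 0.30
      fdr_crc: 0.40
      fdr_crc_age: -0.30
      fdr_ec: 0.50
      fdr_other: 0.20
      sdr_crc: 0.25
      sdr_ec: 0.30
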