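economic:
  discount_rate_annual: 0.03
  cycle_length_years: 1.0
  start_age: 1
  horizon_end_age: 84
  currency_label: USD
  sgd_per_usd: 1.317
  half_cycle_on_qalys_only: true
clinical:
  p_major_first_year: 0.01
  p_major_subsequent: 0.001
  p_wound_first_year: 0.005
  p_wound_subsequent: 0.0005
  p_explant_first_year: 0.005
  p_explant_subsequent: 0.0005
  max_internal_replacements: 2
  warranty_years: 10
  first_implant_complications_in_sequential: false
utilities:
  base_increment_bimodal: 0.232
  base_increment_bilateral_extra: 0.03
  bands:
  - age_low: 1
    age_high: 1
    scaling: 0.28
    bimodal_cell: 0.066
    bilateral_cell: 0.009
  - age_low: 2
    age_high: 3
    scaling: 0.91
    bimodal_cell: 0.212
    bilateral_cell: 0.027
  - age_low: 4
    age_high: 54
    scaling: 1.0
    bimodal_cell: 0.232
    bilateral_cell: 0.03
  - age_low: 55
    age_high: 64
    scaling: 0.98
    bimodal_cell: 0.227
    bilateral_cell: 0.0294
  - age_low: 65
    age_high: 69
    scaling: 0.96
    bimodal_cell: 0.223
    bilateral_cell: 0.0288
  - age_low: 70
    age_high: 74
    scaling: 0.91
    bimodal_cell: 0.211
    bilateral_cell: 0.0273
  - age_low: 75
    age_high: 79
    scaling: 0.84
    bimodal_cell: 0.195
    bilateral_cell: 0.0252
  - age_low: 80
    age_high: 84
    scaling: 0.72
    bimodal_cell: 0.167
    bilateral_cell: 0.0216
costs:
  surgery_implantation: 4940.0
  surgery_wound_revision: 6454.0
  surgery_explant_reimplant: 7115.0
  ward_day: 172.0
  ci_device: 28216.0
  hearing_aid: 949.0
  aided_hearing_test: 29.0
  audiologist_session: 81.0
  auditory_assessment: 53.0
  avt_slp_session: 116.0
  ct_scan: 405.0
  ent_review: 57.0
  speech_assessment: 35.0
  external_processor_replacement: 5895.74
  external_processor_cycle_years: 7
  hearing_aid_cycle_years: 5
  bilateral_acquisition_multiplier: 1.0
reliability:
  intercept: 0.998749
  slope_per_year: 0.002911
  valid_from_year: 20
  valid_to_year: 80
resource_schedule:
  incremental:
  - arm: simultaneous
    model_year: 1
    resource: ci_device
    units: 1.0
  - arm: simultaneous
    model_year: 1
    resource: surgery_implantation
    units: 1.0
  - arm: sequential
    model_year: 2
    resource: audiologist_session
    units: 4.0
  - arm: sequential
    model_year: 2
    resource: auditory_assessment
    units: 4.0
  - arm: sequential
    model_year: 2
    resource: avt_slp_session
    units: 6.0
  - arm: sequential
    model_year: 2
    resource: ent_review
    units: 2.0
  - arm: sequential
    model_year: 2
    resource: speech_assessment
    units: 1.0
  - arm: sequential
    model_year: 2
    resource: ct_scan
    units: 1.0
  - arm: sequential
    model_year: 3
    resource: ci_device
    units: 1.0
  - arm: sequential
    model_year: 3
    resource: surgery_implantation
    units: 1.0
  - arm: sequential
    model_year: 3
    resource: ward_day
    units: 1.0
  - arm: sequential
    model_year: 3
    resource: audiologist_session
    units: 10.0
  - arm: sequential
    model_year: 3
    resource: auditory_assessment
    units: 2.0
  - arm: sequential
    model_year: 3
    resource: avt_slp_session
    units: 52.0
  - arm: sequential
    model_year: 3
    resource: ent_review
    units: 2.0
  - arm: sequential
    model_year: 3
    resource: speech_assessment
    units: 2.0
  - arm: sequential
    model_year: 4
    resource: audiologist_session
    units: 2.0
  - arm: sequential
    model_year: 4
    resource: auditory_assessment
    units: 2.0
  - arm: sequential
    model_year: 4
    resource: avt_slp_session
    units: 26.0
  - arm: sequential
    model_year: 4
    resource: ent_review
    units: 1.0
  - arm: sequential
    model_year: 4
    resource: speech_assessment
    units: 2.0
  - arm: sequential
    model_year: 5
    resource: audiologist_session
    units: 2.0
  - arm: sequential
    model_year: 5
    resource: auditory_assessment
    units: 2.0
  - arm: sequential
    model_year: 5
    resource: avt_slp_session
    units: 2.0
  - arm: sequential
    model_year: 5
    resource: ent_review
    units: 1.0
  - arm: sequential
    model_year: 5
    resource: speech_assessment
    units: 2.0
  backbone:
  - model_year: 1
    resource: ci_device
    units: 1.0
  - model_year: 1
    resource: surgery_implantation
    units: 1.0
  - model_year: 1
    resource: ward_day
    units: 1.0
  - model_year: 1
    resource: audiologist_session
    units: 4.0
  - model_year: 1
    resource: auditory_assessment
    units: 4.0
  - model_year: 1
    resource: avt_slp_session
    units: 6.0
  - model_year: 1
    resource: ent_review
    units: 2.0
  - model_year: 1
    resource: speech_assessment
    units: 1.0
  - model_year: 1
    resource: ct_scan
    units: 1.0
  - model_year: 1
    resource: audiologist_session
    units: 10.0
  - model_year: 1
    resource: auditory_assessment
    units: 2.0
  - model_year: 1
    resource: avt_slp_session
    units: 52.0
  - model_year: 1
    resource: ent_review
    units: 2.0
  - model_year: 1
    resource: speech_assessment
    units: 2.0
  - model_year: 2
    resource: audiologist_session
    units: 2.0
  - model_year: 2
    resource: auditory_assessment
    units: 2.0
  - model_year: 2
    resource: avt_slp_session
    units: 26.0
  - model_year: 2
    resource: ent_review
    units: 1.0
  - model_year: 2
    resource: speech_assessment
    units: 2.0
  - model_year: 3
    resource: audiologist_session
    units: 2.0
  - model_year: 3
    resource: auditory_assessment
    units: 2.0
  - model_year: 3
    resource: avt_slp_session
    units: 2.0
  - model_year: 3
    resource: ent_review
    units: 1.0
  - model_year: 3
    resource: speech_assessment
    units: 2.0
life_table: synthetic_sg_lifetable.csv
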