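# Parameter-file schema (YAML mapping). All keys optional unless noted;
# omitted fields take the published defaults. Loaded by
# cochlear_cea.parameters.load_parameters; unknown keys are errors.

economic:                     # discounting and horizon
  discount_rate_annual: float   # [0,1), default 0.03
  cycle_length_years: float     # fixed 1.0
  start_age: int                # default 1
  horizon_end_age: int          # default 84 (end of last utility band)
  currency_label: str           # default "USD"
  sgd_per_usd: float            # reporting only, default 1.317
  half_cycle_on_qalys_only: bool  # default true

clinical:                     # annual event probabilities and caps
  p_major_first_year: float     # default 0.01 (= wound + explant halves)
  p_major_subsequent: float     # default 0.001
  p_wound_first_year: float     # default 0.005
  p_wound_subsequent: float     # default 0.0005
  p_explant_first_year: float   # default 0.005
  p_explant_subsequent: float   # default 0.0005
  # invariant: p_wound_* + p_explant_* == p_major_* per period
  max_internal_replacements: int  # default 2
  warranty_years: int             # default 10
  first_implant_complications_in_sequential: bool  # default false

utilities:                    # utility-gain schedule (over no implantation)
  base_increment_bimodal: float          # default 0.232 /yr
  base_increment_bilateral_extra: float  # default 0.03 /yr
  bands:                      # contiguous ascending age bands
    - age_low: int
      age_high: int
      scaling: float          # (0,1]
      bimodal_cell: float     # printed cell, used verbatim
      bilateral_cell: float   # printed cell, used verbatim

costs:                        # unit costs, 2017 USD; all >= 0
  surgery_implantation: float           # 4940
  surgery_wound_revision: float         # 6454
  surgery_explant_reimplant: float      # 7115
  ward_day: float                       # 172
  ci_device: float                      # 28216
  hearing_aid: float                    # 949
  aided_hearing_test: float             # 29
  audiologist_session: float            # 81
  auditory_assessment: float            # 53
  avt_slp_session: float                # 116
  ct_scan: float                        # 405
  ent_review: float                     # 57
  speech_assessment: float              # 35
  external_processor_replacement: float # REQUIRED; no published value
  external_processor_cycle_years: int   # default 7
  hearing_aid_cycle_years: int          # default 5
  bilateral_acquisition_multiplier: float  # DSA lever, default 1.0

reliability:                  # linear cumulative-survival model
  intercept: float            # default 0.998749
  slope_per_year: float       # annual DECLINE, default 0.002911
  valid_from_year: int        # default 20
  valid_to_year: int          # default 80

resource_schedule:            # optional; defaults to the published schedule
  incremental:                # arm-specific items
    - {arm: bimodal|simultaneous|sequential, model_year: int,
       resource: <costs field name>, units: number}
  backbone:                   # shared first-implant pathway (cancels in ICERs)
    - {model_year: int, resource: <costs field name>, units: number}

life_table: str               # optional reference to an age,qx CSV
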