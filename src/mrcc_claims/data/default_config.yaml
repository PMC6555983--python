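# Default study configuration for the mRCC claims pipeline.
#
# Day-count rules mirror the study conventions: "6 months" = 180 days,
# "3 months" = 90 days, 30-day windows literal.  All values here are
# plain user configuration and can be overridden by a partial YAML file.
#
# Code sets below marked SYNTHETIC DEFAULTS are plausible ICD-9/ICD-10-CM
# prefix lists assembled for testing with the synthetic generator; they
# are NOT an authoritative clinical code list and should be replaced for
# any real-data use.

parameters:
  gap_days: 90               # <= 3-month gap permitted inside an episode
  switch_window_days: 30     # new agent > 30 d post-index starts 2L
  index_replace_window_days: 30
  combination_window_days: 30
  five_day_exclusion_days: 5
  washout_acute_days: 30
  washout_chronic_days: 365
  enrollment_pre_days: 180
  enrollment_post_days: 180
  baseline_days: 180         # covariate look-back
  ae_post_treatment_days: 30 # AE risk window extends 30 d past end of 1L
  tcc_pre_index_days: 30
  index_window: ["2011-01-01", "2015-12-31"]
  # diagnosis claims may fall anywhere in the total study period, which
  # pads the index period (Jul 2010 / Sep 2016 style margins)
  dx_window_pad_before_days: 184
  dx_window_pad_after_days: 273

catalog:
  cycle_lengths:             # labeled dosing intervals, days (configurable)
    bevacizumab: 14
    temsirolimus: 7
    aldesleukin: 14
    ifn_alfa: 14

code_sets:
  kidney_cancer: ["189.0", "C64"]
  metastasis:                # secondary-metastasis site groupings
    lung: ["197.0", "197.1", "197.2", "197.3", "C78.0", "C78.1", "C78.2", "C78.3"]
    liver: ["197.7", "C78.7"]
    brain: ["198.3", "198.4", "C79.3", "C79.49"]
    bone: ["198.5", "C79.5"]
    other: ["196", "197.4", "197.5", "197.6", "197.8", "198.0", "198.1",
            "198.2", "198.6", "198.7", "198.8", "C77", "C78.4", "C78.5",
            "C78.6", "C78.8", "C79.0", "C79.1", "C79.2", "C79.40",
            "C79.6", "C79.7", "C79.8", "C79.9"]
  comorbidity:               # SYNTHETIC DEFAULTS (baseline flags)
    diabetes: ["250", "E10", "E11"]
    ckd: ["585", "N18"]
    liver_disease: ["571", "K70", "K74", "K76"]
    copd: ["491", "492", "496", "J41", "J42", "J43", "J44"]
    chf: ["428", "I50"]
  other_primary_cancer:      # SYNTHETIC DEFAULTS (exclusion criterion);
    breast: ["174", "C50"]   # lung/bone/brain/liver primaries deliberately
    prostate: ["185", "C61"] # absent per the exception for common RCC
    colorectal: ["153", "154", "C18", "C19", "C20"]   # metastatic sites
    bladder: ["188", "C67"]
    pancreas: ["157", "C25"]
  nephrectomy_procedures:    # SYNTHETIC DEFAULTS
    ["50220", "50225", "50230", "50240", "55.4", "55.5", "0TT0", "0TT1"]

tcc_agents:                  # receipt of any of these flags urothelial ca.
  ["gemcitabine", "cisplatin", "carboplatin", "methotrexate", "vinblastine"]

adverse_events:              # SYNTHETIC DEFAULT code sets; chronic flags
  - {name: nausea_vomiting,      codes: ["787.0", "R11"],          chronic: false}
  - {name: hypertension,         codes: ["401", "I10"],            chronic: true}
  - {name: diarrhea,             codes: ["787.91", "R19.7"],       chronic: false}
  - {name: fatigue_asthenia,     codes: ["780.7", "R53"],          chronic: false}
  - {name: anemia,               codes: ["285", "D64"],            chronic: false}
  - {name: renal_insufficiency,  codes: ["584", "586", "N17", "N19"], chronic: true}
  - {name: thyroid_disorders,    codes: ["244", "E03"],            chronic: true}
  - {name: hypotension,          codes: ["458", "I95"],            chronic: true}
  - {name: hepatitis,            codes: ["573.3", "K75"],          chronic: true}
  - {name: adrenal_insufficiency, codes: ["255.4", "E27.1"],       chronic: true}
  - {name: myasthenia_gravis,    codes: ["358.0", "G70.0"],        chronic: true}
  - {name: rash,                 codes: ["782.1", "R21"],          chronic: false}
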