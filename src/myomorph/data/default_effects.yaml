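# Default effect model for the synthetic tenotomy cohort (version 1).
#
# Values are literature-inspired generator choices, NOT measured ground truth:
# they are set so the simulated cohort reproduces the qualitative
# structure of the study system (sex-specific atrophy routes: male mass
# loss via type 2b fiber CSA, female via fiber number, fiber length the
# dominant factor in both sexes, larger male deficit at week 8).
# All effect factors are dimensionless tenotomy-to-sham ratios.

density_g_cm3: 1.056
fl_to_ml_ratio: 0.6
noise_cv: 0.05

area_fractions:
  "1": 0.02
  "2a": 0.28
  "2x": 0.30
  "2b": 0.40

baselines:
  M:
    body_mass_g: 32.0
    fiber_number: 2800
    csa_um2: {"1": 900.0, "2a": 1100.0, "2x": 1800.0, "2b": 2600.0}
    muscle_length_cm: 1.2
    ta_mass_mg: 50.0
    is_to_ss_ratio: 1.2
    specific_tension_n_cm2: 22.0
  F:
    body_mass_g: 25.0
    fiber_number: 2600
    csa_um2: {"1": 720.0, "2a": 880.0, "2x": 1440.0, "2b": 2080.0}
    muscle_length_cm: 1.1
    ta_mass_mg: 40.0
    is_to_ss_ratio: 1.2
    specific_tension_n_cm2: 22.0

# effect factors per (sex, timepoint), applied to tenotomized animals only
effects:
  M:
    W1: {fn_ratio: 0.97, fl_ratio: 0.88, tension_ratio: 0.80,
         csa_ratio: {"1": 1.0, "2a": 1.0, "2x": 1.0, "2b": 0.90}}
    W2: {fn_ratio: 0.93, fl_ratio: 0.80, tension_ratio: 0.75,
         csa_ratio: {"1": 1.0, "2a": 1.0, "2x": 1.0, "2b": 0.75}}
    W8: {fn_ratio: 0.90, fl_ratio: 0.72, tension_ratio: 0.75,
         csa_ratio: {"1": 1.0, "2a": 1.05, "2x": 1.0, "2b": 0.6225}}
  F:
    W1: {fn_ratio: 0.93, fl_ratio: 0.85, tension_ratio: 0.80,
         csa_ratio: {"1": 1.0, "2a": 1.0, "2x": 1.0, "2b": 1.0}}
    W2: {fn_ratio: 0.85, fl_ratio: 0.70, tension_ratio: 0.75,
         csa_ratio: {"1": 1.0, "2a": 1.0, "2x": 1.0, "2b": 1.0}}
    W8: {fn_ratio: 0.82, fl_ratio: 0.72, tension_ratio: 0.75,
         csa_ratio: {"1": 1.0, "2a": 1.0, "2x": 1.0, "2b": 1.0}}
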