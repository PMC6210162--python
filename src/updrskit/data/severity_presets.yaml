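# Severity presets: per-task, per-class uniform ranges for MotionParams.
# Classes: HC (healthy controls) and UPDRS 0-3.  Class means follow the
# clinical ordering: amplitude and frequency decrease, cycle-to-cycle
# variability, amplitude decrement and hesitation rate increase with
# worsening class.  HC is drawn like class 0 with tighter variance.
# Units: mm (FT/OC apertures), degrees (PS rotation), Hz, seconds.

# FT_SEPARATED: a validation variant with non-overlapping class ranges and a
# healthy-control class distinctly better than UPDRS 0.  Used to check the
# classifier chain on a problem where the classes are separable by
# construction; the clinical ladder above (HC ~ class 0) is what cohort-level
# properties are evaluated on.
FT_SEPARATED:
  HC:
    base_amplitude: [68.0, 74.0]
    base_frequency: [3.4, 3.6]
    amplitude_cv: [0.02, 0.04]
    period_cv: [0.02, 0.04]
    decrement_rate: [0.0, 0.002]
    hesitation_prob: [0.0, 0.0]
    hesitation_duration: [0.15, 0.3]
    baseline: [10.0, 12.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "0":
    base_amplitude: [55.0, 61.0]
    base_frequency: [2.9, 3.1]
    amplitude_cv: [0.05, 0.07]
    period_cv: [0.05, 0.07]
    decrement_rate: [0.002, 0.006]
    hesitation_prob: [0.0, 0.02]
    hesitation_duration: [0.15, 0.3]
    baseline: [10.0, 12.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "1":
    base_amplitude: [42.0, 48.0]
    base_frequency: [2.4, 2.6]
    amplitude_cv: [0.10, 0.13]
    period_cv: [0.09, 0.11]
    decrement_rate: [0.008, 0.014]
    hesitation_prob: [0.04, 0.07]
    hesitation_duration: [0.15, 0.35]
    baseline: [10.0, 12.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "2":
    base_amplitude: [28.0, 34.0]
    base_frequency: [1.9, 2.1]
    amplitude_cv: [0.17, 0.21]
    period_cv: [0.13, 0.16]
    decrement_rate: [0.025, 0.035]
    hesitation_prob: [0.09, 0.13]
    hesitation_duration: [0.2, 0.4]
    baseline: [10.0, 12.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "3":
    base_amplitude: [16.0, 22.0]
    base_frequency: [1.4, 1.6]
    amplitude_cv: [0.27, 0.32]
    period_cv: [0.19, 0.24]
    decrement_rate: [0.05, 0.065]
    hesitation_prob: [0.16, 0.25]
    hesitation_duration: [0.25, 0.45]
    baseline: [10.0, 12.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]

FT:
  HC:
    base_amplitude: [57.0, 63.0]
    base_frequency: [2.9, 3.1]
    amplitude_cv: [0.03, 0.05]
    period_cv: [0.03, 0.05]
    decrement_rate: [0.0, 0.003]
    hesitation_prob: [0.0, 0.01]
    hesitation_duration: [0.15, 0.3]
    baseline: [8.0, 14.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "0":
    base_amplitude: [55.0, 65.0]
    base_frequency: [2.8, 3.2]
    amplitude_cv: [0.04, 0.07]
    period_cv: [0.04, 0.07]
    decrement_rate: [0.0, 0.006]
    hesitation_prob: [0.0, 0.03]
    hesitation_duration: [0.15, 0.3]
    baseline: [8.0, 14.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "1":
    base_amplitude: [40.0, 50.0]
    base_frequency: [2.3, 2.7]
    amplitude_cv: [0.09, 0.15]
    period_cv: [0.08, 0.12]
    decrement_rate: [0.006, 0.016]
    hesitation_prob: [0.03, 0.08]
    hesitation_duration: [0.15, 0.35]
    baseline: [8.0, 14.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "2":
    base_amplitude: [25.0, 35.0]
    base_frequency: [1.8, 2.2]
    amplitude_cv: [0.16, 0.24]
    period_cv: [0.12, 0.18]
    decrement_rate: [0.02, 0.04]
    hesitation_prob: [0.08, 0.15]
    hesitation_duration: [0.2, 0.4]
    baseline: [8.0, 14.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "3":
    base_amplitude: [15.0, 25.0]
    base_frequency: [1.3, 1.7]
    amplitude_cv: [0.25, 0.35]
    period_cv: [0.18, 0.26]
    decrement_rate: [0.05, 0.07]
    hesitation_prob: [0.15, 0.3]
    hesitation_duration: [0.25, 0.45]
    baseline: [8.0, 14.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]

OC:
  HC:
    base_amplitude: [85.0, 95.0]
    base_frequency: [1.9, 2.1]
    amplitude_cv: [0.03, 0.05]
    period_cv: [0.03, 0.05]
    decrement_rate: [0.0, 0.003]
    hesitation_prob: [0.0, 0.01]
    hesitation_duration: [0.15, 0.3]
    baseline: [25.0, 35.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "0":
    base_amplitude: [82.0, 98.0]
    base_frequency: [1.8, 2.2]
    amplitude_cv: [0.04, 0.07]
    period_cv: [0.04, 0.07]
    decrement_rate: [0.0, 0.006]
    hesitation_prob: [0.0, 0.03]
    hesitation_duration: [0.15, 0.3]
    baseline: [25.0, 35.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "1":
    base_amplitude: [62.0, 76.0]
    base_frequency: [1.5, 1.8]
    amplitude_cv: [0.09, 0.15]
    period_cv: [0.08, 0.12]
    decrement_rate: [0.006, 0.016]
    hesitation_prob: [0.03, 0.08]
    hesitation_duration: [0.15, 0.35]
    baseline: [25.0, 35.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "2":
    base_amplitude: [44.0, 56.0]
    base_frequency: [1.25, 1.5]
    amplitude_cv: [0.16, 0.24]
    period_cv: [0.12, 0.18]
    decrement_rate: [0.02, 0.04]
    hesitation_prob: [0.08, 0.15]
    hesitation_duration: [0.2, 0.4]
    baseline: [25.0, 35.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "3":
    base_amplitude: [30.0, 40.0]
    base_frequency: [0.95, 1.2]
    amplitude_cv: [0.25, 0.35]
    period_cv: [0.18, 0.26]
    decrement_rate: [0.05, 0.07]
    hesitation_prob: [0.15, 0.3]
    hesitation_duration: [0.25, 0.45]
    baseline: [25.0, 35.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]

PS:
  HC:
    base_amplitude: [155.0, 165.0]
    base_frequency: [1.5, 1.7]
    amplitude_cv: [0.03, 0.05]
    period_cv: [0.03, 0.05]
    decrement_rate: [0.0, 0.003]
    hesitation_prob: [0.0, 0.01]
    hesitation_duration: [0.15, 0.3]
    baseline: [0.0, 0.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "0":
    base_amplitude: [150.0, 170.0]
    base_frequency: [1.45, 1.75]
    amplitude_cv: [0.04, 0.07]
    period_cv: [0.04, 0.07]
    decrement_rate: [0.0, 0.006]
    hesitation_prob: [0.0, 0.03]
    hesitation_duration: [0.15, 0.3]
    baseline: [0.0, 0.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "1":
    base_amplitude: [120.0, 140.0]
    base_frequency: [1.2, 1.45]
    amplitude_cv: [0.09, 0.15]
    period_cv: [0.08, 0.12]
    decrement_rate: [0.006, 0.016]
    hesitation_prob: [0.03, 0.08]
    hesitation_duration: [0.15, 0.35]
    baseline: [0.0, 0.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "2":
    base_amplitude: [90.0, 110.0]
    base_frequency: [0.95, 1.2]
    amplitude_cv: [0.16, 0.24]
    period_cv: [0.12, 0.18]
    decrement_rate: [0.02, 0.04]
    hesitation_prob: [0.08, 0.15]
    hesitation_duration: [0.2, 0.4]
    baseline: [0.0, 0.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
  "3":
    base_amplitude: [60.0, 80.0]
    base_frequency: [0.7, 0.95]
    amplitude_cv: [0.25, 0.35]
    period_cv: [0.18, 0.26]
    decrement_rate: [0.05, 0.07]
    hesitation_prob: [0.15, 0.3]
    hesitation_duration: [0.25, 0.45]
    baseline: [0.0, 0.0]
    noise_sd: [0.8, 1.2]
    sample_rate: [60.0, 60.0]
    n_cycles: [12, 18]
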