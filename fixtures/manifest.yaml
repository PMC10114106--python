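cox:
  baseline_hazard: 0.08
  categorical_levels: 3
  censor_horizon: 10.0
  covariate_effects:
    age: 0.1
    sex: 0.2
  effects:
    exp01: 0.5
    exp02: 0.5
  family: cox
  interaction_effects: {}
  intercept: 0.0
  missing_rate: 0.02
  n: 250
  n_categorical: 2
  n_continuous: 4
  noise_sd: 1.0
  rho: 0.2
  seed: 103
  unwanted_rate: 0.02
lm:
  baseline_hazard: 0.05
  categorical_levels: 3
  censor_horizon: 10.0
  covariate_effects:
    age: 0.1
    sex: 0.2
  effects:
    cat01: 0.3
    exp01: 0.4
    exp02: 0.4
  family: lm
  interaction_effects: {}
  intercept: 0.0
  missing_rate: 0.02
  n: 250
  n_categorical: 2
  n_continuous: 4
  noise_sd: 1.0
  rho: 0.2
  seed: 101
  unwanted_rate: 0.02
lm_interactions:
  baseline_hazard: 0.05
  categorical_levels: 3
  censor_horizon: 10.0
  covariate_effects:
    age: 0.1
    sex: 0.2
  effects:
    exp01: 0.5
    exp02: 0.5
  family: lm
  interaction_effects:
    exp01 * exp02: 0.5
  intercept: 0.0
  missing_rate: 0.02
  n: 250
  n_categorical: 0
  n_continuous: 4
  noise_sd: 1.0
  rho: 0.2
  seed: 104
  unwanted_rate: 0.02
logistic:
  baseline_hazard: 0.05
  categorical_levels: 3
  censor_horizon: 10.0
  covariate_effects:
    age: 0.1
    sex: 0.2
  effects:
    cat01: 0.4
    exp01: 0.5
    exp02: 0.5
  family: logistic
  interaction_effects: {}
  intercept: -1.0
  missing_rate: 0.02
  n: 250
  n_categorical: 2
  n_continuous: 4
  noise_sd: 1.0
  rho: 0.2
  seed: 102
  unwanted_rate: 0.02
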