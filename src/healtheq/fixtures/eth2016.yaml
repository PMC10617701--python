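n_strata: 6
clusters_per_stratum: 25
households_per_cluster: 30
sigma_cluster: 0.45
sigma_household: 0.9
stratum_ses_means:
- -0.9
- -0.5
- -0.1
- 0.1
- 0.5
- 1.1
selection_probs:
- 0.01
- 0.006
- 0.012
- 0.005
- 0.008
- 0.015
asset_loadings:
- 0.8
- 1.0
- 1.2
- 1.5
- 1.8
- 2.0
asset_offsets:
- 1.5
- 0.6
- 0.0
- -0.6
- -1.2
- -1.8
covariate_models:
  sex:
    kind: bernoulli
    levels:
    - women
    - men
    intercept: -0.3
    ses_slope: 0.0
  residence:
    kind: bernoulli
    levels:
    - rural
    - urban
    intercept: -2.2
    ses_slope: 1.4
  education:
    kind: ordered
    levels:
    - no_education
    - primary
    - secondary
    - higher
    thresholds:
    - 0.2
    - 1.9
    - 3.0
    ses_slope: 1.2
  newspaper:
    kind: bernoulli
    levels:
    - 'no'
    - 'yes'
    intercept: -1.9
    ses_slope: 0.8
  radio:
    kind: bernoulli
    levels:
    - 'no'
    - 'yes'
    intercept: -0.5
    ses_slope: 0.7
  television:
    kind: bernoulli
    levels:
    - 'no'
    - 'yes'
    intercept: -1.0
    ses_slope: 1.5
  ever_tested:
    kind: bernoulli
    levels:
    - 'no'
    - 'yes'
    intercept: -0.3
    ses_slope: 0.5
outcome_coefficients:
  intercept: -1.97
  sex=men: 0.6354
  residence=urban: 0.0489
  education=primary: 0.5376
  education=secondary: 0.8309
  education=higher: 1.1241
  newspaper=yes: 0.1271
  radio=yes: -0.0391
  television=yes: 0.3519
  ever_tested=yes: 0.2737
  wealth=poorer: 0.0489
  wealth=middle: 0.0391
  wealth=richer: 0.0684
  wealth=richest: 0.2933
heard_model:
  intercept: 2.8
  ses_slope: 0.6
seed: 0
label: eth2016-like
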