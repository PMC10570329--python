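seed: 20230901
n_pre: 1074
n_post: 2126
n_menopause_missing: 2
n_all_missing_outcomes: 29
covariates:
  age:
    family: truncnorm
    pre:
      loc: 46.7
      scale: 5.41
      lower: 35.0
      upper: 62.0
    post:
      loc: 59.5
      scale: 7.12
      lower: 40.0
      upper: 74.0
  bmi:
    family: truncnorm
    pre:
      loc: 25.91
      scale: 5.8
      lower: 15.0
      upper: 60.0
    post:
      loc: 26.7
      scale: 5.85
      lower: 15.0
      upper: 60.0
  alcohol:
    family: lognormal
    pre:
      median: 4.0
      sigma_log: 0.8
      upper: 60.0
    post:
      median: 3.0
      sigma_log: 0.8
      upper: 60.0
  exercise:
    family: lognormal
    pre:
      median: 6.0
      sigma_log: 0.7
      upper: 90.0
    post:
      median: 5.0
      sigma_log: 0.7
      upper: 90.0
  meat:
    family: lognormal
    pre:
      median: 4.0
      sigma_log: 0.5
      upper: 30.0
    post:
      median: 4.0
      sigma_log: 0.5
      upper: 30.0
  dietary_supp_iron:
    family: lognormal
    pre:
      median: 18.7
      sigma_log: 0.7
      upper: 150.0
    post:
      median: 24.6
      sigma_log: 0.64
      upper: 150.0
  dietary_supp_calcium:
    family: lognormal
    pre:
      median: 947.7
      sigma_log: 0.67
      upper: 6000.0
    post:
      median: 1472.7
      sigma_log: 0.58
      upper: 6000.0
  years_pregnant_breastfeeding:
    family: lognormal
    pre:
      median: 2.94
      sigma_log: 0.9
      upper: 20.0
    post:
      median: 2.56
      sigma_log: 0.8
      upper: 20.0
  aspirin:
    family: bernoulli
    pre:
      p: 0.166
    post:
      p: 0.358
  statin:
    family: bernoulli
    pre:
      p: 0.134
    post:
      p: 0.311
  blood_donation_12mo:
    family: bernoulli
    pre:
      p: 0.164
    post:
      p: 0.127
  ida_ever:
    family: bernoulli
    pre:
      p: 0.1
    post:
      p: 0.08
  polyps_ever:
    family: bernoulli
    pre:
      p: 0.079
    post:
      p: 0.232
  ibd_ever:
    family: bernoulli
    pre:
      p: 0.01
    post:
      p: 0.016
  pcos_ever:
    family: bernoulli
    pre:
      p: 0.029
    post:
      p: 0.024
  preeclampsia_ever:
    family: bernoulli
    pre:
      p: 0.074
    post:
      p: 0.052
  ep_use_years:
    family: lognormal
    post_only: true
    post:
      median: 1.5
      sigma_log: 1.0
      upper: 35.0
  reproductive_lifespan:
    family: derived
    post_only: true
  years_since_lmp:
    family: derived
    post_only: true
menopause_link:
  age_menopause_mean: 50.5
  age_menopause_sd: 4.0
  age_menopause_lower: 30.0
  age_menopause_upper: 58.0
  min_years_since: 0.5
  menarche_mean: 13.0
  menarche_sd: 1.5
  menarche_lower: 9.0
  menarche_upper: 18.0
outcome_medians:
  ferritin:
    pre: 40.0
    post: 80.0
  serum_iron:
    pre: 92.0
    post: 93.0
  transferrin_saturation:
    pre: 28.0
    post: 29.0
betas:
  ferritin:
    pre:
      age: 0.014
      aspirin: 0.098
      statin: 0.14
      blood_donation_12mo: -0.7
      ida_ever: -0.347
      polyps_ever: 0.016
      ibd_ever: 0.592
      pcos_ever: 0.112
      preeclampsia_ever: 0.388
      alcohol: 0.008
      bmi: 0.008
      exercise: 0.003
      years_pregnant_breastfeeding: -0.009
      dietary_supp_calcium: -0.003
      dietary_supp_iron: 0.002
      meat: 0.016
    post:
      age: 0.013
      aspirin: 0.056
      statin: 0.024
      blood_donation_12mo: -1.121
      ida_ever: -0.234
      polyps_ever: -0.046
      ibd_ever: 0.151
      pcos_ever: -0.056
      preeclampsia_ever: 0.107
      alcohol: 0.006
      bmi: 0.003
      exercise: 0.0
      ep_use_years: -0.005
      reproductive_lifespan: -0.003
      years_pregnant_breastfeeding: -0.001
      years_since_lmp: 0.001
      dietary_supp_calcium: -0.014
      dietary_supp_iron: 0.001
      meat: 0.018
  serum_iron:
    pre:
      age: -0.005
      aspirin: 0.018
      statin: -0.008
      blood_donation_12mo: -0.253
      ida_ever: -0.175
      polyps_ever: -0.069
      ibd_ever: 0.038
      pcos_ever: -0.207
      preeclampsia_ever: 0.018
      alcohol: 0.006
      bmi: -0.03
      exercise: 0.007
      years_pregnant_breastfeeding: 0.001
      dietary_supp_calcium: 0.007
      dietary_supp_iron: 0.0
      meat: 0.004
    post:
      age: 0.003
      aspirin: 0.125
      statin: -0.081
      blood_donation_12mo: -0.167
      ida_ever: -0.101
      polyps_ever: -0.067
      ibd_ever: 0.26
      pcos_ever: -0.024
      preeclampsia_ever: -0.015
      alcohol: 0.004
      bmi: -0.033
      exercise: 0.004
      ep_use_years: 0.007
      reproductive_lifespan: 0.002
      years_pregnant_breastfeeding: 0.001
      years_since_lmp: -0.007
      dietary_supp_calcium: 0.003
      dietary_supp_iron: -0.002
      meat: 0.006
  transferrin_saturation:
    pre:
      age: -0.002
      aspirin: 0.019
      statin: -0.042
      blood_donation_12mo: -0.394
      ida_ever: -0.214
      polyps_ever: 0.01
      ibd_ever: 0.124
      pcos_ever: -0.181
      preeclampsia_ever: 0.089
      alcohol: 0.004
      bmi: -0.033
      exercise: 0.005
      years_pregnant_breastfeeding: -0.004
      dietary_supp_calcium: 0.004
      dietary_supp_iron: 0.001
      meat: 0.003
    post:
      age: 0.01
      aspirin: 0.134
      statin: -0.119
      blood_donation_12mo: -0.406
      ida_ever: -0.105
      polyps_ever: -0.067
      ibd_ever: 0.24
      pcos_ever: -0.133
      preeclampsia_ever: -0.003
      alcohol: 0.002
      bmi: -0.037
      exercise: 0.003
      ep_use_years: 0.004
      reproductive_lifespan: 0.0
      years_pregnant_breastfeeding: -0.002
      years_since_lmp: -0.008
      dietary_supp_calcium: -0.004
      dietary_supp_iron: -0.001
      meat: 0.01
sigma:
  ferritin:
    pre: 0.7740166809597184
    post: 0.8182226617311575
  serum_iron:
    pre: 0.6
    post: 0.6
  transferrin_saturation:
    pre: 0.6
    post: 0.6
residual_corr:
  iron_ts: 0.9347867285329602
  ferritin_iron: 0.26329205841130365
  ferritin_ts: 0.36640671795665886
missingness:
  dependence:
    age: 0.35
    bmi: 0.35
  rate_caps:
    pre: 0.08
    post: 0.14
  predictor_rates:
    bmi:
      pre: 0.0005439715151852601
      post: 0.0006899971172532715
    alcohol:
      pre: 0.034814176971856646
      post: 0.044159815504209374
    exercise:
      pre: 0.005439715151852601
      post: 0.006899971172532714
    meat:
      pre: 0.012511344849260982
      post: 0.015869933696825243
    dietary_supp_iron:
      pre: 0.012511344849260982
      post: 0.015869933696825243
    dietary_supp_calcium:
      pre: 0.012511344849260982
      post: 0.015869933696825243
    years_pregnant_breastfeeding:
      pre: 0.0032638290911115608
      post: 0.004139982703519628
    aspirin:
      pre: 0.011423401818890462
      post: 0.014489939462318701
    statin:
      pre: 0.010879430303705202
      post: 0.013799942345065428
    blood_donation_12mo:
      pre: 0.0010879430303705202
      post: 0.001379994234506543
    ida_ever:
      pre: 0.010879430303705202
      post: 0.013799942345065428
    polyps_ever:
      pre: 0.04351772121482081
      post: 0.07796967424961967
    ibd_ever:
      pre: 0.007071629697408381
      post: 0.008969962524292528
    pcos_ever:
      pre: 0.020126946061854622
      post: 0.02552989333837104
    preeclampsia_ever:
      pre: 0.0016319145455557804
      post: 0.002069991351759814
    ep_use_years:
      post: 0.013799942345065428
    reproductive_lifespan:
      post: 0.001379994234506543
    years_since_lmp:
      post: 0.0006899971172532715
  outcome_rates:
    serum_iron: 0.007
    ferritin: 0.006
    uibc: 0.058
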