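variables:
- age_group
- fever
- diarrhoea
- birth_weight
- residence
- wealth
- education
theta1:
- 2.481808847859013
- 0.226
- -0.829
- 0.153
- -0.227
- -1.248
- -0.653
- 1.065
- 1.253
- -1.473
- -1.841
theta2:
- 1.1972953346136994
- 0.531
- 0.096
- -0.712
- -0.496
- 0.038
- 0.102
- 0.224
- 0.282
- -0.772
- -0.519
Sigma:
  sigma11: 0.104
  sigma22: 0.314
  sigma12: 0.18070971196922428
n_clusters: 400
mean_children_per_cluster: 8.0
marginals:
  sex:
    Male: 0.46
    Female: 0.54
  age_group:
    '>39 months': 0.32
    20-39 months: 0.36
    <20 months: 0.32
  fever:
    'Yes': 0.17
    'No': 0.83
  diarrhoea:
    'Yes': 0.13
    'No': 0.87
  birth_weight:
    <2500 g: 0.09
    '>=2500 g': 0.91
  residence:
    Urban: 0.28
    Rural: 0.72
  wealth:
    Richer: 0.37
    Middle: 0.21
    Poorer: 0.42
  education:
    No education: 0.01
    Primary: 0.46
    Post primary: 0.53
weight_lognormal_sigma: 0.3
seed: 0
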