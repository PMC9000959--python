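# Default 24-strain vocabulary: 6 GFP sensors, 12 signal synthesizers,
# 6 attenuator-enzyme strains. Units: nM, hours, fluorescence a.u.
schema_version: 1
strains:
- id: aF_act_GFP
  inputs:
  - alpha_factor
  transfer:
  - activating
  output: GFP
  role: sensor
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 6.0
    n: 1.0
    d2: 0.5
    k3: 40.5
    c0: 9.0
    d3: 0.3
- id: aF_rep_GFP
  inputs:
  - alpha_factor
  transfer:
  - repressing
  output: GFP
  role: sensor
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 89.0
    n: 0.8
    d2: 0.5
    k3: 40.5
    c0: 9.0
    d3: 0.3
- id: IAA_act_GFP
  inputs:
  - auxin
  transfer:
  - activating
  output: GFP
  role: sensor
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 964.8
    n: 0.8
    d2: 0.5
    k3: 30.0
    c0: 30.0
    d3: 0.3
- id: IAA_rep_GFP
  inputs:
  - auxin
  transfer:
  - repressing
  output: GFP
  role: sensor
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 276.5
    n: 1.0
    d2: 0.5
    k3: 37.5
    c0: 15.0
    d3: 0.3
- id: bE_act_GFP
  inputs:
  - beta_estradiol
  transfer:
  - activating
  output: GFP
  role: sensor
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 12.6
    n: 1.3
    d2: 0.5
    k3: 61.5
    c0: 3.0
    d3: 0.3
- id: bE_rep_GFP
  inputs:
  - beta_estradiol
  transfer:
  - repressing
  output: GFP
  role: sensor
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 0.5
    n: 2.2
    d2: 0.5
    k3: 40.5
    c0: 9.0
    d3: 0.3
- id: aF_act_aF
  inputs:
  - alpha_factor
  transfer:
  - activating
  output: alpha_factor
  role: synthesizer
  feedback: self_positive
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 6.0
    n: 1.0
    d2: 0.5
    k3: 15.0
    c0: 0.5
    d3: 0.3
- id: aF_rep_aF
  inputs:
  - alpha_factor
  transfer:
  - repressing
  output: alpha_factor
  role: synthesizer
  feedback: self_negative
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 89.0
    n: 0.8
    d2: 0.5
    k3: 15.0
    c0: 0.5
    d3: 0.3
- id: IAA_act_aF
  inputs:
  - auxin
  transfer:
  - activating
  output: alpha_factor
  role: synthesizer
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 964.8
    n: 0.8
    d2: 0.5
    k3: 15.0
    c0: 0.5
    d3: 0.3
- id: IAA_rep_aF
  inputs:
  - auxin
  transfer:
  - repressing
  output: alpha_factor
  role: synthesizer
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 276.5
    n: 1.0
    d2: 0.5
    k3: 15.0
    c0: 0.5
    d3: 0.3
- id: bE_act_aF
  inputs:
  - beta_estradiol
  transfer:
  - activating
  output: alpha_factor
  role: synthesizer
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 12.6
    n: 1.3
    d2: 0.5
    k3: 15.0
    c0: 0.5
    d3: 0.3
- id: bE_rep_aF
  inputs:
  - beta_estradiol
  transfer:
  - repressing
  output: alpha_factor
  role: synthesizer
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 0.5
    n: 2.2
    d2: 0.5
    k3: 15.0
    c0: 0.5
    d3: 0.3
- id: aF_act_IAA
  inputs:
  - alpha_factor
  transfer:
  - activating
  output: auxin
  role: synthesizer
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 6.0
    n: 1.0
    d2: 0.5
    k3: 100.0
    c0: 2.0
    d3: 0.3
- id: aF_rep_IAA
  inputs:
  - alpha_factor
  transfer:
  - repressing
  output: auxin
  role: synthesizer
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 89.0
    n: 0.8
    d2: 0.5
    k3: 100.0
    c0: 2.0
    d3: 0.3
- id: IAA_act_IAA
  inputs:
  - auxin
  transfer:
  - activating
  output: auxin
  role: synthesizer
  feedback: self_positive
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 964.8
    n: 0.8
    d2: 0.5
    k3: 100.0
    c0: 2.0
    d3: 0.3
- id: IAA_rep_IAA
  inputs:
  - auxin
  transfer:
  - repressing
  output: auxin
  role: synthesizer
  feedback: self_negative
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 276.5
    n: 1.0
    d2: 0.5
    k3: 100.0
    c0: 2.0
    d3: 0.3
- id: bE_act_IAA
  inputs:
  - beta_estradiol
  transfer:
  - activating
  output: auxin
  role: synthesizer
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 12.6
    n: 1.3
    d2: 0.5
    k3: 100.0
    c0: 2.0
    d3: 0.3
- id: bE_rep_IAA
  inputs:
  - beta_estradiol
  transfer:
  - repressing
  output: auxin
  role: synthesizer
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 0.5
    n: 2.2
    d2: 0.5
    k3: 100.0
    c0: 2.0
    d3: 0.3
- id: aF_act_BAR1
  inputs:
  - alpha_factor
  transfer:
  - activating
  output: BAR1
  role: attenuator
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 6.0
    n: 1.0
    d2: 0.5
    k3: 50.0
    c0: 0.5
    d3: 0.3
- id: aF_act_GH3
  inputs:
  - alpha_factor
  transfer:
  - activating
  output: GH3.3
  role: attenuator
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 6.0
    n: 1.0
    d2: 0.5
    k3: 50.0
    c0: 0.5
    d3: 0.3
- id: aF_rep_BAR1
  inputs:
  - alpha_factor
  transfer:
  - repressing
  output: BAR1
  role: attenuator
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 89.0
    n: 0.8
    d2: 0.5
    k3: 50.0
    c0: 0.5
    d3: 0.3
- id: IAA_act_BAR1
  inputs:
  - auxin
  transfer:
  - activating
  output: BAR1
  role: attenuator
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 964.8
    n: 0.8
    d2: 0.5
    k3: 50.0
    c0: 0.5
    d3: 0.3
- id: IAA_act_GH3
  inputs:
  - auxin
  transfer:
  - activating
  output: GH3.3
  role: attenuator
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 964.8
    n: 0.8
    d2: 0.5
    k3: 50.0
    c0: 0.5
    d3: 0.3
- id: IAA_rep_GH3
  inputs:
  - auxin
  transfer:
  - repressing
  output: GH3.3
  role: attenuator
  feedback: none
  params:
    model: model1
    d1: 1.0
    V: 1.0
    K: 276.5
    n: 1.0
    d2: 0.5
    k3: 50.0
    c0: 0.5
    d3: 0.3
enumeration_pool:
- IAA_act_BAR1
- IAA_act_GH3
- IAA_act_IAA
- IAA_act_aF
- IAA_rep_GH3
- IAA_rep_aF
- aF_act_BAR1
- aF_act_GH3
- aF_act_IAA
- aF_act_aF
- aF_rep_BAR1
- aF_rep_IAA
- bE_act_IAA
- bE_act_aF
- bE_rep_IAA
- bE_rep_aF
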