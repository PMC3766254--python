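# Extreme protective case: strong education, income and social support
# against a low level of addiction and family breakdown.
label: "Case 2: least likely to result in homelessness"
activations:
  Addiction: 0.30
  Social Support Network: 0.61
  Education: 1.0
  Family Breakdown: 0.30
  Income: 0.72
settings:
  threshold: tanh
  self_memory: 1
  epsilon: 1.0e-5
  max_iter: 100
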