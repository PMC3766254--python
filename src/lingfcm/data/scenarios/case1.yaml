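# Extreme case expected to drive the outcome concept high: co-occurring
# addiction, family breakdown and mental illness with a government response.
label: "Case 1: most likely to result in homelessness"
activations:
  Addiction: 0.65
  Family Breakdown: 0.57
  Government Assistance: 0.46
  Mental Illness: 0.61
settings:
  threshold: tanh
  self_memory: 1
  epsilon: 1.0e-5
  max_iter: 100
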