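# Middle case: protective education/income against moderate family breakdown,
# low addiction and weak social support; outcome uncertain.
label: "Case 3: uncertain outcome of homelessness"
activations:
  Addiction: 0.20
  Social Support Network: 0.11
  Education: 0.94
  Family Breakdown: 0.51
  Income: 1.0
settings:
  threshold: tanh
  self_memory: 1
  epsilon: 1.0e-5
  max_iter: 100
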