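# Large two-sample case/control polygenic score study:
# training 3322 cases / 3587 controls, replication 2687 / 2656,
# 74,062 independent markers, disease prevalence 1%,
# markers with training P < 0.5 included in the score.
model:
  m: 74062
  vg1: 0.287
design:
  n1: 6909
  n2: 5343
  q1: 0.5
trait1:
  kind: binary
  K: 0.01
  P: 0.4808
trait2:
  kind: binary
  K: 0.01
  P: 0.5029
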