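# Tiny synthetic study driving the full pipeline in seconds.
# Usage: glycosite simulate --config examples/smoke.yaml --out smoke/
n_proteins: 40
length_range: [60, 200]
glyco_type: N
positive_rate: 0.2
seed: 7
signal:
  - [-3, P, 0.5]
  - [-1, G, 0.5]
  - [3, A, 0.5]
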