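# Desk-scale tagger configuration (CPU-friendly).
# The full-size defaults are cd=30 / 3 char heads / cd_ff=60,
# d_model=256 with 8 heads, 2 encoder layers, peak_lr=0.0008, 100 epochs.
char:
  cd: 12
  heads: 3
  cd_ff: 24
  layers: 1
wd: 16
d_model: 32
heads: 4
layers: 1
epochs: 15
peak_lr: 0.02
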