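in_channels: 6
num_classes: 2
npoints: 512
stem_width: 8
stage_widths: [18, 40, 50, 112]
decoder_widths: [64, 44, 20, 16]
head_width: 24
fps_rate: 0.5
local_k: 16
ball_radius: 0.15
eafp_k: 16
ablation:
  rsa: true
  cam_se: true
  eafp: true
  resmlp: true
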