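in_channels: 6
num_classes: 2
npoints: 2048
stem_width: 32
stage_widths: [72, 160, 200, 448]
decoder_widths: [256, 176, 80, 64]
head_width: 96
fps_rate: 0.5
local_k: 24
ball_radius: 0.1
eafp_k: 16
ablation:
  rsa: true
  cam_se: true
  eafp: true
  resmlp: true
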