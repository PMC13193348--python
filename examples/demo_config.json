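{
  "seed": 1,
  "out_dir": "results/demo",
  "image_shape": [192, 192],
  "n_cisternae": 6,
  "conditions": [
    {"name": "sac_like", "substructure": "sac", "n_images": 8},
    {"name": "nanohole_like", "substructure": "sac_nanoholes", "n_images": 8}
  ]
}
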