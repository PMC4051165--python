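{
  "hidden_weights": [
    [0.8523, 0.7190, 0.0156, 0.3914],
    [-0.4030, -0.3190, 0.7133, 0.2558],
    [-0.03238, -0.7238, -0.2314, -0.0992]
  ],
  "hidden_biases": [-0.0528, 0.8994, -0.8330],
  "output_weights": [-0.0877, -0.0166, -1.1731],
  "output_bias": -0.0336,
  "activation": "logistic"
}
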