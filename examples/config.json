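{
  "encoder": "ONEHOT2",
  "folds": 5,
  "seed": 0,
  "vote_threshold": 3,
  "validation_fraction": 0.2,
  "grids": {
    "RF": {"n_estimators": [100, 300]},
    "SGD": {"alpha": [1e-05, 0.0001, 0.001]}
  }
}
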