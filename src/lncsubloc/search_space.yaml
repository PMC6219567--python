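# Default random-search space for `lncsubloc search`.
# Fields mirror ModelConfig; the search minimizes validation misclassification.
hidden_sizes:
  - [128, 128, 64]
  - [256, 128, 64]
  - [64, 64, 32]
hidden_dropout: [0.3, 0.5]
input_dropout: [0.0, 0.1, 0.2]
l1: [0.0, 1.0e-6, 1.0e-5]
l2: [0.0, 1.0e-4, 1.0e-3]
learning_rate: [0.01, 0.03, 0.05, 0.1]
batch_size: [32, 64, 128]
epochs: [20, 30]
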