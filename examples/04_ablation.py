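"""Module ablation: what do the graph features actually contribute?

Simulates a dataset in which the two classes have identical mean responses
and differ only in covariance structure, then compares the full model
against the variant with graph features zeroed out.  The raw signals still
contain the class information in principle, but the explicit connectivity
features make it far easier to exploit.  Takes a few minutes on one core.
"""

import numpy as np

import topofnirs as tf
from topofnirs.ablation import module_ablation
from topofnirs.train import prepare_inputs

cfg = tf.two_class_block_config(n_pairs=8, n_subjects=1,
                                n_trials_per_class=8, seed=11)
assert np.array_equal(cfg.task_amplitude[0], cfg.task_amplitude[1]), \
    "classes share the mean response; only covariance differs"
ds = tf.simulate_dataset(cfg)
pre = tf.PreprocessConfig(filter_kind="lowpass", band=(0.0, 2.0))
ep = tf.concatenate_epoch_sets(
    [tf.preprocess_recording(r, pre) for r in ds.recordings]
)
inputs = prepare_inputs(ep)

model_cfg = tf.ModelConfig(d_model=16, n_heads=2, ffn_dim=32,
                           lstm_hidden=16, mlp_hidden=32)
train_cfg = tf.TrainConfig(max_epochs=40, seed=0)

table = module_ablation(
    inputs, model_cfg, train_cfg,
    variants=("full", "no_graph_features", "no_GAM", "no_BiLSTM"),
    seeds=(0, 1, 2),
)
means = table.groupby("variant")["accuracy"].agg(["mean", "std"])
print(means.round(2).to_string())
gap = means.loc["full", "mean"] - means.loc["no_graph_features", "mean"]
print(f"\ngraph features are worth {gap:.1f} accuracy points here: "
      "with covariance-only class structure, the explicit connectivity "
      "features carry most of the decodable signal.")
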