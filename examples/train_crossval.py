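"""Cross-validate the full CNN/attention/BiLSTM model on synthetic data.

Generates a small alpha-signature dataset, extracts DE features and runs
5-fold cross-validation of the full model on the valence task.  Expect a
mean accuracy well above 0.9: the synthetic classes are strongly
separated in alpha power, so this is a functional sanity check of the
whole pipeline rather than an estimate of real-EEG performance.
"""

from musemo.evaluate import TrainConfig, cross_validate
from musemo.features import build_feature_matrix
from musemo.model import model_spec_for_input
from musemo.preprocess import preprocess_dataset
from musemo.synth import make_dataset, small_scale_spec

spec = small_scale_spec(seed=3, n_trials_per_class=6)
recordings, ratings = make_dataset(spec)
matrix = build_feature_matrix(preprocess_dataset(recordings, ratings))

cfg = TrainConfig(epochs=15, batch_size=32, seed=3, task="valence")
model_spec = model_spec_for_input(matrix.values.shape[1], variant="CSBN")
folds, agg = cross_validate(model_spec, matrix.values,
                            matrix.row_meta["valence"].to_numpy(), cfg, k=5)

print("Per-fold accuracy:",
      [round(f.metrics.accuracy, 3) for f in folds])
print(f"Mean accuracy: {agg['mean'].accuracy:.3f}  "
      f"(max over folds {agg['max'].accuracy:.3f})")
print(f"Mean precision/F1/AUC: {agg['mean'].precision:.3f} / "
      f"{agg['mean'].f1:.3f} / {agg['mean'].auc:.3f}")
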