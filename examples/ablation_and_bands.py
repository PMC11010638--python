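"""Run reduced ablation and single-band experiment suites.

The ablation suite compares the four model variants (CNN only, BiLSTM
only, CNN-BiLSTM, and the full model with attention) under k-fold
cross-validation on both tasks.  The band suite restricts the feature
matrix to single rhythms; because only alpha power carries class
information in the generator, the alpha row should clearly dominate —
the same qualitative pattern the full-scale experiments probe on real
music-evoked EEG.

(Reduced here to 3 folds / 10 epochs so the script runs in ~1 minute;
the test suite runs the full 10-fold versions.)
"""

from musemo.evaluate import TrainConfig, run_ablation_suite, run_band_suite
from musemo.features import build_feature_matrix
from musemo.preprocess import preprocess_dataset
from musemo.synth import make_dataset, small_scale_spec

spec = small_scale_spec(seed=0, n_trials_per_class=6)
recordings, ratings = make_dataset(spec)
matrix = build_feature_matrix(preprocess_dataset(recordings, ratings))

cfg = TrainConfig(epochs=10, batch_size=32, seed=0)
print("Ablation (3-fold mean accuracy):")
table = run_ablation_suite(matrix, cfg, k=3)
print(table[["variant", "task", "mean_accuracy"]].round(3).to_string(index=False))

print("\nSingle-band suite (valence, 3-fold mean accuracy):")
bands = run_band_suite(matrix, cfg, k=3,
                       subsets=[("theta",), ("alpha",), ("beta",), ("gamma",)],
                       tasks=("valence",))
print(bands[["bands", "mean_accuracy"]].round(3).to_string(index=False))
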