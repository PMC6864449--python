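"""Stratified 5-fold cross-validation and a dropout-rate sweep, using the
fast decision-tree model so the example completes in seconds.

Swap model="dt" for "rnn" (and raise epochs) for the full protocol.
"""

from pathlib import Path

from pcglearn import ClassLabel, SynthConfig, TrainConfig, generate_dataset
from pcglearn.pipeline import PipelineConfig, run_cv, sweep_dropout

out = Path("example_output/cv_demo")
synth = SynthConfig(
    duration_range_s=(3.0, 8.0),
    n_per_class={lab: 15 for lab in ClassLabel},
    seed=2,
)
manifest = generate_dataset(synth, out / "data")

cfg = PipelineConfig(
    model="dt",
    train=TrainConfig(epochs=5, batch_size=16, seed=2),
    cv_folds=5,
    seed=2,
)

print("5-fold cross-validation (decision tree):")
report = run_cv(cfg, manifest, out_dir=out)
for i, fold in enumerate(report.per_fold):
    print(f"  fold {i + 1}: accuracy {fold.accuracy_pct:5.1f}%  (n={fold.n})")
print(f"  size-weighted accuracy {report.weighted_accuracy_pct:.2f}%")

print("\ndropout sweep protocol (three rates, mlp6 model):")
cfg_mlp = PipelineConfig(
    model="mlp6",
    train=TrainConfig(epochs=10, batch_size=16, seed=2),
    seed=2,
)
table = sweep_dropout(cfg_mlp, manifest, (0.05, 0.20, 0.35), out_dir=out)
print(table.to_string(index=False))
# Each row is one full train/evaluate cycle at that dropout rate; the
# feature cache under example_output/cv_demo is shared between the runs.
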