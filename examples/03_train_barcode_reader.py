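"""Train the machine-learning barcode reader on simulated fingerprints.

Simulates ten barcode classes, extracts fingerprints, compares classifier
families under stratified cross-validation, tunes the best one and reports
held-out accuracy with the confusion-matrix metrics.
"""

from nanobarcode import (
    LocalizeParams,
    build_feature_table,
    compare_models,
    evaluate,
    generate_dataset,
    stratified_split,
    tune_top,
)
from nanobarcode.scheme import barcode_from_id

codes = [barcode_from_id(i) for i in (1, 2, 4, 6, 8, 12, 16, 20, 24, 26)]
fovs, truth = generate_dataset(codes, particles_per_class=60, seed=17)
table = build_feature_table(fovs, LocalizeParams(), truth)
table = table[table["label"] > 0]

train, test = stratified_split(table, test_fraction=0.2, seed=17)
board = compare_models(train, roster=("lightgbm", "lda", "knn"), folds=5, seed=17)
print("cross-validation leaderboard (mean over folds):")
print(board.table.round(3).to_string(index=False))

model = tune_top(train, board.best_family, budget=3, seed=17, folds=3)
cm = evaluate(model, test)
print(f"\ntuned {model.family}: held-out accuracy {100 * cm.accuracy:.1f} % "
      f"({cm.total} particles, {len(model.classes)} classes)")
print(f"macro precision {100 * cm.macro_precision:.1f} %, "
      f"macro sensitivity {100 * cm.macro_sensitivity:.1f} %")
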