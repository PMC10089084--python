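"""Experiments around the reader: PCA, Y-scrambling, class elimination.

Runs the fingerprint-space PCA, the label-permutation control and backward
class elimination on a small simulated dataset and prints what each
diagnostic says about the barcode reader.
"""

from nanobarcode import (
    LocalizeParams,
    backward_eliminate,
    build_feature_table,
    generate_dataset,
    pca_fingerprint,
    stratified_split,
    y_scramble,
)
from nanobarcode.scheme import barcode_from_id

codes = [barcode_from_id(i) for i in (1, 2, 4, 6, 10, 26)]
fovs, truth = generate_dataset(codes, particles_per_class=60, seed=23)
table = build_feature_table(fovs, LocalizeParams(), truth)
table = table[table["label"] > 0]

res = pca_fingerprint(table, components=3)
print("PCA of the 14-D fingerprints (mean-centered, SVD):")
print("  explained variance: "
      + ", ".join(f"PC{i + 1} {p:.1f} %" for i, p in enumerate(res.explained_pct[:3]))
      + f" (all 14 sum to {res.explained_pct.sum():.0f} %)")

train, test = stratified_split(table, 0.2, seed=23)
scores, reference = y_scramble(train, test, "lda", repeats=10, seed=23)
print(f"\nY-scrambling ({len(codes)} classes): scrambled accuracy "
      f"{100 * scores.mean():.1f} +- {100 * scores.std():.1f} % vs "
      f"{100 * reference:.1f} % with true labels -> no chance correlation")

trace = backward_eliminate(table, roster=("lda",), seed=23, folds=3, budget=1)
print("\nbackward class elimination (drop the least precise class each round):")
for step in trace.steps:
    print(f"  {len(step.remaining):2d} classes: accuracy {100 * step.accuracy:5.1f} % "
          f"(dropping barcode {step.dropped})")
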