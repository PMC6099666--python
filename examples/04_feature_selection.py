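"""Fisher-Markov ranking and incremental feature selection.

Features are ranked by between-class separation (the linear-kernel
Fisher-Markov criterion); growing prefixes of the ranking are then scored
by pooled 5-fold cross-validated MCC and the best prefix is kept.
"""

from imsp import (encode_dataset, incremental_search, load_pcp_table,
                  make_benchmark_suite, mine_top_motifs, rank_features)
from imsp.model_eval import (cross_validate, fold_assignment,
                             grid_search_svm)

ds = make_benchmark_suite(0)["separable"]
motifs = mine_top_motifs(ds.positives(), ds.negatives(), k=20)
fm = encode_dataset(ds, motifs, load_pcp_table())

ranking = rank_features(fm)
print("top 5 ranked features:")
for name, score in zip(ranking.names[:5], ranking.scores[:5]):
    print(f"  {name:12s} score {score:.4f}")

y = fm.y()
folds = fold_assignment(y, 5, seed=0)
hp = grid_search_svm(fm.X.to_numpy(), y, seed=0)
result = incremental_search(
    fm, ranking,
    evaluator=lambda sub: cross_validate(sub, k=5, seed=0, folds=folds,
                                         hyperparams=hp),
    step=5)

print("\nsubset size -> CV MCC:")
for size in result.evaluated_sizes:
    marker = "  <- optimal" if size == result.optimal_size else ""
    print(f"  {size:3d}  {result.reports[size].mcc:.3f}{marker}")
print(f"\nthe search keeps the smallest prefix maximising MCC "
      f"({result.optimal_size} of {len(ranking.names)} features).")
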