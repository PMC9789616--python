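"""Cluster a simulated scRNA-seq count matrix end to end.

Simulates raw counts for three cell types with 30% dropout, then runs
the full pipeline: remove genes detected in <= 2 cells, rescale each
cell to the median library size, log10(x+1), build the kNN Gaussian
affinity graph, fit the model and read labels off H.
"""

from dlnlrr import SolverConfig, evaluate, make_count_data, run_pipeline

X, truth = make_count_data(r=3, genes=200, n_per=40, dropout_rate=0.3, seed=0)
print(f"raw matrix: {X.n_genes} genes x {X.n_cells} cells, "
      f"{(X.values == 0).mean():.0%} zeros")

result = run_pipeline(X, SolverConfig(r=3, lam=1.0, beta=7.0, seed=0))
print(f"after gene filter: {result.X.n_genes} genes "
      f"(steps: {' -> '.join(result.X.transform_log[-3:])})")

scores = evaluate(result.labels, truth)
print(f"ARI = {scores.ari:.3f}, NMI = {scores.nmi:.3f}")
print("Values near 1 mean the inferred clusters match the simulated cell types "
      "despite dropout noise.")
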