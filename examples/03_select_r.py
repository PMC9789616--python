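"""Choose the subspace count r with the |H^T H| block diagnostic.

The model is fitted for each candidate r; the number of diagonal blocks
in |H^T H| stops growing once r reaches the true cluster count, and the
plateau point is selected.  Here the data contain four subspaces.
"""

from dlnlrr import (
    SolverConfig,
    SubspaceSpec,
    gaussian_affinity,
    make_subspace_data,
    select_r,
)

X, truth = make_subspace_data(SubspaceSpec(r=4, d=2, m=30, n_per=40, seed=1))
graph = gaussian_affinity(X, t=1.0)

r_star, diagnostics = select_r(
    X, graph.L, SolverConfig(r=2, lam=1.0, beta=7.0, seed=1), r_grid=list(range(2, 8))
)

print(" r  blocks in |H^T H|")
for r in sorted(diagnostics):
    print(f" {r}  {diagnostics[r]['block_count']}")
print(f"selected r = {r_star} (true number of subspaces: 4)")
print("The block count should rise with r, then level off at the true cluster "
      "number; the plateau is the selected r.")
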