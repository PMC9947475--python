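"""Train the height regressor and compare it with the raw smartphone estimate.

Runs the end-to-end study on a reduced scale so it finishes in seconds: 80
simulated jumps and a pruned hyperparameter grid (the package default is the
full 4 activations x 3 solvers x 16 hidden sizes = 192 combinations; pass
``grid=None`` for it).  Prints the held-out comparison and the permutation
feature importances of the Lasso-selected descriptors.
"""

from cmjump import run_study

grid = {
    "activation": ["identity", "logistic"],
    "solver": ["lbfgs"],
    "hidden_layer_sizes": [(4,), (8,)],
}

res = run_study(n=80, seed=7, grid=grid)

print(res.summary())
print()
print(f"Lasso kept {len(res.bundle.selected)}/26 features: {res.bundle.selected}")
print(f"best combination: {res.bundle.hyperparams}")
print()
print("permutation feature importance (MSE ratio, training set):")
for name in res.importance.ranking()[:5]:
    fi = res.importance.fi[res.importance.names.index(name)]
    print(f"  {name:4s} {fi:6.2f}")
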