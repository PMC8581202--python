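"""Hyperparameter search mirroring the selection protocol.

Greedy layer-by-layer sweep of hidden-layer widths, then a learning-rate
sweep at the chosen architecture, each cell trained on the train half and
scored on the held-out half. Sized down (few widths, short training) so
it runs in seconds; widen the grids for a real search.
"""

from mibci import (
    GridSpec,
    IDNNConfig,
    SynthConfig,
    generate_mi_trials,
    grid_search,
    trials_to_features,
)

ts = generate_mi_trials(SynthConfig(n_per_class=40, erd_depth=0.6, seed=5))
fm = trials_to_features(ts)

grid = GridSpec(widths=(5, 8, 11), max_depth=2, lrs=(0.05, 0.07, 0.1), iters=300)
res = grid_search(fm, grid, seed=5, base_cfg=IDNNConfig(iters=300, seed=5))

print(f"{'stage':<14} {'units':<8} {'lr':>5} {'accuracy':>9}")
for r in res.records:
    units = "x".join(map(str, r["units"]))
    print(f"{r['stage']:<14} {units:<8} {r['lr']:>5.2f} {r['accuracy']:>9.4f}")
print("best:", res.best)
print("tie-break:", res.tie_break)
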