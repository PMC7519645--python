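"""Simulate a full Design-Build-Test-Learn campaign on a synthetic landscape.

Each cycle trains the ensemble on all data so far, recommends 16 new
designs (exploration weight tempered from 0.9 down to 0), "builds and
tests" them by evaluating the true landscape, and folds them back into the
training set. Watch the best production rise toward the landscape optimum
while predictive uncertainty and held-out error shrink.
"""

from dbtlearn.benchmark import BenchmarkProblem, simulate_dbtl

problem = BenchmarkProblem("FE", dim=2)
history = simulate_dbtl(problem, n_cycles=5, n_init=16, batch=16, seed=3,
                        n_samples=1000, burn_in=300, pi_draws=800, pi_burn=200)

print(f"landscape optimum (brute-force grid): {problem.grid_optimum(500):.3f}")
print("cycle  n_train  best_so_far  top_SD  MAE_cv  MAE_test  alpha")
for r in history.records:
    print(f"{r.cycle:5d}  {r.training_size:7d}  {r.best_so_far:11.3f}  "
          f"{r.top_sd:6.3f}  {r.mae_train_cv:6.3f}  {r.mae_test:8.3f}  {r.alpha:5.2f}")
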