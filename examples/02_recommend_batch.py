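"""Ask a trained model for the next batch of strain designs.

The surrogate blends predicted titer (exploitation) with predictive
uncertainty (exploration) through alpha; parallel-tempered sampling finds
its high-value regions, and the gamma rule keeps the batch diverse: every
recommendation differs by at least 20% in some feature from all training
strains and from the other recommendations.
"""

import numpy as np

import dbtlearn as dl
from dbtlearn.benchmark import BenchmarkProblem, latin_hypercube

problem = BenchmarkProblem("FE", dim=2)
X = latin_hypercube(16, problem.bounds, seed=7)
y = problem.evaluate(X)
data = dl.TrainingSet(X, y[:, None], ["protein_1", "protein_2"], ["titer"])
model = dl.fit_ensemble(data, learners=dl.fast_learners(),
                        n_samples=2000, burn_in=500, seed=7)

objective = dl.ObjectiveConfig(mode="maximize", alpha=0.5, gamma=0.2,
                               batch_size=8, bounds=problem.bounds)
batch = dl.recommend(model, data, objective, seed=11, n_draws=3000, burn_in=500)

print(f"best titer observed so far: {y.max():.3f}")
print(f"gamma used: {batch.gamma_used}")
print(f"P(at least one recommendation improves on it): {batch.success_prob:.3f}")
print("top recommendations (input, surrogate G, predicted mean +/- SD):")
for x, g, pred in list(zip(batch.inputs, batch.surrogate_values, batch.predictions))[:4]:
    print(f"  {np.round(x, 2)}  G={g:.3f}  {pred.mean:.2f} +/- {pred.sd:.2f}")

p_single = max(pred.sf(y.max()) for pred in batch.predictions)
print(f"builds needed for a 95% chance of improvement at the best single-shot rate "
      f"({p_single:.2f}): {dl.n_required(p_single, 0.95)}")
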