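"""Generate a synthetic kinase-profiling benchmark and recover it with CGKronRLS.

Builds 40 compounds x 30 kinases with cluster/family structure, observes
30% of the pKd matrix with 0.2 units of assay noise censored at the
10 uM floor, fits a sparse Kronecker kernel regressor with the
generating kernels, and reports how well the unobserved cells are ranked.
"""

import numpy as np
from scipy import stats

from kronbind.kronrls import TrainSpec, fit_cg, predict
from kronbind.synthetic import SyntheticSpec, generate

ds = generate(SyntheticSpec(seed=7))
print(f"observed {len(ds.observed)} of {ds.truth.size} cells "
      f"(censored at pKd {ds.spec.censor_floor})")

model = fit_cg(ds.compound_kernel, ds.protein_kernel, ds.observed,
               TrainSpec(lam=0.5, epochs=400))

observed = set(ds.observed.pairs())
held = [(c.compound_id, p.protein_id)
        for c in ds.compounds for p in ds.proteins
        if (c.compound_id, p.protein_id) not in observed]
truth_map = ds.truth_table().pkd_map()
pred = predict(model, held).values_for(held)
truth = np.array([truth_map[pr] for pr in held])

rho = stats.spearmanr(pred, truth).statistic
rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
print(f"held-out Spearman = {rho:.3f}, RMSE = {rmse:.3f} pKd units")
print("-> the model ranks unmeasured compound-kinase affinities from "
      "kernel similarity alone; Spearman near 1 means near-perfect ranking.")
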