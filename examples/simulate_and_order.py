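"""Generate a synthetic embryo time course and recover its developmental
order from the expression data alone.

Builds a 179-embryo, 500-gene dataset, calls probes present/absent,
filters and normalises them, selects monotone training transcripts from
the epiboly extremes and orders the embryos by their mean.  Prints how
well the recovered order matches the planted one.
"""

import numpy as np
from scipy.stats import spearmanr

from epitrend import detection, ordering
from epitrend.synthetic import SyntheticConfig, generate_dataset

ds = generate_dataset(SyntheticConfig(n_genes=500, seed=1))
mask = detection.call_presence(ds.probe_matrix)
meta = ds.sample_meta.set_index("embryo_id")
epiboly_order = list(meta["epiboly_pct"].sort_values().index)
expressed = detection.expressed_probes(mask, epiboly_order)
norm = detection.quantile_normalize(ds.probe_matrix.loc[expressed])
tx = detection.collapse_to_transcripts(norm, ds.annotation)

training = ordering.select_training_transcripts(tx, meta["epiboly_pct"])
dev = ordering.order_samples(tx, training, "increasing", meta["epiboly_pct"])

true_rank = {e: i for i, e in enumerate(ds.truth.true_order)}
rho = spearmanr(np.arange(len(dev.ranks)),
                [true_rank[e] for e in dev.ranks]).statistic
print(f"expressed probes retained: {len(expressed)} of {mask.shape[0]}")
print(f"training transcripts (increasing): {len(training)}")
print(f"Spearman rho, recovered vs planted order: {rho:.4f}")
print("rho near 1 means the expression-derived order reproduces true")
print("developmental progression far better than noisy epiboly alone.")
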