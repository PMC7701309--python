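"""Read expression TSVs, select features, assign age groups, map to the grid.

Writes a small simulated expression matrix with per-sample ages spanning
gestation to late adulthood, then runs the preprocessing steps a real
study would use: top-variance gene selection, the nine-bin age grouping
(fetus ... 60s), and the mapping of groups onto the unit-interval grid.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

import tvgnet as tv
from tvgnet.preprocess import gestational_weeks_to_age

rng = np.random.default_rng(0)
tmp = Path(tempfile.mkdtemp())

genes = [f"GENE{i:03d}" for i in range(50)]
ages = [gestational_weeks_to_age(16), 0.2, 4.0, 15.0, 25.0, 35.0, 45.0, 55.0, 70.0] * 3
samples = [f"S{j:02d}" for j in range(len(ages))]
values = rng.standard_normal((50, len(ages))) * rng.uniform(0.2, 2.0, (50, 1))
pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples).to_csv(
    tmp / "expr.tsv", sep="\t"
)
pd.DataFrame({"sample_id": samples, "age": ages}).to_csv(
    tmp / "meta.tsv", sep="\t", index=False
)

X = tv.read_expression_matrix(tmp / "expr.tsv", tmp / "meta.tsv")
X = tv.select_top_variance_genes(X, 10)
groups = tv.assign_age_groups(X.ages)
times, grid = tv.map_groups_to_grid(groups)

print(f"kept {X.n_genes} top-variance genes of 50")
for s, a, g, t in zip(X.sample_ids[:9], ages[:9], groups[:9], times[:9]):
    print(f"{s}: age {a:7.3f} y -> {g:>6} -> t = {t:.3f}")

# Prenatal ages are negative years (-(40 - gestational weeks)/52); the nine
# verbal age bins map to nine equally spaced grid coordinates in [0, 1],
# which is the time axis every later estimation step uses.
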