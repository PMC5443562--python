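"""Quantify how polar effects inflate validation by positive cofitness.

A transposon insertion in a TF can silence downstream genes of the same
operon, creating artifactual positive cofitness with co-transcribed
"targets".  Here 35 of 40 polar-flagged TFs receive such leakage (and no
real regulation) while the comparison group has none; both groups carry
the same small share of genuine regulators.
"""

from cofitval.genome_context import maximal_runs, polar_validation_comparison
from cofitval.pipeline import validate_predictions
from cofitval.synthetic import (
    SimulationConfig, TfSpec, predictions_from_truth, simulate_fitness, simulate_genome,
)

specs = tuple(
    [TfSpec("activator", 2, 0.0, polar=True, polar_leak=0.6)] * 35
    + [TfSpec("activator", 2, 0.85, polar=True)] * 5
    + [TfSpec("activator", 2, 0.85)] * 5
    + [TfSpec("activator", 2, 0.0)] * 35
)
cfg = SimulationConfig(
    n_genes=1500, n_experiments=100, tf_specs=specs,
    mean_operon_len=2.5, make_sequence=False, seed=7,
)
ann, _, _, truth = simulate_genome(cfg)
table = simulate_fitness(ann, truth, cfg)
predictions = predictions_from_truth(truth)

results, _ = validate_predictions(predictions, table, ann, correct_bias=False, seed=7)
comparisons = polar_validation_comparison(results, list(predictions), maximal_runs(ann))

for c in comparisons.values():
    print(f"{c.direction:>16}: polar {c.k_polar}/{c.n_polar} vs other "
          f"{c.k_other}/{c.n_other} -> difference {c.diff:+.1%} +- {c.ci95:.1%} (95% CI)")
print()
print("Validation by positive cofitness is strongly enriched among predictions")
print("whose TF is co-transcribed with a target; the anti-cofitness direction")
print("is a negative control whose confidence interval should cover zero.")
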