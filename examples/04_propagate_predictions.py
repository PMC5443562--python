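"""Carry predictions from one organism to another via orthology + motif.

A small source organism is simulated with binding sites planted upstream of
every predicted target; a second organism is derived as a diverged copy
(90% protein identity).  Predictions propagate when both genes map through
reciprocal-best-hit orthology AND the motif is found upstream of the target
ortholog with empirical genome-wide p <= 0.01.
"""

from cofitval.propagation import propagate, reciprocal_best_hits
from cofitval.synthetic import (
    MotifSpec, SimulationConfig, TfSpec, derive_ortholog_copy,
    predictions_from_truth, simulate_genome, strong_pwm,
)

pwm = strong_pwm()
specs = tuple(TfSpec("activator", 1, 0.8) for _ in range(6))
cfg = SimulationConfig(
    n_genes=1200, n_experiments=10, tf_specs=specs, mean_operon_len=1.0,
    inter_gap=(600, 1200), motif=MotifSpec(pwm, planting_fraction=1.0),
    make_proteins=True, protein_len=150, seed=11,
)
ann, seqs, proteins, truth = simulate_genome(cfg)
predictions = predictions_from_truth(truth, motif_id=pwm.motif_id)

# restrict the RBH run to the genes involved in predictions (plus the rest of
# a small genome this stays cheap; all-vs-all alignment scales quadratically)
involved = {truth.tfs[0].tf_locus}
for tf in truth.tfs:
    involved.add(tf.tf_locus)
    involved.update(tf.targets)
sub_proteins = {k: v for k, v in proteins.items() if k in involved}
ann2, prots2, true_map = derive_ortholog_copy(ann, sub_proteins, identity=0.9, seed=12)

pairs = reciprocal_best_hits(sub_proteins, prots2)
print(f"RBH orthologs recovered: {len(pairs)}/{len(sub_proteins)} "
      f"(median identity {sorted(p.identity for p in pairs)[len(pairs)//2]:.0f}%)")

# the ortholog copy shares the source's coordinates and sequence, so the
# planted sites are conserved upstream of every target ortholog
omap = {p.locus_a: p.locus_b for p in pairs}
propagated, details = propagate(predictions, ann2, seqs, {pwm.motif_id: pwm},
                                ortholog_map=omap)
print(f"propagated predictions: {len(propagated)}/{len(predictions)}")
for d in details:
    print(f"  {d['tf']} -> {d['target_ortholog']}: motif score {d['score']:.1f}, "
          f"empirical p = {d['pvalue']:.4f}")
print()
print("Every pair passes because the sites are perfectly conserved; scrambling")
print("the sites would drop the pass rate to the ~1% empirical-p floor.")
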