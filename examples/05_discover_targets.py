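"""Nominate a candidate target for a putative TF with no predictions.

A putative TF is paired with its most cofit gene when that gene clears one
of two bars: cofitness > 0.8 outright, or cofitness > 0.6 conserved in a
second organism (orthologous pair also > 0.6) with cofitness rank <= 10.
"""

import numpy as np

from cofitval.cofitness import corrected_cofitness_profile
from cofitval.discovery import find_candidate_target
from cofitval.data_io import FitnessTable
import pandas as pd


def compendium(seed, coupled):
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(120)
    rows = {"putTF": v}
    for i in range(80):
        rows[f"g{i}"] = rng.standard_normal(120)
    for locus, c in coupled.items():
        rows[locus] = c * v + np.sqrt(1 - c * c) * rng.standard_normal(120)
    df = pd.DataFrame(rows).T
    df.columns = [f"exp{j}" for j in range(df.shape[1])]
    return FitnessTable(f"org{seed}", df, df * 2)


# organism 1: moderate cofitness (0.7) with g9; organism 2 conserves it
t1 = compendium(1, {"g9": 0.7})
t2 = compendium(2, {"g9": 0.7})
ortholog_map = {"putTF": "putTF", "g9": "g9"}

profile = corrected_cofitness_profile("putTF", t1)
candidate = find_candidate_target("putTF", profile, ortholog_map, {"org2": t2})
print(f"candidate: {candidate.target_locus}  cofitness={candidate.cofitness:.2f}  "
      f"conserved={candidate.conserved_cofitness:.2f}  "
      f"rank={candidate.conserved_rank:.0f}  criterion={candidate.criterion}")

# without the second organism, 0.7 is not enough on its own
alone = find_candidate_target("putTF", profile)
print(f"without conservation evidence: {alone}")
print()
print("Moderate cofitness becomes credible only when an orthologous gene pair")
print("shows it too; very strong cofitness (> 0.8) stands on its own.")
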