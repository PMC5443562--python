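"""Nominating candidate targets for putative TFs that lack predictions.

A putative TF (e.g. a gene from a known TF family with no curated regulon)
is paired with the gene it is most strongly cofit with, provided that gene
clears one of two bars: conserved cofitness (cofitness > 0.6 in this
organism, cofitness of the orthologous pair > 0.6 in a second organism, and
cofitness rank <= 10 in the TF's profile) or simply very strong cofitness
(> 0.8).  Genes the TF is already predicted to regulate are excluded.
These candidates are leads for comparative-genomics follow-up, not
validated predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .cofitness import CofitnessProfile, pearson_cofitness
from .data_io import FitnessTable

__all__ = ["CandidateTarget", "conserved_cofitness", "find_candidate_target"]

CONSERVED_COFITNESS_MIN = 0.6
CONSERVED_RANK_MAX = 10
STRONG_COFITNESS_MIN = 0.8


@dataclass(frozen=True)
class CandidateTarget:
    tf_locus: str
    target_locus: str
    cofitness: float
    conserved_cofitness: float | None
    conserved_rank: float | None
    criterion: str  # "conserved" or "strong"


def conserved_cofitness(
    pair: tuple[str, str],
    ortholog_map: Mapping[str, str],
    tables: Mapping[str, FitnessTable],
) -> float | None:
    """Cofitness of the orthologous pair in a second organism, or None.

    ``ortholog_map`` maps loci of the focal organism to loci of the other
    organism; ``tables`` maps genome_id -> FitnessTable and must contain the
    other organism's table.  Returns None when either ortholog is missing
    or lacks fitness data; thresholding is the caller's job.
    """
    tf, gene = pair
    o_tf = ortholog_map.get(tf)
    o_gene = ortholog_map.get(gene)
    if o_tf is None or o_gene is None:
        return None
    for table in tables.values():
        if o_tf in table and o_gene in table:
            r, _m = pearson_cofitness(table.fitness_row(o_tf), table.fitness_row(o_gene))
            return None if math.isnan(r) else r
    return None


def find_candidate_target(
    tf: str,
    profile: CofitnessProfile,
    ortholog_map: Mapping[str, str] | None = None,
    tables: Mapping[str, FitnessTable] | None = None,
    exclusions: set[str] | None = None,
) -> CandidateTarget | None:
    """The non-excluded gene with the highest cofitness among those passing
    the conserved (>0.6 both organisms, rank <= 10) or strong (>0.8)
    criterion; None if no gene qualifies."""
    if profile.focal_gene != tf:
        raise ValueError(f"profile is for {profile.focal_gene!r}, not {tf!r}")
    exclusions = exclusions or set()
    order = sorted(
        (
            k
            for k, v in enumerate(profile.corrected)
            if math.isfinite(v) and profile.partner_ids[k] not in exclusions
        ),
        key=lambda k: -profile.corrected[k],
    )
    for k in order:
        locus = profile.partner_ids[k]
        r = float(profile.corrected[k])
        if r <= CONSERVED_COFITNESS_MIN:
            break  # sorted descending: nothing further can qualify
        if r > STRONG_COFITNESS_MIN:
            cc = (
                conserved_cofitness((tf, locus), ortholog_map, tables)
                if ortholog_map and tables
                else None
            )
            return CandidateTarget(tf, locus, r, cc, float(profile.rank[k]), "strong")
        if ortholog_map and tables:
            cc = conserved_cofitness((tf, locus), ortholog_map, tables)
            rank = float(profile.rank[k])
            if cc is not None and cc > CONSERVED_COFITNESS_MIN and rank <= CONSERVED_RANK_MAX:
                return CandidateTarget(tf, locus, r, cc, rank, "conserved")
    return None
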