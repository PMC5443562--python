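"""Operon structure and polar-effect analysis.

A transposon insertion in a gene can terminate transcription of downstream
genes in the same operon ("polar effect"), inducing artifactual positive
cofitness between co-transcribed genes.  Predictions whose TF is
co-transcribed with a predicted target are therefore flagged, and validation
rates of flagged vs other predictions are compared with an (unpooled)
two-proportion z confidence interval, separately for validation by positive
cofitness and by anti-cofitness (the latter is a negative control).

Potential operons are maximal runs of adjacent same-strand genes with
intergenic gaps under 250 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import norm

from .data_io import GenomeAnnotation, PredictionRecord
from .validation import TfTestResult

__all__ = [
    "PotentialOperon",
    "PolarComparison",
    "maximal_runs",
    "same_operon",
    "flag_polar",
    "two_proportion_diff_ci",
    "polar_validation_comparison",
]

OPERON_MAX_GAP = 250


@dataclass(frozen=True)
class PotentialOperon:
    """Maximal run of adjacent same-strand genes with gaps < 250 bp.

    ``members`` are ordered 5'->3' in transcription direction;
    ``upstream_end`` is the transcriptional 5' boundary coordinate.
    """

    scaffold: str
    strand: str
    members: tuple[str, ...]
    upstream_end: int

    def __contains__(self, locus: str) -> bool:
        return locus in self.members


def maximal_runs(
    ann: GenomeAnnotation, max_gap: int = OPERON_MAX_GAP
) -> list[PotentialOperon]:
    """Partition the genome into maximal potential operons.

    The gap between genome-order neighbours is the intergenic distance
    (next begin - previous end - 1, clamped at 0 for overlaps); a run breaks
    on a strand flip or a gap >= ``max_gap`` (strict "less than" rule).
    Singletons form singleton runs; every gene lands in exactly one run.
    """
    runs: list[PotentialOperon] = []
    for scaffold in ann.scaffolds:
        genes = ann.genes_on(scaffold)
        block: list = []
        for g in genes:
            if block:
                prev = block[-1]
                gap = max(0, g.begin - prev.end - 1)
                if g.strand != prev.strand or gap >= max_gap:
                    runs.append(_make_run(scaffold, block))
                    block = []
            block.append(g)
        if block:
            runs.append(_make_run(scaffold, block))
    return runs


def _make_run(scaffold: str, block: list) -> PotentialOperon:
    strand = block[0].strand
    ordered = block if strand == "+" else list(reversed(block))
    upstream_end = block[0].begin if strand == "+" else block[-1].end
    return PotentialOperon(
        scaffold=scaffold,
        strand=strand,
        members=tuple(g.locus_id for g in ordered),
        upstream_end=upstream_end,
    )


def _run_index(runs: Sequence[PotentialOperon]) -> dict[str, PotentialOperon]:
    return {locus: run for run in runs for locus in run.members}


def same_operon(a: str, b: str, runs: Sequence[PotentialOperon]) -> bool:
    """True iff both genes belong to the same maximal run."""
    idx = _run_index(runs)
    if a not in idx:
        raise KeyError(f"locus {a!r} not in any run")
    if b not in idx:
        raise KeyError(f"locus {b!r} not in any run")
    return idx[a] is idx[b]


def flag_polar(
    prediction: PredictionRecord, runs: Sequence[PotentialOperon]
) -> bool:
    """True iff any predicted target is co-transcribed with the TF
    (shares its maximal run)."""
    idx = _run_index(runs)
    tf_run = idx.get(prediction.tf_locus)
    if tf_run is None:
        raise KeyError(f"TF {prediction.tf_locus!r} not in any run")
    return any(t in tf_run.members for t in prediction.targets if t != prediction.tf_locus)


def two_proportion_diff_ci(
    k1: int, n1: int, k2: int, n2: int, level: float = 0.95
) -> tuple[float, float]:
    """Unpooled Wald CI for the difference of two proportions.

    Returns ``(diff, half_width)`` with ``diff = k1/n1 - k2/n2`` and
    ``half_width = z * sqrt(p1 q1 / n1 + p2 q2 / n2)``.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both group sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1 = k1 / n1
    p2 = k2 / n2
    z = norm.ppf(0.5 + level / 2)
    half = z * (p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2) ** 0.5
    return (p1 - p2, half)


@dataclass(frozen=True)
class PolarComparison:
    """Validation-rate contrast of polar-flagged vs other predictions."""

    direction: str  # "cofitness" or "anti-cofitness"
    n_polar: int
    k_polar: int
    n_other: int
    k_other: int
    diff: float
    ci95: float

    @property
    def excludes_zero(self) -> bool:
        return abs(self.diff) > self.ci95


def polar_validation_comparison(
    results: Iterable[TfTestResult],
    predictions: Iterable[PredictionRecord],
    runs: Sequence[PotentialOperon],
    alpha: float = 0.01,
) -> dict[str, PolarComparison]:
    """Compare validation rates between polar-flagged and other predictions.

    Only TFs with a significant phenotype and at least one usable target are
    eligible (i.e. the TFs with a computed test result and
    ``has_phenotype``).  Validation by positive cofitness means
    ``p_activator <= alpha``; by anti-cofitness, ``p_repressor <= alpha``.
    Returns one :class:`PolarComparison` per direction.
    """
    preds_by_tf: Mapping[str, PredictionRecord] = {
        p.tf_locus: p for p in predictions
    }
    groups: dict[bool, list[TfTestResult]] = {True: [], False: []}
    for res in results:
        if not res.has_phenotype or res.T < 1:
            continue
        pred = preds_by_tf.get(res.tf_locus)
        if pred is None:
            continue
        groups[flag_polar(pred, runs)].append(res)

    out: dict[str, PolarComparison] = {}
    for direction, attr in (("cofitness", "p_activator"), ("anti-cofitness", "p_repressor")):
        polar = groups[True]
        other = groups[False]
        if not polar or not other:
            continue
        k1 = sum(1 for r in polar if getattr(r, attr) <= alpha)
        k2 = sum(1 for r in other if getattr(r, attr) <= alpha)
        diff, half = two_proportion_diff_ci(k1, len(polar), k2, len(other))
        out[direction] = PolarComparison(
            direction=direction,
            n_polar=len(polar),
            k_polar=k1,
            n_other=len(other),
            k_other=k2,
            diff=diff,
            ci95=half,
        )
    return out
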