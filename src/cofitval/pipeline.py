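"""High-level drivers tying bias estimation, profiles and the test together."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .cofitness import BiasEstimate, corrected_cofitness_profile, estimate_position_bias
from .data_io import FitnessTable, GenomeAnnotation, PredictionSet
from .genome_context import flag_polar, maximal_runs
from .validation import DEFAULT_ALPHA, TfTestResult, UntestableError, estimate_fdr, validate_tf

__all__ = ["ValidationSummary", "validate_predictions"]

log = logging.getLogger(__name__)


@dataclass
class ValidationSummary:
    n_predictions: int
    n_tested: int
    n_validated: int
    n_activator: int
    n_repressor: int
    n_ambiguous: int
    fdr: float | None
    bias: BiasEstimate | None
    alpha: float

    def __str__(self) -> str:
        fdr = f"{self.fdr:.1%}" if self.fdr is not None else "undefined"
        bias = f"{self.bias.bias:.4f}" if self.bias is not None else "off"
        return (
            f"tested {self.n_tested}/{self.n_predictions} TFs, "
            f"validated {self.n_validated} "
            f"({self.n_activator} activators, {self.n_repressor} repressors, "
            f"{self.n_ambiguous} ambiguous) at alpha={self.alpha:g}; "
            f"FDR={fdr}; proximity bias={bias}"
        )


def validate_predictions(
    predictions: PredictionSet,
    table: FitnessTable,
    ann: GenomeAnnotation | None = None,
    alpha: float = DEFAULT_ALPHA,
    correct_bias: bool = True,
    seed: int = 0,
    gate_phenotype: bool = True,
) -> tuple[list[TfTestResult], ValidationSummary]:
    """Validate every prediction in a set against one fitness compendium.

    Estimates the genome's proximity bias once (when an annotation is given
    and ``correct_bias``), builds each TF's corrected profile, runs the
    hypothesis test, flags polar-vulnerable predictions, and reports the
    plug-in FDR over tested TFs.  TFs without fitness data or without usable
    targets are recorded as skipped, not tested.
    """
    bias = None
    if correct_bias and ann is not None:
        bias = estimate_position_bias(table, ann, seed=seed)
        log.info("%s: proximity bias = %.4f", table.genome_id, bias.bias)
    runs = maximal_runs(ann) if ann is not None else None

    results: list[TfTestResult] = []
    n_tested = 0
    for pred in predictions:
        tf = pred.tf_locus
        if tf not in table:
            log.info("%s: no fitness data; skipped", tf)
            continue
        profile = corrected_cofitness_profile(tf, table, ann, bias)
        try:
            res = validate_tf(
                tf, list(pred.targets), profile, table,
                alpha=alpha, gate_phenotype=gate_phenotype, group_id=pred.group_id,
            )
        except UntestableError as exc:
            log.info("%s", exc)
            continue
        if runs is not None and tf in {m for r in runs for m in r.members}:
            res.polar = flag_polar(pred, runs)
        if res.has_phenotype or not gate_phenotype:
            n_tested += 1
        results.append(res)

    n_validated = sum(1 for r in results if r.validated)
    summary = ValidationSummary(
        n_predictions=len(predictions),
        n_tested=n_tested,
        n_validated=n_validated,
        n_activator=sum(1 for r in results if r.sign == "activator"),
        n_repressor=sum(1 for r in results if r.sign == "repressor"),
        n_ambiguous=sum(1 for r in results if r.sign == "ambiguous"),
        fdr=estimate_fdr(alpha, n_tested, n_validated) if n_validated else None,
        bias=bias,
        alpha=alpha,
    )
    return results, summary
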