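"""Null calibration of the hypothesis test by target randomization.

To check that the test's p-values are on the right scale, each TF's
predicted targets are replaced by the same number of randomly drawn genes
with fitness data, the test is re-run, and the fraction of cases reaching
p <= 0.01 / 0.05 is tallied.  On real or realistically correlated data the
0.05 fraction may exceed the nominal level somewhat because fitness
profiles of functionally related genes are correlated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cofitness import BiasEstimate, corrected_cofitness_profile
from .data_io import FitnessTable, GenomeAnnotation, PredictionSet
from .validation import UntestableError, validate_tf

__all__ = ["CalibrationReport", "resample_targets", "calibrate"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationReport:
    n_tfs: int
    reps: int
    n_cases: int
    n_p01: int
    n_p05: int
    seed: int

    @property
    def frac_p01(self) -> float:
        return self.n_p01 / self.n_cases if self.n_cases else 0.0

    @property
    def frac_p05(self) -> float:
        return self.n_p05 / self.n_cases if self.n_cases else 0.0

    def summary(self) -> str:
        return (
            f"{self.n_tfs} TFs x {self.reps} reps = {self.n_cases} cases; "
            f"p<=0.01 in {self.n_p01} ({self.frac_p01:.1%}), "
            f"p<=0.05 in {self.n_p05} ({self.frac_p05:.1%})"
        )


def resample_targets(
    tf: str, T: int, gene_pool: list[str], rng: np.random.Generator
) -> list[str]:
    """Draw T distinct random 'targets' for a TF from the genes with fitness
    data (the TF itself excluded from the pool by the caller)."""
    pool = [g for g in gene_pool if g != tf]
    if len(pool) < T:
        raise UntestableError(
            f"{tf}: pool of {len(pool)} genes smaller than T = {T}"
        )
    picked = rng.choice(len(pool), size=T, replace=False)
    return [pool[i] for i in picked]


def calibrate(
    predictions: PredictionSet,
    table: FitnessTable,
    ann: GenomeAnnotation | None = None,
    reps: int = 10,
    seed: int = 0,
    gate_phenotype: bool = True,
    bias: BiasEstimate | None = None,
    alpha_levels: tuple[float, float] = (0.01, 0.05),
) -> CalibrationReport:
    """Re-run the validation test with randomized targets.

    For each testable TF (fitness data present; T >= 1 targets with data,
    excluding the TF) the bias-corrected profile is computed once and reused
    across ``reps`` resampling rounds; each round replaces the targets by a
    fresh uniform draw of the same size and records whether
    min(p_activator, p_repressor) falls at or below each alpha level.
    """
    rng = np.random.default_rng(seed)
    pool = table.gene_ids
    lo, hi = alpha_levels
    n_tfs = 0
    n_p01 = 0
    n_p05 = 0
    for pred in predictions:
        tf = pred.tf_locus
        if tf not in table:
            log.info("calibrate: %s has no fitness data; skipped", tf)
            continue
        T = len({t for t in pred.targets if t != tf and t in table})
        if T < 1 or T > len(pool) - 1:
            log.info("calibrate: %s has no usable targets; skipped", tf)
            continue
        profile = corrected_cofitness_profile(tf, table, ann, bias)
        tested_any = False
        for _ in range(reps):
            targets = resample_targets(tf, T, pool, rng)
            try:
                res = validate_tf(
                    tf, targets, profile, table, alpha=lo,
                    gate_phenotype=gate_phenotype,
                )
            except UntestableError:
                continue
            if gate_phenotype and not res.has_phenotype:
                continue
            tested_any = True
            p = min(res.p_activator, res.p_repressor)
            if p <= lo:
                n_p01 += 1
            if p <= hi:
                n_p05 += 1
        if tested_any:
            n_tfs += 1
    n_cases = n_tfs * reps
    return CalibrationReport(
        n_tfs=n_tfs, reps=reps, n_cases=n_cases,
        n_p01=n_p01, n_p05=n_p05, seed=seed,
    )
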