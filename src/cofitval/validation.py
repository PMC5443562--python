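"""The core hypothesis test for validating TF-motif predictions.

A TF-motif prediction is statistically validated when the TF has a
significant mutant phenotype and BOTH of two tests reach p <= alpha in the
same direction:

* a rank test on the top (anti-)cofitness rank R of the predicted targets
  among all N-1 partners,

      p_rank = 2 * [1 - (1 - R/(N-1))^T]

  (T predicted targets, sampling with replacement; the factor 2 is a
  Bonferroni correction for testing both signs), and

* a Fisher-transform test on the corresponding extreme cofitness value r,

      z = sqrt(M-3) * atanh(r),    p_fisher = 2 * T * P(Z >= z)

  (M shared experiments behind r; Bonferroni 2T for both signs and T
  targets).

The combined p per direction is the max of the two, the validated sign is
the direction reaching alpha, and the study-level FDR is the plug-in
estimate alpha * tested / validated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .cofitness import CofitnessProfile, _competition_ranks
from .data_io import AssociationMatrix, FitnessTable

__all__ = [
    "UntestableError",
    "TfTestResult",
    "significant_phenotype",
    "rank_pvalue",
    "fisher_pvalue",
    "validate_tf",
    "validate_from_association",
    "estimate_fdr",
]

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
FITNESS_THRESHOLD = 0.5
T_THRESHOLD = 4.0

_TINY = np.nextafter(0.0, 1.0)  # p-values live in (0, 1]


class UntestableError(ValueError):
    """The TF cannot be tested (no usable targets, or too little data)."""


@dataclass
class TfTestResult:
    """All quantities of the hypothesis test for one TF.

    ``N`` is the number of genes with fitness data in the genome, ``T`` the
    number of predicted targets with data (TF excluded), ``R``/``R_prime``
    the top cofitness / anti-cofitness ranks among targets, ``r_max`` /
    ``r_min`` the extreme corrected cofitness values, and ``M_top`` the
    shared-experiment count behind the winning direction's top pair.
    """

    tf_locus: str
    N: int
    T: int
    M_top: int
    R: int
    R_prime: int
    r_max: float
    r_min: float
    p_rank_act: float
    p_rank_rep: float
    p_fisher_act: float
    p_fisher_rep: float
    p_activator: float
    p_repressor: float
    has_phenotype: bool
    validated: bool
    sign: str
    top_target_act: str
    top_target_rep: str
    group_id: str = ""
    polar: bool | None = None
    dropped_targets: tuple[str, ...] = field(default_factory=tuple)


def significant_phenotype(
    fit_row: np.ndarray,
    t_row: np.ndarray,
    fit_thresh: float = FITNESS_THRESHOLD,
    t_thresh: float = T_THRESHOLD,
) -> bool:
    """True iff some experiment has |fitness| > fit_thresh AND |t| > t_thresh.

    Both inequalities are strict; experiments where either value is missing
    do not qualify.
    """
    f = np.asarray(fit_row, dtype=float)
    t = np.asarray(t_row, dtype=float)
    ok = np.isfinite(f) & np.isfinite(t)
    return bool(np.any(ok & (np.abs(f) > fit_thresh) & (np.abs(t) > t_thresh)))


def rank_pvalue(R_obs: int, T: int, N: int) -> float:
    """Probability (x2 for two signs, capped at 1) that the best of T uniform
    draws from ranks 1..N-1, with replacement, ranks as well as ``R_obs``."""
    if T < 1:
        raise UntestableError("T must be >= 1 (TF has no targets with data)")
    if N < 3:
        raise UntestableError("N must be >= 3")
    if not 1 <= R_obs <= N - 1:
        raise ValueError(f"rank {R_obs} outside 1..{N - 1}")
    # 1 - (1 - R/(N-1))^T via expm1/log1p for small R/(N-1)
    if R_obs == N - 1:
        tail = 1.0
    else:
        tail = -math.expm1(T * math.log1p(-R_obs / (N - 1)))
    return max(_TINY, min(1.0, 2.0 * tail))


def fisher_pvalue(r: float, M: int, T: int, side: str) -> float:
    """Fisher z-transform p-value for an extreme correlation among T targets.

    ``z = sqrt(M-3) * atanh(r)``; the one-sided normal tail (upper for
    ``side='positive'``, lower for ``'negative'``) is Bonferroni-corrected by
    ``2*T`` for both signs and T targets, then capped at 1.
    """
    if side not in ("positive", "negative"):
        raise ValueError("side must be 'positive' or 'negative'")
    if T < 1:
        raise UntestableError("T must be >= 1")
    if M < 4:
        raise UntestableError(f"M = {M} < 4: too few shared experiments")
    if not math.isfinite(r) or abs(r) > 1:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    if abs(r) == 1.0:
        # atanh diverges; the p-value underflows rather than erroring
        p1 = 0.0 if (r > 0) == (side == "positive") else 1.0
    else:
        z = math.sqrt(M - 3) * math.atanh(r)
        p1 = norm.sf(z) if side == "positive" else norm.cdf(z)
    return max(_TINY, min(1.0, 2.0 * T * p1))


def _classify(p_act: float, p_rep: float, alpha: float) -> str:
    act = p_act <= alpha
    rep = p_rep <= alpha
    if act and rep:
        return "ambiguous"
    if act:
        return "activator"
    if rep:
        return "repressor"
    return "none"


def _test_from_profile(
    tf: str,
    targets: list[str],
    N: int,
    value_of,
    rank_of,
    anti_rank_of,
    m_of,
    alpha: float,
    has_phenotype: bool,
    gate_phenotype: bool,
    group_id: str = "",
) -> TfTestResult:
    """Shared core of validate_tf / validate_from_association."""
    usable: list[str] = []
    dropped: list[str] = []
    seen: set[str] = set()
    for t in targets:
        if t == tf or t in seen:
            continue
        seen.add(t)
        v = value_of(t)
        if v is None or not math.isfinite(v):
            dropped.append(t)
        else:
            usable.append(t)
    if dropped:
        log.warning("%s: dropping %d target(s) without usable data: %s",
                    tf, len(dropped), ", ".join(dropped))
    if not usable:
        raise UntestableError(f"{tf}: no targets with defined cofitness")
    T = len(usable)

    vals = {t: value_of(t) for t in usable}
    top_act = max(usable, key=lambda t: vals[t])
    top_rep = min(usable, key=lambda t: vals[t])
    r_max = vals[top_act]
    r_min = vals[top_rep]
    R = int(min(rank_of(t) for t in usable))
    R_prime = int(min(anti_rank_of(t) for t in usable))

    p_rank_act = rank_pvalue(R, T, N)
    p_rank_rep = rank_pvalue(R_prime, T, N)
    p_fisher_act = fisher_pvalue(r_max, m_of(top_act), T, "positive")
    p_fisher_rep = fisher_pvalue(r_min, m_of(top_rep), T, "negative")
    p_act = max(p_fisher_act, p_rank_act)
    p_rep = max(p_fisher_rep, p_rank_rep)

    passes = min(p_act, p_rep) <= alpha
    validated = passes and (has_phenotype or not gate_phenotype)
    sign = _classify(p_act, p_rep, alpha) if validated else "none"
    m_top = m_of(top_act) if p_act <= p_rep else m_of(top_rep)

    return TfTestResult(
        tf_locus=tf,
        N=N,
        T=T,
        M_top=m_top,
        R=R,
        R_prime=R_prime,
        r_max=r_max,
        r_min=r_min,
        p_rank_act=p_rank_act,
        p_rank_rep=p_rank_rep,
        p_fisher_act=p_fisher_act,
        p_fisher_rep=p_fisher_rep,
        p_activator=p_act,
        p_repressor=p_rep,
        has_phenotype=has_phenotype,
        validated=validated,
        sign=sign,
        top_target_act=top_act,
        top_target_rep=top_rep,
        group_id=group_id,
        dropped_targets=tuple(dropped),
    )


def validate_tf(
    tf: str,
    targets: list[str],
    profile: CofitnessProfile,
    table: FitnessTable,
    alpha: float = DEFAULT_ALPHA,
    gate_phenotype: bool = True,
    group_id: str = "",
) -> TfTestResult:
    """Run the full hypothesis test for one TF against its predicted targets.

    ``profile`` must be the (bias-corrected) cofitness profile of ``tf``.
    Targets equal to the TF or without defined cofitness are dropped (with a
    warning); N is the number of genes with fitness data in the genome.
    """
    if profile.focal_gene != tf:
        raise ValueError(f"profile is for {profile.focal_gene!r}, not {tf!r}")
    if tf not in table:
        raise KeyError(f"TF {tf!r} has no fitness data")
    idx = {p: k for k, p in enumerate(profile.partner_ids)}

    def value_of(t):
        k = idx.get(t)
        return None if k is None else float(profile.corrected[k])

    has_phen = significant_phenotype(table.fitness_row(tf), table.t_row(tf))
    return _test_from_profile(
        tf,
        targets,
        table.n_genes,
        value_of,
        lambda t: profile.rank[idx[t]],
        lambda t: profile.anti_rank[idx[t]],
        lambda t: int(profile.m_shared[idx[t]]),
        alpha,
        has_phen,
        gate_phenotype=gate_phenotype,
        group_id=group_id,
    )


def validate_from_association(
    tf: str,
    targets: list[str],
    assoc: AssociationMatrix,
    M: int,
    alpha: float = DEFAULT_ALPHA,
    exclude: set[str] | None = None,
    group_id: str = "",
) -> TfTestResult:
    """Run the identical test on a generic association matrix (e.g.
    coexpression); no bias correction and no phenotype gate.

    ``M`` is the number of arrays/experiments underlying the correlations;
    ``exclude`` removes partners (e.g. same-operon targets) from the test.
    """
    if tf not in assoc.values.index:
        raise KeyError(f"{tf!r} not in association matrix")
    exclude = exclude or set()
    partner_ids = [g for g in assoc.gene_ids if g != tf and g not in exclude]
    row = assoc.values.loc[tf, partner_ids].to_numpy(dtype=float)
    rank, anti = _competition_ranks(row)
    idx = {p: k for k, p in enumerate(partner_ids)}
    N = len(assoc.gene_ids)

    def value_of(t):
        k = idx.get(t)
        return None if k is None else float(row[k])

    return _test_from_profile(
        tf,
        [t for t in targets if t not in exclude],
        N,
        value_of,
        lambda t: rank[idx[t]],
        lambda t: anti[idx[t]],
        lambda t: M,
        alpha,
        has_phenotype=True,
        gate_phenotype=False,
        group_id=group_id,
    )


def estimate_fdr(alpha: float, n_tested: int, n_validated: int) -> float:
    """Plug-in false discovery rate: expected false positives over positives,
    ``alpha * n_tested / n_validated``."""
    if n_validated < 1:
        raise ValueError("FDR undefined with zero validated TFs")
    return alpha * n_tested / n_validated
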