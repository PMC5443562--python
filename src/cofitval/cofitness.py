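"""Cofitness: Pearson correlation of fitness profiles, proximity-bias
correction, and cofitness / anti-cofitness ranks.

Cofitness of two genes is the Pearson correlation of their fitness values
across experiments, computed over pairwise-complete experiments.  Pairs of
chromosomally close genes tend to show a small positive correlation that is
unrelated to regulation (residual DNA copy-number structure), so a per-genome
bias is estimated by contrasting close (<= 20 kb) against far (>= 50 kb or
trans-scaffold) gene pairs and subtracted from positively cofit close pairs
before ranking.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data_io import FitnessTable, GeneRecord, GenomeAnnotation

__all__ = [
    "BiasEstimate",
    "CofitnessProfile",
    "pearson_cofitness",
    "gene_distance",
    "estimate_position_bias",
    "corrected_cofitness_profile",
]

log = logging.getLogger(__name__)

#: below this many shared experiments a correlation is treated as undefined
DEFAULT_MIN_SHARED = 10
CLOSE_MAX_BP = 20_000
FAR_MIN_BP = 50_000


def pearson_cofitness(
    x: np.ndarray, y: np.ndarray, min_shared: int = DEFAULT_MIN_SHARED
) -> tuple[float, int]:
    """Pearson correlation over pairwise-complete experiments.

    Returns ``(r, m_shared)``; ``r`` is NaN (undefined) when fewer than
    ``min_shared`` experiments are shared or either restricted vector has
    zero variance.  Symmetric in its arguments by construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    m = int(mask.sum())
    if m < max(min_shared, 2):
        return (math.nan, m)
    xs = x[mask]
    ys = y[mask]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    denom = math.sqrt(float(xs @ xs) * float(ys @ ys))
    if denom == 0.0:
        return (math.nan, m)
    r = float(xs @ ys) / denom
    return (max(-1.0, min(1.0, r)), m)


def _profile_correlations(
    focal_row: np.ndarray, mat: np.ndarray, min_shared: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pairwise-complete Pearson of one row against a matrix.

    Returns (r, m) arrays over the matrix rows; undefined entries are NaN.
    """
    vf = np.isfinite(focal_row)
    V = np.isfinite(mat)
    W = V & vf  # shared-experiment masks
    Xa = np.where(V, mat, 0.0)
    fa = np.where(vf, focal_row, 0.0)
    n = W.sum(axis=1).astype(float)
    sx = (Xa * W).sum(axis=1)
    sf = W @ fa
    sxx = (Xa**2 * W).sum(axis=1)
    sff = W @ (fa**2)
    sxf = Xa @ fa  # fa is 0 where focal missing, Xa is 0 where gene missing
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxf - sx * sf / n
        vx = sxx - sx**2 / n
        vfv = sff - sf**2 / n
        r = cov / np.sqrt(vx * vfv)
    bad = (n < max(min_shared, 2)) | ~np.isfinite(r)
    r = np.clip(r, -1.0, 1.0)
    r[bad] = np.nan
    return r, n.astype(int)


@dataclass(frozen=True)
class BiasEstimate:
    """Proximity-bias estimate for one genome.

    ``bias = max(0, median_close - median_far)`` where the medians are over
    the cofitness of sampled close / far gene pairs.
    """

    genome_id: str
    bias: float
    median_close: float
    median_far: float
    n_close: int
    n_far: int
    seed: int

    @classmethod
    def zero(cls, genome_id: str = "", seed: int = 0) -> "BiasEstimate":
        return cls(genome_id, 0.0, math.nan, math.nan, 0, 0, seed)


@dataclass
class CofitnessProfile:
    """Cofitness of one focal gene against every other gene with data.

    ``rank`` is the competition (min) rank by descending corrected cofitness
    (1 = most positive); ``anti_rank`` by ascending (1 = most negative).
    Partners with undefined cofitness have NaN ranks.
    """

    focal_gene: str
    partner_ids: list[str]
    raw: np.ndarray
    corrected: np.ndarray
    m_shared: np.ndarray
    rank: np.ndarray
    anti_rank: np.ndarray

    def _idx(self, locus: str) -> int:
        try:
            return self.partner_ids.index(locus)
        except ValueError:
            raise KeyError(f"{locus!r} not a partner of {self.focal_gene}") from None

    def corrected_of(self, locus: str) -> float:
        return float(self.corrected[self._idx(locus)])

    def rank_of(self, locus: str) -> float:
        return float(self.rank[self._idx(locus)])

    def anti_rank_of(self, locus: str) -> float:
        return float(self.anti_rank[self._idx(locus)])

    def m_of(self, locus: str) -> int:
        return int(self.m_shared[self._idx(locus)])

    @property
    def n_defined(self) -> int:
        return int(np.isfinite(self.corrected).sum())


def gene_distance(a: GeneRecord, b: GeneRecord) -> float:
    """Midpoint distance in bp; infinite across scaffolds."""
    if a.scaffold != b.scaffold:
        return math.inf
    return abs(a.midpoint - b.midpoint)


def _competition_ranks(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min-ranks by descending (rank) and ascending (anti_rank) value; NaN in,
    NaN out."""
    rank = np.full(values.shape, np.nan)
    anti = np.full(values.shape, np.nan)
    ok = np.isfinite(values)
    if ok.any():
        v = values[ok]
        rank[ok] = rankdata(-v, method="min")
        anti[ok] = rankdata(v, method="min")
    return rank, anti


def estimate_position_bias(
    table: FitnessTable,
    ann: GenomeAnnotation,
    n_pairs: int = 1000,
    close_max: float = CLOSE_MAX_BP,
    far_min: float = FAR_MIN_BP,
    seed: int = 0,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> BiasEstimate:
    """Estimate the chromosomal-proximity cofitness bias for a genome.

    Samples ``n_pairs`` gene pairs at most ``close_max`` bp apart and
    ``n_pairs`` pairs at least ``far_min`` bp apart (or on different
    scaffolds), uniformly with replacement among eligible pairs with defined
    cofitness, and returns ``max(0, median_close - median_far)``.
    """
    rng = np.random.default_rng(seed)
    genes = [g for g in ann.genes if g.locus_id in table]
    if len(genes) < 2:
        log.warning("%s: fewer than 2 genes with fitness data; bias = 0", ann.genome_id)
        return BiasEstimate(ann.genome_id, 0.0, math.nan, math.nan, 0, 0, seed)
    mat = table.fitness.loc[[g.locus_id for g in genes]].to_numpy(dtype=float)

    # enumerate close pairs per scaffold with a sliding midpoint window
    by_scaffold: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        by_scaffold.setdefault(g.scaffold, []).append(i)
    close_pairs: list[tuple[int, int]] = []
    for idxs in by_scaffold.values():
        mids = [genes[i].midpoint for i in idxs]
        for a_pos, i in enumerate(idxs):
            hi = bisect_right(mids, mids[a_pos] + close_max)
            for b_pos in range(a_pos + 1, hi):
                close_pairs.append((i, idxs[b_pos]))

    def sample_median(pairs_of) -> tuple[float, int]:
        vals: list[float] = []
        attempts = 0
        while len(vals) < n_pairs and attempts < 50 * n_pairs:
            attempts += 1
            pair = pairs_of()
            if pair is None:
                continue
            i, j = pair
            r, _m = pearson_cofitness(mat[i], mat[j], min_shared)
            if math.isfinite(r):
                vals.append(r)
        if not vals:
            return (math.nan, 0)
        return (float(np.median(vals)), len(vals))

    def draw_close():
        if not close_pairs:
            return None
        return close_pairs[int(rng.integers(len(close_pairs)))]

    n = len(genes)

    def draw_far():
        i = int(rng.integers(n))
        j = int(rng.integers(n))
        if i == j:
            return None
        d = gene_distance(genes[i], genes[j])
        return (i, j) if d >= far_min else None

    med_close, n_close = sample_median(draw_close)
    med_far, n_far = sample_median(draw_far)
    if n_close == 0 or n_far == 0:
        log.warning(
            "%s: empty distance class (close=%d, far=%d); bias set to 0",
            ann.genome_id, n_close, n_far,
        )
        return BiasEstimate(ann.genome_id, 0.0, med_close, med_far, n_close, n_far, seed)
    bias = max(0.0, med_close - med_far)
    return BiasEstimate(ann.genome_id, bias, med_close, med_far, n_close, n_far, seed)


def corrected_cofitness_profile(
    focal: str,
    table: FitnessTable,
    ann: GenomeAnnotation | None = None,
    bias: BiasEstimate | None = None,
    min_shared: int = DEFAULT_MIN_SHARED,
    close_max: float = CLOSE_MAX_BP,
) -> CofitnessProfile:
    """Cofitness profile of ``focal`` against all other genes with data.

    When ``bias`` (and an annotation) is given, the bias is subtracted from
    positively cofit partners at most ``close_max`` bp from the focal gene;
    negative correlations and distant partners are untouched.  Ranks are
    competition ranks over the corrected values.
    """
    if focal not in table:
        raise KeyError(f"focal gene {focal!r} has no fitness data")
    partner_ids = [g for g in table.gene_ids if g != focal]
    mat = table.fitness.loc[partner_ids].to_numpy(dtype=float)
    focal_row = table.fitness_row(focal)
    raw, m = _profile_correlations(focal_row, mat, min_shared)

    corrected = raw.copy()
    if bias is not None and bias.bias > 0:
        if ann is None:
            raise ValueError("bias correction requires a genome annotation")
        if focal in ann:
            fg = ann[focal]
            near = np.zeros(len(partner_ids), dtype=bool)
            for k, pid in enumerate(partner_ids):
                if pid in ann and gene_distance(fg, ann[pid]) <= close_max:
                    near[k] = True
            apply = near & (raw > 0)
            corrected[apply] = raw[apply] - bias.bias
    rank, anti = _competition_ranks(corrected)
    return CofitnessProfile(
        focal_gene=focal,
        partner_ids=partner_ids,
        raw=raw,
        corrected=corrected,
        m_shared=m,
        rank=rank,
        anti_rank=anti,
    )
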