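"""Propagating regulatory predictions between organisms.

A prediction made in a source organism is carried to a target organism when
(1) both the TF and the target map through reciprocal-best-hit (RBH)
protein orthology, and (2) the TF's binding motif is found upstream of the
target's ortholog with an empirical genome-wide p-value <= 0.01.

Orthology uses Smith-Waterman local alignment (BLOSUM62, affine gaps
open 11 / extend 1) with Karlin-Altschul bit scores and E-values, filtered
at E <= 1e-5, identity >= 50% and query coverage >= 80% in both directions.
Motif hits are the best log-odds PWM score over both strands of the 250 bp
upstream of each potential-operon start the target belongs to; the
empirical p-value is the fraction of genes genome-wide whose best hit
scores at least as well (the target's own operon mates excluded).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .data_io import GenomeAnnotation, PredictionRecord, PredictionSet, Pwm
from .genome_context import PotentialOperon, maximal_runs

__all__ = [
    "AlignParams",
    "OrthologPair",
    "MotifHit",
    "align_and_score",
    "reciprocal_best_hits",
    "choose_source",
    "upstream_windows",
    "pwm_best_hit",
    "genome_best_scores",
    "motif_empirical_pvalue",
    "propagate",
]

log = logging.getLogger(__name__)

# Karlin-Altschul parameters for gapped BLOSUM62 with open 11 / extend 1
GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041

UPSTREAM_WINDOW = 250
_SCORE_TOL = 1e-6  # float slack when comparing PWM scores across strands

_VALID_AA = set("ARNDCQEGHILKMFPSTWYVBZX")


@dataclass(frozen=True)
class AlignParams:
    evalue_max: float = 1e-5
    identity_min: float = 50.0
    coverage_min: float = 80.0
    gap_open: int = 11
    gap_extend: int = 1


@dataclass(frozen=True)
class OrthologPair:
    locus_a: str
    locus_b: str
    bit_score: float
    identity: float
    coverage: float
    evalue: float


@dataclass(frozen=True)
class MotifHit:
    target_locus: str
    operon_upstream_locus: str
    position: int  # 0-based offset within the upstream window
    strand: str
    score: float
    pvalue: float | None = None


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -params.gap_open
    a.extend_gap_score = -params.gap_extend
    return a


def align_and_score(
    query: str,
    subject: str,
    params: AlignParams = AlignParams(),
    db_residues: int | None = None,
) -> tuple[float, float, float, float]:
    """Local-align two proteins; return (bit_score, identity%, coverage%, E).

    Identity is over alignment columns (gaps included in the denominator),
    coverage is the aligned query span over the query length, and the
    E-value uses Karlin-Altschul scaling with ``db_residues`` as the
    database size (defaults to the subject length).
    """
    for name, seq in (("query", query), ("subject", subject)):
        if len(seq) < 10:
            raise ValueError(f"{name} shorter than 10 residues")
        bad = set(seq.upper()) - _VALID_AA
        if bad:
            raise ValueError(f"{name} contains non-amino-acid characters {sorted(bad)}")
    aligner = _aligner(params)
    alns = aligner.align(query.upper(), subject.upper())
    aln = alns[0]
    raw = float(aln.score)
    n_db = db_residues if db_residues is not None else len(subject)
    bit = (GAPPED_LAMBDA * raw - math.log(GAPPED_K)) / math.log(2)
    evalue = GAPPED_K * len(query) * n_db * math.exp(-GAPPED_LAMBDA * raw)

    qblocks, sblocks = aln.aligned
    matches = 0
    for (qs, qe), (ss, _se) in zip(qblocks, sblocks):
        qseg = query[qs:qe].upper()
        sseg = subject[ss : ss + (qe - qs)].upper()
        matches += sum(1 for x, y in zip(qseg, sseg) if x == y)
    n_cols = aln.length
    identity = 100.0 * matches / n_cols if n_cols else 0.0
    q_span = qblocks[-1][1] - qblocks[0][0] if len(qblocks) else 0
    coverage = 100.0 * q_span / len(query)
    return (bit, identity, coverage, evalue)


def _passes(params: AlignParams, identity: float, coverage: float, evalue: float) -> bool:
    return (
        evalue <= params.evalue_max
        and identity >= params.identity_min
        and coverage >= params.coverage_min
    )


def reciprocal_best_hits(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    params: AlignParams = AlignParams(),
) -> list[OrthologPair]:
    """Reciprocal-best-hit ortholog pairs between two proteomes.

    Best hits are by raw Smith-Waterman score with a lexicographic tie-break
    on the subject locus id (logged); mutual best hits are kept only if the
    E-value / identity / coverage thresholds pass in both directions
    (coverage measured on each direction's query).
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    aligner = _aligner(params)
    ids_a = sorted(proteome_a)
    ids_b = sorted(proteome_b)
    scores = np.zeros((len(ids_a), len(ids_b)))
    for i, a in enumerate(ids_a):
        sa = proteome_a[a].upper()
        for j, b in enumerate(ids_b):
            scores[i, j] = aligner.score(sa, proteome_b[b].upper())

    def best(row: np.ndarray, labels: list[str]) -> int:
        m = row.max()
        ties = np.flatnonzero(row == m)
        if len(ties) > 1:
            log.warning("tied best hits (%s); keeping %s",
                        ", ".join(labels[t] for t in ties), labels[ties[0]])
        return int(ties[0])  # labels sorted, so first tie = lexicographic

    best_ab = {i: best(scores[i], ids_b) for i in range(len(ids_a))}
    best_ba = {j: best(scores[:, j], ids_a) for j in range(len(ids_b))}

    n_res_a = sum(len(s) for s in proteome_a.values())
    n_res_b = sum(len(s) for s in proteome_b.values())
    pairs: list[OrthologPair] = []
    for i, j in best_ab.items():
        if best_ba[j] != i:
            continue
        a, b = ids_a[i], ids_b[j]
        bit, ident, cov_ab, ev = align_and_score(
            proteome_a[a], proteome_b[b], params, db_residues=n_res_b
        )
        bit2, ident2, cov_ba, ev2 = align_and_score(
            proteome_b[b], proteome_a[a], params, db_residues=n_res_a
        )
        if _passes(params, ident, cov_ab, ev) and _passes(params, ident2, cov_ba, ev2):
            pairs.append(OrthologPair(a, b, bit, ident, min(cov_ab, cov_ba), ev))
    return pairs


def choose_source(
    tf: str,
    candidate_sources: Sequence[tuple[str, str, float, bool]],
) -> str | None:
    """Pick the source organism whose TF ortholog has the highest bit score,
    among organisms with at least one orthologous TF-target pair.

    Candidates are (organism, tf_ortholog, bit_score, has_orthologous_pair);
    ties break on organism id.  Returns None when nothing is eligible.
    """
    eligible = [c for c in candidate_sources if c[3]]
    if not eligible:
        log.info("%s: no source organism with an orthologous pair", tf)
        return None
    return min(eligible, key=lambda c: (-c[2], c[0]))[0]


def upstream_windows(
    target: str,
    ann: GenomeAnnotation,
    runs: Sequence[PotentialOperon],
    window: int = UPSTREAM_WINDOW,
    seq_lengths: Mapping[str, int] | None = None,
) -> list[tuple[str, tuple[int, int], str]]:
    """Upstream windows to scan for a target gene.

    One window (the ``window`` bp immediately 5' of the transcription start,
    strand-aware, 1-based inclusive, truncated at scaffold edges) per member
    of the target's maximal run from its 5' end down to the target itself —
    i.e. one per sub-series (potential operon) containing the target.
    """
    g = ann[target]
    run = next((r for r in runs if target in r.members), None)
    if run is None:
        raise KeyError(f"{target!r} not in any potential operon")
    out: list[tuple[str, tuple[int, int], str]] = []
    for member in run.members:  # members are 5'->3' in transcription order
        mg = ann[member]
        if mg.strand == "+":
            lo, hi = max(1, mg.begin - window), mg.begin - 1
        else:
            hi = mg.end + window
            if seq_lengths and mg.scaffold in seq_lengths:
                hi = min(hi, seq_lengths[mg.scaffold])
            lo = mg.end + 1
        if hi >= lo:
            out.append((member, (lo, hi), mg.strand))
        if member == target:
            break
    return out


_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def _scan_scores(codes: np.ndarray, lo_ext: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset of an integer-coded sequence."""
    w = lo_ext.shape[0]
    if len(codes) < w:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return lo_ext[np.arange(w)[None, :], windows].sum(axis=1)


def pwm_best_hit(
    windows: Sequence[tuple[str, tuple[int, int], str]],
    pwm: Pwm,
    seqs: Mapping[str, str],
    ann: GenomeAnnotation | None = None,
    target_locus: str = "",
) -> MotifHit | None:
    """Best log-odds PWM hit over both strands of the given windows.

    Ties break leftmost within a window, then '+' strand, then first window.
    Windows shorter than the motif are skipped; returns None if nothing is
    scorable.
    """
    lo = pwm.log_odds()
    lo_ext = np.column_stack([lo, np.full(pwm.width, -np.inf)])  # column 4 = non-ACGT
    w = pwm.width
    best: MotifHit | None = None
    for upstream_locus, (start, end), _strand in windows:
        g_scaffold = ann[upstream_locus].scaffold if ann else next(iter(seqs))
        seq = seqs[g_scaffold]
        lo_c = max(1, start)
        hi_c = min(len(seq), end)
        if hi_c - lo_c + 1 < w:
            continue
        codes = _CODE[np.frombuffer(seq[lo_c - 1 : hi_c].encode(), dtype=np.uint8)]
        fwd = _scan_scores(codes, lo_ext)
        rev = _scan_scores(_COMP[codes][::-1], lo_ext)
        L = len(codes)
        cands: list[tuple[float, int, str]] = []
        if fwd.size:
            k = int(np.argmax(fwd))
            cands.append((float(fwd[k]), k, "+"))
        if rev.size:
            k = int(np.argmax(rev))
            cands.append((float(rev[k]), L - w - k, "-"))
        if not cands:
            continue
        score, pos, strand = max(cands, key=lambda c: (c[0], -c[1], c[2] == "+"))
        if best is None or score > best.score + _SCORE_TOL:
            best = MotifHit(
                target_locus=target_locus or upstream_locus,
                operon_upstream_locus=upstream_locus,
                position=pos,
                strand=strand,
                score=score,
            )
    return best


def genome_best_scores(
    ann: GenomeAnnotation,
    runs: Sequence[PotentialOperon],
    pwm: Pwm,
    seqs: Mapping[str, str],
    window: int = UPSTREAM_WINDOW,
) -> dict[str, float | None]:
    """Best upstream PWM score for every gene in the genome (None if the
    gene has no scorable window)."""
    lengths = {sc: len(s) for sc, s in seqs.items()}
    out: dict[str, float | None] = {}
    for g in ann.genes:
        wins = upstream_windows(g.locus_id, ann, runs, window, lengths)
        hit = pwm_best_hit(wins, pwm, seqs, ann, g.locus_id)
        out[g.locus_id] = hit.score if hit else None
    return out


def motif_empirical_pvalue(
    target_hit: MotifHit,
    ann: GenomeAnnotation,
    runs: Sequence[PotentialOperon],
    pwm: Pwm,
    seqs: Mapping[str, str],
    best_scores: Mapping[str, float | None] | None = None,
    window: int = UPSTREAM_WINDOW,
) -> float:
    """Fraction of genes genome-wide whose best upstream hit scores at least
    as well as the target's.

    Genes co-operonic with the target are excluded from numerator and
    denominator — except the target itself, which ties itself, so the
    minimum attainable p is 1/(genes scored).  Genes with no scorable
    window count as scoring below.
    """
    if best_scores is None:
        best_scores = genome_best_scores(ann, runs, pwm, seqs, window)
    target = target_hit.target_locus
    run = next((r for r in runs if target in r.members), None)
    excluded = set(run.members) - {target} if run else set()
    n_scored = 0
    n_ge = 0
    for locus, score in best_scores.items():
        if locus in excluded:
            continue
        n_scored += 1
        if score is not None and score >= target_hit.score - _SCORE_TOL:
            n_ge += 1
    if n_scored == 0:
        return 1.0
    return max(n_ge, 1) / n_scored


def propagate(
    source_predictions: PredictionSet,
    target_ann: GenomeAnnotation,
    target_seqs: Mapping[str, str],
    pwms: Mapping[str, Pwm],
    ortholog_map: Mapping[str, str] | None = None,
    source_proteins: Mapping[str, str] | None = None,
    target_proteins: Mapping[str, str] | None = None,
    params: AlignParams = AlignParams(),
    alpha: float = 0.01,
    window: int = UPSTREAM_WINDOW,
) -> tuple[PredictionSet, list[dict]]:
    """Propagate predictions into a target organism.

    Orthology comes from ``ortholog_map`` (source locus -> target locus) or,
    if absent, from an RBH run over the supplied proteomes.  An orthologous
    TF-target pair becomes a propagated prediction when the source motif has
    an upstream hit near the target ortholog with empirical p <= ``alpha``.
    Returns the propagated PredictionSet plus per-pair details.
    """
    if ortholog_map is None:
        if source_proteins is None or target_proteins is None:
            raise ValueError(
                "need either an ortholog_map or both proteomes for RBH"
            )
        pairs = reciprocal_best_hits(source_proteins, target_proteins, params)
        ortholog_map = {p.locus_a: p.locus_b for p in pairs}

    runs = maximal_runs(target_ann)
    score_cache: dict[str, dict[str, float | None]] = {}
    details: list[dict] = []
    records: list[PredictionRecord] = []
    for pred in source_predictions:
        tf_orth = ortholog_map.get(pred.tf_locus)
        if tf_orth is None or pred.motif_id is None:
            continue
        pwm = pwms.get(pred.motif_id)
        if pwm is None:
            raise KeyError(f"no PWM for motif {pred.motif_id!r}")
        if pred.motif_id not in score_cache:
            score_cache[pred.motif_id] = genome_best_scores(
                target_ann, runs, pwm, target_seqs, window
            )
        best = score_cache[pred.motif_id]
        kept: list[str] = []
        for t in pred.targets:
            t_orth = ortholog_map.get(t)
            if t_orth is None or t_orth not in target_ann:
                continue
            wins = upstream_windows(
                t_orth, target_ann, runs, window,
                {sc: len(s) for sc, s in target_seqs.items()},
            )
            hit = pwm_best_hit(wins, pwm, target_seqs, target_ann, t_orth)
            if hit is None:
                continue
            p = motif_empirical_pvalue(
                hit, target_ann, runs, pwm, target_seqs, best_scores=best
            )
            details.append(
                {
                    "tf": pred.tf_locus, "tf_ortholog": tf_orth,
                    "target": t, "target_ortholog": t_orth,
                    "score": hit.score, "pvalue": p,
                }
            )
            if p <= alpha:
                kept.append(t_orth)
        if kept:
            records.append(
                PredictionRecord(
                    tf_locus=tf_orth,
                    group_id=pred.group_id,
                    annotated_sign=pred.annotated_sign,
                    targets=tuple(kept),
                    motif_id=pred.motif_id,
                )
            )
    return PredictionSet(records), details
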