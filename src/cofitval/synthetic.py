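"""Synthetic genomes, proteomes, sequences and fitness compendia with known
ground truth.

The generator emulates the statistical structure the validation method is
built on: TF rows correlated (positively or negatively) with a planted
target, polar leakage of a downstream operon member's fitness into the TF,
a small extra correlation between chromosomally close gene pairs, operon
geometry with short intra-operon gaps, and motif sites planted in upstream
windows.  All correlations are induced by shared latent factors, so the
implied covariance is positive-semidefinite by construction.

Every emitted object is in the exact in-memory/file forms the rest of the
package consumes, and :class:`GroundTruth` records what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .data_io import (
    FitnessTable,
    GeneRecord,
    GenomeAnnotation,
    PredictionRecord,
    PredictionSet,
    Pwm,
)

__all__ = [
    "TfSpec",
    "MotifSpec",
    "SimulationConfig",
    "PlantedTf",
    "GroundTruth",
    "simulate_genome",
    "simulate_fitness",
    "make_null_compendium",
    "predictions_from_truth",
    "derive_ortholog_copy",
    "mutate_protein",
    "strong_pwm",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class TfSpec:
    """One planted transcription factor.

    ``coupling`` is the target correlation between the TF and its first
    (primary) target; negative sign means repressor-like anti-cofitness.
    ``polar`` places the TF inside a multi-gene operon and ``polar_leak``
    mixes that fraction (in correlation units) of the downstream member's
    fitness into the TF row, always with positive sign.
    """

    sign: str = "activator"
    n_targets: int = 3
    coupling: float = 0.8
    polar: bool = False
    polar_leak: float = 0.0

    def __post_init__(self):
        if not -1 < self.coupling < 1:
            raise ValueError("coupling must be in (-1, 1)")
        if self.coupling**2 + self.polar_leak**2 > 1:
            raise ValueError("coupling^2 + polar_leak^2 must be <= 1")


@dataclass(frozen=True)
class MotifSpec:
    """Motif sites to plant in upstream windows.

    ``planting_fraction`` of the eligible genes (prediction targets when
    ``plant_in='targets'``, all genes otherwise) receive one consensus site
    at a random offset/strand in the 250 bp upstream of their start;
    ``scramble`` shuffles each site's letters before insertion (same
    composition, no motif).
    """

    pwm: Pwm
    planting_fraction: float = 1.0
    plant_in: str = "targets"
    scramble: bool = False


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_scaffolds: int = 1
    n_experiments: int = 100
    mean_operon_len: float = 1.0
    gene_len: tuple[int, int] = (300, 1500)
    intra_gap: tuple[int, int] = (20, 200)
    inter_gap: tuple[int, int] = (300, 800)
    tf_specs: tuple[TfSpec, ...] = ()
    bias_amplitude: float = 0.0
    bias_length_scale: float = 40_000.0
    noise_sd: float = 1.0
    pseudo_replicates: int = 4
    motif: MotifSpec | None = None
    protein_len: int = 120
    make_proteins: bool = False
    make_sequence: bool = True
    seed: int = 0
    genome_id: str = "synth"

    def __post_init__(self):
        if not 0 <= self.bias_amplitude < 1:
            raise ValueError("bias_amplitude must be in [0, 1)")
        if self.motif and not 0 <= self.motif.planting_fraction <= 1:
            raise ValueError("planting fraction must be in [0, 1]")


@dataclass
class PlantedTf:
    tf_locus: str
    sign: str
    targets: tuple[str, ...]
    coupling: float
    polar_member: str | None = None
    polar_leak: float = 0.0


@dataclass
class GroundTruth:
    tfs: list[PlantedTf] = field(default_factory=list)
    bias_amplitude: float = 0.0
    motif_sites: dict[str, tuple[str, int, str]] = field(default_factory=dict)
    operon_members: list[tuple[str, ...]] = field(default_factory=list)
    ortholog_map: dict[str, str] | None = None


def strong_pwm(consensus: str = "TTGACACGTGTCAA", motif_id: str = "synthM1") -> Pwm:
    """A near-consensus PWM usable for planting easily detectable sites.

    Per-position probabilities are deliberately heterogeneous (major allele
    0.85-0.94, unequal minor alleles) so that hit scores are effectively
    continuous; a homogeneous matrix would put all scores on a small lattice
    of match counts and create massive ties in empirical p-values.
    """
    idx = {b: i for i, b in enumerate("ACGT")}
    majors = [0.85, 0.88, 0.91, 0.94]
    minors = [0.55, 0.30, 0.15]
    probs = np.zeros((len(consensus), 4))
    for p, base in enumerate(consensus):
        major = majors[p % len(majors)]
        rest = [i for i in range(4) if i != idx[base]]
        for k, i in enumerate(rest):
            probs[p, i] = (1 - major) * minors[(k + p) % 3]
        probs[p, idx[base]] = major
    return Pwm(motif_id, probs, pseudocount=0.0)


# ---------------------------------------------------------------------------
# genome layout


def _operon_sizes(rng: np.random.Generator, n_genes: int, mean_len: float) -> list[int]:
    if mean_len <= 1.0:
        return [1] * n_genes
    sizes: list[int] = []
    total = 0
    p = 1.0 / mean_len
    while total < n_genes:
        k = min(int(rng.geometric(p)), 8, n_genes - total)
        sizes.append(k)
        total += k
    return sizes


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeAnnotation, dict[str, str], dict[str, str], GroundTruth]:
    """Lay out a genome, plant TFs/operons/motif sites, and emit annotation,
    scaffold sequences, proteins (optional) and the ground truth."""
    rng = np.random.default_rng(config.seed)
    n_per = [config.n_genes // config.n_scaffolds] * config.n_scaffolds
    n_per[0] += config.n_genes - sum(n_per)

    genes: list[GeneRecord] = []
    operons: list[list[str]] = []  # transcription order
    seq_arrays: dict[str, np.ndarray] = {}
    gi = 0
    for s in range(config.n_scaffolds):
        scaffold = f"sc{s + 1}"
        pos = 400 + int(rng.integers(*config.inter_gap))
        scaffold_genes: list[GeneRecord] = []
        remaining = n_per[s]
        for size in _operon_sizes(rng, remaining, config.mean_operon_len):
            strand = "+" if rng.random() < 0.5 else "-"
            block: list[GeneRecord] = []
            for k in range(size):
                length = int(rng.integers(*config.gene_len))
                g = GeneRecord(
                    locus_id=f"{config.genome_id}_{gi + 1:05d}",
                    scaffold=scaffold,
                    begin=pos,
                    end=pos + length - 1,
                    strand=strand,
                    description="synthetic gene",
                )
                block.append(g)
                gi += 1
                gap = int(
                    rng.integers(*config.intra_gap)
                    if k < size - 1
                    else rng.integers(*config.inter_gap)
                )
                pos = g.end + 1 + gap
            scaffold_genes.extend(block)
            ordered = block if strand == "+" else list(reversed(block))
            operons.append([g.locus_id for g in ordered])
        genes.extend(scaffold_genes)
        if config.make_sequence or config.motif is not None:
            seq_len = scaffold_genes[-1].end + 500 if scaffold_genes else 1000
            seq_arrays[scaffold] = _BASES[rng.integers(0, 4, size=seq_len)].copy()

    ann = GenomeAnnotation(config.genome_id, genes)
    truth = GroundTruth(
        bias_amplitude=config.bias_amplitude,
        operon_members=[tuple(o) for o in operons],
    )

    _assign_tfs(rng, config, ann, operons, truth)
    if config.motif is not None:
        _plant_motif_sites(rng, config, ann, truth, seq_arrays)

    seqs = {sc: arr.tobytes().decode("ascii") for sc, arr in seq_arrays.items()}
    proteins: dict[str, str] = {}
    if config.make_proteins:
        for g in ann.genes:
            proteins[g.locus_id] = "".join(
                rng.choice(list(_AA), size=config.protein_len)
            )
    return ann, seqs, proteins, truth


def _assign_tfs(rng, config, ann, operons, truth) -> None:
    run_of = {loc: i for i, op in enumerate(operons) for loc in op}
    multi = [i for i, op in enumerate(operons) if len(op) >= 2]
    rng.shuffle(multi)
    taken: set[str] = set()
    all_loci = [g.locus_id for g in ann.genes]

    polar_specs = [s for s in config.tf_specs if s.polar]
    plain_specs = [s for s in config.tf_specs if not s.polar]
    if len(polar_specs) > len(multi):
        raise ValueError(
            f"{len(polar_specs)} polar TFs requested but only {len(multi)} "
            "multi-gene operons laid out; raise mean_operon_len or n_genes"
        )

    def sample_targets(tf_locus, n, forbidden):
        pool = [
            x for x in all_loci
            if x not in forbidden and x not in taken and run_of[x] != run_of[tf_locus]
        ]
        picked = rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in picked]

    for spec in polar_specs:
        op = operons[multi.pop()]
        tf_locus, member = op[0], op[1]  # TF 5' of its co-transcribed member
        taken.update(op)
        extra = sample_targets(tf_locus, max(0, spec.n_targets - 1), set(op))
        targets = tuple([member] + extra)
        taken.update(targets)
        truth.tfs.append(
            PlantedTf(tf_locus, spec.sign, targets, spec.coupling, member, spec.polar_leak)
        )

    free = [x for x in all_loci if x not in taken]
    rng.shuffle(free)
    for spec in plain_specs:
        tf_locus = free.pop()
        taken.add(tf_locus)
        targets = tuple(sample_targets(tf_locus, spec.n_targets, {tf_locus}))
        taken.update(targets)
        truth.tfs.append(PlantedTf(tf_locus, spec.sign, targets, spec.coupling))


def _plant_motif_sites(rng, config, ann, truth, seq_arrays) -> None:
    spec = config.motif
    if spec.plant_in == "targets":
        eligible = sorted({t for tf in truth.tfs for t in tf.targets})
    else:
        eligible = [g.locus_id for g in ann.genes]
    n_plant = int(round(spec.planting_fraction * len(eligible)))
    chosen = [eligible[i] for i in rng.choice(len(eligible), size=n_plant, replace=False)]
    site = spec.pwm.consensus()
    comp = str.maketrans("ACGT", "TGCA")
    for locus in chosen:
        g = ann[locus]
        w = len(site)
        if g.strand == "+":
            lo, hi = max(1, g.begin - 250), g.begin - 1
        else:
            lo, hi = g.end + 1, min(len(seq_arrays[g.scaffold]), g.end + 250)
        if hi - lo + 1 < w:
            continue
        start = int(rng.integers(lo, hi - w + 2))  # 1-based site start
        strand = "+" if rng.random() < 0.5 else "-"
        placed = site if strand == "+" else site.translate(comp)[::-1]
        if spec.scramble:
            letters = list(placed)
            rng.shuffle(letters)
            placed = "".join(letters)
        arr = seq_arrays[g.scaffold]
        arr[start - 1 : start - 1 + w] = np.frombuffer(placed.encode(), dtype="S1")
        truth.motif_sites[locus] = (g.scaffold, start, strand)


# ---------------------------------------------------------------------------
# fitness


def simulate_fitness(
    ann: GenomeAnnotation, truth: GroundTruth, config: SimulationConfig
) -> FitnessTable:
    """Draw a fitness compendium realizing the planted correlation structure.

    Non-TF rows are unit-variance Gaussians, optionally sharing a positional
    Gaussian-process factor (squared-exponential kernel) so that pairs
    within ~20 kb correlate at ~``bias_amplitude``.  Each TF row is
    ``sign*c*primary_target + leak*polar_member + noise``, normalized to
    unit variance, so realized cofitness ~ the configured coupling.
    t statistics are ``fitness * sqrt(pseudo_replicates) / noise_sd``.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    loci = [g.locus_id for g in ann.genes]
    idx = {loc: i for i, loc in enumerate(loci)}
    G, E = len(loci), config.n_experiments
    rows = rng.standard_normal((G, E))

    b = config.bias_amplitude
    if b > 0:
        sb, snoise = math.sqrt(b), math.sqrt(1 - b)
        for scaffold in ann.scaffolds:
            sg = ann.genes_on(scaffold)
            mids = np.array([g.midpoint for g in sg])
            d = np.abs(mids[:, None] - mids[None, :])
            K = np.exp(-((d / config.bias_length_scale) ** 2))
            K[np.diag_indices_from(K)] += 1e-8
            L = np.linalg.cholesky(K)
            gp = L @ rng.standard_normal((len(sg), E))
            ii = [idx[g.locus_id] for g in sg]
            rows[ii] = sb * gp + snoise * rows[ii]

    for tf in truth.tfs:
        parts = np.zeros(E)
        var = 0.0
        c = tf.coupling
        if c != 0 and tf.targets:
            s = 1.0 if tf.sign == "activator" else -1.0
            parts = parts + s * abs(c) * rows[idx[tf.targets[0]]]
            var += c * c
        if tf.polar_member is not None and tf.polar_leak > 0:
            parts = parts + tf.polar_leak * rows[idx[tf.polar_member]]
            var += tf.polar_leak**2
        rows[idx[tf.tf_locus]] = parts + math.sqrt(max(0.0, 1 - var)) * rng.standard_normal(E)

    exps = [f"exp{j + 1:03d}" for j in range(E)]
    fit = pd.DataFrame(rows, index=loci, columns=exps)
    t = fit * (math.sqrt(config.pseudo_replicates) / config.noise_sd)
    return FitnessTable(ann.genome_id, fit, t)


def make_null_compendium(
    n_genes: int,
    n_experiments: int,
    seed: int = 0,
    genome_id: str = "null",
    pseudo_replicates: int = 4,
    noise_sd: float = 1.0,
) -> FitnessTable:
    """Independent Gaussian fitness values with consistent t statistics."""
    rng = np.random.default_rng(seed)
    loci = [f"{genome_id}_{i + 1:05d}" for i in range(n_genes)]
    exps = [f"exp{j + 1:03d}" for j in range(n_experiments)]
    fit = pd.DataFrame(
        rng.standard_normal((n_genes, n_experiments)), index=loci, columns=exps
    )
    t = fit * (math.sqrt(pseudo_replicates) / noise_sd)
    return FitnessTable(genome_id, fit, t)


def predictions_from_truth(truth: GroundTruth, motif_id: str | None = None) -> PredictionSet:
    """The planted TF->targets map as a PredictionSet (the objects under test)."""
    recs = [
        PredictionRecord(
            tf_locus=tf.tf_locus,
            group_id=f"RG{i + 1:04d}",
            annotated_sign=tf.sign if tf.sign in ("activator", "repressor") else "unknown",
            targets=tf.targets,
            motif_id=motif_id,
        )
        for i, tf in enumerate(truth.tfs)
    ]
    return PredictionSet(recs)


def mutate_protein(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute residues uniformly so expected identity is ``identity``."""
    out = list(seq)
    for i in range(len(out)):
        if rng.random() > identity:
            choices = _AA.replace(out[i], "")
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def derive_ortholog_copy(
    ann: GenomeAnnotation,
    proteins: dict[str, str],
    identity: float = 0.9,
    prefix: str = "org2",
    seed: int = 0,
) -> tuple[GenomeAnnotation, dict[str, str], dict[str, str]]:
    """A second organism as a renamed copy of the first, proteins mutated to
    the requested identity.  Returns (annotation, proteins, ortholog map
    old->new)."""
    rng = np.random.default_rng(seed)
    mapping = {g.locus_id: f"{prefix}_{i + 1:05d}" for i, g in enumerate(ann.genes)}
    genes = [
        GeneRecord(mapping[g.locus_id], g.scaffold, g.begin, g.end, g.strand, g.description)
        for g in ann.genes
    ]
    prots = {
        mapping[loc]: mutate_protein(p, identity, rng) for loc, p in proteins.items()
    }
    return GenomeAnnotation(prefix, genes), prots, mapping
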