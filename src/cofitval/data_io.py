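"""Core domain types and readers/writers for the external file formats.

The package works with five kinds of objects:

* :class:`FitnessTable` — a genes x experiments matrix of gene fitness values
  (log2 strain-abundance ratios from pooled transposon-mutant assays) plus a
  parallel matrix of t-like statistics, read from Fitness-Browser-style TSVs.
* :class:`GenomeAnnotation` — ordered gene coordinates per scaffold, read from
  a simple tab format or GFF3.  Coordinates are 1-based inclusive everywhere.
* :class:`PredictionSet` — TF -> targets regulatory predictions under test.
* :class:`Pwm` — a position weight matrix with background model (MEME minimal).
* :class:`AssociationMatrix` — a generic symmetric gene x gene correlation
  matrix (e.g. coexpression), usable in place of cofitness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs

__all__ = [
    "FormatError",
    "GeneRecord",
    "GenomeAnnotation",
    "FitnessTable",
    "PredictionRecord",
    "PredictionSet",
    "Pwm",
    "AssociationMatrix",
    "read_fitness_table",
    "read_genome_annotation",
    "read_pwm_meme",
    "read_predictions",
    "read_protein_fasta",
    "read_nucleotide_fasta",
    "read_association_matrix",
    "write_results",
    "read_results",
    "write_predictions",
]

ALPHABET = "ACGT"
SIGNS = ("activator", "repressor", "dual", "unknown")


class FormatError(ValueError):
    """A file did not conform to the expected format."""


def _norm_strand(s: str) -> str:
    s = s.strip()
    if s in ("+",):
        return "+"
    if s in ("-", "−"):  # ASCII hyphen or unicode minus
        return "-"
    raise FormatError(f"unknown strand symbol {s!r} (expected '+' or '-')")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene; coordinates 1-based inclusive on its scaffold."""

    locus_id: str
    scaffold: str
    begin: int
    end: int
    strand: str
    description: str = ""
    protein: str | None = None

    def __post_init__(self) -> None:
        if self.begin > self.end:
            raise FormatError(
                f"{self.locus_id}: begin {self.begin} > end {self.end}"
            )
        object.__setattr__(self, "strand", _norm_strand(self.strand))

    @property
    def midpoint(self) -> float:
        return (self.begin + self.end) / 2.0

    @property
    def tss(self) -> int:
        """Transcriptional start coordinate (strand-aware)."""
        return self.begin if self.strand == "+" else self.end


class GenomeAnnotation:
    """Ordered gene annotation for one genome, grouped by scaffold."""

    def __init__(self, genome_id: str, genes: Iterable[GeneRecord]):
        self.genome_id = genome_id
        genes = list(genes)
        seen: set[str] = set()
        for g in genes:
            if g.locus_id in seen:
                raise FormatError(f"duplicate locus_id {g.locus_id!r}")
            seen.add(g.locus_id)
        self.genes: list[GeneRecord] = sorted(
            genes, key=lambda g: (g.scaffold, g.begin, g.end)
        )
        self._by_locus = {g.locus_id: g for g in self.genes}
        self._by_scaffold: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            self._by_scaffold.setdefault(g.scaffold, []).append(g)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_locus

    def __getitem__(self, locus_id: str) -> GeneRecord:
        try:
            return self._by_locus[locus_id]
        except KeyError:
            raise KeyError(
                f"locus {locus_id!r} not in annotation of {self.genome_id}"
            ) from None

    @property
    def scaffolds(self) -> list[str]:
        return list(self._by_scaffold)

    def genes_on(self, scaffold: str) -> list[GeneRecord]:
        return self._by_scaffold.get(scaffold, [])


class FitnessTable:
    """Genes x experiments fitness values with parallel t statistics.

    Both matrices are pandas DataFrames indexed by locus id with one column
    per experiment; missing values are NaN and are carried, never imputed.
    """

    def __init__(self, genome_id: str, fitness: pd.DataFrame, t_stats: pd.DataFrame):
        if list(fitness.index) != list(t_stats.index):
            raise FormatError(
                "fitness and t tables index different genes; first difference: "
                + _first_diff(fitness.index, t_stats.index)
            )
        if list(fitness.columns) != list(t_stats.columns):
            raise FormatError(
                "fitness and t tables have different experiments; first difference: "
                + _first_diff(fitness.columns, t_stats.columns)
            )
        for name, df in (("fitness", fitness), ("t", t_stats)):
            vals = df.to_numpy(dtype=float)
            bad = np.isinf(vals)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise FormatError(
                    f"non-finite {name} value at gene {df.index[i]!r}, "
                    f"experiment {df.columns[j]!r}"
                )
        self.genome_id = genome_id
        self.fitness = fitness.astype(float)
        self.t_stats = t_stats.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fitness.index)

    @property
    def experiment_ids(self) -> list[str]:
        return list(self.fitness.columns)

    @property
    def n_genes(self) -> int:
        return self.fitness.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.fitness.shape[1]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.fitness.index

    def fitness_row(self, locus_id: str) -> np.ndarray:
        return self.fitness.loc[locus_id].to_numpy(dtype=float)

    def t_row(self, locus_id: str) -> np.ndarray:
        return self.t_stats.loc[locus_id].to_numpy(dtype=float)


@dataclass(frozen=True)
class PredictionRecord:
    """One TF-motif prediction: a TF and its predicted target genes."""

    tf_locus: str
    group_id: str = ""
    annotated_sign: str = "unknown"
    targets: tuple[str, ...] = ()
    motif_id: str | None = None

    def __post_init__(self) -> None:
        if self.annotated_sign not in SIGNS:
            raise FormatError(
                f"annotated sign {self.annotated_sign!r} not one of {SIGNS}"
            )
        object.__setattr__(self, "targets", tuple(self.targets))


@dataclass
class PredictionSet:
    records: list[PredictionRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


class Pwm:
    """Position weight matrix over ACGT with background and pseudocount.

    ``probs`` holds the pseudocount-mixed, re-normalized probabilities; rows
    (positions) sum to one.  Scores are log2 odds against ``background``.
    """

    def __init__(
        self,
        motif_id: str,
        probs: np.ndarray,
        background: Sequence[float] | None = None,
        pseudocount: float = 0.5,
    ):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise FormatError("PWM must be width x 4 over A,C,G,T")
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
            raise FormatError(f"PWM {motif_id}: a row does not sum to 1")
        if pseudocount < 0:
            raise FormatError("pseudocount must be nonnegative")
        bg = (
            np.full(4, 0.25)
            if background is None
            else np.asarray(background, dtype=float)
        )
        if abs(bg.sum() - 1.0) > 1e-9:
            raise FormatError("background frequencies must sum to 1")
        # mix in pseudocount mass and re-normalize
        mixed = probs + pseudocount * bg
        mixed /= mixed.sum(axis=1, keepdims=True)
        self.motif_id = motif_id
        self.probs = mixed
        self.background = bg
        self.pseudocount = float(pseudocount)
        if pseudocount == 0 and np.any(probs == 0):
            self.has_zeros = True
        else:
            self.has_zeros = False

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """width x 4 matrix of log2(p / background); -inf if zeros remain."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


class AssociationMatrix:
    """Symmetric gene x gene association (e.g. coexpression correlation)."""

    def __init__(self, values: pd.DataFrame):
        if list(values.index) != list(values.columns):
            raise FormatError("association matrix must have matching row/col ids")
        arr = values.to_numpy(dtype=float)
        both = np.isfinite(arr) & np.isfinite(arr.T)
        if np.nanmax(np.abs(np.where(both, arr - arr.T, 0.0)), initial=0.0) > 1e-9:
            raise FormatError("association matrix not symmetric")
        diag = np.diag(arr)
        if np.any(np.abs(diag[np.isfinite(diag)] - 1.0) > 1e-9):
            raise FormatError("association matrix diagonal must be 1 where defined")
        self.values = values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def row(self, locus_id: str) -> np.ndarray:
        return self.values.loc[locus_id].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers


def _first_diff(a: Iterable, b: Iterable) -> str:
    sa, sb = list(a), list(b)
    only_a = [x for x in sa if x not in set(sb)]
    only_b = [x for x in sb if x not in set(sa)]
    if only_a:
        return f"{only_a[0]!r} only in first"
    if only_b:
        return f"{only_b[0]!r} only in second"
    return "same sets, different order"


_META_COLUMNS = ("locusId", "sysName", "desc", "geneName", "locus_id")


def _read_fitness_tsv(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", ""], keep_default_na=True)
    id_col = next((c for c in ("locusId", "locus_id") if c in df.columns), None)
    if id_col is None:
        raise FormatError(f"{what} table {path}: no locusId column")
    df = df.set_index(id_col)
    df = df.drop(columns=[c for c in _META_COLUMNS if c in df.columns])
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise FormatError(
                f"{what} table {path}: non-numeric value {bad.iloc[0]!r} at gene "
                f"{bad.index[0]!r}, experiment {col!r}"
            ) from None
    return out


def read_fitness_table(
    fitness_path: str | Path, t_path: str | Path, genome_id: str | None = None
) -> FitnessTable:
    """Read paired fitness / t-statistic TSVs (Fitness-Browser style).

    Both files are tab-separated with a ``locusId`` column (``sysName`` /
    ``desc`` columns are tolerated and dropped) and one column per experiment.
    Empty cells and ``NA`` become missing values.
    """
    fit = _read_fitness_tsv(fitness_path, "fitness")
    t = _read_fitness_tsv(t_path, "t")
    gid = genome_id or Path(fitness_path).stem
    return FitnessTable(gid, fit, t)


def read_genome_annotation(
    path: str | Path, format: str = "tab", genome_id: str | None = None
) -> GenomeAnnotation:
    """Read gene coordinates from tab (locus/scaffold/begin/end/strand) or GFF3."""
    gid = genome_id or Path(path).stem
    if format == "tab":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"locusId", "scaffoldId", "begin", "end", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"annotation {path}: missing columns {sorted(missing)}")
        genes = [
            GeneRecord(
                locus_id=row.locusId,
                scaffold=row.scaffoldId,
                begin=int(row.begin),
                end=int(row.end),
                strand=row.strand,
                description=getattr(row, "desc", "") or "",
            )
            for row in df.itertuples()
        ]
        return GenomeAnnotation(gid, genes)
    if format == "gff3":
        return _read_gff3(path, gid)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_gff3(path: str | Path, genome_id: str) -> GenomeAnnotation:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{ln}: GFF3 line has {len(parts)} fields")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in ("gene", "CDS"):
                continue
            attr = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr[k.strip()] = v.strip()
            locus = attr.get("locus_tag") or attr.get("ID") or attr.get("Name")
            if locus is None:
                raise FormatError(f"{path}:{ln}: no ID/locus_tag attribute")
            genes.append(
                GeneRecord(
                    locus_id=locus,
                    scaffold=seqid,
                    begin=int(start),
                    end=int(end),
                    strand=strand,
                    description=attr.get("product", ""),
                )
            )
    # a file may carry both gene and CDS rows for the same locus; keep first
    uniq: dict[str, GeneRecord] = {}
    for g in genes:
        uniq.setdefault(g.locus_id, g)
    return GenomeAnnotation(genome_id, uniq.values())


def read_pwm_meme(
    path: str | Path,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.5,
) -> list[Pwm]:
    """Parse motifs from a MEME minimal format file into :class:`Pwm` objects.

    ``background`` defaults to the background block of the file when present,
    else uniform.  A pseudocount of 0 with zero matrix entries is allowed here
    but flagged on the Pwm (scores involving those cells are -inf).
    """
    with open(path) as fh:
        try:
            records = motifs.parse(fh, "minimal")
        except Exception as exc:  # biopython raises bare ValueError subtypes
            raise FormatError(f"{path}: not a MEME minimal motif file ({exc})") from exc
    out: list[Pwm] = []
    for m in records:
        letters = "".join(sorted(m.alphabet))
        if letters != ALPHABET:
            raise FormatError(
                f"{path}: unsupported alphabet {m.alphabet!r} (only ACGT)"
            )
        probs = np.column_stack([list(m.pwm[b]) for b in ALPHABET])
        if background is None and getattr(m, "background", None):
            bg = np.array([m.background[b] for b in ALPHABET], dtype=float)
            bg = bg / bg.sum()
        elif background is None:
            bg = None
        else:
            bg = background
        out.append(Pwm(m.name or f"motif_{len(out) + 1}", probs, bg, pseudocount))
    if not out:
        raise FormatError(f"{path}: file contains no motifs")
    return out


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_nucleotide_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_predictions(path: str | Path) -> PredictionSet:
    """Read predictions from TSV (tf_locus, group_id, sign, motif_id, targets)
    or from an equivalent JSON list of records."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        recs = [
            PredictionRecord(
                tf_locus=d["tf_locus"],
                group_id=d.get("group_id", ""),
                annotated_sign=d.get("annotated_sign", "unknown"),
                targets=tuple(d.get("targets", ())),
                motif_id=d.get("motif_id"),
            )
            for d in data
        ]
        return PredictionSet(recs)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "tf_locus" not in df.columns or "targets" not in df.columns:
        raise FormatError(f"{path}: predictions TSV needs tf_locus and targets columns")
    recs = []
    for row in df.itertuples():
        targets = tuple(t for t in row.targets.split(",") if t)
        recs.append(
            PredictionRecord(
                tf_locus=row.tf_locus,
                group_id=getattr(row, "group_id", ""),
                annotated_sign=getattr(row, "sign", "") or "unknown",
                targets=targets,
                motif_id=getattr(row, "motif_id", "") or None,
            )
        )
    return PredictionSet(recs)


def write_predictions(preds: PredictionSet, path: str | Path) -> None:
    rows = [
        {
            "tf_locus": r.tf_locus,
            "group_id": r.group_id,
            "sign": r.annotated_sign,
            "motif_id": r.motif_id or "",
            "targets": ",".join(r.targets),
        }
        for r in preds
    ]
    pd.DataFrame(rows, columns=["tf_locus", "group_id", "sign", "motif_id", "targets"]).to_csv(
        path, sep="\t", index=False
    )


def read_association_matrix(path: str | Path) -> AssociationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AssociationMatrix(df)


# ---------------------------------------------------------------------------
# results table

_RESULT_COLUMNS = [
    "tf_locus",
    "group_id",
    "N",
    "T",
    "M_top",
    "R",
    "R_prime",
    "r_max",
    "r_min",
    "p_rank_act",
    "p_rank_rep",
    "p_fisher_act",
    "p_fisher_rep",
    "p_activator",
    "p_repressor",
    "has_phenotype",
    "validated",
    "sign",
    "top_target_act",
    "top_target_rep",
    "polar",
]


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        if math.isnan(v):
            return ""
        return f"{v:.6g}"
    return str(v)


def write_results(results: Sequence, path: str | Path) -> None:
    """Write TfTestResult rows as a TSV with a fixed column order.

    Floats are formatted at 6 significant digits; an empty list yields a
    header-only file.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for res in results:
            row = [_fmt(getattr(res, c, None)) for c in _RESULT_COLUMNS]
            fh.write("\t".join(row) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
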