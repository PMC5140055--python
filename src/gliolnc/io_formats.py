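"""Readers and writers for every on-disk format the pipeline touches.

Formats: GTF transcript models (1-based inclusive on disk, 0-based
half-open in memory), TSV gene×sample matrices (expression FPKM, CNV
segment means, binary mutation calls), TSV clinical tables, GMT pathway
collections, and plain-text peptide lists. All readers validate structure
and raise instead of silently coercing; every writer round-trips through
its reader.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .catalog import TranscriptModel

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Columns a clinical table must provide.
CLINICAL_COLUMNS = (
    "sample",
    "time_days",
    "event",
    "age",
    "sex",
    "grade",
    "idh_mut",
    "codel_1p19q",
    "subtype",
)

ALLOWED_SEX = frozenset({"male", "female"})
ALLOWED_GRADE = frozenset({"II", "III", "IV"})


class ParseError(ValueError):
    """Structurally invalid input file."""


@dataclass
class GenomeAnnotation:
    """A collection of transcripts indexed by genomic interval.

    Transcript IDs are unique; per chromosome an interval tree over
    transcript spans supports overlap queries.
    """

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._trees and self.transcripts:
            for t in self.transcripts.values():
                self._index(t)

    def _index(self, t: TranscriptModel) -> None:
        start, end = t.span
        self._trees.setdefault(t.chrom, IntervalTree()).addi(start, end, t.id)

    def add(self, t: TranscriptModel) -> None:
        if t.id in self.transcripts:
            raise ValueError(f"duplicate transcript id {t.id!r}")
        self.transcripts[t.id] = t
        self._index(t)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._trees

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) shares ≥1 base with any transcript span."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))


@dataclass
class RunConfig:
    """Thresholds, resampling sizes, and the RNG seed for a pipeline run.

    Defaults are the study's operating points: coding-potential cutoff
    0.5242, 200 bp length floor, 0.5 FPKM expression floor, FDR 0.05 with
    four-fold change for tumor-vs-normal calls, log2 fold change 0.5 for
    mutation-associated calls, Spearman rho 0.2 for CNV linkage, and the
    100×66% subsample Cox ensemble with 80% selection frequency and the
    |Z| ≥ 1 summed-coefficient rule.
    """

    cpat_cutoff: float = 0.5242
    min_length_bp: int = 200
    min_orf_aa: int = 25
    expr_floor_fpkm: float = 0.5
    fdr_alpha: float = 0.05
    fc_min: float = 4.0
    log2fc_min: float = 0.5
    cnv_rho_min: float = 0.2
    z_cutoff: float = 1.0
    n_subsamples: int = 100
    subsample_frac: float = 0.66
    selection_freq: float = 0.80
    alpha_select: float = 0.05
    n_permutations: int = 1000
    outlier_sd_mult: float = 3.0
    outlier_max_frac: float = 0.15
    gba_top_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cpat_cutoff < 1.0:
            raise ValueError("cpat_cutoff must lie in (0,1)")
        if self.min_length_bp < 1 or self.min_orf_aa < 1:
            raise ValueError("length floors must be positive")
        for name in ("fdr_alpha", "alpha_select", "subsample_frac", "selection_freq", "gba_top_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1)")
        if self.fc_min < 1.0 or self.log2fc_min < 0.0:
            raise ValueError("fold-change thresholds out of range")
        if not -1.0 <= self.cnv_rho_min <= 1.0:
            raise ValueError("cnv_rho_min must lie in [-1,1]")
        if self.n_subsamples < 1 or self.n_permutations < 1:
            raise ValueError("resampling counts must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _parse_gtf_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> GenomeAnnotation:
    """Read exon records of a GTF file into a :class:`GenomeAnnotation`.

    Disk coordinates are 1-based inclusive; in memory exons become 0-based
    half-open (disk 101–200 → [100, 200)). Only ``exon`` features are
    consumed; every exon must carry a ``transcript_id`` attribute. Malformed
    lines raise :class:`ParseError` naming the line number.
    """
    exons_by_tx: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            if start < 1 or end < start:
                raise ParseError(f"line {lineno}: invalid 1-based interval {start}-{end}")
            attrs = _parse_gtf_attributes(attr_s, lineno)
            tx = attrs.get("transcript_id")
            if not tx:
                raise ParseError(f"line {lineno}: exon without transcript_id")
            prev = meta.get(tx)
            if prev is not None and prev != (chrom, strand):
                raise ParseError(f"line {lineno}: transcript {tx} spans chromosomes/strands")
            meta[tx] = (chrom, strand)
            if "cpat_score" in attrs:
                scores[tx] = float(attrs["cpat_score"])
            exons_by_tx.setdefault(tx, []).append((start - 1, end))
    annotation = GenomeAnnotation()
    for tx, exons in exons_by_tx.items():
        chrom, strand = meta[tx]
        annotation.add(
            TranscriptModel(
                id=tx, chrom=chrom, strand=strand, exons=tuple(sorted(exons)), cpat_score=scores.get(tx)
            )
        )
    return annotation


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path, source: str = "gliolnc") -> None:
    """Write transcripts as GTF exon records (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for i, (s, e) in enumerate(t.exons, start=1):
                attrs = f'gene_id "{t.id}"; transcript_id "{t.id}"; exon_number "{i}";'
                if t.cpat_score is not None:
                    attrs += f' cpat_score "{t.cpat_score:.6g}";'
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def _read_numeric_matrix(path: str | Path, allow_negative: bool) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene ids {dups[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ParseError(f"{path}: non-numeric cell at gene {df.index[gi]!r}, sample {df.columns[si]!r}")
    df = numeric
    values = df.to_numpy(dtype=float)
    if not allow_negative and (values < 0).any():
        gi, si = np.argwhere(values < 0)[0]
        raise ParseError(f"{path}: negative value at gene {df.index[gi]!r}, sample {df.columns[si]!r}")
    return df.astype(float)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene×sample FPKM TSV (first column gene id, header sample ids)."""
    return _read_numeric_matrix(path, allow_negative=False)


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_cnv_table(path: str | Path) -> pd.DataFrame:
    """Read a gene×sample copy-number segment-mean TSV (values may be negative)."""
    return _read_numeric_matrix(path, allow_negative=True)


def write_cnv_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene")


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    """Read a gene×sample binary mutation TSV into a boolean frame."""
    df = _read_numeric_matrix(path, allow_negative=False)
    values = df.to_numpy()
    if not np.isin(values, (0.0, 1.0)).all():
        raise ParseError(f"{path}: mutation table must contain only 0/1")
    return df.astype(bool)


def write_mutation_table(table: pd.DataFrame, path: str | Path) -> None:
    table.astype(int).to_csv(path, sep="\t", index_label="gene")


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-sample clinical TSV.

    Required columns: sample, time_days, event, age, sex, grade, idh_mut,
    codel_1p19q, subtype. ``subtype``, ``codel_1p19q`` and ``idh_mut`` may
    be "NA" (missing); times must be positive, events 0/1.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample": str, "subtype": str, "grade": str, "sex": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if df["sample"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    if df["time_days"].isna().any() or (df["time_days"] <= 0).any():
        raise ParseError(f"{path}: time_days must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ParseError(f"{path}: event must be 0 or 1")
    bad_sex = set(df["sex"].dropna()) - ALLOWED_SEX
    if bad_sex:
        raise ParseError(f"{path}: invalid sex values {sorted(bad_sex)}")
    bad_grade = set(df["grade"].dropna()) - ALLOWED_GRADE
    if bad_grade:
        raise ParseError(f"{path}: invalid grade values {sorted(bad_grade)}")
    for col in ("idh_mut", "codel_1p19q"):
        if not df[col].dropna().isin([0, 1]).all():
            raise ParseError(f"{path}: {col} must be 0, 1 or NA")
    return df.set_index("sample", drop=False)


def write_clinical_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name, description, then member genes per line."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: GMT record needs name, description and ≥1 member")
            name, _desc, *members = fields
            if name in pathways:
                raise ParseError(f"line {lineno}: duplicate pathway {name!r}")
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"line {lineno}: pathway {name!r} has no members")
            pathways[name] = set(members)
    return pathways


def write_gmt(pathways: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in pathways.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_peptides(path: str | Path) -> set[str]:
    """Read a plain-text peptide list (one uppercase amino-acid string per line)."""
    peptides: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            pep = line.strip()
            if not pep:
                continue
            bad = set(pep) - AMINO_ACIDS
            if bad:
                raise ParseError(f"line {lineno}: invalid amino-acid letters {sorted(bad)} in {pep!r}")
            peptides.add(pep)
    return peptides


def write_peptides(peptides: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{p}\n" for p in sorted(peptides)))


def write_run_manifest(config: RunConfig, path: str | Path, extra: Mapping | None = None) -> None:
    """Write the effective configuration (thresholds + seed) next to outputs."""
    payload = dataclasses.asdict(config)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
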