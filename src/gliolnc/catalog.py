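"""Novel-lncRNA catalog filtering.

A candidate transcript from a de-novo assembly is kept as a novel lncRNA
only if it survives a cascade of filters:

1. ``annotation_overlap`` — its genomic span must not intersect any
   annotated transcript (strand-agnostic, span-level).
2. ``too_short`` — summed exon length must be at least 200 bp.
3. ``no_splice_junction`` — it must have at least two exons.
4. ``coding_potential`` — its coding-potential score (a logistic
   probability supplied per transcript, e.g. from CPAT) must be below the
   noncoding/coding decision boundary (default 0.5242; a score exactly at
   the cutoff fails).
5. ``peptide_evidence`` — at most one mass-spectrometry peptide (from the
   set of peptides that do not map to any known protein) may map to the
   translated open reading frames of the transcript; two or more mapped
   peptides drop it.

The module also provides the cohort-level screens used before any
statistics are run: an expression floor (median FPKM > 0.5) and an
outlier-sample screen (a sample is removed when more than 15% of its genes
lie more than three standard deviations from the cohort mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import GenomeAnnotation, RunConfig

logger = logging.getLogger(__name__)

#: Coding-potential decision boundary separating noncoding from coding
#: transcripts; scores at or above it fail the filter.
CPAT_CUTOFF = 0.5242

#: Minimum summed exon length (bp) for a lncRNA.
MIN_LENGTH_BP = 200

#: Filter rule names, in cascade order (first failure is attributed).
RULE_ORDER = (
    "annotation_overlap",
    "too_short",
    "no_splice_junction",
    "coding_potential",
    "peptide_evidence",
)

_VALID_STRANDS = frozenset("+-")
_DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript.

    Exons are 0-based half-open intervals on the genome, sorted and
    non-overlapping. ``cpat_score`` is the coding-potential probability in
    [0, 1] if available.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cpat_score: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"transcript {self.id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.id}: must have at least one exon")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if e <= s:
                raise ValueError(f"transcript {self.id}: empty exon interval [{s},{e})")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"transcript {self.id}: exons overlap or are unsorted")
        if self.cpat_score is not None and not (0.0 <= self.cpat_score <= 1.0):
            raise ValueError(f"transcript {self.id}: cpat_score outside [0,1]")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span [min start, max end) covering all exons."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        """Summed exon length in bp."""
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class OpenReadingFrame:
    """An ATG-initiated open reading frame on a spliced transcript sequence.

    ``start``/``end`` are 0-based half-open offsets on the spliced sense
    sequence; ``end`` includes the stop codon when one was reached.
    """

    frame: int
    start: int
    end: int
    peptide: str


@dataclass
class FilterReport:
    """Outcome of the filter cascade over a candidate set."""

    verdicts: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["candidate", "keep", "failed_rule"]))

    @property
    def kept_ids(self) -> list[str]:
        return self.verdicts.loc[self.verdicts["keep"], "candidate"].tolist()

    @property
    def rule_counts(self) -> dict[str, int]:
        """Candidates dropped per rule, plus 'keep'; sums to the candidate count."""
        counts = {rule: 0 for rule in RULE_ORDER}
        counts["keep"] = 0
        for _, row in self.verdicts.iterrows():
            counts["keep" if row["keep"] else row["failed_rule"]] += 1
        return counts


def intersects_annotation(candidate: TranscriptModel, annotation: "GenomeAnnotation") -> bool:
    """True iff the candidate's span overlaps any annotated transcript span.

    Overlap is strand-agnostic and at whole-span level: a single shared base
    suffices, half-open abutment does not. A chromosome absent from the
    annotation cannot overlap and is logged.
    """
    start, end = candidate.span
    if not annotation.has_chrom(candidate.chrom):
        logger.debug("chromosome %s of %s absent from annotation", candidate.chrom, candidate.id)
        return False
    return annotation.overlaps(candidate.chrom, start, end)


def length_and_splice_filter(candidate: TranscriptModel, min_length: int = MIN_LENGTH_BP) -> tuple[bool, str | None]:
    """Length and splice-junction screens; returns (passed, failing rule).

    A candidate fails ``too_short`` when its summed exon length is below
    ``min_length`` (200 bp kept), and ``no_splice_junction`` when it is
    mono-exonic. Length is checked first.
    """
    if candidate.length < min_length:
        return False, "too_short"
    if candidate.n_exons < 2:
        return False, "no_splice_junction"
    return True, None


def coding_potential_filter(candidate: TranscriptModel, cutoff: float = CPAT_CUTOFF) -> bool:
    """True (pass) iff the coding-potential score is strictly below the cutoff.

    A score exactly at the cutoff fails: the cutoff marks the beginning of
    the "possibly coding" regime.
    """
    if candidate.cpat_score is None:
        raise ValueError(f"transcript {candidate.id}: no coding-potential score available")
    return candidate.cpat_score < cutoff


def spliced_sequence(candidate: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced sense-strand sequence of a transcript.

    Exon sequences are concatenated in genomic order; minus-strand
    transcripts are reverse-complemented so the result reads 5'→3'.
    """
    try:
        chrom_seq = genome[candidate.chrom]
    except KeyError:
        raise KeyError(f"chromosome {candidate.chrom} not in genome") from None
    seq = "".join(chrom_seq[s:e] for s, e in candidate.exons).upper()
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"transcript {candidate.id}: non-DNA characters {sorted(bad)}")
    if candidate.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


_STOPS = frozenset({"TAA", "TAG", "TGA"})


def enumerate_orfs(sequence: str, min_aa: int = 25) -> list[OpenReadingFrame]:
    """All ATG-initiated ORFs in the three sense frames of a sequence.

    Each ATG opens its own ORF (nested ORFs are all reported), translated
    with the standard genetic code up to the first stop codon or, failing
    that, to the last complete codon. ORFs whose nucleotide span contains an
    ``N`` are excluded, as are translations shorter than ``min_aa`` amino
    acids.
    """
    sequence = sequence.upper()
    bad = set(sequence) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-DNA characters {sorted(bad)}")
    orfs: list[OpenReadingFrame] = []
    n = len(sequence)
    for frame in range(3):
        for start in range(frame, n - 2, 3):
            if sequence[start : start + 3] != "ATG":
                continue
            end = start
            for pos in range(start, n - 2, 3):
                codon = sequence[pos : pos + 3]
                if codon in _STOPS:
                    end = pos + 3
                    break
                end = pos + 3
            nt = sequence[start:end]
            if "N" in nt:
                continue
            coding = nt[:-3] if nt[-3:] in _STOPS else nt
            peptide = str(Seq(coding).translate())
            if len(peptide) >= min_aa:
                orfs.append(OpenReadingFrame(frame=frame, start=start, end=end, peptide=peptide))
    return orfs


def peptide_evidence_filter(
    orfs: Sequence[OpenReadingFrame], unmatched_peptides: Iterable[str]
) -> tuple[int, bool]:
    """Count peptides mapping to the ORFs; fail when two or more map.

    ``unmatched_peptides`` are mass-spectrometry peptides that did not map
    to any known protein. A peptide "maps" when it occurs as an exact
    substring of any translated ORF. Returns (mapped count, passed); a
    single mapped peptide is tolerated.
    """
    peptides = set(unmatched_peptides)
    translations = [orf.peptide for orf in orfs]
    count = sum(1 for pep in peptides if any(pep in t for t in translations))
    return count, count < 2


def expression_floor(
    matrix: pd.DataFrame, threshold: float = 0.5, statistic: str = "median"
) -> list[str]:
    """Genes whose per-cohort summary FPKM exceeds the floor (strict >).

    ``statistic`` is ``"median"`` (default) or ``"mean"``.
    """
    if statistic == "median":
        summary = matrix.median(axis=1)
    elif statistic == "mean":
        summary = matrix.mean(axis=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return summary.index[summary > threshold].tolist()


def flag_outlier_samples(
    matrix: pd.DataFrame, sd_mult: float = 3.0, max_frac: float = 0.15
) -> list[str]:
    """Samples with an excess of extreme expression values.

    Expression is put on a log2(FPKM+1) scale; per gene, the cohort mean and
    standard deviation are computed, and a sample is flagged when the
    fraction of its genes further than ``sd_mult`` standard deviations from
    the mean strictly exceeds ``max_frac``.
    """
    if matrix.shape[1] < 3:
        raise ValueError("outlier screen needs at least 3 samples")
    log = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    mean = log.mean(axis=1, keepdims=True)
    sd = log.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        extreme = np.abs(log - mean) > sd_mult * sd
    frac = extreme.mean(axis=0)
    flagged = matrix.columns[frac > max_frac].tolist()
    if flagged:
        logger.info("outlier screen removed %d of %d samples", len(flagged), matrix.shape[1])
    return flagged


def run_catalog(
    candidates: Sequence[TranscriptModel],
    annotation: "GenomeAnnotation",
    peptides: Iterable[str] | None = None,
    genome: Mapping[str, str] | None = None,
    config: "RunConfig | None" = None,
    min_orf_aa: int | None = None,
) -> FilterReport:
    """Run the full filter cascade and report a verdict per candidate.

    Filters are applied in the documented order and the first failing rule
    is recorded. The peptide filter requires both ``genome`` (for spliced
    sequences) and ``peptides``; when either is absent it is skipped.
    """
    cutoff = config.cpat_cutoff if config is not None else CPAT_CUTOFF
    min_len = config.min_length_bp if config is not None else MIN_LENGTH_BP
    if min_orf_aa is None:
        min_orf_aa = config.min_orf_aa if config is not None else 25
    peptide_set = set(peptides) if peptides is not None else None

    rows = []
    for cand in candidates:
        failed: str | None = None
        if intersects_annotation(cand, annotation):
            failed = "annotation_overlap"
        if failed is None:
            ok, reason = length_and_splice_filter(cand, min_length=min_len)
            if not ok:
                failed = reason
        if failed is None and not coding_potential_filter(cand, cutoff=cutoff):
            failed = "coding_potential"
        if failed is None and peptide_set is not None and genome is not None:
            orfs = enumerate_orfs(spliced_sequence(cand, genome), min_aa=min_orf_aa)
            _, ok = peptide_evidence_filter(orfs, peptide_set)
            if not ok:
                failed = "peptide_evidence"
        rows.append({"candidate": cand.id, "keep": failed is None, "failed_rule": failed})
    return FilterReport(verdicts=pd.DataFrame(rows, columns=["candidate", "keep", "failed_rule"]))
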