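"""Synthetic cohorts and fixtures with planted, exported ground truth.

The generators emulate the statistical structure the downstream analysis
assumes — log-normal FPKM expression with additive log-scale group effects,
Weibull proportional-hazards survival with independent exponential
censoring, rank-copula CNV segment means, and a toy genome with candidate
transcripts planted to fail exactly one catalog filter each — so every
stage of the pipeline is testable without external data. Ground truth
(which genes carry which effects, each sample's latent class) is returned
alongside the data and is serializable.

All generators are deterministic under a fixed seed; independent named
substreams are spawned per component so one module's draws never shift
another's.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .catalog import TranscriptModel
from .io_formats import (
    GenomeAnnotation,
    write_expression_matrix,
    write_gtf,
    write_peptides,
)
from .survival import transform_matrix


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible RNG substream derived from one master seed."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass
class CohortTruth:
    """Planted ground truth of a simulated cohort.

    ``effects`` maps gene → group → log2 expression shift; every planted
    effect appears exactly once. ``prognostic`` maps gene → true Cox
    coefficient on the inverse-normal-transformed expression scale.
    """

    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    sample_groups: dict[str, str] = field(default_factory=dict)
    gene_baseline: dict[str, tuple[float, float]] = field(default_factory=dict)
    cnv_targets: dict[str, float] = field(default_factory=dict)
    prognostic: dict[str, float] = field(default_factory=dict)
    clinical_coefs: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def affected_genes(self, group: str | None = None) -> set[str]:
        """Genes with a planted expression effect (optionally in one group)."""
        if group is None:
            return set(self.effects)
        return {g for g, e in self.effects.items() if group in e}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        payload = json.loads(Path(path).read_text())
        payload["gene_baseline"] = {g: tuple(v) for g, v in payload.get("gene_baseline", {}).items()}
        return cls(**payload)


def simulate_expression(
    n_genes: int,
    groups: Mapping[str, int],
    effects: Mapping[str, Mapping[str, float]] | None = None,
    sigma: float | tuple[float, float] = (0.2, 0.8),
    baseline_log2_mean: tuple[float, float] = (0.5, 5.0),
    seed: int = 0,
    gene_prefix: str = "lnc",
) -> tuple[pd.DataFrame, CohortTruth]:
    """Log-normal FPKM-like expression with additive log2-scale group effects.

    Per gene g a baseline log2 mean μ_g and dispersion σ_g are drawn once;
    sample values are 2^(μ_g + effect + Normal(0, σ_g)), hence nonnegative
    with the heavy right tail typical of FPKM. ``effects[gene][group]``
    plants a log2 fold change for that gene in that group; genes are named
    ``{gene_prefix}0000`` …, samples ``{group}_0`` ….
    """
    for name, size in groups.items():
        if size < 2:
            raise ValueError(f"group {name!r} needs at least 2 samples")
    if np.isscalar(sigma):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        sigma_range = (float(sigma), float(sigma))
    else:
        sigma_range = (float(sigma[0]), float(sigma[1]))
        if sigma_range[0] <= 0 or sigma_range[1] < sigma_range[0]:
            raise ValueError("sigma range must be positive and ordered")
    effects = {g: dict(e) for g, e in (effects or {}).items()}
    for gene, per_group in effects.items():
        for group, shift in per_group.items():
            if group not in groups:
                raise ValueError(f"effect for unknown group {group!r}")
            if not np.isfinite(shift):
                raise ValueError(f"non-finite effect for gene {gene!r}")

    rng = substream(seed, "expression")
    genes = [f"{gene_prefix}{i:04d}" for i in range(n_genes)]
    mu = rng.uniform(*baseline_log2_mean, size=n_genes)
    sig = rng.uniform(sigma_range[0], sigma_range[1], size=n_genes)
    columns: list[str] = []
    sample_groups: dict[str, str] = {}
    shift_cols: list[np.ndarray] = []
    for group, size in groups.items():
        shift = np.zeros(n_genes)
        for gi, gene in enumerate(genes):
            if gene in effects and group in effects[gene]:
                shift[gi] = effects[gene][group]
        for j in range(size):
            sample = f"{group}_{j}"
            columns.append(sample)
            sample_groups[sample] = group
            shift_cols.append(shift)
    shifts = np.column_stack(shift_cols)
    noise = rng.normal(0.0, 1.0, size=(n_genes, len(columns))) * sig[:, None]
    log2_expr = mu[:, None] + shifts + noise
    matrix = pd.DataFrame(np.exp2(log2_expr), index=genes, columns=columns)
    truth = CohortTruth(
        effects={g: e for g, e in effects.items()},
        sample_groups=sample_groups,
        gene_baseline={g: (float(m), float(s)) for g, m, s in zip(genes, mu, sig)},
        seed=seed,
    )
    return matrix, truth


def simulate_survival(
    eta: Sequence[float],
    shape: float = 1.3,
    scale: float = 3000.0,
    censor_rate: float = 0.25,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Weibull proportional-hazards survival times with exponential censoring.

    T = scale·(−ln U)^(1/shape)·exp(−η/shape), so the hazard is
    proportional to exp(η). Censoring times are independent exponentials
    whose rate is solved so the expected censored fraction matches
    ``censor_rate``; ``event = (T ≤ C)``. ``censor_rate=0`` disables
    censoring.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("linear predictor must be finite")
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = substream(seed, "survival")
    u = rng.uniform(size=eta.size)
    t = scale * (-np.log(u)) ** (1.0 / shape) * np.exp(-eta / shape)
    if censor_rate == 0.0:
        return t, np.ones(eta.size, dtype=int)

    def censored_fraction(rate: float) -> float:
        return float(np.mean(1.0 - np.exp(-rate * t))) - censor_rate

    rate = optimize.brentq(censored_fraction, 1e-12 / scale, 1e6 / scale)
    c = rng.exponential(scale=1.0 / rate, size=eta.size)
    times = np.minimum(t, c)
    events = (t <= c).astype(int)
    return times, events


def simulate_cnv(
    expression: pd.DataFrame,
    targets: Mapping[str, float],
    seed: int = 0,
    segment_sd: float = 0.25,
) -> pd.DataFrame:
    """Copy-number segment means with a target Spearman link to expression.

    Target genes get segment means generated through a Gaussian rank copula
    calibrated so the population Spearman correlation with expression equals
    the target rho (Pearson r of the normal scores = 2·sin(π·rho/6));
    non-target genes get independent noise.
    """
    for gene, rho in targets.items():
        if gene not in expression.index:
            raise KeyError(f"target gene {gene!r} not in expression matrix")
        if abs(rho) > 1.0:
            raise ValueError(f"|target rho| > 1 for gene {gene!r}")
    rng = substream(seed, "cnv")
    n = expression.shape[1]
    out = rng.normal(0.0, segment_sd, size=expression.shape)
    for gene, rho in targets.items():
        z = transform_matrix(expression.loc[[gene]]).to_numpy()[0]
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        noise = rng.normal(size=n)
        out[expression.index.get_loc(gene)] = segment_sd * (r * z + np.sqrt(1.0 - r * r) * noise)
    return pd.DataFrame(out, index=expression.index, columns=expression.columns)


# --- LGG-like survival cohort ------------------------------------------------

@dataclass
class LGGCohort:
    """A simulated LGG-like cohort with planted prognostic lncRNAs."""

    expression: pd.DataFrame
    clinical: pd.DataFrame
    truth: CohortTruth
    test_samples: list[str]
    validation_samples: list[str]


#: Clinical covariate effects on the log-hazard used by the LGG generator:
#: older age, grade III, male sex, and wild-type IDH raise the hazard.
LGG_CLINICAL_COEFS = {"age": 0.03, "grade": 0.4, "sex": 0.1, "idh_mut": -1.0}


def simulate_lgg_cohort(
    n_samples: int = 450,
    n_lncrnas: int = 200,
    n_prognostic: int = 10,
    prognostic_beta: float = 0.8,
    test_frac: float = 0.60,
    weibull_shape: float = 1.3,
    weibull_scale: float = 3000.0,
    censor_rate: float = 0.30,
    sigma: float | tuple[float, float] = 0.3,
    seed: int = 0,
) -> LGGCohort:
    """Simulate an LGG-like cohort for the survival algorithm.

    Expression is log-normal; the first ``n_prognostic`` randomly chosen
    lncRNAs carry alternating ±``prognostic_beta`` coefficients on the
    inverse-normal-transformed expression scale in the log-hazard, together
    with clinical effects (age, grade, sex, IDH status). Survival is
    Weibull proportional-hazards with exponential censoring. Patients are
    split ``test_frac`` / 1−``test_frac`` into test and validation sets.
    """
    if not 0.0 < test_frac < 1.0:
        raise ValueError("test_frac must lie in (0,1)")
    expression, truth = simulate_expression(
        n_genes=n_lncrnas, groups={"lgg": n_samples}, sigma=sigma, seed=seed
    )
    rng = substream(seed, "clinical")
    samples = list(expression.columns)
    age = np.clip(rng.normal(47.0, 12.0, size=n_samples), 18.0, 85.0)
    sex = rng.choice(["male", "female"], size=n_samples)
    grade = rng.choice(["II", "III"], size=n_samples)
    idh_mut = rng.binomial(1, 0.8, size=n_samples)
    codel = np.where(idh_mut == 1, rng.binomial(1, 0.4, size=n_samples), 0)
    subtype = np.where(idh_mut == 0, "IDHwt", np.where(codel == 1, "IDHmut-codel", "IDHmut"))

    gene_rng = substream(seed, "prognostic-genes")
    prog_idx = gene_rng.choice(n_lncrnas, size=n_prognostic, replace=False)
    betas = {
        expression.index[gi]: float(prognostic_beta * (1 if k % 2 == 0 else -1))
        for k, gi in enumerate(sorted(prog_idx))
    }
    transformed = transform_matrix(expression)
    eta = (
        LGG_CLINICAL_COEFS["age"] * (age - age.mean())
        + LGG_CLINICAL_COEFS["grade"] * (grade == "III")
        + LGG_CLINICAL_COEFS["sex"] * (sex == "male")
        + LGG_CLINICAL_COEFS["idh_mut"] * (idh_mut - idh_mut.mean())
    )
    for gene, beta in betas.items():
        eta = eta + beta * transformed.loc[gene].to_numpy()
    eta = eta - eta.mean()
    times, events = simulate_survival(
        eta, shape=weibull_shape, scale=weibull_scale, censor_rate=censor_rate, seed=seed
    )
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "time_days": np.round(times, 1),
            "event": events,
            "age": np.round(age, 1),
            "sex": sex,
            "grade": grade,
            "idh_mut": idh_mut,
            "codel_1p19q": codel,
            "subtype": subtype,
        }
    ).set_index("sample", drop=False)
    split_rng = substream(seed, "split")
    perm = split_rng.permutation(n_samples)
    n_test = int(np.floor(test_frac * n_samples))
    test = [samples[i] for i in perm[:n_test]]
    validation = [samples[i] for i in perm[n_test:]]
    truth.prognostic = betas
    truth.clinical_coefs = dict(LGG_CLINICAL_COEFS)
    return LGGCohort(
        expression=expression,
        clinical=clinical,
        truth=truth,
        test_samples=test,
        validation_samples=validation,
    )


# --- catalog filter fixtures --------------------------------------------------

#: One deterministic codon per amino acid (used to plant peptide evidence).
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def _encode(peptide: str) -> str:
    return "".join(_CODON[aa] for aa in peptide)


@dataclass
class FixtureSet:
    """Toy genome, annotation, and candidate transcripts with known verdicts.

    Each candidate is planted to fail exactly one named catalog filter, or
    to pass all of them; ``expected`` maps candidate id → (keep, rule).
    """

    genome: dict[str, str]
    annotation: GenomeAnnotation
    candidates: list[TranscriptModel]
    peptides: set[str]
    expected: dict[str, tuple[bool, str | None]]

    @property
    def expected_kept(self) -> set[str]:
        return {cid for cid, (keep, _) in self.expected.items() if keep}

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_gtf(self.annotation, directory / "annotation.gtf")
        write_gtf(self.candidates, directory / "candidates.gtf")
        with open(directory / "cpat_scores.tsv", "w") as fh:
            fh.write("transcript_id\tscore\n")
            for cand in self.candidates:
                if cand.cpat_score is not None:
                    fh.write(f"{cand.id}\t{cand.cpat_score}\n")
        write_peptides(self.peptides, directory / "peptides.txt")
        with open(directory / "genome.fa", "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        expected = {cid: {"keep": keep, "rule": rule} for cid, (keep, rule) in self.expected.items()}
        (directory / "expected.json").write_text(json.dumps(expected, indent=2) + "\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_filter_fixtures(seed: int = 0, per_mode: int = 5) -> FixtureSet:
    """Build the catalog-filter fixture set.

    Plants ``per_mode`` candidates per failure mode (annotation overlap,
    <200 bp, mono-exonic, coding-potential score at/above 0.5242, ≥2 mapped
    peptides), ``per_mode`` clean passing candidates, and one borderline
    keeper with exactly one mapped peptide (a single peptide is tolerated).
    One peptide-bearing candidate sits on the minus strand to exercise
    reverse-complement splicing.
    """
    rng = substream(seed, "fixtures")
    chrom = "chrS"
    cursor = 1000
    overrides: list[tuple[int, str]] = []
    annotation = GenomeAnnotation()
    candidates: list[TranscriptModel] = []
    expected: dict[str, tuple[bool, str | None]] = {}
    peptides: set[str] = set()

    def alloc(length: int) -> int:
        nonlocal cursor
        start = cursor
        cursor += length + int(rng.integers(300, 600))
        return start

    def two_exons(start: int, total: int, intron: int = 80) -> tuple[tuple[int, int], tuple[int, int]]:
        first = total // 2
        return (start, start + first), (start + first + intron, start + total + intron)

    # annotated "known" transcripts
    known_spans = []
    for i in range(per_mode):
        start = alloc(1200)
        exons = two_exons(start, 1000, intron=200)
        annotation.add(TranscriptModel(id=f"KNOWN{i}", chrom=chrom, strand="+", exons=exons))
        known_spans.append((exons[0][0], exons[1][1]))

    low_score = lambda: float(np.round(rng.uniform(0.02, 0.40), 4))

    # candidates overlapping an annotated transcript
    for i, (ks, ke) in enumerate(known_spans):
        exons = two_exons(ks + 100, 400)
        cid = f"CAND_OVERLAP{i}"
        candidates.append(TranscriptModel(id=cid, chrom=chrom, strand="+", exons=exons, cpat_score=low_score()))
        expected[cid] = (False, "annotation_overlap")

    # candidates shorter than 200 bp (spliced, so the length rule fires first)
    for i in range(per_mode):
        start = alloc(300)
        total = int(rng.integers(100, 180))
        exons = two_exons(start, total)
        cid = f"CAND_SHORT{i}"
        candidates.append(TranscriptModel(id=cid, chrom=chrom, strand="+", exons=exons, cpat_score=low_score()))
        expected[cid] = (False, "too_short")

    # mono-exonic candidates (long enough, so only the splice rule fires)
    for i in range(per_mode):
        start = alloc(700)
        length = int(rng.integers(300, 600))
        cid = f"CAND_MONO{i}"
        candidates.append(
            TranscriptModel(id=cid, chrom=chrom, strand="+", exons=((start, start + length),), cpat_score=low_score())
        )
        expected[cid] = (False, "no_splice_junction")

    # candidates at or above the coding-potential cutoff (0.5242 itself fails)
    for i, score in enumerate([0.5242, 0.55, 0.70, 0.90, 0.99][:per_mode]):
        start = alloc(700)
        exons = two_exons(start, 400)
        cid = f"CAND_CODING{i}"
        candidates.append(TranscriptModel(id=cid, chrom=chrom, strand="+", exons=exons, cpat_score=score))
        expected[cid] = (False, "coding_potential")

    aa_alphabet = list("ACDEFGHIKLNPQRSTVWY")  # no M: peptides must not start new ORFs

    def random_peptide(length: int = 9) -> str:
        return "".join(rng.choice(aa_alphabet, size=length))

    def planted_orf_seq(n_peptides: int) -> str:
        """Designed exonic sequence whose single ORF contains n listed peptides."""
        peps = [random_peptide() for _ in range(n_peptides)]
        peptides.update(peps)
        orf_aa = "M" + "GG".join(peps) + "G" * max(0, 24 - (9 * n_peptides + 2 * (n_peptides - 1)))
        nt = _encode(orf_aa) + "TAA"
        flank5 = _random_seq(rng, 70).replace("ATG", "ATT")
        flank3 = _random_seq(rng, 70)
        return flank5 + nt + flank3

    # candidates with two mapped peptides (dropped)
    for i in range(per_mode):
        seq = planted_orf_seq(2)
        start = alloc(len(seq) + 100)
        exons = two_exons(start, len(seq))
        overrides.append((exons[0][0], seq[: exons[0][1] - exons[0][0]]))
        overrides.append((exons[1][0], seq[exons[0][1] - exons[0][0] :]))
        cid = f"CAND_PEPFAIL{i}"
        candidates.append(TranscriptModel(id=cid, chrom=chrom, strand="+", exons=exons, cpat_score=low_score()))
        expected[cid] = (False, "peptide_evidence")

    # one candidate with exactly one mapped peptide, on the minus strand (kept)
    from Bio.Seq import Seq as _Seq

    seq = planted_orf_seq(1)
    start = alloc(len(seq) + 100)
    exons = two_exons(start, len(seq))
    genome_seq = str(_Seq(seq).reverse_complement())
    overrides.append((exons[0][0], genome_seq[: exons[0][1] - exons[0][0]]))
    overrides.append((exons[1][0], genome_seq[exons[0][1] - exons[0][0] :]))
    candidates.append(TranscriptModel(id="CAND_ONEPEP", chrom=chrom, strand="-", exons=exons, cpat_score=low_score()))
    expected["CAND_ONEPEP"] = (True, None)

    # clean passing candidates
    for i in range(per_mode):
        start = alloc(700)
        exons = two_exons(start, int(rng.integers(250, 500)))
        cid = f"CAND_PASS{i}"
        candidates.append(TranscriptModel(id=cid, chrom=chrom, strand="+", exons=exons, cpat_score=low_score()))
        expected[cid] = (True, None)

    genome_len = cursor + 1000
    genome_arr = np.array(list(_random_seq(rng, genome_len)))
    for start, seq in overrides:
        genome_arr[start : start + len(seq)] = list(seq)
    genome = {chrom: "".join(genome_arr)}
    return FixtureSet(
        genome=genome,
        annotation=annotation,
        candidates=candidates,
        peptides=peptides,
        expected=expected,
    )
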