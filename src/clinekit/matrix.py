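"""Genotype matrix container and the SNP filtering pipeline.

The :class:`GenotypeMatrix` is the substrate every converter operates on:
individuals x loci diploid genotypes coded as the number of copies of the
second (alternate) allele, with an explicit ``MISSING`` sentinel.  Samples
carry population labels; the two reserved labels ``P0`` and ``P1`` mark the
parental reference populations required by bgc and Introgress, and any other
label denotes an admixed population.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a missing diploid genotype (bgc convention).
MISSING: int = -9

#: Reserved population label for parental population 0.
POP_P0 = "P0"
#: Reserved population label for parental population 1.
POP_P1 = "P1"


class FilterError(ValueError):
    """Raised when a filtering stage removes every locus or individual."""


@dataclass
class GenotypeMatrix:
    """Diploid SNP genotypes for a set of samples with population labels.

    Parameters
    ----------
    sample_ids
        Unique sample names, one per row of ``genotypes``.
    pop_labels
        Per-sample population label.  ``"P0"`` and ``"P1"`` are the parental
        populations; any other label is treated as an admixed population.
    locus_ids
        Unique locus names, one per column of ``genotypes``.
    alleles
        Per-locus ordered ``(allele1, allele2)`` nucleotide pair,
        reference/major allele first.  Genotypes count copies of ``allele2``.
    genotypes
        ``(n_samples, n_loci)`` integer array with values in
        ``{0, 1, 2, MISSING}``.
    allele_count
        Per-locus number of distinct alleles observed in the source data
        (>= 1); loci with ``allele_count != 2`` are non-biallelic.
    positions
        Optional per-locus ``(chrom, pos)`` physical coordinates
        (1-based), retained from VCF input.
    """

    sample_ids: list[str]
    pop_labels: list[str]
    locus_ids: list[str]
    alleles: list[tuple[str, str]]
    genotypes: np.ndarray
    allele_count: np.ndarray
    positions: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        self.allele_count = np.asarray(self.allele_count, dtype=np.int64)
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} genotype rows")
        if len(self.pop_labels) != n:
            raise ValueError("pop_labels length does not match sample count")
        if len(self.locus_ids) != m or len(self.alleles) != m or len(self.allele_count) != m:
            raise ValueError("locus metadata length does not match locus count")
        if len(set(self.locus_ids)) != m:
            raise ValueError("locus_ids are not unique")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype {self.genotypes[i, j]} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        if self.positions is not None and len(self.positions) != m:
            raise ValueError("positions length does not match locus count")

    # -- shape & population helpers ------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def sample_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.pop_labels) == label)

    @property
    def admixed_labels(self) -> list[str]:
        """Admixed population labels in order of first appearance."""
        seen: list[str] = []
        for lab in self.pop_labels:
            if lab not in (POP_P0, POP_P1) and lab not in seen:
                seen.append(lab)
        return seen

    def require_export_populations(self) -> None:
        """bgc/Introgress export needs both parentals and >= 1 admixed sample."""
        labels = set(self.pop_labels)
        if POP_P0 not in labels or POP_P1 not in labels:
            raise ValueError("export requires at least one P0 and one P1 sample")
        if not self.admixed_labels:
            raise ValueError("export requires at least one admixed sample")

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    # -- subsetting ----------------------------------------------------
    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return dataclasses.replace(
            self,
            locus_ids=[self.locus_ids[i] for i in idx],
            alleles=[self.alleles[i] for i in idx],
            genotypes=self.genotypes[:, idx],
            allele_count=self.allele_count[idx],
            positions=None if self.positions is None else [self.positions[i] for i in idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return dataclasses.replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            pop_labels=[self.pop_labels[i] for i in idx],
            genotypes=self.genotypes[idx, :],
        )

    # -- equality ------------------------------------------------------
    def equals(self, other: "GenotypeMatrix", allow_polarity_flip: bool = False) -> bool:
        """Genotype-level equality with another matrix.

        With ``allow_polarity_flip`` a locus also matches when its allele
        pair is reversed and genotypes are complemented (``g -> 2 - g``),
        which is the inherent ambiguity of sequence-only formats such as
        PHYLIP where allele order is set by first observation.
        """
        if self.genotypes.shape != other.genotypes.shape:
            return False
        if self.locus_ids != other.locus_ids or self.sample_ids != other.sample_ids:
            return False
        a, b = self.genotypes, other.genotypes
        for j in range(self.n_loci):
            col_a, col_b = a[:, j], b[:, j]
            same = np.array_equal(col_a, col_b) and self.alleles[j] == other.alleles[j]
            if same:
                continue
            if not allow_polarity_flip:
                return False
            flipped = np.where(col_b == MISSING, MISSING, 2 - col_b)
            if not (
                np.array_equal(col_a, flipped)
                and self.alleles[j] == other.alleles[j][::-1]
            ):
                return False
        return True


@dataclass
class ReadCountMatrix:
    """Per-sample per-locus allele read depths ``(reads_allele1, reads_allele2)``.

    ``counts`` has shape ``(n_samples, n_loci, 2)``; missing entries hold
    ``MISSING`` in both slots.  A ``(0, 0)`` pair is kept verbatim when the
    source encodes it so.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.sample_ids), len(self.locus_ids), 2):
            raise ValueError("counts shape does not match sample/locus ids")
        valid = (self.counts >= 0) | (self.counts == MISSING)
        if not valid.all():
            raise ValueError("read counts must be non-negative or MISSING")

    def take_loci(self, idx: np.ndarray) -> "ReadCountMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return ReadCountMatrix(
            sample_ids=list(self.sample_ids),
            locus_ids=[self.locus_ids[i] for i in idx],
            counts=self.counts[:, idx, :],
        )


@dataclass
class FilterSpec:
    """Thresholds for the SNP filtering pipeline.

    ``max_missing_per_locus`` and ``max_missing_per_individual`` are maximum
    tolerated missing-data fractions; ``min_maf`` is the minimum minor allele
    frequency (computed over non-missing calls of surviving individuals).
    ``subsample_n`` randomly retains that many loci using ``seed``.
    """

    max_missing_per_locus: float = 1.0
    max_missing_per_individual: float = 1.0
    min_maf: float = 0.0
    biallelic_only: bool = False
    drop_monomorphic: bool = False
    subsample_n: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_per_locus <= 1.0:
            raise ValueError("max_missing_per_locus must be in [0, 1]")
        if not 0.0 <= self.max_missing_per_individual <= 1.0:
            raise ValueError("max_missing_per_individual must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.subsample_n is not None and self.subsample_n < 1:
            raise ValueError("subsample_n must be a positive integer")


@dataclass
class FilterReport:
    """Per-stage removal counts from :func:`filter_genotypes`.

    Locus-dropping stage counts sum to ``loci_in - loci_out`` and
    ``individuals_removed = samples_in - samples_out``.
    """

    loci_in: int = 0
    samples_in: int = 0
    non_biallelic: int = 0
    monomorphic: int = 0
    locus_missing: int = 0
    individual_missing: int = 0
    maf: int = 0
    subsampled_out: int = 0
    loci_out: int = 0
    samples_out: int = 0
    removed_loci: dict[str, list[str]] = field(default_factory=dict)
    removed_samples: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [
            ("non_biallelic", self.non_biallelic),
            ("monomorphic", self.monomorphic),
            ("locus_missing", self.locus_missing),
            ("individual_missing", self.individual_missing),
            ("maf", self.maf),
            ("subsampled_out", self.subsampled_out),
        ]
        df = pd.DataFrame(rows, columns=["stage", "removed"])
        df.to_csv(path, sep="\t", index=False)


def _missing_fraction(geno: np.ndarray, axis: int) -> np.ndarray:
    return (geno == MISSING).mean(axis=axis)


def filter_genotypes(gm: GenotypeMatrix, spec: FilterSpec) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the SNP filtering pipeline in a fixed, documented order.

    Stages, in order: (1) drop non-biallelic loci, (2) drop monomorphic
    loci, (3) drop loci exceeding the per-locus missing threshold, (4) drop
    individuals exceeding the per-individual missing threshold computed over
    the surviving loci, (5) drop loci whose minor allele frequency over the
    surviving individuals' non-missing calls falls below ``min_maf``,
    (6) randomly subsample ``subsample_n`` loci with ``spec.seed``.

    Raises :class:`FilterError` naming the stage that removed everything.
    """
    report = FilterReport(loci_in=gm.n_loci, samples_in=gm.n_samples)
    out = gm

    def _check(stage: str, m: GenotypeMatrix) -> None:
        if m.n_loci == 0:
            raise FilterError(f"all loci removed at stage {stage!r}")
        if m.n_samples == 0:
            raise FilterError(f"all individuals removed at stage {stage!r}")

    # non-biallelic means >2 observed alleles; loci with a single observed
    # allele are handled by the separate monomorphic stage
    if spec.biallelic_only:
        keep = out.allele_count <= 2
        report.non_biallelic = int((~keep).sum())
        report.removed_loci["non_biallelic"] = [
            lid for lid, k in zip(out.locus_ids, keep) if not k
        ]
        out = out.take_loci(np.flatnonzero(keep))
        _check("biallelic_only", out)

    if spec.drop_monomorphic:
        keep = out.allele_count >= 2
        report.monomorphic = int((~keep).sum())
        report.removed_loci["monomorphic"] = [
            lid for lid, k in zip(out.locus_ids, keep) if not k
        ]
        out = out.take_loci(np.flatnonzero(keep))
        _check("drop_monomorphic", out)

    if spec.max_missing_per_locus < 1.0:
        frac = _missing_fraction(out.genotypes, axis=0)
        keep = frac <= spec.max_missing_per_locus
        report.locus_missing = int((~keep).sum())
        report.removed_loci["locus_missing"] = [
            lid for lid, k in zip(out.locus_ids, keep) if not k
        ]
        out = out.take_loci(np.flatnonzero(keep))
        _check("max_missing_per_locus", out)

    if spec.max_missing_per_individual < 1.0:
        frac = _missing_fraction(out.genotypes, axis=1)
        keep = frac <= spec.max_missing_per_individual
        report.individual_missing = int((~keep).sum())
        report.removed_samples = [s for s, k in zip(out.sample_ids, keep) if not k]
        out = out.take_samples(np.flatnonzero(keep))
        _check("max_missing_per_individual", out)

    if spec.min_maf > 0.0:
        geno = out.genotypes.astype(float)
        obs = geno != MISSING
        called = obs.sum(axis=0)
        alt = np.where(obs, geno, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called > 0, alt / (2.0 * called), 0.0)
        maf = np.minimum(p, 1.0 - p)
        keep = maf >= spec.min_maf
        report.maf = int((~keep).sum())
        report.removed_loci["maf"] = [lid for lid, k in zip(out.locus_ids, keep) if not k]
        out = out.take_loci(np.flatnonzero(keep))
        _check("min_maf", out)

    if spec.subsample_n is not None and spec.subsample_n < out.n_loci:
        rng = np.random.default_rng(spec.seed)
        pick = np.sort(rng.choice(out.n_loci, size=spec.subsample_n, replace=False))
        report.subsampled_out = out.n_loci - spec.subsample_n
        dropped = sorted(set(range(out.n_loci)) - set(pick.tolist()))
        report.removed_loci["subsampled_out"] = [out.locus_ids[i] for i in dropped]
        out = out.take_loci(pick)

    report.loci_out = out.n_loci
    report.samples_out = out.n_samples
    return out, report
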