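"""Core domain types shared across the genotyping pipeline.

The pipeline operates on pre-validated biallelic SNP loci. At each locus, in
each sample, a pileup of read-base observations is reduced to a diploid
genotype call carrying the standard VCF per-sample fields (GT, DP, AD, PL).
Calls for a whole panel are held in a loci x samples genotype matrix, one per
sequencing platform, which downstream modules filter and compare.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

BASES = ("A", "C", "G", "T")


class Genotype(enum.IntEnum):
    """Diploid genotype class at a biallelic site."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = 3

    @property
    def is_hom(self) -> bool:
        return self in (Genotype.HOM_REF, Genotype.HOM_ALT)

    @property
    def is_het(self) -> bool:
        return self is Genotype.HET

    @property
    def is_missing(self) -> bool:
        return self is Genotype.MISSING


@dataclass(frozen=True)
class SnpLocus:
    """A pre-validated biallelic SNP site.

    Coordinates are 1-based inclusive (VCF convention). ``dup_flag`` marks
    loci lying in duplicated (homoeologous/paralogous) regions, where
    short-read misalignment can manufacture apparent heterozygotes
    ("hemi-SNPs").
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    dup_flag: bool = False

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(
                f"{self.chrom}:{self.pos}: ref/alt must be single bases "
                f"from {BASES}, got ref={self.ref!r} alt={self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == alt ({self.ref})")
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def is_at_only(self) -> bool:
        """True when both alleles are A or T (used for the A/T-restricted panel)."""
        return self.ref in ("A", "T") and self.alt in ("A", "T")


@dataclass(frozen=True)
class PileupObservation:
    """One read-base observation overlapping a locus.

    ``qual`` is the phred base quality; ``read_length`` the originating
    read's length in bp; ``read_offset`` the distance in bp from the nearer
    read end (so end-trimming removes observations with small offsets).
    """

    base: str
    qual: int
    read_length: int
    read_offset: int

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise ValueError(f"base must be one of {BASES}, got {self.base!r}")
        if self.qual < 0:
            raise ValueError("phred quality must be >= 0")
        if self.read_offset > self.read_length / 2 + 1:
            raise ValueError(
                f"read_offset {self.read_offset} exceeds half read length "
                f"{self.read_length}"
            )


@dataclass
class LocusPileup:
    """All read-base observations at one locus in one sample."""

    locus: SnpLocus
    observations: list[PileupObservation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class GenotypeCall:
    """A called genotype plus its supporting evidence.

    ``dp`` counts observations used by the caller (after base-quality
    exclusion); ``ad`` is (ref_count, alt_count); ``pl`` the phred-scaled
    genotype likelihoods (hom_ref, het, hom_alt) normalised so the minimum
    is 0. ``pl`` is None when the call carries no likelihood information
    (dp == 0, or the genotype was set to missing by a filter).
    """

    gt: Genotype
    dp: int = 0
    ad: tuple[int, int] = (0, 0)
    pl: Optional[tuple[int, int, int]] = None

    MISSING: "GenotypeCall" = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dp < self.ad[0] + self.ad[1]:
            raise ValueError(
                f"dp={self.dp} smaller than ad sum {self.ad[0] + self.ad[1]}"
            )
        if self.gt is Genotype.MISSING and self.dp == 0 and self.pl is not None:
            raise ValueError("no-data calls must not carry PL")
        if self.pl is not None and min(self.pl) != 0:
            raise ValueError(f"PL must be normalised to min 0, got {self.pl}")

    @property
    def is_missing(self) -> bool:
        return self.gt is Genotype.MISSING

    def with_gt(self, gt: Genotype) -> "GenotypeCall":
        return GenotypeCall(gt=gt, dp=self.dp, ad=self.ad, pl=self.pl)

    def as_missing(self) -> "GenotypeCall":
        return GenotypeCall(gt=Genotype.MISSING, dp=self.dp, ad=self.ad, pl=None)


GenotypeCall.MISSING = GenotypeCall(gt=Genotype.MISSING)


class GenotypeMatrix:
    """Loci x samples grid of :class:`GenotypeCall` for one platform.

    Stores per-sample genome coverage (x multiples) as metadata so that
    coverage-heterozygosity analyses need no extra bookkeeping.
    """

    def __init__(
        self,
        loci: Sequence[SnpLocus],
        samples: Sequence[str],
        calls: Optional[list[list[GenotypeCall]]] = None,
        coverage: Optional[Sequence[float]] = None,
    ) -> None:
        self.loci = list(loci)
        self.samples = list(samples)
        if calls is None:
            calls = [
                [GenotypeCall.MISSING for _ in self.samples] for _ in self.loci
            ]
        if len(calls) != len(self.loci):
            raise ValueError("calls row count must equal number of loci")
        for row in calls:
            if len(row) != len(self.samples):
                raise ValueError("calls column count must equal number of samples")
        self.calls = calls
        if coverage is not None and len(coverage) != len(self.samples):
            raise ValueError("coverage length must equal number of samples")
        self.coverage = list(coverage) if coverage is not None else None
        self._locus_index = {loc.key: i for i, loc in enumerate(self.loci)}
        if len(self._locus_index) != len(self.loci):
            raise ValueError("duplicate locus keys in matrix")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def get(self, locus_key: tuple[str, int], sample: str) -> GenotypeCall:
        return self.calls[self._locus_index[locus_key]][self.samples.index(sample)]

    def set(self, locus_key: tuple[str, int], sample: str, call: GenotypeCall) -> None:
        self.calls[self._locus_index[locus_key]][self.samples.index(sample)] = call

    def map_calls(self, fn) -> "GenotypeMatrix":
        """Return a new matrix with ``fn`` applied to every call."""
        new = [[fn(c) for c in row] for row in self.calls]
        return GenotypeMatrix(self.loci, self.samples, new, self.coverage)

    def subset_loci(self, keys: Iterable[tuple[str, int]]) -> "GenotypeMatrix":
        keyset = set(keys)
        idx = [i for i, loc in enumerate(self.loci) if loc.key in keyset]
        return GenotypeMatrix(
            [self.loci[i] for i in idx],
            self.samples,
            [self.calls[i] for i in idx],
            self.coverage,
        )

    def gt_array(self) -> np.ndarray:
        """Genotype classes as an int array (loci x samples)."""
        return np.array(
            [[int(c.gt) for c in row] for row in self.calls], dtype=np.int8
        ).reshape(self.n_loci, self.n_samples)

    def pct_het_per_sample(self) -> list[float]:
        """% heterozygous among non-missing calls, per sample.

        Returns NaN for samples with no non-missing call.
        """
        out = []
        g = self.gt_array()
        for j in range(self.n_samples):
            col = g[:, j]
            nonmiss = col != int(Genotype.MISSING)
            n = int(nonmiss.sum())
            if n == 0:
                out.append(float("nan"))
            else:
                out.append(100.0 * float((col == int(Genotype.HET)).sum()) / n)
        return out


class ConcordanceClass(enum.Enum):
    """Classification of a reference-platform vs query-platform call pair."""

    CONCORDANT = "concordant"
    HET_REF_HOM_QUERY = "het_ref_hom_query"
    HOM_REF_HET_QUERY = "hom_ref_het_query"
    ALT_HOM = "alt_hom"
    NOT_COMPARABLE = "not_comparable"


@dataclass(frozen=True)
class ConcordanceRecord:
    """A classified pair of calls at one locus/sample."""

    locus_key: tuple[str, int]
    sample: str
    ref_call: GenotypeCall
    query_call: GenotypeCall
    cls: ConcordanceClass
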