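"""Sample-level statistical summaries.

Covers the three analyses that distinguish random sequencing error from
systematic misalignment:

* per-sample genome coverage (total sequenced bases / genome size);
* the coverage-heterozygosity Pearson correlation across samples — strongly
  negative when apparent heterozygosity is sampling noise that deeper
  coverage drowns out (random-error regime), near zero when heterozygosity
  is manufactured consistently by misalignment;
* a nucleotide-bias table conditioning query discrepancy rates on the
  homozygous genotype class (AA/CC/GG/TT) observed in the reference, with a
  chi-square homogeneity test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .concordance import ConcordanceClass, classify_matrices
from .filters import FilterSpec
from .types import Genotype, GenotypeMatrix


@dataclass(frozen=True)
class SampleSummary:
    """One sample's realised coverage and apparent heterozygosity."""

    sample: str
    coverage: float  # genome-coverage multiple (x)
    pct_het: float  # % het among non-missing calls

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not (0 <= self.pct_het <= 100 or np.isnan(self.pct_het)):
            raise ValueError("pct_het must be in [0, 100]")


def coverage_from_reads(total_bases: float, genome_size: float) -> float:
    """Genome-coverage multiple: total sequenced bases over genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    return total_bases / genome_size


def sample_summaries(matrix: GenotypeMatrix) -> list[SampleSummary]:
    """SampleSummary per sample from a matrix carrying coverage metadata."""
    if matrix.coverage is None:
        raise ValueError("matrix has no per-sample coverage metadata")
    hets = matrix.pct_het_per_sample()
    return [
        SampleSummary(sample=s, coverage=c, pct_het=h)
        for s, c, h in zip(matrix.samples, matrix.coverage, hets)
    ]


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    defined: bool
    signif_001: bool = False
    signif_002: bool = False


def coverage_het_correlation(
    summaries: Sequence[SampleSummary],
) -> CorrelationResult:
    """Pearson correlation of per-sample coverage vs % heterozygosity.

    The p-value is two-sided from the t-distribution; significance is
    flagged at the 0.01 and 0.02 levels. Zero variance in either vector
    leaves the correlation undefined (flagged, not raised).
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    x = np.array([s.coverage for s in summaries], dtype=float)
    y = np.array([s.pct_het for s in summaries], dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(
            r=float("nan"), p_value=float("nan"), n=len(x), defined=False
        )
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(
        r=float(r),
        p_value=float(p),
        n=len(x),
        defined=True,
        signif_001=p < 0.01,
        signif_002=p < 0.02,
    )


def homogeneity_test(
    n_ok: Sequence[int], n_bad: Sequence[int]
) -> tuple[float, float, int]:
    """Chi-square homogeneity test on a classes x (ok, bad) count table.

    Returns (chi2, p, df). Rows with zero totals must be excluded by the
    caller; no continuity correction is applied.
    """
    table = np.column_stack([np.asarray(n_ok, float), np.asarray(n_bad, float)])
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p), int(df)


@dataclass
class NucleotideBiasTable:
    """Query discrepancy rates by reference homozygous genotype class."""

    classes: list[str]  # subset of ["AA", "CC", "GG", "TT"]
    n_total: dict[str, int]
    n_discrepant: dict[str, int]
    pct_discrepant: dict[str, float]
    chi2: float
    p_value: float
    df: int


def nucleotide_bias_table(
    ref_matrix: GenotypeMatrix,
    query_matrix: GenotypeMatrix,
    spec: Optional[FilterSpec] = None,
) -> NucleotideBiasTable:
    """Discrepancy rate in the query, conditioned on the reference's
    homozygous nucleotide class, with a chi-square homogeneity test.

    The nucleotide class of a homozygous reference call is the doubled
    allele actually called (ref base for hom-ref, alt base for hom-alt).
    Classes with zero comparable cells are reported with zero counts but
    excluded from the test.
    """
    records = classify_matrices(ref_matrix, query_matrix, spec)
    loci_by_key = {loc.key: loc for loc in ref_matrix.loci}

    n_total = {b + b: 0 for b in "ACGT"}
    n_disc = {b + b: 0 for b in "ACGT"}
    for r in records:
        if r.cls is ConcordanceClass.NOT_COMPARABLE:
            continue
        if not r.ref_call.gt.is_hom:
            continue
        loc = loci_by_key[r.locus_key]
        base = loc.ref if r.ref_call.gt is Genotype.HOM_REF else loc.alt
        cls = base + base
        n_total[cls] += 1
        if r.cls is not ConcordanceClass.CONCORDANT:
            n_disc[cls] += 1

    classes = [c for c in ("AA", "CC", "GG", "TT")]
    pct = {
        c: (round(100.0 * n_disc[c] / n_total[c], 1) if n_total[c] else float("nan"))
        for c in classes
    }

    # homogeneity test on the 4x2 (class x concordant/discrepant) table,
    # restricted to non-empty classes
    used = [c for c in classes if n_total[c] > 0]
    chi2, p, df = float("nan"), float("nan"), 0
    if len(used) >= 2:
        ok = [n_total[c] - n_disc[c] for c in used]
        bad = [n_disc[c] for c in used]
        if sum(ok) > 0 and sum(bad) > 0:
            chi2, p, df = homogeneity_test(ok, bad)
    return NucleotideBiasTable(
        classes=classes,
        n_total=n_total,
        n_discrepant=n_disc,
        pct_discrepant=pct,
        chi2=chi2,
        p_value=p,
        df=int(df),
    )
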