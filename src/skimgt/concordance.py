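"""Platform-vs-platform genotype concordance and accuracy summaries.

The reference platform plays the short-read (high per-base accuracy) role
and the query platform the long-read role. "Accuracy" is operationally
defined as concordance of the genotype class between the two platforms over
comparable cells (both calls non-missing). Because the panel is doubled
haploid, a separate DH-adjusted accuracy additionally counts cells that are
heterozygous in the reference but homozygous in the query as correct: the
reference heterozygote is the likelier error there (misalignment between
duplicated regions), not the query homozygote.

Conventions: the reference matrix is always filtered to a minimum depth of
2 (no maximum); the query side follows the active FilterSpec. Percentages
are reported to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .filters import FilterSpec, apply_matrix_filters, filter_depth
from .types import (
    ConcordanceClass,
    ConcordanceRecord,
    Genotype,
    GenotypeCall,
    GenotypeMatrix,
)

REFERENCE_DP_MIN = 2

# Default threshold grid for cumulative per-SNP accuracy curves: a 0.1 grid,
# which contains the conventionally reported thresholds 0.5/0.8/0.9/1.0.
DEFAULT_THRESHOLDS = tuple(round(0.1 * i, 1) for i in range(11))


def classify_pair(ref_call: GenotypeCall, query_call: GenotypeCall) -> ConcordanceClass:
    """Classify one reference/query call pair.

    Exhaustive and mutually exclusive: not_comparable if either side is
    missing; concordant iff genotype classes are identical (het=het
    included); otherwise het-in-reference/hom-in-query, hom-in-reference/
    het-in-query, or opposite homozygous classes.
    """
    if ref_call.is_missing or query_call.is_missing:
        return ConcordanceClass.NOT_COMPARABLE
    if ref_call.gt == query_call.gt:
        return ConcordanceClass.CONCORDANT
    if ref_call.gt.is_het and query_call.gt.is_hom:
        return ConcordanceClass.HET_REF_HOM_QUERY
    if ref_call.gt.is_hom and query_call.gt.is_het:
        return ConcordanceClass.HOM_REF_HET_QUERY
    return ConcordanceClass.ALT_HOM  # both hom, opposite classes


def _prepare(
    ref_matrix: GenotypeMatrix,
    query_matrix: GenotypeMatrix,
    spec: Optional[FilterSpec],
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Apply the asymmetric platform filters and align locus panels."""
    if ref_matrix.samples != query_matrix.samples:
        raise ValueError("matrices must share the same sample columns")
    ref = ref_matrix.map_calls(lambda c: filter_depth(c, REFERENCE_DP_MIN, None))
    query = query_matrix
    if spec is not None:
        query = apply_matrix_filters(query, spec)
        if spec.locus_subset is not None or spec.at_only:
            ref = ref.subset_loci({loc.key for loc in query.loci})
    if [l.key for l in ref.loci] != [l.key for l in query.loci]:
        common = {l.key for l in ref.loci} & {l.key for l in query.loci}
        ref = ref.subset_loci(common)
        query = query.subset_loci(common)
    return ref, query


def classify_matrices(
    ref_matrix: GenotypeMatrix,
    query_matrix: GenotypeMatrix,
    spec: Optional[FilterSpec] = None,
) -> list[ConcordanceRecord]:
    """Classified records for every locus x sample cell after filtering."""
    ref, query = _prepare(ref_matrix, query_matrix, spec)
    records = []
    for i, locus in enumerate(ref.loci):
        for j, sample in enumerate(ref.samples):
            rc, qc = ref.calls[i][j], query.calls[i][j]
            records.append(
                ConcordanceRecord(
                    locus_key=locus.key,
                    sample=sample,
                    ref_call=rc,
                    query_call=qc,
                    cls=classify_pair(rc, qc),
                )
            )
    return records


@dataclass
class SampleAccuracy:
    """Concordance summary for one sample (or the pooled panel)."""

    sample: str
    n_comparable: int
    pct_concordant: float
    pct_discrepant: float
    pct_het_query: float  # % het among non-missing query calls
    breakdown: dict[str, float] = field(default_factory=dict)
    pct_dh_adjusted: Optional[float] = None


@dataclass
class AccuracyReport:
    """Per-sample and pooled concordance summaries."""

    per_sample: list[SampleAccuracy]
    pooled: SampleAccuracy

    def to_dataframe(self):
        import pandas as pd

        rows = [vars(s).copy() for s in self.per_sample + [self.pooled]]
        for r in rows:
            r.update(r.pop("breakdown"))
        return pd.DataFrame(rows)


def _summarise(records: Sequence[ConcordanceRecord], label: str) -> SampleAccuracy:
    comparable = [r for r in records if r.cls is not ConcordanceClass.NOT_COMPARABLE]
    n = len(comparable)
    nonmissing_query = [r for r in records if not r.query_call.is_missing]
    n_q = len(nonmissing_query)
    pct_het_query = (
        round(100.0 * sum(r.query_call.gt.is_het for r in nonmissing_query) / n_q, 1)
        if n_q
        else float("nan")
    )
    if n == 0:
        return SampleAccuracy(
            sample=label,
            n_comparable=0,
            pct_concordant=float("nan"),
            pct_discrepant=float("nan"),
            pct_het_query=pct_het_query,
        )
    n_conc = sum(r.cls is ConcordanceClass.CONCORDANT for r in comparable)
    n_disc = n - n_conc
    breakdown: dict[str, float] = {}
    if n_disc:
        for cls in (
            ConcordanceClass.HET_REF_HOM_QUERY,
            ConcordanceClass.HOM_REF_HET_QUERY,
            ConcordanceClass.ALT_HOM,
        ):
            k = sum(r.cls is cls for r in comparable)
            breakdown[cls.value] = round(100.0 * k / n_disc, 1)
    pct_concordant = round(100.0 * n_conc / n, 1)
    pct_discrepant = round(100.0 * n_disc / n, 1)
    adjusted = round(
        100.0 * (n_conc + sum(r.cls is ConcordanceClass.HET_REF_HOM_QUERY
                              for r in comparable)) / n,
        1,
    )
    return SampleAccuracy(
        sample=label,
        n_comparable=n,
        pct_concordant=pct_concordant,
        pct_discrepant=pct_discrepant,
        pct_het_query=pct_het_query,
        breakdown=breakdown,
        pct_dh_adjusted=adjusted,
    )


def per_sample_accuracy(
    ref_matrix: GenotypeMatrix,
    query_matrix: GenotypeMatrix,
    spec: Optional[FilterSpec] = None,
) -> AccuracyReport:
    """Per-sample and pooled concordance percentages after filtering."""
    records = classify_matrices(ref_matrix, query_matrix, spec)
    per_sample = []
    for sample in ref_matrix.samples:
        recs = [r for r in records if r.sample == sample]
        per_sample.append(_summarise(recs, sample))
    pooled = _summarise(records, "pooled")
    return AccuracyReport(per_sample=per_sample, pooled=pooled)


def dh_adjusted_accuracy(
    pct_concordant: float, pct_discrepant: float, het_ref_share: float
) -> float:
    """DH-adjusted accuracy from printed summary percentages.

    ``het_ref_share`` is the percentage of discrepant calls that are
    heterozygous in the reference platform (and therefore assumed wrong in
    the reference, correct in the query, in a doubled-haploid panel):

        adjusted = pct_concordant + pct_discrepant * het_ref_share / 100

    Result rounded to one decimal. Linear in het_ref_share and bounded by
    [pct_concordant, 100].
    """
    for name, v in (
        ("pct_concordant", pct_concordant),
        ("pct_discrepant", pct_discrepant),
        ("het_ref_share", het_ref_share),
    ):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    if abs(pct_concordant + pct_discrepant - 100.0) > 0.2:
        raise ValueError(
            "pct_concordant and pct_discrepant must sum to 100 "
            f"(got {pct_concordant + pct_discrepant})"
        )
    return round(pct_concordant + pct_discrepant * het_ref_share / 100.0, 1)


@dataclass
class PerSnpAccuracy:
    """Per-SNP correct-call proportions and their cumulative curve."""

    n_snps: int
    proportions: dict[tuple[str, int], float]
    thresholds: tuple[float, ...]
    cumulative_pct: list[float]  # % of SNPs with proportion >= t, per t


def per_snp_accuracy(
    ref_matrix: GenotypeMatrix,
    query_matrix: GenotypeMatrix,
    min_samples: int = 7,
    count_het_ref_as_correct: bool = False,
    hom_only: bool = False,
    spec: Optional[FilterSpec] = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> PerSnpAccuracy:
    """Per-SNP proportion of samples correctly genotyped, plus the
    cumulative percentage of SNPs meeting each proportion threshold.

    SNPs comparable in fewer than ``min_samples`` samples are excluded.
    ``hom_only`` drops heterozygous query calls before comparison;
    ``count_het_ref_as_correct`` treats het-in-reference/hom-in-query cells
    as correct (the DH adjustment at per-SNP scale).
    """
    if min_samples > ref_matrix.n_samples:
        raise ValueError("min_samples exceeds panel size")
    eff_spec = spec
    if hom_only:
        base = spec if spec is not None else FilterSpec()
        eff_spec = FilterSpec(
            dp_min=base.dp_min,
            dp_max=base.dp_max,
            drop_het=True,
            min_read_length=base.min_read_length,
            end_trim=base.end_trim,
            min_bq=base.min_bq,
            locus_subset=base.locus_subset,
            at_only=base.at_only,
        )
    records = classify_matrices(ref_matrix, query_matrix, eff_spec)

    by_locus: dict[tuple[str, int], list[ConcordanceRecord]] = {}
    for r in records:
        by_locus.setdefault(r.locus_key, []).append(r)

    good = {ConcordanceClass.CONCORDANT}
    if count_het_ref_as_correct:
        good.add(ConcordanceClass.HET_REF_HOM_QUERY)

    proportions: dict[tuple[str, int], float] = {}
    for key, recs in by_locus.items():
        comp = [r for r in recs if r.cls is not ConcordanceClass.NOT_COMPARABLE]
        if len(comp) < min_samples:
            continue
        proportions[key] = sum(r.cls in good for r in comp) / len(comp)

    n = len(proportions)
    vals = np.array(list(proportions.values()))
    cumulative = [
        round(100.0 * float((vals >= t - 1e-12).sum()) / n, 1) if n else float("nan")
        for t in thresholds
    ]
    return PerSnpAccuracy(
        n_snps=n,
        proportions=proportions,
        thresholds=tuple(thresholds),
        cumulative_pct=cumulative,
    )


@dataclass
class ZygosityBreakdown:
    """Concordance conditioned on the reference platform's zygosity."""

    n_ref_hom: int
    hom_pct_same: float
    hom_pct_discrepant: float
    hom_discrepant_pct_hom: float  # of hom-reference discrepancies
    hom_discrepant_pct_het: float
    n_ref_het: int
    het_pct_same: float
    het_pct_query_hom: float


def zygosity_breakdown(
    ref_matrix: GenotypeMatrix,
    query_matrix: GenotypeMatrix,
    spec: Optional[FilterSpec] = None,
) -> ZygosityBreakdown:
    """Condition concordance on whether the reference call is hom or het."""
    records = classify_matrices(ref_matrix, query_matrix, spec)
    comp = [r for r in records if r.cls is not ConcordanceClass.NOT_COMPARABLE]

    ref_hom = [r for r in comp if r.ref_call.gt.is_hom]
    ref_het = [r for r in comp if r.ref_call.gt.is_het]

    def pct(k: int, n: int) -> float:
        return round(100.0 * k / n, 1) if n else float("nan")

    n_hom = len(ref_hom)
    hom_same = sum(r.cls is ConcordanceClass.CONCORDANT for r in ref_hom)
    hom_disc = [r for r in ref_hom if r.cls is not ConcordanceClass.CONCORDANT]
    hom_disc_het = sum(r.query_call.gt.is_het for r in hom_disc)
    n_het = len(ref_het)
    het_same = sum(r.cls is ConcordanceClass.CONCORDANT for r in ref_het)
    het_qhom = sum(r.query_call.gt.is_hom for r in ref_het)

    return ZygosityBreakdown(
        n_ref_hom=n_hom,
        hom_pct_same=pct(hom_same, n_hom),
        hom_pct_discrepant=pct(n_hom - hom_same, n_hom),
        hom_discrepant_pct_hom=pct(len(hom_disc) - hom_disc_het, len(hom_disc)),
        hom_discrepant_pct_het=pct(hom_disc_het, len(hom_disc)),
        n_ref_het=n_het,
        het_pct_same=pct(het_same, n_het),
        het_pct_query_hom=pct(het_qhom, n_het),
    )


@dataclass
class OptimalDepthResult:
    """Per-sample accuracy-maximising supporting-read count and its
    association with realised coverage."""

    optimal_dp: dict[str, int]
    accuracy_by_dp: dict[str, dict[int, float]]
    pearson_r: float
    p_value: float


def optimal_supporting_reads(
    ref_matrix: GenotypeMatrix,
    query_matrix: GenotypeMatrix,
    coverage: Optional[Sequence[float]] = None,
    min_cells: int = 20,
    spec: Optional[FilterSpec] = None,
) -> OptimalDepthResult:
    """Accuracy within each exact query-depth stratum, per sample.

    The optimum is the depth with maximal accuracy (ties broken toward the
    smaller depth); strata with fewer than ``min_cells`` comparable cells
    are excluded from the argmax. When per-sample coverage is supplied (or
    present on the query matrix) the Pearson correlation of optimum vs
    coverage is reported with its two-sided p-value.
    """
    if coverage is None:
        coverage = query_matrix.coverage
    records = classify_matrices(ref_matrix, query_matrix, spec)

    accuracy_by_dp: dict[str, dict[int, float]] = {}
    optimal: dict[str, int] = {}
    for sample in ref_matrix.samples:
        strata: dict[int, list[bool]] = {}
        for r in records:
            if r.sample != sample or r.cls is ConcordanceClass.NOT_COMPARABLE:
                continue
            strata.setdefault(r.query_call.dp, []).append(
                r.cls is ConcordanceClass.CONCORDANT
            )
        acc = {
            dp: 100.0 * sum(v) / len(v)
            for dp, v in sorted(strata.items())
            if len(v) >= min_cells
        }
        accuracy_by_dp[sample] = acc
        if acc:
            best = max(acc.values())
            optimal[sample] = min(dp for dp, a in acc.items() if a == best)

    r_val, p_val = float("nan"), float("nan")
    if coverage is not None and len(optimal) >= 3:
        xs, ys = [], []
        for j, sample in enumerate(ref_matrix.samples):
            if sample in optimal:
                xs.append(coverage[j])
                ys.append(optimal[sample])
        if len(xs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
            r_val, p_val = sps.pearsonr(xs, ys)
            r_val, p_val = float(r_val), float(p_val)
    return OptimalDepthResult(
        optimal_dp=optimal,
        accuracy_by_dp=accuracy_by_dp,
        pearson_r=r_val,
        p_value=p_val,
    )
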