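"""Heterozygote reassignment for genotyping heterozygous material.

Discarding heterozygous calls only works in fully homozygous panels. Two
reassignment rules convert a heterozygous call to a homozygous class using
evidence already present in the VCF record:

* PL-based: when the heterozygous genotype's PL is non-zero (i.e. het is
  not the most likely genotype), reassign to the homozygous class with the
  smaller PL. A PL tie between the two homozygous classes leaves the call
  unconverted.
* AD-based: reassign to the homozygous class of the majority allele by
  allelic depth; an exact ref/alt tie leaves the call unconverted
  (conservative — the evidence favours neither class). Other-base reads are
  not part of AD and play no role in the majority.

Both rules are idempotent and never touch homozygous or missing calls. The
AD rule converts a superset-like share of heterozygotes (any depth
imbalance triggers it), while the PL rule only fires when the likelihood
ranking itself already contradicts the het call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .concordance import ConcordanceClass, classify_pair
from .filters import FilterSpec, apply_matrix_filters, filter_depth
from .types import Genotype, GenotypeCall, GenotypeMatrix


def adjust_by_pl(call: GenotypeCall) -> GenotypeCall:
    """Reassign a het call to the best homozygous class by PL.

    Fires only when PL_het != 0; a hom/hom PL tie leaves the call as het.
    Raises if a het call carries no PL.
    """
    if call.gt is not Genotype.HET:
        return call
    if call.pl is None:
        raise ValueError("het call without PL cannot be PL-adjusted")
    pl_ref, pl_het, pl_alt = call.pl
    if pl_het == 0:
        return call
    if pl_ref == pl_alt:
        return call
    return call.with_gt(Genotype.HOM_REF if pl_ref < pl_alt else Genotype.HOM_ALT)


def adjust_by_ad(call: GenotypeCall) -> GenotypeCall:
    """Reassign a het call to the homozygous class of the majority allele."""
    if call.gt is not Genotype.HET:
        return call
    ad_ref, ad_alt = call.ad
    if ad_ref == ad_alt:
        return call
    return call.with_gt(Genotype.HOM_REF if ad_ref > ad_alt else Genotype.HOM_ALT)


def adjust_matrix(matrix: GenotypeMatrix, method: str) -> GenotypeMatrix:
    """Apply one reassignment rule ('pl' or 'ad') to a whole matrix."""
    fn = {"pl": adjust_by_pl, "ad": adjust_by_ad}.get(method)
    if fn is None:
        raise ValueError(f"unknown adjustment method {method!r} (use 'pl' or 'ad')")
    return matrix.map_calls(fn)


@dataclass
class AdjustmentOutcome:
    """Conversion tally for one reassignment run.

    When a reference matrix is supplied, converted cells are classified
    against it: concordant, discrepant because the reference is het, or
    discrepant because the reference carries the opposite homozygous class.
    """

    n_het_input: int
    n_converted: int
    pct_converted: float
    pct_concordant: Optional[float] = None
    pct_discrepant_het_ref: Optional[float] = None
    pct_discrepant_alt_hom: Optional[float] = None


def evaluate_adjustment(
    query_before: GenotypeMatrix,
    query_after: GenotypeMatrix,
    ref_matrix: Optional[GenotypeMatrix] = None,
    spec: Optional[FilterSpec] = None,
) -> AdjustmentOutcome:
    """Tally how many heterozygotes a reassignment converted, and how the
    converted calls compare with the reference platform.

    ``spec`` (e.g. a dp 2-5 or dp 4-6 window) is applied to the query
    before counting, so the tally covers the same cells a filtered
    comparison would.
    """
    before = apply_matrix_filters(query_before, spec) if spec else query_before
    after = apply_matrix_filters(query_after, spec) if spec else query_after
    if [l.key for l in before.loci] != [l.key for l in after.loci]:
        raise ValueError("before/after matrices must share the locus panel")

    ref = None
    if ref_matrix is not None:
        ref = ref_matrix.map_calls(lambda c: filter_depth(c, 2, None))
        ref = ref.subset_loci([l.key for l in before.loci])

    n_het = 0
    converted: list[tuple[int, int]] = []
    for i in range(before.n_loci):
        for j in range(before.n_samples):
            b, a = before.calls[i][j], after.calls[i][j]
            if b.gt is Genotype.HET:
                n_het += 1
                if a.gt.is_hom:
                    converted.append((i, j))

    n_conv = len(converted)
    pct_conv = round(100.0 * n_conv / n_het, 1) if n_het else 0.0
    outcome = AdjustmentOutcome(
        n_het_input=n_het, n_converted=n_conv, pct_converted=pct_conv
    )
    if ref is not None and n_conv:
        tallies = {"conc": 0, "het_ref": 0, "alt_hom": 0}
        n_comp = 0
        for i, j in converted:
            cls = classify_pair(ref.calls[i][j], after.calls[i][j])
            if cls is ConcordanceClass.NOT_COMPARABLE:
                continue
            n_comp += 1
            if cls is ConcordanceClass.CONCORDANT:
                tallies["conc"] += 1
            elif cls is ConcordanceClass.HET_REF_HOM_QUERY:
                tallies["het_ref"] += 1
            else:
                tallies["alt_hom"] += 1
        if n_comp:
            outcome.pct_concordant = round(100.0 * tallies["conc"] / n_comp, 1)
            outcome.pct_discrepant_het_ref = round(
                100.0 * tallies["het_ref"] / n_comp, 1
            )
            outcome.pct_discrepant_alt_hom = round(
                100.0 * tallies["alt_hom"] / n_comp, 1
            )
    return outcome
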