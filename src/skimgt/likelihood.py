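"""Diploid genotype calling at known biallelic loci from pileups.

Implements the standard independent-error genotype likelihood: each retained
observation with phred quality q has error probability e = 10^(-q/10), and

    P(b | hom X)  = 1 - e   if b == X, else e/3
    P(b | het)    = (P(b | hom ref) + P(b | hom alt)) / 2

The genotype log-likelihood is the sum of per-observation log terms;
observations matching neither allele still contribute through the error
terms. PLs are the usual phred-scaled, min-normalised likelihoods
(PL_g = round(-10 log10 L_g) - min), and the call is the argmin-PL genotype.

By default no genotype prior is applied (uniform): priors differ across
caller versions, and a uniform prior keeps PLs directly interpretable by
the PL-based heterozygote reassignment downstream. An optional ``het_prior``
gives the prior probability mass of the heterozygous genotype (the two
homozygous classes share the remainder equally). Following the convention
of production callers, the prior affects only the genotype assignment
(argmax of likelihood x prior); PL values remain pure likelihood. Without a
het-suppressing prior, a single error read among up to ~7 high-quality
concordant reads always wins the het call — apparent heterozygosity would
then grow with depth instead of being drowned out by it, which is not how
skim-coverage data behaves under production callers.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from .types import Genotype, GenotypeCall, LocusPileup, SnpLocus

DEFAULT_MIN_BQ = 13  # conventional mpileup default


def phred_to_error(qual: float) -> float:
    """Per-base error probability implied by a phred quality."""
    return 10.0 ** (-qual / 10.0)


def genotype_log_likelihoods(
    pileup: LocusPileup,
    locus: Optional[SnpLocus] = None,
    min_bq: int = DEFAULT_MIN_BQ,
) -> tuple[float, float, float]:
    """Natural-log likelihoods of (hom_ref, het, hom_alt) for one pileup.

    Observations with quality below ``min_bq`` are excluded. An empty
    retained set yields (0, 0, 0); the caller must then emit a missing call.
    """
    if locus is None:
        locus = pileup.locus
    ll = [0.0, 0.0, 0.0]
    for ob in pileup.observations:
        if ob.qual < min_bq:
            continue
        e = phred_to_error(ob.qual)
        p_ref = (1.0 - e) if ob.base == locus.ref else e / 3.0
        p_alt = (1.0 - e) if ob.base == locus.alt else e / 3.0
        ll[0] += math.log(p_ref)
        ll[1] += math.log(0.5 * (p_ref + p_alt))
        ll[2] += math.log(p_alt)
    return (ll[0], ll[1], ll[2])


def counts_after_filter(
    pileup: LocusPileup,
    locus: Optional[SnpLocus] = None,
    min_bq: int = DEFAULT_MIN_BQ,
) -> tuple[int, tuple[int, int]]:
    """(dp, (ref_count, alt_count)) over observations passing min_bq.

    dp counts every retained observation including other-base reads, so
    dp >= ref_count + alt_count.
    """
    if locus is None:
        locus = pileup.locus
    dp = 0
    ad_ref = 0
    ad_alt = 0
    for ob in pileup.observations:
        if ob.qual < min_bq:
            continue
        dp += 1
        if ob.base == locus.ref:
            ad_ref += 1
        elif ob.base == locus.alt:
            ad_alt += 1
    return dp, (ad_ref, ad_alt)


def call_genotype(
    loglik: Sequence[float],
    dp: int,
    ad: tuple[int, int],
    het_prior: Optional[float] = None,
) -> GenotypeCall:
    """Turn log-likelihoods plus depth/allelic-depth into a GenotypeCall.

    PL_g = round(-10 log10 L_g), shifted so min(PL) = 0. With the default
    uniform prior, gt is the argmin-PL genotype; with ``het_prior`` set, gt
    maximises likelihood x prior where the prior is
    ((1-h)/2, h, (1-h)/2), while PL stays prior-free. dp == 0 yields a
    missing call. A tie between a homozygote and the het is broken toward
    the genotype supported by the larger AD component; a residual tie
    yields missing.
    """
    if dp == 0:
        return GenotypeCall(gt=Genotype.MISSING, dp=0, ad=ad, pl=None)

    raw = [-10.0 * ll / math.log(10.0) for ll in loglik]
    m = min(raw)
    pl = tuple(int(round(r - m)) for r in raw)

    if het_prior is None:
        best = min(pl)
        winners = [g for g, p in enumerate(pl) if p == best]
    else:
        if not 0 < het_prior < 1:
            raise ValueError("het_prior must be in (0, 1)")
        lp_hom = math.log((1.0 - het_prior) / 2.0)
        lp_het = math.log(het_prior)
        post = [
            loglik[0] + lp_hom,
            loglik[1] + lp_het,
            loglik[2] + lp_hom,
        ]
        best_post = max(post)
        # float path: tolerate summation-order noise when detecting ties
        winners = [g for g, p in enumerate(post) if p >= best_post - 1e-9]
    if len(winners) == 1:
        gt = Genotype(winners[0])
    else:
        # tie: prefer the genotype the allelic depths support
        if ad[0] > ad[1]:
            preferred = [int(Genotype.HOM_REF), int(Genotype.HET)]
        elif ad[1] > ad[0]:
            preferred = [int(Genotype.HOM_ALT), int(Genotype.HET)]
        else:
            preferred = []
        pick = [g for g in preferred if g in winners]
        gt = Genotype(pick[0]) if pick else Genotype.MISSING
    # ties that AD cannot break yield missing but keep the computed PL
    return GenotypeCall(gt=gt, dp=dp, ad=ad, pl=pl)  # type: ignore[arg-type]


def call_pileup(
    pileup: LocusPileup,
    min_bq: int = DEFAULT_MIN_BQ,
    het_prior: Optional[float] = None,
) -> GenotypeCall:
    """Full pipeline for one pileup: filter by quality, likelihood, call."""
    dp, ad = counts_after_filter(pileup, min_bq=min_bq)
    if dp == 0:
        return GenotypeCall(gt=Genotype.MISSING, dp=0, ad=(0, 0), pl=None)
    ll = genotype_log_likelihoods(pileup, min_bq=min_bq)
    return call_genotype(ll, dp, ad, het_prior=het_prior)
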