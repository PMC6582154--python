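"""End-to-end wiring: simulate -> filter pileups -> call -> matrices.

Convenience layer used by the CLI, the test suite and analysis scripts. It
also provides the canonical two-platform study configuration: nine fully
homozygous DH samples genotyped by a short-read-style reference platform
(low error, misalignment at duplicated loci) and a long-read-style query
platform (~10% random error, no misalignment), with per-sample mean depths
spanning sub-1x to a few x to emulate uneven pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .filters import FilterSpec, apply_pileup_filters
from .likelihood import call_pileup
from .simulate import (
    PlatformConfig,
    SimConfig,
    TruthSet,
    simulate_platform_pileups,
    simulate_truth,
)
from .types import GenotypeMatrix, LocusPileup

# Study-shaped defaults: 9 DH samples; reference platform per-sample depths
# mirror deep-but-variable short-read coverage; query platform depths span
# sub-1x to a few x (uneven pooling across the panel).
N_SAMPLES = 9
REF_DEPTHS = (7.6, 9.1, 4.9, 8.4, 4.4, 6.3, 12.0, 14.4, 9.5)
QUERY_DEPTHS = (4.2, 7.4, 2.8, 3.9, 1.7, 2.4, 4.9, 4.9, 1.7)

LRS_ERROR_RATE = 0.10  # nanopore-like random base error
SRS_ERROR_RATE = 0.001  # short-read-like base error
LRS_MEAN_READ_LENGTH = 7525.0
SRS_MEAN_READ_LENGTH = 150.0
# Reported base qualities: constants above the default q13 caller cutoff so
# quality filtering is neutral by default; the long-read platform's realised
# ~10% error is set by base_error_rate (basecaller overconfidence at error
# sites), not by the reported quality.
LRS_BASE_QUAL = 20
SRS_BASE_QUAL = 30

# Genotype prior for the study caller: expected heterozygosity of doubled-
# haploid material (~1% residual). The prior affects the call only, not PL.
DEFAULT_HET_PRIOR = 0.01


def study_config(
    n_loci: int = 2000,
    seed: int = 0,
    dup_fraction: float = 0.1,
    srs_misalignment_rate: float = 0.5,
    lrs_error_rate: float = LRS_ERROR_RATE,
    query_depths: Sequence[float] = QUERY_DEPTHS,
    ref_depths: Sequence[float] = REF_DEPTHS,
    residual_het_rate: float = 0.0,
    allele_freq: float = 0.5,
) -> SimConfig:
    """The canonical DH two-platform configuration.

    The reference ("srs") platform has near-zero random error but draws a
    fraction of reads from the paralog at duplicated loci; the query
    ("lrs") platform has high random error and no misalignment.
    """
    return SimConfig(
        n_samples=len(query_depths),
        n_loci=n_loci,
        allele_freq=allele_freq,
        residual_het_rate=residual_het_rate,
        dup_fraction=dup_fraction,
        paralog_divergence=1.0,
        platforms={
            "srs": PlatformConfig(
                mean_depth=tuple(ref_depths),
                base_error_rate=SRS_ERROR_RATE,
                misalignment_rate=srs_misalignment_rate,
                mean_read_length=SRS_MEAN_READ_LENGTH,
                base_qual=SRS_BASE_QUAL,
            ),
            "lrs": PlatformConfig(
                mean_depth=tuple(query_depths),
                base_error_rate=lrs_error_rate,
                misalignment_rate=0.0,
                mean_read_length=LRS_MEAN_READ_LENGTH,
                base_qual=LRS_BASE_QUAL,
            ),
        },
        seed=seed,
    )


def call_matrix(
    truth: TruthSet,
    pileups_by_sample: list[list[LocusPileup]],
    spec: Optional[FilterSpec] = None,
    coverage: Optional[Sequence[float]] = None,
    het_prior: Optional[float] = DEFAULT_HET_PRIOR,
) -> GenotypeMatrix:
    """Call genotypes for every sample's pileups into a matrix.

    Pileup-level parts of ``spec`` (read length, end trim, min_bq) are
    applied before calling; matrix-level parts are NOT applied here so that
    different filtering treatments can be compared on one called matrix.
    """
    spec = spec or FilterSpec()
    samples = [f"DH-{i + 1}" for i in range(len(pileups_by_sample))]
    matrix = GenotypeMatrix(truth.loci, samples, coverage=coverage)
    for j, pileups in enumerate(pileups_by_sample):
        for p in pileups:
            fp = apply_pileup_filters(p, spec)
            call = call_pileup(fp, min_bq=spec.min_bq, het_prior=het_prior)
            matrix.set(p.locus.key, samples[j], call)
    return matrix


@dataclass
class SimulatedStudy:
    """A simulated two-platform experiment, called into matrices."""

    truth: TruthSet
    ref_matrix: GenotypeMatrix
    query_matrix: GenotypeMatrix
    ref_pileups: list[list[LocusPileup]]
    query_pileups: list[list[LocusPileup]]


def run_study(
    config: SimConfig,
    spec: Optional[FilterSpec] = None,
    ref_platform: str = "srs",
    query_platform: str = "lrs",
    het_prior: Optional[float] = DEFAULT_HET_PRIOR,
) -> SimulatedStudy:
    """Simulate truth + both platforms and call genotype matrices.

    Per-sample coverage metadata on each matrix is the platform's mean
    depth for that sample (the panel-level analogue of genome coverage).
    """
    truth = simulate_truth(config)
    ss = np.random.SeedSequence(config.seed)
    plat_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(sorted(config.platforms), ss.spawn(len(config.platforms)))
    }
    ref_cfg = config.platforms[ref_platform]
    query_cfg = config.platforms[query_platform]
    ref_pileups = simulate_platform_pileups(truth, ref_cfg, plat_seeds[ref_platform])
    query_pileups = simulate_platform_pileups(
        truth, query_cfg, plat_seeds[query_platform]
    )
    ref_cov = [ref_cfg.depth_for(s) for s in range(config.n_samples)]
    query_cov = [query_cfg.depth_for(s) for s in range(config.n_samples)]
    ref_matrix = call_matrix(truth, ref_pileups, spec, coverage=ref_cov,
                             het_prior=het_prior)
    query_matrix = call_matrix(truth, query_pileups, spec, coverage=query_cov,
                               het_prior=het_prior)
    return SimulatedStudy(
        truth=truth,
        ref_matrix=ref_matrix,
        query_matrix=query_matrix,
        ref_pileups=ref_pileups,
        query_pileups=query_pileups,
    )
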