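"""Synthetic doubled-haploid truth sets and per-platform pileups.

Emulates the statistical structure of a two-platform genotyping comparison
in a doubled-haploid (DH) panel:

* Truth genotypes are homozygous at every locus (DH expectation), with an
  optional residual heterozygosity leak.
* A short-read-style platform ("SRS") has a very low random base error but,
  at loci lying in duplicated regions, a fraction of its reads originates
  from the paralogous copy and co-aligns to the locus — the hemi-SNP
  mechanism. Its apparent heterozygosity is therefore systematic and
  coverage-independent.
* A long-read-style platform ("LRS") has a high (~10%) random base error and
  no misalignment: its apparent heterozygosity is driven by sampling noise
  and shrinks with coverage.

Simulation operates at the pileup level: alignment itself is out of scope,
so misalignment is modelled as a read-origin mixture at duplicated loci.
Read lengths follow a unimodal log-normal distribution around the platform
mean, and each observation carries a position within its read so end-trim
and length filters act on realistic metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import BASES, Genotype, LocusPileup, PileupObservation, SnpLocus

MIN_READ_LENGTH = 100  # bp floor of the shifted geometric length model


@dataclass(frozen=True)
class NucleotideBias:
    """Optional error-channel bias multipliers.

    ``gc_substitution`` scales the base-substitution probability when the
    truth base is G or C; ``at_deletion`` is the probability an observation
    whose truth base is A or T is dropped from the pileup (deletions are
    modelled as observation dropout only, since indel genotyping is out of
    scope).
    """

    gc_substitution: float = 1.0
    at_deletion: float = 0.0

    def __post_init__(self) -> None:
        if self.gc_substitution < 0:
            raise ValueError("gc_substitution multiplier must be >= 0")
        if not 0 <= self.at_deletion < 1:
            raise ValueError("at_deletion must be in [0, 1)")


@dataclass(frozen=True)
class PlatformConfig:
    """Sequencing-platform block of the simulation configuration.

    ``mean_depth`` is per sample (one value per sample allows the uneven
    pooling that produces variable genome coverage across samples);
    ``base_error_rate`` the per-base substitution probability;
    ``misalignment_rate`` the fraction of reads at duplicated loci drawn
    from the paralog; ``base_qual`` the constant phred quality reported for
    every observation, optionally jittered per observation by up to
    ``qual_jitter`` either way.

    Reported quality and realised error are deliberately decoupled: the
    caller consumes quality only through its implied error probability, and
    long-read basecallers are overconfident at error sites, so the realised
    substitution rate is controlled by ``base_error_rate`` while
    ``base_qual`` sets what the caller is told. The platform constant
    should normally sit above the caller's minimum-base-quality cutoff,
    otherwise every observation is excluded before calling.
    """

    mean_depth: tuple[float, ...]
    base_error_rate: float = 0.0
    misalignment_rate: float = 0.0
    mean_read_length: float = 7500.0
    base_qual: int = 30
    qual_jitter: int = 0
    nucleotide_bias: Optional[NucleotideBias] = None

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.mean_depth):
            raise ValueError("mean depths must be >= 0")
        if not 0 <= self.base_error_rate < 1:
            raise ValueError("base_error_rate must be in [0, 1)")
        if not 0 <= self.misalignment_rate <= 1:
            raise ValueError("misalignment_rate must be in [0, 1]")
        if self.mean_read_length <= 0:
            raise ValueError("mean_read_length must be > 0")
        if self.base_qual < 0:
            raise ValueError("base_qual must be >= 0")
        if self.qual_jitter < 0 or self.qual_jitter > self.base_qual:
            raise ValueError("qual_jitter must be in [0, base_qual]")

    def depth_for(self, sample: int) -> float:
        if len(self.mean_depth) == 1:
            return self.mean_depth[0]
        return self.mean_depth[sample]


@dataclass(frozen=True)
class SimConfig:
    """Full simulation configuration for a DH two-platform experiment.

    ``allele_freq`` is the probability a locus's truth genotype is hom-alt;
    ``residual_het_rate`` the probability a truth genotype is heterozygous
    (DH production is not always complete); ``dup_fraction`` the probability
    a locus lies in a duplicated region; ``paralog_divergence`` the
    probability the paralogous copy carries the non-truth allele at a
    duplicated locus (only divergent paralogs can manufacture hemi-SNPs).
    """

    n_samples: int
    n_loci: int
    allele_freq: float = 0.5
    residual_het_rate: float = 0.0
    dup_fraction: float = 0.0
    paralog_divergence: float = 1.0
    platforms: dict[str, PlatformConfig] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0 or self.n_loci < 0:
            raise ValueError("n_samples and n_loci must be >= 0")
        for name, p in (
            ("allele_freq", self.allele_freq),
            ("residual_het_rate", self.residual_het_rate),
            ("dup_fraction", self.dup_fraction),
            ("paralog_divergence", self.paralog_divergence),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for pname, plat in self.platforms.items():
            if len(plat.mean_depth) not in (1, self.n_samples):
                raise ValueError(
                    f"platform {pname!r}: mean_depth must have length 1 or "
                    f"n_samples={self.n_samples}"
                )


@dataclass
class TruthSet:
    """Simulated ground truth: loci, genotypes, and duplication annotations.

    ``genotypes`` is loci x samples; ``paralog_alleles[i]`` is the base
    carried by the paralog at duplicated locus i (equal to the truth-allele
    base when the paralog is not divergent), or None at non-duplicated loci.
    """

    loci: list[SnpLocus]
    genotypes: np.ndarray  # int8, values from Genotype
    paralog_alleles: list[Optional[str]]
    config: SimConfig

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return 0 if self.genotypes.size == 0 else self.genotypes.shape[1]

    @property
    def dup_flags(self) -> np.ndarray:
        return np.array([loc.dup_flag for loc in self.loci], dtype=bool)

    def truth_call(self, locus_idx: int, sample: int) -> Genotype:
        return Genotype(int(self.genotypes[locus_idx, sample]))

    def to_tsv(self, path) -> None:
        """Write the truth set as TSV: chrom, pos, ref, alt, dup_flag, GTs."""
        code = {0: "hom_ref", 1: "het", 2: "hom_alt"}
        with open(path, "w") as fh:
            names = "\t".join(f"sample_{i}" for i in range(self.n_samples))
            fh.write(f"chrom\tpos\tref\talt\tdup_flag\t{names}\n")
            for i, loc in enumerate(self.loci):
                gts = "\t".join(
                    code[int(g)] for g in self.genotypes[i]
                )
                fh.write(
                    f"{loc.chrom}\t{loc.pos}\t{loc.ref}\t{loc.alt}\t"
                    f"{int(loc.dup_flag)}\t{gts}\n"
                )


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_truth(config: SimConfig) -> TruthSet:
    """Draw a DH truth set.

    Each locus draws ref/alt alleles uniformly (distinct), a duplication
    flag with probability ``dup_fraction``, and per-sample genotypes:
    hom-alt with probability ``allele_freq``, else hom-ref, then flipped to
    het with probability ``residual_het_rate``. At duplicated loci the
    paralog carries the non-ref allele with probability
    ``paralog_divergence``. Deterministic given ``config.seed``.
    """
    rng = _rng(config.seed)
    n_loci, n_samples = config.n_loci, config.n_samples

    loci: list[SnpLocus] = []
    paralog_alleles: list[Optional[str]] = []
    dup_draw = rng.random(n_loci) < config.dup_fraction
    for i in range(n_loci):
        ref, alt = rng.choice(4, size=2, replace=False)
        loc = SnpLocus(
            chrom="chr1",
            pos=i + 1,
            ref=BASES[ref],
            alt=BASES[alt],
            dup_flag=bool(dup_draw[i]),
        )
        loci.append(loc)
        if loc.dup_flag:
            divergent = rng.random() < config.paralog_divergence
            paralog_alleles.append(loc.alt if divergent else loc.ref)
        else:
            paralog_alleles.append(None)

    genotypes = np.where(
        rng.random((n_loci, n_samples)) < config.allele_freq,
        int(Genotype.HOM_ALT),
        int(Genotype.HOM_REF),
    ).astype(np.int8)
    het_mask = rng.random((n_loci, n_samples)) < config.residual_het_rate
    genotypes[het_mask] = int(Genotype.HET)
    genotypes = genotypes.reshape(n_loci, n_samples)

    return TruthSet(
        loci=loci,
        genotypes=genotypes,
        paralog_alleles=paralog_alleles,
        config=config,
    )


READ_LENGTH_LOG_SD = 0.25  # log-normal spread (CV ~ 25%)


def _draw_read_geometry(
    rng: np.random.Generator, mean_read_length: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (read_length, read_offset) arrays for ``n`` observations.

    Lengths are log-normal with the requested mean and a fixed CV of ~25%
    (floored at MIN_READ_LENGTH): sequencing libraries prepared without
    shearing produce unimodal length distributions around the fragment
    mean, and an exponential-tailed model would grossly over-represent
    near-minimum reads, inflating the share of observations close to a
    read end. The locus position within the read is uniform, and the
    offset recorded is the distance to the nearer end.
    """
    sd = READ_LENGTH_LOG_SD
    mu = math.log(max(mean_read_length, MIN_READ_LENGTH)) - sd * sd / 2.0
    lengths = np.maximum(
        rng.lognormal(mean=mu, sigma=sd, size=n).astype(np.int64),
        MIN_READ_LENGTH,
    )
    pos = (rng.random(n) * lengths).astype(np.int64)  # 0-based within read
    offsets = np.minimum(pos, lengths - 1 - pos)
    return lengths, offsets


def simulate_pileup(
    truth: TruthSet,
    sample: int,
    platform: PlatformConfig,
    seed: int,
) -> list[LocusPileup]:
    """Simulate one sample's pileups under one platform model.

    Per locus the observation count is Poisson(mean_depth). Each observation
    draws its originating allele from the truth genotype (het: each allele
    w.p. 1/2); at a duplicated locus the observation is first replaced by a
    paralog-allele read with probability ``misalignment_rate``. The base is
    then substituted uniformly to one of the three other bases with
    probability ``base_error_rate`` (scaled by the G/C multiplier when bias
    is enabled), and observations of A/T truth bases are dropped with the
    A/T deletion probability. Base quality is the platform constant.
    """
    if not 0 <= sample < truth.n_samples:
        raise IndexError(
            f"sample index {sample} out of range for {truth.n_samples} samples"
        )
    rng = _rng(seed)
    depth = platform.depth_for(sample)
    bias = platform.nucleotide_bias
    n_loci = truth.n_loci
    base_index = {b: i for i, b in enumerate(BASES)}

    n_obs = rng.poisson(depth, size=n_loci)
    total = int(n_obs.sum())
    locus_of = np.repeat(np.arange(n_loci), n_obs)

    ref_codes = np.array([base_index[l.ref] for l in truth.loci], dtype=np.int8)
    alt_codes = np.array([base_index[l.alt] for l in truth.loci], dtype=np.int8)
    par_codes = np.array(
        [base_index[a] if a is not None else -1 for a in truth.paralog_alleles],
        dtype=np.int8,
    )
    dup = truth.dup_flags
    gts = truth.genotypes[:, sample] if truth.n_samples else np.zeros(0, np.int8)

    # read origin: truth haplotype, or the paralog at duplicated loci
    g = gts[locus_of]
    het_coin = rng.random(total) < 0.5
    true_code = np.where(g == int(Genotype.HOM_ALT), alt_codes[locus_of],
                         ref_codes[locus_of])
    het_mask = g == int(Genotype.HET)
    true_code = np.where(
        het_mask & het_coin, alt_codes[locus_of], true_code
    )
    misaligned = dup[locus_of] & (rng.random(total) < platform.misalignment_rate)
    true_code = np.where(misaligned, par_codes[locus_of], true_code).astype(np.int8)

    # uniform substitution to one of the 3 other bases, G/C-scaled with bias
    err = np.full(total, platform.base_error_rate)
    if bias is not None:
        gc = (true_code == base_index["G"]) | (true_code == base_index["C"])
        err = np.where(gc, np.minimum(err * bias.gc_substitution, 0.999), err)
    err_mask = rng.random(total) < err
    shift = rng.integers(1, 4, size=total)  # 1..3 steps away from the true base
    code = np.where(err_mask, (true_code + shift) % 4, true_code).astype(np.int8)

    # A/T deletion bias: observation dropped entirely
    keep = np.ones(total, dtype=bool)
    if bias is not None and bias.at_deletion > 0:
        at = (true_code == base_index["A"]) | (true_code == base_index["T"])
        keep &= ~(at & (rng.random(total) < bias.at_deletion))

    lengths, offsets = _draw_read_geometry(rng, platform.mean_read_length, total)
    quals = np.full(total, platform.base_qual, dtype=np.int64)
    if platform.qual_jitter:
        quals += rng.integers(
            -platform.qual_jitter, platform.qual_jitter + 1, size=total
        )

    pileups: list[LocusPileup] = []
    bounds = np.concatenate([[0], np.cumsum(n_obs)])
    for i, locus in enumerate(truth.loci):
        lo, hi = int(bounds[i]), int(bounds[i + 1])
        obs = [
            PileupObservation(
                base=BASES[code[k]],
                qual=int(quals[k]),
                read_length=int(lengths[k]),
                read_offset=int(offsets[k]),
            )
            for k in range(lo, hi)
            if keep[k]
        ]
        pileups.append(LocusPileup(locus=locus, observations=obs))
    return pileups


def simulate_platform_pileups(
    truth: TruthSet, platform: PlatformConfig, seed: int
) -> list[list[LocusPileup]]:
    """Pileups for every sample; per-sample seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(truth.n_samples)]
    return [
        simulate_pileup(truth, s, platform, child_seeds[s])
        for s in range(truth.n_samples)
    ]


def realised_coverage(pileups: list[LocusPileup], genome_size: float) -> float:
    """Genome-coverage multiple implied by summing simulated read lengths.

    Each observation stands for one read; coverage = total read bases /
    genome size. With a panel-scale simulation the 'genome' is the panel
    footprint, so callers pass a genome_size consistent with mean_depth
    (total_expected_reads * mean_read_length / mean_depth).
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    total = sum(ob.read_length for p in pileups for ob in p.observations)
    return total / genome_size


def write_pileups_jsonl(pileups: list[LocusPileup], path) -> None:
    """Serialise pileups as JSON-lines (one locus per line)."""
    with open(path, "w") as fh:
        for p in pileups:
            rec = {
                "chrom": p.locus.chrom,
                "pos": p.locus.pos,
                "ref": p.locus.ref,
                "alt": p.locus.alt,
                "dup_flag": p.locus.dup_flag,
                "obs": [
                    [ob.base, ob.qual, ob.read_length, ob.read_offset]
                    for ob in p.observations
                ],
            }
            fh.write(json.dumps(rec) + "\n")


def read_pileups_jsonl(path) -> list[LocusPileup]:
    """Read pileups written by :func:`write_pileups_jsonl`."""
    out: list[LocusPileup] = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            locus = SnpLocus(
                chrom=rec["chrom"],
                pos=rec["pos"],
                ref=rec["ref"],
                alt=rec["alt"],
                dup_flag=rec["dup_flag"],
            )
            obs = [
                PileupObservation(base=b, qual=q, read_length=rl, read_offset=ro)
                for b, q, rl, ro in rec["obs"]
            ]
            out.append(LocusPileup(locus=locus, observations=obs))
    return out
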