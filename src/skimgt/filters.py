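"""Filtering treatments applied to pileups and genotype matrices.

Two families: pileup-level filters (read length, end trimming) that shrink
the observation set before calling, and call/matrix-level filters (depth
range, heterozygote removal, locus-subset restriction) applied after
calling. Depth bounds are inclusive on both ends: "between 2 and 5
supporting reads" retains dp in {2,3,4,5}. Read-length filtering uses a
strict lower bound (reads strictly longer than the threshold pass).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

from .types import Genotype, GenotypeCall, GenotypeMatrix, LocusPileup


@dataclass(frozen=True)
class FilterSpec:
    """A composable description of one filtering treatment.

    ``dp_min``/``dp_max``: inclusive depth range applied to calls (None =
    unbounded); ``drop_het``: set heterozygous calls to missing;
    ``min_read_length``/``end_trim``: pileup-level read filters in bp;
    ``min_bq``: phred base-quality cutoff the caller applies;
    ``locus_subset``: optional set of (chrom, pos) keys; ``at_only``:
    restrict to loci whose ref and alt are both A or T.
    """

    dp_min: Optional[int] = None
    dp_max: Optional[int] = None
    drop_het: bool = False
    min_read_length: Optional[int] = None
    end_trim: Optional[int] = None
    min_bq: int = 13
    locus_subset: Optional[frozenset] = None
    at_only: bool = False

    def __post_init__(self) -> None:
        if (
            self.dp_min is not None
            and self.dp_max is not None
            and self.dp_min > self.dp_max
        ):
            raise ValueError(f"dp_min {self.dp_min} > dp_max {self.dp_max}")
        if self.end_trim is not None and self.end_trim < 0:
            raise ValueError("end_trim must be >= 0")

    def to_config(self) -> str:
        """Serialise as key=value lines (keys named exactly as the fields)."""
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None or v == f.default:
                continue
            if f.name == "locus_subset":
                v = ",".join(f"{c}:{p}" for c, p in sorted(v))
            lines.append(f"{f.name}={v}")
        return "\n".join(lines)

    @classmethod
    def from_config(cls, text: str) -> "FilterSpec":
        kwargs = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if key in ("dp_min", "dp_max", "min_read_length", "end_trim", "min_bq"):
                kwargs[key] = int(val)
            elif key in ("drop_het", "at_only"):
                kwargs[key] = val.lower() in ("true", "1", "yes")
            elif key == "locus_subset":
                keys = []
                for tok in val.split(","):
                    c, _, p = tok.partition(":")
                    keys.append((c, int(p)))
                kwargs[key] = frozenset(keys)
            else:
                raise ValueError(f"unknown FilterSpec key {key!r}")
        return cls(**kwargs)


def filter_depth(
    call: GenotypeCall,
    dp_min: Optional[int] = None,
    dp_max: Optional[int] = None,
) -> GenotypeCall:
    """Set the call to missing when its depth falls outside [dp_min, dp_max]."""
    if call.is_missing:
        return call
    if dp_min is not None and call.dp < dp_min:
        return call.as_missing()
    if dp_max is not None and call.dp > dp_max:
        return call.as_missing()
    return call


def drop_heterozygotes(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Replace every heterozygous call with missing; hom calls untouched."""
    return matrix.map_calls(
        lambda c: c.as_missing() if c.gt is Genotype.HET else c
    )


def filter_read_length(pileup: LocusPileup, min_len: int) -> LocusPileup:
    """Drop observations from reads not longer than ``min_len`` bp (strict)."""
    kept = [ob for ob in pileup.observations if ob.read_length > min_len]
    return LocusPileup(locus=pileup.locus, observations=kept)


def trim_read_ends(pileup: LocusPileup, trim: int) -> LocusPileup:
    """Drop observations within ``trim`` bp of either read end."""
    kept = [ob for ob in pileup.observations if ob.read_offset >= trim]
    return LocusPileup(locus=pileup.locus, observations=kept)


def apply_pileup_filters(pileup: LocusPileup, spec: FilterSpec) -> LocusPileup:
    """Apply the pileup-level parts of a FilterSpec (length, then trim)."""
    out = pileup
    if spec.min_read_length is not None:
        out = filter_read_length(out, spec.min_read_length)
    if spec.end_trim:
        out = trim_read_ends(out, spec.end_trim)
    return out


def restrict_loci(
    matrix: GenotypeMatrix,
    subset: Optional[frozenset] = None,
    at_only: bool = False,
) -> GenotypeMatrix:
    """Restrict the matrix to a locus subset and/or A/T-only loci."""
    keys = [loc.key for loc in matrix.loci]
    if subset is not None:
        keys = [k for k in keys if k in subset]
    if at_only:
        at_keys = {loc.key for loc in matrix.loci if loc.is_at_only}
        keys = [k for k in keys if k in at_keys]
    return matrix.subset_loci(keys)


def apply_matrix_filters(matrix: GenotypeMatrix, spec: FilterSpec) -> GenotypeMatrix:
    """Apply the call/matrix-level parts of a FilterSpec.

    Order: locus restriction, heterozygote removal, depth range. Het removal
    and the depth filter commute (each only moves calls to missing based on
    independent attributes), so the order is a convention, not a semantics.
    """
    out = matrix
    if spec.locus_subset is not None or spec.at_only:
        out = restrict_loci(out, spec.locus_subset, spec.at_only)
    if spec.drop_het:
        out = drop_heterozygotes(out)
    if spec.dp_min is not None or spec.dp_max is not None:
        out = out.map_calls(lambda c: filter_depth(c, spec.dp_min, spec.dp_max))
    return out
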