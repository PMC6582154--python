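"""Readers and writers for the pipeline's on-disk formats.

* SNP panel: TSV with header ``chrom pos ref alt`` (optional ``dup_flag``),
  1-based positions. Indel and triallelic rows are rejected and counted.
* Genotype matrices: minimal multi-sample VCF 4.2 with FORMAT GT:DP:AD:PL,
  missing genotype "./.". Written by a thin emitter; read back through
  pysam, so anything htslib parses (phased separators included) is
  accepted.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pysam

from .types import Genotype, GenotypeCall, GenotypeMatrix, SnpLocus

logger = logging.getLogger(__name__)

_GT_STRINGS = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


class SnpListError(ValueError):
    pass


def read_snp_list(path) -> list[SnpLocus]:
    """Read a pre-validated SNP panel from TSV.

    Rows whose ref or alt is not a single A/C/G/T base (indels, or
    comma-separated triallelic alternates) are rejected; the rejected count
    is logged. A malformed row or a duplicated (chrom, pos) raises with the
    line number.
    """
    loci: list[SnpLocus] = []
    seen: set[tuple[str, int]] = set()
    n_rejected = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["chrom", "pos", "ref", "alt"]
        if header[: len(required)] != required:
            raise SnpListError(
                f"{path}: header must start with {required}, got {header}"
            )
        has_dup = len(header) > 4 and header[4] == "dup_flag"
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise SnpListError(f"{path}:{lineno}: expected >= 4 columns")
            chrom, pos_s, ref, alt = parts[:4]
            try:
                pos = int(pos_s)
            except ValueError:
                raise SnpListError(f"{path}:{lineno}: non-integer position {pos_s!r}")
            if len(ref) != 1 or len(alt) != 1 or "," in alt:
                n_rejected += 1  # indel or multi-allelic row
                continue
            if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
                n_rejected += 1
                continue
            key = (chrom, pos)
            if key in seen:
                raise SnpListError(f"{path}:{lineno}: duplicate locus {chrom}:{pos}")
            seen.add(key)
            dup_flag = bool(int(parts[4])) if has_dup and len(parts) > 4 else False
            loci.append(SnpLocus(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                 dup_flag=dup_flag))
    if n_rejected:
        logger.info("read_snp_list: rejected %d indel/triallelic rows", n_rejected)
    return loci


def write_snp_list(loci: Sequence[SnpLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tdup_flag\n")
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.pos}\t{loc.ref}\t{loc.alt}\t{int(loc.dup_flag)}\n"
            )


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a genotype matrix as minimal VCF 4.2 (FORMAT GT:DP:AD:PL)."""
    contigs = []
    for loc in matrix.loci:
        if loc.chrom not in contigs:
            contigs.append(loc.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=skimgt\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            '##FORMAT=<ID=PL,Number=G,Type=Integer,'
            'Description="Phred-scaled genotype likelihoods">\n'
        )
        cols = "\t".join(
            ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
            + matrix.samples
        )
        fh.write(cols + "\n")
        for i, loc in enumerate(matrix.loci):
            cells = []
            for call in matrix.calls[i]:
                gt = _GT_STRINGS[call.gt]
                dp = str(call.dp)
                ad = f"{call.ad[0]},{call.ad[1]}"
                pl = ",".join(str(p) for p in call.pl) if call.pl else "."
                cells.append(f"{gt}:{dp}:{ad}:{pl}")
            row = "\t".join(
                [loc.chrom, str(loc.pos), ".", loc.ref, loc.alt, ".", ".", ".",
                 "GT:DP:AD:PL"]
                + cells
            )
            fh.write(row + "\n")


def _gt_from_indices(indices) -> Genotype:
    alleles = [a for a in indices if a is not None]
    if len(alleles) < 2:
        return Genotype.MISSING
    a, b = alleles[0], alleles[1]
    if a == b == 0:
        return Genotype.HOM_REF
    if a == b == 1:
        return Genotype.HOM_ALT
    return Genotype.HET


def read_vcf(
    path,
    panel: Sequence[SnpLocus],
    coverage: Optional[Sequence[float]] = None,
) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix over a locus panel.

    Panel loci absent from the file become missing calls; multi-allelic
    records are skipped with a log message; phased genotype separators are
    accepted. GT is required; DP/AD/PL are carried when present.
    """
    panel = list(panel)
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        matrix = GenotypeMatrix(panel, samples, coverage=coverage)
        panel_keys = {loc.key for loc in panel}
        for rec in vf:
            key = (rec.chrom, rec.pos)
            if key not in panel_keys:
                continue
            if rec.alts is not None and len(rec.alts) > 1:
                logger.info("read_vcf: skipping multi-allelic record %s:%d",
                            rec.chrom, rec.pos)
                continue
            for sample in samples:
                sd = rec.samples[sample]
                gt = _gt_from_indices(sd.get("GT") or ())
                dp = sd.get("DP")
                dp = int(dp) if dp is not None else 0
                ad_raw = sd.get("AD")
                if ad_raw is not None and len(ad_raw) >= 2 and ad_raw[0] is not None:
                    ad = (int(ad_raw[0]), int(ad_raw[1]))
                else:
                    ad = (0, 0)
                pl_raw = sd.get("PL")
                pl: Optional[tuple[int, int, int]]
                if (
                    gt is not Genotype.MISSING
                    and pl_raw is not None
                    and len(pl_raw) == 3
                    and all(p is not None for p in pl_raw)
                ):
                    pl = (int(pl_raw[0]), int(pl_raw[1]), int(pl_raw[2]))
                    shift = min(pl)
                    pl = tuple(p - shift for p in pl)  # type: ignore[assignment]
                else:
                    pl = None
                if gt is Genotype.MISSING:
                    call = GenotypeCall(gt=gt, dp=dp, ad=ad, pl=None)
                else:
                    call = GenotypeCall(gt=gt, dp=max(dp, ad[0] + ad[1]), ad=ad, pl=pl)
                matrix.set(key, sample, call)
    return matrix


def write_report_tsv(df, path) -> None:
    """Write a pandas report table as TSV."""
    df.to_csv(Path(path), sep="\t", index=False)
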