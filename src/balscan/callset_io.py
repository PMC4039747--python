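"""Variant call sets with per-allele read counts, and windowed depth tracks.

The allelic ratio computed here — alt reads over total reads at the site —
is the central screening statistic: a homozygous chromosomal mutation
rescued by one wild-type copy on the duplication sits at 2/3, a homozygous
site outside the duplication at 1, and a single mutant copy out of three at
1/3.

VCF (1-based) positions are converted to the internal 0-based convention on
read and back on write.  Per-allele depths travel in the standard sample AD
field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import pandas as pd
import pysam

from .errors import FormatError, ValidationError

__all__ = [
    "VariantCall",
    "DepthTrack",
    "allelic_ratio",
    "read_calls",
    "write_calls",
    "read_depth_track",
    "write_depth_track",
    "calls_to_frame",
]


@dataclass(frozen=True)
class VariantCall:
    """One biallelic call: site, alleles and per-allele read counts.

    Alleles use VCF conventions (indels left-anchored on a shared base), so
    a (chromosome, position, ref, alt) tuple is a normalized identity key.
    """

    chromosome: str
    position: int  # 0-based
    ref: str
    alt: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(f"negative read count at {self.chromosome}:{self.position}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt at {self.chromosome}:{self.position}")

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.alt) > len(self.ref):
            return "insertion"
        return "deletion"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    def with_counts(self, ref_count: int, alt_count: int) -> "VariantCall":
        return replace(self, ref_count=ref_count, alt_count=alt_count)


def allelic_ratio(call: VariantCall) -> float:
    """Fraction of reads supporting the alternate allele, alt/(alt+ref)."""
    total = call.ref_count + call.alt_count
    if total == 0:
        raise ValidationError(
            f"allelic ratio undefined at {call.chromosome}:{call.position}: zero depth"
        )
    return call.alt_count / total


@dataclass
class DepthTrack:
    """Mean read depth per fixed-width window, sorted and non-overlapping."""

    windows: list[tuple[str, int, int, float]]

    def __post_init__(self) -> None:
        self.windows = sorted(self.windows, key=lambda w: (w[0], w[1]))
        prev: dict[str, int] = {}
        for chrom, start, end, depth in self.windows:
            if depth < 0:
                raise ValidationError(f"negative depth in window {chrom}:{start}-{end}")
            if start >= end:
                raise ValidationError(f"empty window {chrom}:{start}-{end}")
            if chrom in prev and start < prev[chrom]:
                raise ValidationError(f"overlapping windows on {chrom} at {start}")
            prev[chrom] = end

    def mean_depth(self, chromosome: str, start: int, end: int) -> float:
        """Mean of window depths whose midpoints fall inside [start, end)."""
        depths = [
            d
            for chrom, s, e, d in self.windows
            if chrom == chromosome and start <= (s + e) // 2 < end
        ]
        if not depths:
            raise ValidationError(f"no windows inside {chromosome}:{start}-{end}")
        return sum(depths) / len(depths)

    def count_windows(self, chromosome: str, start: int, end: int) -> int:
        return sum(
            1
            for chrom, s, e, _ in self.windows
            if chrom == chromosome and start <= (s + e) // 2 < end
        )


# ---------------------------------------------------------------------------
# VCF


def read_calls(path: str | os.PathLike) -> list[VariantCall]:
    """Parse a VCF with per-allele depths (sample AD field).

    Multiallelic records are split into one call per alternate allele; the
    reference count is shared across the splits.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            ad = None
            if sample_names:
                sample = rec.samples[sample_names[0]]
                ad = sample.get("AD")
            if ad is None or ad[0] is None:
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} {rec.ref}>"
                    f"{','.join(rec.alts or ())} lacks an AD (allele depth) field"
                )
            if rec.alts is None:
                continue
            if len(ad) != 1 + len(rec.alts):
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} has {len(ad)} AD values "
                    f"for {len(rec.alts)} alt allele(s)"
                )
            for i, alt in enumerate(rec.alts):
                calls.append(
                    VariantCall(
                        chromosome=rec.chrom,
                        position=rec.start,
                        ref=rec.ref,
                        alt=alt,
                        ref_count=int(ad[0]),
                        alt_count=int(ad[i + 1]),
                    )
                )
    return calls


def write_calls(
    calls: list[VariantCall],
    path: str | os.PathLike,
    contigs: dict[str, int],
    sample: str = "STRAIN",
) -> None:
    """Write biallelic records (sorted) to an uncompressed VCF with AD."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("AD", "R", "Integer", "Read depth per allele (ref, alt)")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (c.chromosome, c.position, c.ref, c.alt)):
            rec = out.new_record(
                contig=call.chromosome,
                start=call.position,
                stop=call.position + len(call.ref),
                alleles=(call.ref, call.alt),
            )
            rec.samples[sample]["GT"] = (None, None)
            rec.samples[sample]["AD"] = (call.ref_count, call.alt_count)
            out.write(rec)


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    """Normalized tabular view (1-based positions, ratio column)."""
    rows = []
    for c in calls:
        total = c.ref_count + c.alt_count
        rows.append(
            {
                "chrom": c.chromosome,
                "pos": c.position + 1,
                "ref": c.ref,
                "alt": c.alt,
                "kind": c.kind,
                "ref_count": c.ref_count,
                "alt_count": c.alt_count,
                "ratio": c.alt_count / total if total else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "kind", "ref_count", "alt_count", "ratio"],
    )


# ---------------------------------------------------------------------------
# bedGraph


def read_depth_track(path: str | os.PathLike) -> DepthTrack:
    windows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{line_no}: expected 4 bedGraph columns")
            chrom, start, end, depth = fields[:4]
            windows.append((chrom, int(start), int(end), float(depth)))
    return DepthTrack(windows)


def write_depth_track(track: DepthTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, depth in track.windows:
            fh.write(f"{chrom}\t{start}\t{end}\t{depth:.4f}\n")
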