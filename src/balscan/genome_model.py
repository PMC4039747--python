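"""Reference genome, gene models and balancer geometry.

All coordinates inside the package are 0-based, half-open.  The two standard
interchange formats touched here use 1-based conventions (GFF3: 1-based
inclusive; zone/marker TSVs follow GFF3), and are converted at the I/O
boundary only.

The balancer geometry describes a free duplication: an extrachromosomal
fragment carrying wild-type copies of the left arm of a chromosome.  An
animal homozygous for a recessive lethal under the duplication survives
because the fragment supplies a third, wild-type allele; variant sites on the
two mutant homologs are therefore expected at a 2-of-3 allele dosage inside
the duplicated interval and 2-of-2 outside it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import BoundsError, FormatError, ValidationError

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "Genome",
    "GeneModel",
    "MarkerLocus",
    "MapZone",
    "BalancerConfig",
    "load_genome",
    "write_genome",
    "load_gene_models",
    "write_gene_models",
    "extract_cds",
    "translate_cds",
    "reverse_complement",
    "load_zones",
    "write_zones",
    "load_markers",
    "write_markers",
]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class Genome:
    """Nucleotide sequences keyed by chromosome name (uppercase A/C/G/T/N)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValidationError(
                    f"chromosome {name!r} contains invalid characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        seq = self.sequences[chromosome]
        if start < 0 or end > len(seq) or start > end:
            raise BoundsError(
                f"interval [{start}, {end}) outside {chromosome} (length {len(seq)})"
            )
        return seq[start:end]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: ordered, non-overlapping CDS segments on one strand.

    ``cds_segments`` are stored in genomic order regardless of strand; the
    transcription order for minus-strand genes is obtained by reversing and
    complementing at extraction time.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.cds_segments:
            raise ValidationError(f"{self.gene_id}: gene needs at least one CDS segment")
        object.__setattr__(self, "cds_segments", tuple(map(tuple, self.cds_segments)))
        prev_end = None
        for start, end in self.cds_segments:
            if start >= end:
                raise ValidationError(f"{self.gene_id}: empty CDS segment [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"{self.gene_id}: CDS segments overlap or are unsorted at {start}"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.cds_segments[0][0]

    @property
    def end(self) -> int:
        return self.cds_segments[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Inter-segment intervals, genomic order, 0-based half-open."""
        pairs = []
        for (s0, e0), (s1, e1) in zip(self.cds_segments, self.cds_segments[1:]):
            pairs.append((e0, s1))
        return tuple(pairs)

    def splice_positions(self) -> frozenset[int]:
        """Genomic positions of the two intronic bases at each intron end.

        These are the minimal donor/acceptor dinucleotides (GT..AG on the
        coding strand); a substitution here is a splice-signal disruption.
        """
        pos: set[int] = set()
        for s, e in self.introns:
            pos.update((s, s + 1, e - 2, e - 1))
        return frozenset(pos)

    def contains_cds(self, position: int) -> bool:
        return any(s <= position < e for s, e in self.cds_segments)

    def coding_offset(self, position: int) -> int | None:
        """0-based offset of a genomic position within the CDS in transcription
        order, or None when the position is not coding."""
        offset = 0
        for s, e in self.cds_segments:
            if s <= position < e:
                plus = offset + (position - s)
                if self.strand == "+":
                    return plus
                return self.cds_length - 1 - plus
            offset += e - s
        return None

    def genomic_position(self, coding_offset: int) -> int:
        """Inverse of :meth:`coding_offset`."""
        if not 0 <= coding_offset < self.cds_length:
            raise BoundsError(f"{self.gene_id}: coding offset {coding_offset} out of range")
        idx = coding_offset if self.strand == "+" else self.cds_length - 1 - coding_offset
        for s, e in self.cds_segments:
            if idx < e - s:
                return s + idx
            idx -= e - s
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class MarkerLocus:
    """A visible phenotypic marker used as an internal genotype control.

    ``copies_mutant``/``copies_total`` give the allele dosage expected in a
    correctly balanced strain: a marker covered by the duplication is mutant
    on both homologs but wild-type on the duplication (2 of 3); a marker
    outside the duplicated interval is mutant on all copies (2 of 2).
    """

    name: str
    chromosome: str
    position: int
    ref: str
    alt: str
    copies_mutant: int
    copies_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.copies_mutant <= self.copies_total:
            raise ValidationError(f"marker {self.name}: invalid copy counts")
        if self.copies_total not in (2, 3):
            raise ValidationError(f"marker {self.name}: copies_total must be 2 or 3")

    @property
    def expected_ratio(self) -> float:
        return self.copies_mutant / self.copies_total


@dataclass(frozen=True)
class MapZone:
    """One genetically defined mapping interval within the duplicated region."""

    zone_id: str
    interval: tuple[int, int]

    def contains(self, position: int) -> bool:
        return self.interval[0] <= position < self.interval[1]


@dataclass
class BalancerConfig:
    """Geometry of the rescuing duplication: interval, markers and map zones."""

    chromosome: str
    dup_interval: tuple[int, int]
    markers: list[MarkerLocus] = field(default_factory=list)
    zones: list[MapZone] = field(default_factory=list)

    def __post_init__(self) -> None:
        s, e = self.dup_interval
        if s < 0 or e <= s:
            raise ValidationError(f"invalid duplication interval [{s}, {e})")
        for z in self.zones:
            if z.interval[0] < s or z.interval[1] > e:
                raise ValidationError(f"zone {z.zone_id} extends outside the duplication")

    def in_duplication(self, chromosome: str, position: int) -> bool:
        if chromosome != self.chromosome:
            return False
        s, e = self.dup_interval
        return s <= position < e

    def zone_of(self, position: int) -> MapZone | None:
        for z in self.zones:
            if z.contains(position):
                return z
        return None


# ---------------------------------------------------------------------------
# I/O


def load_genome(path: str | os.PathLike) -> Genome:
    """Read a FASTA file into a :class:`Genome` (sequences uppercased)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    sequences: dict[str, str] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad or not seq:
            raise FormatError(
                f"{path}: record {rec.id!r} is empty or contains invalid characters"
            )
        sequences[rec.id] = seq
    return Genome(sequences)


def write_genome(genome: Genome, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def load_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3.

    Only ``CDS`` features define coding structure; exon/UTR features are
    ignored.  Each CDS must name its gene through a ``Parent`` (or
    ``gene_id``) attribute.  GFF3 1-based inclusive coordinates are converted
    to 0-based half-open.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        if "Parent" in feat.attributes:
            gene_id = feat.attributes["Parent"][0]
        elif "gene_id" in feat.attributes:
            gene_id = feat.attributes["gene_id"][0]
        else:
            raise FormatError(
                f"{path}: CDS feature at {feat.seqid}:{feat.start}-{feat.end} "
                "has neither Parent nor gene_id attribute"
            )
        entry = grouped.setdefault(
            gene_id, {"chrom": feat.seqid, "strand": feat.strand, "segments": []}
        )
        entry["segments"].append((feat.start - 1, feat.end))
    genes = []
    for gene_id, entry in grouped.items():
        segments = sorted(entry["segments"])
        for (s0, e0), (s1, e1) in zip(segments, segments[1:]):
            if s1 < e0:
                raise ValidationError(f"{path}: overlapping CDS within gene {gene_id}")
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=entry["chrom"],
                strand=entry["strand"],
                cds_segments=tuple(segments),
            )
        )
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return genes


def write_gene_models(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(genes, key=lambda g: (g.chromosome, g.start)):
            fh.write(
                f"{gene.chromosome}\tbalscan\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for i, (s, e) in enumerate(gene.cds_segments):
                fh.write(
                    f"{gene.chromosome}\tbalscan\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t0\t"
                    f"ID={gene.gene_id}.cds{i};Parent={gene.gene_id}\n"
                )


def extract_cds(gene: GeneModel, genome: Genome) -> str:
    """Spliced coding sequence of ``gene`` in transcription order.

    Genomic-order segments are concatenated and, for minus-strand genes,
    reverse-complemented as a whole.
    """
    parts = [genome.fetch(gene.chromosome, s, e) for s, e in gene.cds_segments]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = reverse_complement(cds)
    return cds


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard genetic code; stops rendered '*'."""
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} is not divisible by 3")
    return str(Seq(cds).translate())


# --- zone / marker TSVs (1-based inclusive coordinates on disk) -------------


def write_zones(zones: list[MapZone], chromosome: str, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("zone_id\tchrom\tstart\tend\n")
        for z in zones:
            fh.write(f"{z.zone_id}\t{chromosome}\t{z.interval[0] + 1}\t{z.interval[1]}\n")


def load_zones(path: str | os.PathLike) -> list[MapZone]:
    zones = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["zone_id", "chrom", "start", "end"]:
            raise FormatError(f"{path}: unexpected zone TSV header {header}")
        for line in fh:
            if not line.strip():
                continue
            zone_id, _chrom, start, end = line.rstrip("\n").split("\t")[:4]
            zones.append(MapZone(zone_id, (int(start) - 1, int(end))))
    return zones


def write_markers(markers: list[MarkerLocus], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("name\tchrom\tposition\tref\talt\tcopies_mutant\tcopies_total\n")
        for m in markers:
            fh.write(
                f"{m.name}\t{m.chromosome}\t{m.position + 1}\t{m.ref}\t{m.alt}\t"
                f"{m.copies_mutant}\t{m.copies_total}\n"
            )


def load_markers(path: str | os.PathLike) -> list[MarkerLocus]:
    markers = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "name":
            raise FormatError(f"{path}: unexpected marker TSV header {header}")
        for line in fh:
            if not line.strip():
                continue
            name, chrom, pos, ref, alt, cm, ct = line.rstrip("\n").split("\t")[:7]
            markers.append(MarkerLocus(name, chrom, int(pos) - 1, ref, alt, int(cm), int(ct)))
    return markers
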