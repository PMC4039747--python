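"""Synthetic strain generator for a balancer-duplication lethal screen.

The generator emulates the genetic structure the analysis assumes:

* one chromosome carrying multi-exon protein-coding genes, a fraction of
  which lie under a duplicated interval covering the left arm;
* a parental strain with a fixed load of background SNVs and small indels
  (homozygous on every copy);
* per-strain mutagen-induced variants concentrated in G>A / C>T transitions,
  restricted to the duplicated interval and carried at 2-of-3 dosage;
* exactly one planted causal lethal variant in an essential gene under the
  duplication (nonsense, splice, missense or frameshift indel on request);
* two marker loci, one under the duplication (2-of-3 dosage expected) and
  one outside it (2-of-2);
* read depth proportional to copy number (3 inside the duplicated interval,
  2 outside), per-site depths Poisson and alternate counts binomial.

Strains may optionally be generated without the duplication (a rare loss
event); they receive no causal variant, homozygous markers and a flat depth
profile, and should be excluded by QC downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .callset_io import DepthTrack, VariantCall, write_calls, write_depth_track
from .errors import ConfigurationError, ValidationError
from .genome_model import (
    BalancerConfig,
    GeneModel,
    Genome,
    MapZone,
    MarkerLocus,
    extract_cds,
    reverse_complement,
    translate_cds,
)

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

CAUSAL_CLASSES = ("nonsense", "splice", "missense", "indel", "random")

__all__ = [
    "SimulationParams",
    "SimVariant",
    "StrainTruth",
    "Reference",
    "simulate_reference",
    "simulate_parental",
    "simulate_strain",
    "sample_reads",
    "write_strain",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the generator.

    Counts and coverage mirror the screen being modelled: 571 background
    SNVs and 167 background indels in the parental strain, on average 44
    mutagen-induced SNVs and 7 small (1-2 bp) indels per strain in the
    duplicated interval, 30X mean coverage for two copies, depth summarised
    in 10 kb windows, and a 7.3 Mbp duplicated interval split into 60 map
    zones.
    """

    chromosome: str = "chrI"
    chromosome_length: int = 15_000_000
    dup_end: int = 7_300_000
    n_genes: int = 300
    genes_in_dup_fraction: float = 0.6
    essential_fraction: float = 0.25
    n_zones: int = 60
    parental_snvs: int = 571
    parental_indels: int = 167
    strain_snvs_mean: float = 44.0
    strain_indels_mean: float = 7.0
    ems_transition_fraction: float = 0.9
    coverage: float = 30.0
    depth_window: int = 10_000
    causal_class: str = "nonsense"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_zones",
            "parental_snvs",
            "parental_indels",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in (
            "genes_in_dup_fraction",
            "essential_fraction",
            "ems_transition_fraction",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.coverage <= 0:
            raise ValidationError("coverage must be positive")
        if self.strain_snvs_mean < 0 or self.strain_indels_mean < 0:
            raise ValidationError("strain variant means must be >= 0")
        if not 0 < self.dup_end <= self.chromosome_length:
            raise ValidationError("dup_end must lie within the chromosome")
        if self.causal_class not in CAUSAL_CLASSES:
            raise ValidationError(f"causal_class must be one of {CAUSAL_CLASSES}")


@dataclass(frozen=True)
class SimVariant:
    """A simulated variant: site, alleles, copy dosage and provenance."""

    chromosome: str
    position: int
    ref: str
    alt: str
    copies_mut: int
    copies_total: int
    origin: str  # parental | marker | ems | causal
    gene_id: str | None = None
    category: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"


@dataclass
class Reference:
    """Shared simulation substrate: genome, gene models, balancer geometry
    and the set of essential gene ids."""

    genome: Genome
    genes: list[GeneModel]
    balancer: BalancerConfig
    essential_ids: frozenset[str]
    params: SimulationParams


@dataclass
class StrainTruth:
    """Ground-truth record for one simulated strain."""

    strain_id: str
    has_duplication: bool
    variants: list[SimVariant]
    causal: SimVariant | None
    background_keys: frozenset
    marker_states: dict[str, tuple[int, int]]
    zone_id: str | None
    chromosome: str
    chromosome_length: int
    dup_interval: tuple[int, int]


# ---------------------------------------------------------------------------
# reference construction


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    return codes[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _build_gene_sequence(
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int]]]:
    """Coding-orientation gene sequence with canonical GT..AG introns.

    Returns the sequence and exon intervals relative to its start.
    """
    n_exons = int(rng.integers(2, 5))
    exon_lens = 3 * rng.integers(40, 120, size=n_exons)  # 120-357 bp, frame-safe
    intron_lens = rng.integers(50, 200, size=n_exons - 1)
    n_codons = int(exon_lens.sum()) // 3
    middle = rng.integers(0, len(_NON_STOP_CODONS), size=n_codons - 2)
    coding = "ATG" + "".join(_NON_STOP_CODONS[i] for i in middle) + STOP_CODONS[int(rng.integers(0, 3))]
    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    cursor = 0
    offset = 0
    for i, elen in enumerate(map(int, exon_lens)):
        pieces.append(coding[offset : offset + elen])
        exons.append((cursor, cursor + elen))
        cursor += elen
        offset += elen
        if i < n_exons - 1:
            ilen = int(intron_lens[i])
            pieces.append("GT" + _random_sequence(rng, ilen - 4) + "AG")
            cursor += ilen
    return "".join(pieces), exons


def _place_genes(
    rng: np.random.Generator,
    region: tuple[int, int],
    n: int,
    id_start: int,
    chromosome: str,
) -> tuple[list[GeneModel], list[tuple[int, str]]]:
    """Non-overlapping genes in equal slots across ``region``.

    Returns models plus (start, plus-strand sequence) patches to splice into
    the chromosome.
    """
    if n == 0:
        return [], []
    slot = (region[1] - region[0]) // n
    genes: list[GeneModel] = []
    patches: list[tuple[int, str]] = []
    for i in range(n):
        seq, exons = _build_gene_sequence(rng)
        if len(seq) + 20 > slot:
            raise ConfigurationError(
                f"cannot place {n} genes in region {region}: slot {slot} bp too small"
            )
        slot_start = region[0] + i * slot
        start = slot_start + int(rng.integers(10, slot - len(seq) - 10))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            genomic = seq
            segments = [(start + a, start + b) for a, b in exons]
        else:
            genomic = reverse_complement(seq)
            L = len(seq)
            segments = sorted((start + L - b, start + L - a) for a, b in exons)
        patches.append((start, genomic))
        genes.append(
            GeneModel(
                gene_id=f"gene_{id_start + i:04d}",
                chromosome=chromosome,
                strand=strand,
                cds_segments=tuple(segments),
            )
        )
    return genes, patches


def _intergenic_position(rng: np.random.Generator, genes: list[GeneModel], lo: int, hi: int) -> int:
    spans = [(g.start - 5, g.end + 5) for g in genes]
    for _ in range(10_000):
        pos = int(rng.integers(lo, hi))
        if not any(s <= pos < e for s, e in spans):
            return pos
    raise ConfigurationError("could not find an intergenic position")


def simulate_reference(params: SimulationParams, seed: int | None = None) -> Reference:
    """Build the shared genome, gene models and balancer geometry."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    chrom = params.chromosome
    seq = _random_sequence(rng, params.chromosome_length)

    n_in = round(params.n_genes * params.genes_in_dup_fraction)
    n_out = params.n_genes - n_in
    genes_in, patches_in = _place_genes(rng, (0, params.dup_end), n_in, 0, chrom)
    genes_out, patches_out = _place_genes(
        rng, (params.dup_end, params.chromosome_length), n_out, n_in, chrom
    )
    genes = genes_in + genes_out
    buf = bytearray(seq, "ascii")
    for start, patch in patches_in + patches_out:
        buf[start : start + len(patch)] = patch.encode("ascii")
    genome = Genome({chrom: buf.decode("ascii")})

    essential = frozenset(
        g.gene_id for g in genes if rng.random() < params.essential_fraction
    )
    if params.n_genes and not any(g.gene_id in essential for g in genes_in):
        # a screen for balanced lethals needs at least one essential target
        essential = essential | {genes_in[0].gene_id} if genes_in else essential
    if n_in and not essential & {g.gene_id for g in genes_in}:
        raise ConfigurationError("no essential gene under the duplication")

    marker_in_pos = _intergenic_position(rng, genes, params.dup_end // 3, 2 * params.dup_end // 3)
    marker_out_pos = _intergenic_position(
        rng,
        genes,
        params.dup_end + (params.chromosome_length - params.dup_end) // 3,
        params.chromosome_length - 1000,
    )
    markers = []
    for name, pos, cm, ct in (
        ("dpy_marker", marker_in_pos, 2, 3),
        ("unc_marker", marker_out_pos, 2, 2),
    ):
        ref = genome.sequences[chrom][pos]
        markers.append(
            MarkerLocus(name, chrom, pos, ref, TRANSITION[ref], cm, ct)
        )

    zone_edges = np.linspace(0, params.dup_end, params.n_zones + 1).astype(int)
    zones = [
        MapZone(f"zone_{i + 1:02d}", (int(zone_edges[i]), int(zone_edges[i + 1])))
        for i in range(params.n_zones)
    ]
    balancer = BalancerConfig(chrom, (0, params.dup_end), markers, zones)
    return Reference(genome, genes, balancer, essential, params)


# ---------------------------------------------------------------------------
# variant generation


def _random_snv(
    rng: np.random.Generator, genome: Genome, chrom: str, lo: int, hi: int, taken: set[int]
) -> tuple[int, str, str]:
    seq = genome.sequences[chrom]
    while True:
        pos = int(rng.integers(lo, hi))
        if pos in taken:
            continue
        ref = seq[pos]
        if ref == "N":
            continue
        alt = BASES[int(rng.integers(0, 4))]
        if alt != ref:
            return pos, ref, alt


def _ems_snv(
    rng: np.random.Generator,
    genome: Genome,
    chrom: str,
    lo: int,
    hi: int,
    taken: set[int],
    transition_fraction: float,
) -> tuple[int, str, str]:
    seq = genome.sequences[chrom]
    if rng.random() < transition_fraction:
        while True:
            pos = int(rng.integers(lo, hi))
            if pos in taken:
                continue
            ref = seq[pos]
            if ref in "GC":
                return pos, ref, TRANSITION[ref]
    return _random_snv(rng, genome, chrom, lo, hi, taken)


def _random_indel(
    rng: np.random.Generator, genome: Genome, chrom: str, lo: int, hi: int, taken: set[int]
) -> tuple[int, str, str]:
    seq = genome.sequences[chrom]
    while True:
        pos = int(rng.integers(lo, hi - 3))
        if pos in taken:
            continue
        length = int(rng.integers(1, 3))  # 1-2 bp
        if rng.random() < 0.5:  # deletion
            ref = seq[pos : pos + 1 + length]
            alt = seq[pos]
        else:  # insertion
            ref = seq[pos]
            alt = ref + _random_sequence(rng, length)
        if ref != alt:
            return pos, ref, alt


def simulate_parental(
    genome: Genome, params: SimulationParams, seed: int | None = None
) -> list[SimVariant]:
    """Background variants of the parental strain, uniform over the chromosome.

    Dosage is filled in per strain (background sites are homozygous on every
    copy, so under the duplication they carry 3-of-3).
    """
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    chrom = params.chromosome
    taken: set[int] = set()
    out: list[SimVariant] = []
    for _ in range(params.parental_snvs):
        pos, ref, alt = _random_snv(rng, genome, chrom, 0, params.chromosome_length, taken)
        taken.add(pos)
        out.append(SimVariant(chrom, pos, ref, alt, 2, 2, "parental"))
    for _ in range(params.parental_indels):
        pos, ref, alt = _random_indel(rng, genome, chrom, 0, params.chromosome_length, taken)
        taken.update(range(pos, pos + len(ref)))
        out.append(SimVariant(chrom, pos, ref, alt, 2, 2, "parental"))
    return out


def _plant_point_mutation(
    rng: np.random.Generator, genome: Genome, gene: GeneModel, want: str
) -> tuple[int, str, str] | None:
    """Find a single-base substitution in ``gene`` producing ``want``
    (nonsense or missense), preferring EMS-type transitions."""
    cds = extract_cds(gene, genome)
    protein = translate_cds(cds)
    n_codons = len(cds) // 3
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    codon_order = rng.permutation(np.arange(1, n_codons - 1))
    for ci in codon_order:
        codon = cds[3 * ci : 3 * ci + 3]
        for within in rng.permutation(3):
            ref_base = codon[within]
            alts = [TRANSITION[ref_base]] + [b for b in BASES if b not in (ref_base, TRANSITION[ref_base])]
            for alt_base in alts:
                alt_codon = codon[:within] + alt_base + codon[within + 1 :]
                alt_aa = translate_cds(alt_codon)
                ref_aa = protein[ci]
                if want == "nonsense" and alt_aa != "*":
                    continue
                if want == "missense" and (alt_aa == ref_aa or alt_aa == "*"):
                    continue
                pos = gene.genomic_position(3 * int(ci) + int(within))
                if gene.strand == "+":
                    return pos, ref_base, alt_base
                return pos, comp[ref_base], comp[alt_base]
    return None


def _plant_causal(
    rng: np.random.Generator,
    reference: Reference,
    causal_class: str,
    taken: set[int],
) -> SimVariant:
    params = reference.params
    chrom = params.chromosome
    genome = reference.genome
    candidates = [
        g
        for g in reference.genes
        if g.gene_id in reference.essential_ids and g.end <= params.dup_end
    ]
    if not candidates:
        raise ConfigurationError("no essential gene available under the duplication")
    if causal_class == "random":
        causal_class = ("nonsense", "splice", "missense", "indel")[int(rng.integers(0, 4))]
    for gi in rng.permutation(len(candidates)):
        gene = candidates[int(gi)]
        if causal_class in ("nonsense", "missense"):
            hit = _plant_point_mutation(rng, genome, gene, causal_class)
            if hit is None:
                continue
            pos, ref, alt = hit
            if pos in taken:
                continue
            return SimVariant(chrom, pos, ref, alt, 2, 3, "causal", gene.gene_id, causal_class)
        if causal_class == "splice":
            introns = gene.introns
            if not introns:
                continue
            s, e = introns[int(rng.integers(0, len(introns)))]
            pos = s if gene.strand == "+" else e - 1
            if pos in taken:
                continue
            ref = genome.sequences[chrom][pos]
            return SimVariant(
                chrom, pos, ref, TRANSITION[ref], 2, 3, "causal", gene.gene_id, "splice_signal"
            )
        if causal_class == "indel":
            # 1-2 bp deletion strictly inside a CDS segment: frameshift
            s, e = gene.cds_segments[int(rng.integers(0, len(gene.cds_segments)))]
            length = int(rng.integers(1, 3))
            if e - s < length + 4:
                continue
            pos = int(rng.integers(s, e - length - 1))
            if any(p in taken for p in range(pos, pos + 1 + length)):
                continue
            ref = genome.sequences[chrom][pos : pos + 1 + length]
            return SimVariant(
                chrom, pos, ref, ref[0], 2, 3, "causal", gene.gene_id, "frameshift_indel"
            )
    raise ConfigurationError(f"could not plant a {causal_class} causal variant")


def simulate_strain(
    reference: Reference,
    parental: list[SimVariant],
    params: SimulationParams,
    seed: int,
    strain_id: str = "strain",
    has_duplication: bool = True,
) -> StrainTruth:
    """Assemble the full variant complement of one mutagenized strain."""
    rng = np.random.default_rng(seed)
    chrom = params.chromosome
    dup = (0, params.dup_end)

    def dosage(position: int, homozygous: bool) -> tuple[int, int]:
        in_dup = dup[0] <= position < dup[1]
        total = 3 if (in_dup and has_duplication) else 2
        mut = total if homozygous else 2
        return mut, total

    taken: set[int] = set()
    variants: list[SimVariant] = []
    for v in parental:
        mut, total = dosage(v.position, homozygous=True)
        variants.append(replace(v, copies_mut=mut, copies_total=total))
        taken.update(range(v.position, v.position + len(v.ref)))

    for m in reference.balancer.markers:
        mut, total = (m.copies_mutant, m.copies_total) if has_duplication else (2, 2)
        variants.append(
            SimVariant(chrom, m.position, m.ref, m.alt, mut, total, "marker")
        )
        taken.add(m.position)

    causal = None
    if has_duplication:
        causal = _plant_causal(rng, reference, params.causal_class, taken)
        variants.append(causal)
        taken.update(range(causal.position, causal.position + len(causal.ref)))

    n_snvs = int(rng.poisson(params.strain_snvs_mean))
    for _ in range(n_snvs):
        pos, ref, alt = _ems_snv(
            rng, reference.genome, chrom, 0, params.dup_end, taken, params.ems_transition_fraction
        )
        taken.add(pos)
        # mutagen hits both homologs of the selfing lineage, never the duplication
        mut, total = dosage(pos, homozygous=not has_duplication)
        variants.append(SimVariant(chrom, pos, ref, alt, mut, total, "ems"))

    n_indels = int(rng.poisson(params.strain_indels_mean))
    for _ in range(n_indels):
        pos, ref, alt = _random_indel(rng, reference.genome, chrom, 0, params.dup_end, taken)
        taken.update(range(pos, pos + len(ref)))
        mut, total = dosage(pos, homozygous=not has_duplication)
        variants.append(SimVariant(chrom, pos, ref, alt, mut, total, "ems"))

    zone = reference.balancer.zone_of(causal.position) if causal else None
    return StrainTruth(
        strain_id=strain_id,
        has_duplication=has_duplication,
        variants=variants,
        causal=causal,
        background_keys=frozenset(v.key for v in parental),
        marker_states={
            m.name: ((m.copies_mutant, m.copies_total) if has_duplication else (2, 2))
            for m in reference.balancer.markers
        },
        zone_id=zone.zone_id if zone else None,
        chromosome=chrom,
        chromosome_length=params.chromosome_length,
        dup_interval=dup,
    )


# ---------------------------------------------------------------------------
# read sampling


def sample_reads(
    truth: StrainTruth,
    coverage: float,
    seed: int,
    depth_window: int = 10_000,
) -> tuple[list[VariantCall], DepthTrack]:
    """Sample allele counts and a windowed depth track for one strain.

    Per site: total depth ~ Poisson(coverage · copies/2); alternate count
    ~ Binomial(depth, copies_mut/copies_total).  Window depth is the mean of
    per-base Poisson coverage over the window (3 copies inside the
    duplicated interval when present, 2 elsewhere).
    """
    if coverage <= 0:
        raise ValidationError("coverage must be positive")
    rng = np.random.default_rng(seed)
    calls: list[VariantCall] = []
    for v in truth.variants:
        lam = coverage * v.copies_total / 2.0
        depth = int(rng.poisson(lam))
        alt = int(rng.binomial(depth, v.copies_mut / v.copies_total)) if depth else 0
        calls.append(
            VariantCall(v.chromosome, v.position, v.ref, v.alt, depth - alt, alt)
        )
    windows = []
    dup_s, dup_e = truth.dup_interval
    for start in range(0, truth.chromosome_length, depth_window):
        end = min(start + depth_window, truth.chromosome_length)
        mid = (start + end) // 2
        copies = 3 if (truth.has_duplication and dup_s <= mid < dup_e) else 2
        lam = coverage * copies / 2.0
        mean_depth = rng.poisson(lam * (end - start)) / (end - start)
        windows.append((truth.chromosome, start, end, float(mean_depth)))
    return calls, DepthTrack(windows)


# ---------------------------------------------------------------------------
# on-disk artifacts


TRUTH_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "copies_mut",
    "copies_total",
    "origin",
    "gene_id",
    "category",
]


def write_truth(truth: StrainTruth, path: str | os.PathLike) -> None:
    """Truth TSV: header comments with strain metadata, one row per variant
    (1-based positions)."""
    with open(path, "w") as fh:
        fh.write(f"#strain_id={truth.strain_id}\n")
        fh.write(f"#has_duplication={str(truth.has_duplication).lower()}\n")
        fh.write(f"#zone_id={truth.zone_id or ''}\n")
        fh.write(f"#chromosome={truth.chromosome}\n")
        fh.write(f"#chromosome_length={truth.chromosome_length}\n")
        fh.write(f"#dup_interval={truth.dup_interval[0]}-{truth.dup_interval[1]}\n")
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for v in truth.variants:
            fh.write(
                f"{v.chromosome}\t{v.position + 1}\t{v.ref}\t{v.alt}\t{v.copies_mut}\t"
                f"{v.copies_total}\t{v.origin}\t{v.gene_id or ''}\t{v.category or ''}\n"
            )


def read_truth(path: str | os.PathLike) -> StrainTruth:
    meta: dict[str, str] = {}
    variants: list[SimVariant] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
                continue
            if line.startswith("chrom\t") or not line:
                continue
            chrom, pos, ref, alt, cm, ct, origin, gene_id, category = line.split("\t")
            variants.append(
                SimVariant(
                    chrom,
                    int(pos) - 1,
                    ref,
                    alt,
                    int(cm),
                    int(ct),
                    origin,
                    gene_id or None,
                    category or None,
                )
            )
    causal = next((v for v in variants if v.origin == "causal"), None)
    dup_s, _, dup_e = meta["dup_interval"].partition("-")
    return StrainTruth(
        strain_id=meta["strain_id"],
        has_duplication=meta["has_duplication"] == "true",
        variants=variants,
        causal=causal,
        background_keys=frozenset(v.key for v in variants if v.origin == "parental"),
        marker_states={},
        zone_id=meta["zone_id"] or None,
        chromosome=meta["chromosome"],
        chromosome_length=int(meta["chromosome_length"]),
        dup_interval=(int(dup_s), int(dup_e)),
    )


def write_strain(
    truth: StrainTruth,
    calls: list[VariantCall],
    track: DepthTrack,
    outdir: str | os.PathLike,
) -> dict[str, Path]:
    """Write one strain's VCF, bedGraph and truth TSV into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / f"{truth.strain_id}.vcf",
        "bedgraph": outdir / f"{truth.strain_id}.bedgraph",
        "truth": outdir / f"{truth.strain_id}.truth.tsv",
    }
    write_calls(
        calls,
        paths["vcf"],
        contigs={truth.chromosome: truth.chromosome_length},
        sample=truth.strain_id,
    )
    write_depth_track(track, paths["bedgraph"])
    write_truth(truth, paths["truth"])
    return paths
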