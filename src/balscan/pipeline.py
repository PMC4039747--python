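"""Cohort orchestration: simulate -> QC -> filter -> annotate -> rank.

A cohort directory produced by :func:`simulate_cohort` is self-contained:

    cohort/
      genome.fa          reference sequence
      genes.gff3         gene models (CDS features)
      zones.tsv          map zones tiling the duplicated interval
      markers.tsv        marker loci with expected copy dosages
      config.json        chromosome geometry, coverage, master seed
      parental.vcf       background call set of the parental strain
      strains/<id>.vcf / .bedgraph / .truth.tsv

Analysis reads these files back through the public loaders, so the pipeline
exercises the same code paths a user would run on real call sets.  All
randomness derives from the single master seed (per-strain sub-seeds are
master + strain index), so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import strain_simulator as sim
from .callset_io import read_calls, read_depth_track
from .candidate_ranking import CandidateReport, cohort_summary, rank_candidates
from .effect_annotation import annotate_all
from .errors import ValidationError
from .genome_model import (
    BalancerConfig,
    load_gene_models,
    load_genome,
    load_markers,
    load_zones,
    write_gene_models,
    write_genome,
    write_markers,
    write_zones,
)
from .strain_qc import qc_strain
from .variant_filtering import (
    FilterConfig,
    filter_by_ratio,
    filter_by_region,
    filter_coding,
    subtract_background,
)

logger = logging.getLogger("balscan")

__all__ = ["Cohort", "simulate_cohort", "load_cohort", "run_strain", "run_cohort"]


@dataclass
class Cohort:
    root: Path
    genome: object
    genes: list
    balancer: BalancerConfig
    parental: list
    strain_ids: list[str]
    config: dict = field(default_factory=dict)

    def strain_paths(self, strain_id: str) -> dict[str, Path]:
        base = self.root / "strains"
        return {
            "vcf": base / f"{strain_id}.vcf",
            "bedgraph": base / f"{strain_id}.bedgraph",
            "truth": base / f"{strain_id}.truth.tsv",
        }


def simulate_cohort(
    params: sim.SimulationParams,
    n_strains: int,
    outdir: str | Path,
    n_unbalanced: int = 0,
) -> Path:
    """Generate a full cohort on disk; returns the cohort root.

    The first ``n_strains`` strains are balanced (duplication present, one
    causal variant each); ``n_unbalanced`` additional strains model
    duplication loss.
    """
    if n_strains < 1:
        raise ValidationError("need at least one balanced strain")
    root = Path(outdir)
    (root / "strains").mkdir(parents=True, exist_ok=True)
    reference = sim.simulate_reference(params)
    parental = sim.simulate_parental(reference.genome, params)

    write_genome(reference.genome, root / "genome.fa")
    write_gene_models(reference.genes, root / "genes.gff3")
    write_zones(reference.balancer.zones, params.chromosome, root / "zones.tsv")
    write_markers(reference.balancer.markers, root / "markers.tsv")
    config = {
        "chromosome": params.chromosome,
        "chromosome_length": params.chromosome_length,
        "dup_start": 0,
        "dup_end": params.dup_end,
        "coverage": params.coverage,
        "depth_window": params.depth_window,
        "seed": params.seed,
        "essential_genes": sorted(reference.essential_ids),
    }
    (root / "config.json").write_text(json.dumps(config, indent=2))

    # parental strain carries the duplication too; write its sampled calls
    parental_truth = sim.StrainTruth(
        strain_id="parental",
        has_duplication=True,
        variants=[
            replace(
                v,
                copies_mut=3 if v.position < params.dup_end else 2,
                copies_total=3 if v.position < params.dup_end else 2,
            )
            for v in parental
        ]
        + [
            sim.SimVariant(params.chromosome, m.position, m.ref, m.alt, m.copies_mutant,
                           m.copies_total, "marker")
            for m in reference.balancer.markers
        ],
        causal=None,
        background_keys=frozenset(),
        marker_states={},
        zone_id=None,
        chromosome=params.chromosome,
        chromosome_length=params.chromosome_length,
        dup_interval=(0, params.dup_end),
    )
    parental_calls, _ = sim.sample_reads(parental_truth, params.coverage, params.seed + 7)
    from .callset_io import write_calls

    write_calls(
        parental_calls,
        root / "parental.vcf",
        contigs={params.chromosome: params.chromosome_length},
        sample="parental",
    )

    total = n_strains + n_unbalanced
    for i in range(total):
        balanced = i < n_strains
        strain_id = f"strain_{i + 1:03d}"
        truth = sim.simulate_strain(
            reference,
            parental,
            params,
            seed=params.seed + 1000 + i,
            strain_id=strain_id,
            has_duplication=balanced,
        )
        calls, track = sim.sample_reads(
            truth, params.coverage, seed=params.seed + 5000 + i, depth_window=params.depth_window
        )
        sim.write_strain(truth, calls, track, root / "strains")
        logger.info("simulated %s (balanced=%s, %d variants)", strain_id, balanced, len(calls))
    return root


def load_cohort(root: str | Path) -> Cohort:
    root = Path(root)
    config = json.loads((root / "config.json").read_text())
    genome = load_genome(root / "genome.fa")
    genes = load_gene_models(root / "genes.gff3")
    zones = load_zones(root / "zones.tsv")
    markers = load_markers(root / "markers.tsv")
    balancer = BalancerConfig(
        config["chromosome"], (config["dup_start"], config["dup_end"]), markers, zones
    )
    parental = read_calls(root / "parental.vcf")
    strain_ids = sorted(p.stem for p in (root / "strains").glob("*.vcf"))
    return Cohort(root, genome, genes, balancer, parental, strain_ids, config)


def run_strain(
    cohort: Cohort,
    strain_id: str,
    filter_config: FilterConfig | None = None,
) -> tuple[object, CandidateReport | None]:
    """QC one strain, then filter, annotate and rank its calls.

    Returns (QCReport, CandidateReport or None when QC excluded the strain).
    The strain's mapped zone (from the genetic mapping guide, here the truth
    sidecar) steers ranking when available.  Filter stage counts are logged.
    """
    cfg = filter_config or FilterConfig()
    paths = cohort.strain_paths(strain_id)
    calls = read_calls(paths["vcf"])
    track = read_depth_track(paths["bedgraph"])
    qc = qc_strain(strain_id, calls, track, cohort.balancer, background=cohort.parental)
    if qc.exclude:
        logger.info("%s excluded by QC: %s", strain_id, "; ".join(qc.reasons))
        return qc, None

    stage = subtract_background(calls, cohort.parental)
    logger.info("%s: %d calls after background subtraction (of %d)", strain_id, len(stage), len(calls))
    stage = filter_by_ratio(stage, cfg)
    logger.info("%s: %d calls after ratio window", strain_id, len(stage))
    stage = filter_by_region(stage, cohort.balancer)
    logger.info("%s: %d calls in the duplicated interval", strain_id, len(stage))
    if cfg.coding_only:
        stage = filter_coding(stage, cohort.genes)
        logger.info("%s: %d coding/splice calls", strain_id, len(stage))

    annotations = annotate_all(stage, cohort.genes, cohort.genome)
    zone = None
    if paths["truth"].exists():
        truth = sim.read_truth(paths["truth"])
        if truth.zone_id is not None:
            zone = next((z for z in cohort.balancer.zones if z.zone_id == truth.zone_id), None)
    report = rank_candidates(strain_id, annotations, zone, qc)
    return qc, report


def run_cohort(
    cohort: Cohort,
    filter_config: FilterConfig | None = None,
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Run every strain; returns (and optionally writes) the summary table.

    When truth sidecars exist, a ``recovered`` column compares each top
    candidate with the planted causal variant; excluded strains are listed
    with their QC reason.
    """
    if not cohort.strain_ids:
        raise ValidationError("cohort has no strains")
    reports: list[CandidateReport] = []
    rows = []
    for strain_id in cohort.strain_ids:
        qc, report = run_strain(cohort, strain_id, filter_config)
        truth_path = cohort.strain_paths(strain_id)["truth"]
        truth = sim.read_truth(truth_path) if truth_path.exists() else None
        if report is None:
            rows.append(
                {
                    "strain_id": strain_id,
                    "excluded": True,
                    "reason": "; ".join(qc.reasons),
                    "gene_id": "",
                    "category": "",
                    "aa_change": "",
                    "recovered": (truth is not None and truth.causal is None and
                                  not truth.has_duplication),
                }
            )
            continue
        reports.append(report)
        top = report.top_candidate
        recovered = None
        if truth is not None and truth.causal is not None:
            recovered = top is not None and top.variant.key == truth.causal.key
        rows.append(
            {
                "strain_id": strain_id,
                "excluded": False,
                "reason": "",
                "gene_id": (top.gene_id if top else ""),
                "category": (top.category if top else "no candidate"),
                "aa_change": (top.aa_change if top else ""),
                "recovered": recovered,
            }
        )
    summary = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False)
        if reports:
            cohort_summary(reports).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    return summary
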