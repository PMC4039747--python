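"""Per-strain quality control.

Three independent checks gate a strain into the candidate analysis:

* **Marker ratios** — the two phenotypic marker mutations must show the
  allelic ratio their copy configuration predicts: ~2/3 for the marker under
  the duplication (mutant on both homologs, wild-type on the duplication)
  and ~1 for the marker outside it.  A marker at ~1/3 indicates a single
  mutant copy; ~0 indicates the marker mutation is missing altogether.
* **Duplication presence** — with the duplication present the duplicated
  interval carries 3 copies against 2 elsewhere, so its mean read depth is
  higher by a third.  The statistic D = 1 - depth_outside/depth_inside is
  ~1/3 under the 3:2 model and ~0 for a flat track.
* **Mutagen spectrum** — EMS produces predominantly G>A / C>T transitions;
  the observed fraction is reported for inspection (it is not an exclusion
  criterion).

A strain failing a marker check or lacking the duplication is excluded with
an explicit reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .callset_io import DepthTrack, VariantCall, allelic_ratio
from .errors import InsufficientDataError, ValidationError
from .genome_model import BalancerConfig, MarkerLocus

# Band boundaries are midway between the analytic expectations 0, 1/3, 2/3, 1.
ABSENT_MAX = 0.10
SINGLE_COPY_MAX = 0.45
BALANCED_MAX = 0.85

# Midpoint of D between the no-duplication (0) and 3:2 (1/3) expectations.
DUP_D_THRESHOLD = 1.0 / 6.0

MIN_WINDOWS = 5

MARKER_STATES = ("absent", "single_copy", "balanced", "homozygous", "anomalous")

__all__ = [
    "MarkerState",
    "QCReport",
    "expected_allelic_ratio",
    "ratio_band",
    "classify_marker",
    "detect_duplication",
    "ems_spectrum",
    "EMSSpectrum",
    "qc_strain",
]


def expected_allelic_ratio(copies_mut: int, copies_total: int) -> float:
    """Expected alt-read fraction for ``copies_mut`` mutant copies out of
    ``copies_total`` at a locus: 2/3 under the duplication, 1 outside it."""
    if copies_total <= 0:
        raise ValidationError("copies_total must be positive")
    if not 0 <= copies_mut <= copies_total:
        raise ValidationError("copies_mut must lie in [0, copies_total]")
    return copies_mut / copies_total


def ratio_band(ratio: float) -> str:
    """Banded dosage state for an observed allelic ratio."""
    if not 0 <= ratio <= 1:
        raise ValidationError(f"ratio {ratio} outside [0, 1]")
    if ratio < ABSENT_MAX:
        return "absent"
    if ratio < SINGLE_COPY_MAX:
        return "single_copy"
    if ratio < BALANCED_MAX:
        return "balanced"
    return "homozygous"


@dataclass(frozen=True)
class MarkerState:
    name: str
    state: str
    observed_ratio: float | None
    expected_ratio: float

    @property
    def expected_state(self) -> str:
        return ratio_band(self.expected_ratio)

    @property
    def ok(self) -> bool:
        return self.state == self.expected_state


def classify_marker(call: VariantCall | None, marker: MarkerLocus) -> MarkerState:
    """Band the observed marker ratio against its copy-based expectation.

    ``call=None`` stands for a site where every read supported the
    reference (no variant record emitted), i.e. the marker is absent.
    A present record with zero depth is anomalous, not classifiable.
    """
    if call is None:
        return MarkerState(marker.name, "absent", 0.0, marker.expected_ratio)
    if call.depth == 0:
        return MarkerState(marker.name, "anomalous", None, marker.expected_ratio)
    ratio = allelic_ratio(call)
    return MarkerState(marker.name, ratio_band(ratio), ratio, marker.expected_ratio)


def detect_duplication(
    track: DepthTrack, config: BalancerConfig, threshold: float = DUP_D_THRESHOLD
) -> tuple[bool, float]:
    """Test for the duplication from windowed depth.

    D = 1 - mean(outside)/mean(inside); the 3:2 copy model predicts 1/3,
    matching the observed one-third depth excess over the duplicated
    interval.  Requires at least ``MIN_WINDOWS`` windows on each side.
    """
    chrom = config.chromosome
    dup_s, dup_e = config.dup_interval
    chrom_end = max(e for c, _, e, _ in track.windows if c == chrom)
    n_in = track.count_windows(chrom, dup_s, dup_e)
    n_out = track.count_windows(chrom, dup_e, chrom_end) + track.count_windows(chrom, 0, dup_s)
    if n_in < MIN_WINDOWS or n_out < MIN_WINDOWS:
        raise InsufficientDataError(
            f"need >= {MIN_WINDOWS} depth windows inside and outside the duplication "
            f"(got {n_in} / {n_out})"
        )
    inside = track.mean_depth(chrom, dup_s, dup_e)
    outs = [
        d
        for c, s, e, d in track.windows
        if c == chrom and not (dup_s <= (s + e) // 2 < dup_e)
    ]
    outside = sum(outs) / len(outs)
    if inside == 0:
        raise InsufficientDataError("zero mean depth inside the duplicated interval")
    d_stat = 1.0 - outside / inside
    return d_stat >= threshold, d_stat


TRANSITION_PAIRS = frozenset({("G", "A"), ("C", "T")})


@dataclass
class EMSSpectrum:
    counts: dict[str, int]
    n_snvs: int

    @property
    def transition_fraction(self) -> float | None:
        """Fraction of SNVs that are G>A or C>T; None when no SNVs."""
        if self.n_snvs == 0:
            return None
        hits = sum(self.counts.get(f"{a}>{b}", 0) for a, b in TRANSITION_PAIRS)
        return hits / self.n_snvs


def ems_spectrum(calls: list[VariantCall]) -> EMSSpectrum:
    """Per-substitution counts over the SNVs of a call set."""
    counts: dict[str, int] = {}
    n = 0
    for call in calls:
        if call.kind != "SNV":
            continue
        key = f"{call.ref}>{call.alt}"
        counts[key] = counts.get(key, 0) + 1
        n += 1
    return EMSSpectrum(counts, n)


@dataclass
class QCReport:
    strain_id: str
    marker_states: dict[str, MarkerState]
    duplication_present: bool
    depth_statistic: float
    ems_transition_fraction: float | None
    exclude: bool = False
    reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "strain_id": self.strain_id,
            "markers": {
                name: {
                    "state": ms.state,
                    "observed_ratio": ms.observed_ratio,
                    "expected_ratio": ms.expected_ratio,
                    "ok": ms.ok,
                }
                for name, ms in self.marker_states.items()
            },
            "duplication_present": self.duplication_present,
            "depth_statistic": self.depth_statistic,
            "ems_transition_fraction": self.ems_transition_fraction,
            "exclude": self.exclude,
            "reasons": list(self.reasons),
        }


def qc_strain(
    strain_id: str,
    calls: list[VariantCall],
    track: DepthTrack,
    config: BalancerConfig,
    dup_threshold: float = DUP_D_THRESHOLD,
    background: list[VariantCall] | None = None,
) -> QCReport:
    """Aggregate marker, duplication and spectrum checks into one report.

    When the parental ``background`` is given, the mutagen spectrum is
    summarised over strain-private calls only (the background SNVs carry no
    mutagen signature and would dilute the transition fraction).
    """
    by_site = {(c.chromosome, c.position): c for c in calls}
    marker_states: dict[str, MarkerState] = {}
    reasons: list[str] = []
    for marker in config.markers:
        call = by_site.get((marker.chromosome, marker.position))
        state = classify_marker(call, marker)
        marker_states[marker.name] = state
        if not state.ok:
            reasons.append(
                f"marker {marker.name}: observed state {state.state!r} "
                f"(ratio {state.observed_ratio}), expected {state.expected_state!r}"
            )
    present, d_stat = detect_duplication(track, config, threshold=dup_threshold)
    if not present:
        reasons.append(f"duplication absent (depth statistic D = {d_stat:.3f})")
    private = calls
    if background is not None:
        marker_sites = {(m.chromosome, m.position) for m in config.markers}
        background_keys = {c.key for c in background}
        private = [
            c for c in calls
            if c.key not in background_keys
            and (c.chromosome, c.position) not in marker_sites
        ]
    spectrum = ems_spectrum(private)
    return QCReport(
        strain_id=strain_id,
        marker_states=marker_states,
        duplication_present=present,
        depth_statistic=d_stat,
        ems_transition_fraction=spectrum.transition_fraction,
        exclude=bool(reasons),
        reasons=reasons,
    )
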