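"""Stage-resolved expression profiles: normalization, clustering, maternal call.

Profiles cover a developmental time course: 23 embryonic stages in 30-minute
bins (0-660 min), four larval stages (L1-L4), a pre-gravid young adult and a
gravid young adult stage, plus an optional germline-less mutant column used
as an advisory germline-expression comparator.

Per-gene expression is the total normalized read count over the coding
base-pairs divided by the CDS length.  Profiles are clustered bottom-up
(agglomerative, average linkage on Euclidean distance of row-standardized
profiles) and the tree cut into k stage-pattern groups (seven in the screen
being modelled: early-, early+mid-, mid-, late-, mid+late-embryonic,
gastrulation-specific and larval).

A gene is called maternally contributed when it is high very early in
embryogenesis and in gravid adults but low across the larval stages — the
signature of transcripts deposited by the maternal germline.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .enrichment import Chi2Result, chi_square_2x2
from .errors import ValidationError

EMBRYO_STAGES = tuple(f"embryo_{m:03d}min" for m in range(0, 690, 30))  # 23 bins
LARVAL_STAGES = ("L1", "L2", "L3", "L4")
ADULT_STAGES = ("pre_gravid_adult", "gravid_adult")
STAGE_ORDER = EMBRYO_STAGES + LARVAL_STAGES + ADULT_STAGES
GERMLINELESS_COLUMN = "glp1_germlineless"

EARLY_EMBRYO_STAGES = EMBRYO_STAGES[:6]  # 0-150 min bins
MATERNAL_FACTOR = 2.0
DEFAULT_K = 7

__all__ = [
    "STAGE_ORDER",
    "EMBRYO_STAGES",
    "LARVAL_STAGES",
    "GERMLINELESS_COLUMN",
    "mean_normalized_expression",
    "validate_matrix",
    "cluster_profiles",
    "classify_maternal",
    "maternal_enrichment",
    "simulate_profiles",
]


def mean_normalized_expression(total_normalized_reads: float, cds_length: int) -> float:
    """Normalized read count over all coding base-pairs divided by CDS length."""
    if cds_length <= 0:
        raise ValidationError("cds_length must be positive")
    return total_normalized_reads / cds_length


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check stage columns and non-negativity; reorder columns canonically."""
    missing = [s for s in STAGE_ORDER if s not in matrix.columns]
    if missing:
        raise ValidationError(f"expression matrix missing stages: {missing}")
    cols = list(STAGE_ORDER)
    if GERMLINELESS_COLUMN in matrix.columns:
        cols.append(GERMLINELESS_COLUMN)
    out = matrix[cols]
    if (out.values < 0).any():
        raise ValidationError("expression values must be non-negative")
    return out


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    std = values.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return (values - mean) / std


def cluster_profiles(
    matrix: pd.DataFrame,
    k: int = DEFAULT_K,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of row-standardized stage profiles.

    Returns the cluster assignment per gene (labels 1..k) and the merge
    tree (scipy linkage matrix).  Row standardization makes the grouping
    invariant to per-gene affine scaling, so clusters reflect the *shape*
    of the stage pattern, not expression magnitude.
    """
    if len(matrix) < k:
        raise ValidationError(f"need at least k={k} profiles, got {len(matrix)}")
    stage_cols = [c for c in matrix.columns if c in STAGE_ORDER]
    z = _standardize_rows(matrix[stage_cols].to_numpy(dtype=float))
    tree = linkage(z, method=method, metric=metric)
    labels = fcluster(tree, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.index, name="cluster"), tree


def classify_maternal(
    profile: Mapping[str, float] | pd.Series,
    factor: float = MATERNAL_FACTOR,
) -> bool:
    """Maternal-contribution call for one profile.

    Maternal iff mean expression over the first embryonic bins (0-150 min)
    and the gravid-adult value both exceed ``factor`` times the mean larval
    (L1-L4) expression.  With zero larval expression, any positive early and
    adult signal qualifies.
    """
    missing = [
        s
        for s in (*EARLY_EMBRYO_STAGES, *LARVAL_STAGES, "gravid_adult")
        if s not in profile
    ]
    if missing:
        raise ValidationError(f"profile missing stages: {missing}")
    early = float(np.mean([profile[s] for s in EARLY_EMBRYO_STAGES]))
    larval = float(np.mean([profile[s] for s in LARVAL_STAGES]))
    adult = float(profile["gravid_adult"])
    if any(v < 0 for v in (early, larval, adult)):
        raise ValidationError("expression values must be non-negative")
    if larval == 0:
        return early > 0 and adult > 0
    return early > factor * larval and adult > factor * larval


def maternal_enrichment(flags_a: list[bool], flags_b: list[bool]) -> Chi2Result:
    """Chi-square comparison of maternal-contribution fractions in two sets."""
    if not flags_a or not flags_b:
        raise ValidationError("both flag sets must be non-empty")
    a_mat = sum(flags_a)
    b_mat = sum(flags_b)
    return chi_square_2x2(a_mat, len(flags_a) - a_mat, b_mat, len(flags_b) - b_mat)


# ---------------------------------------------------------------------------
# synthetic profiles for the seven stage-pattern templates


_TEMPLATE_WINDOWS = {
    # name -> stages with elevated expression
    "early_embryonic": set(EMBRYO_STAGES[:6]) | {"gravid_adult"},  # maternal-like
    "early_mid_embryonic": set(EMBRYO_STAGES[:14]),
    "mid_embryonic": set(EMBRYO_STAGES[10:20]),
    "late_embryonic": set(EMBRYO_STAGES[20:]),
    "mid_late_embryonic": set(EMBRYO_STAGES[10:]),
    "gastrulation": set(EMBRYO_STAGES[4:8]),
    "larval": set(LARVAL_STAGES),
}


def simulate_profiles(
    n_per_cluster: int = 10,
    noise: float = 0.5,
    high: float = 10.0,
    low: float = 1.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic expression matrix built from the seven stage templates.

    Each template sets ``high`` expression in its stage window and ``low``
    elsewhere; Gaussian noise (sd ``noise``) is added and values clipped at
    zero.  Returns the matrix and the true template label per gene.
    """
    rng = np.random.default_rng(seed)
    rows, labels, index = [], [], []
    for name, window in _TEMPLATE_WINDOWS.items():
        base = np.array([high if s in window else low for s in STAGE_ORDER])
        for i in range(n_per_cluster):
            rows.append(np.clip(base + rng.normal(0, noise, len(base)), 0, None))
            labels.append(name)
            index.append(f"{name}_{i:02d}")
    matrix = pd.DataFrame(rows, index=index, columns=STAGE_ORDER)
    return matrix, pd.Series(labels, index=index, name="template")
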