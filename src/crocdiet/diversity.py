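"""Dietary diversity and niche overlap between size classes.

Simpson diversity of a prey-count vector is the complement form

    D = 1 - sum_i (n_i / T)^2,        T = sum_i n_i,

the probability that two prey individuals drawn at random belong to
different categories; 0 for a single category, bounded above by 1 - 1/S for
S categories.

Two classes are compared with a nonparametric bootstrap over stomachs: each
replicate resamples a class's stomachs with replacement, pools the resampled
counts and recomputes D; the replicate spread estimates each class's
standard error, and

    t = (D_a - D_b) / sqrt(se_a^2 + se_b^2)

is referred to a t distribution with Welch-Satterthwaite degrees of freedom.

Niche overlap between classes j and k uses the symmetric Pianka index on
resource-use proportion vectors p and q:

    O_jk = sum_i p_i q_i / sqrt(sum_i p_i^2 * sum_i q_i^2),

0 for disjoint diets, 1 for identical proportions.  The proportion basis is
selectable: numeric (prey-count shares, default), volumetric (displaced
volume shares) or occurrence (incidence shares).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import DietTable, PreyRecord, StomachRecord
from .errors import DegenerateTestError, UndefinedMetricError

OVERLAP_BASES = ("numeric", "volumetric", "occurrence")


def simpson_diversity(counts: Sequence[float] | np.ndarray) -> float:
    """Simpson diversity D = 1 - sum p_i^2 of a category count vector."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise UndefinedMetricError("Simpson diversity undefined for empty class")
    p = counts / total
    return float(1.0 - np.sum(p * p))


def pianka_overlap(p: Sequence[float], q: Sequence[float]) -> float:
    """Pianka overlap of two proportion vectors over the same category order."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("proportion vectors must align on the same categories")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("proportions must be non-negative")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise UndefinedMetricError(f"{name} must sum to 1, got {v.sum()}")
    denom = np.sqrt(np.sum(p * p) * np.sum(q * q))
    return float(np.sum(p * q) / denom)


def overlap_label(overlap: float) -> str:
    """Verbal annotation: high >= 0.6, moderate [0.4, 0.6), low below."""
    if overlap >= 0.6:
        return "high"
    if overlap >= 0.4:
        return "moderate"
    return "low"


def class_proportions(diet: DietTable, basis: str = "numeric") -> pd.DataFrame:
    """Per-class category proportion vectors on the chosen basis."""
    if basis == "numeric":
        mat = diet.counts.astype(float)
    elif basis == "volumetric":
        mat = diet.volume.astype(float)
    elif basis == "occurrence":
        mat = diet.incidence.astype(float)
    else:
        raise ValueError(f"basis must be one of {OVERLAP_BASES}, got {basis!r}")
    totals = mat.sum(axis=1)
    if (totals <= 0).any():
        empty = [j for j in diet.classes if totals[j] <= 0]
        raise UndefinedMetricError(f"empty class(es) {empty} have no proportions")
    return mat.div(totals, axis=0)


def pairwise_overlap(diet: DietTable, basis: str = "numeric") -> pd.DataFrame:
    """Pianka overlap for every unordered pair of size classes."""
    props = class_proportions(diet, basis)
    rows = []
    for a, b in combinations(diet.classes, 2):
        o = pianka_overlap(props.loc[a].to_numpy(), props.loc[b].to_numpy())
        rows.append(
            {
                "class_a": a,
                "class_b": b,
                "basis": basis,
                "overlap": o,
                "label": overlap_label(o),
            }
        )
    return pd.DataFrame(rows)


def stomach_category_matrix(
    stomachs: Sequence[StomachRecord],
    prey: Sequence[PreyRecord],
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Stomach-by-category prey-count matrix (rows ordered as ``stomachs``)."""
    if categories is None:
        seen: dict[str, None] = {}
        for p in prey:
            seen.setdefault(p.category, None)
        categories = list(seen)
    ids = [s.stomach_id for s in stomachs]
    mat = pd.DataFrame(0, index=ids, columns=list(categories), dtype=int)
    for p in prey:
        mat.at[p.stomach_id, p.category] += p.count
    return mat


@dataclass(frozen=True)
class DiversityComparison:
    """Bootstrap comparison of Simpson diversity between two classes."""

    d_a: float
    d_b: float
    se_a: float
    se_b: float
    t: float
    df: float
    p: float
    replicates: int
    seed: int | None


def _bootstrap_d(counts: np.ndarray, replicates: int, rng: np.random.Generator) -> np.ndarray:
    n = counts.shape[0]
    idx = rng.integers(0, n, size=(replicates, n))
    pooled = counts[idx].sum(axis=1).astype(float)  # (replicates, S)
    totals = pooled.sum(axis=1)
    ok = totals > 0
    if not ok.any():
        raise DegenerateTestError("all bootstrap replicates empty")
    p = pooled[ok] / totals[ok, None]
    return 1.0 - np.sum(p * p, axis=1)


def diversity_compare(
    counts_a: pd.DataFrame | np.ndarray,
    counts_b: pd.DataFrame | np.ndarray,
    replicates: int = 1000,
    seed: int | None = None,
) -> DiversityComparison:
    """Two-sided bootstrap t comparison of Simpson diversity.

    ``counts_a``/``counts_b`` are stomach-by-category count matrices for the
    two classes (see :func:`stomach_category_matrix`).  Stomachs are resampled
    with replacement within each class; D is recomputed on each replicate's
    pooled counts.  Reproducible given ``seed``.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if replicates < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    for name, m in (("a", a), ("b", b)):
        if m.ndim != 2 or m.shape[0] < 2:
            raise DegenerateTestError(
                f"class {name} needs >= 2 stomachs for a bootstrap comparison"
            )
    d_a = simpson_diversity(a.sum(axis=0))
    d_b = simpson_diversity(b.sum(axis=0))
    rng = np.random.default_rng(seed)
    rep_a = _bootstrap_d(a, replicates, rng)
    rep_b = _bootstrap_d(b, replicates, rng)
    se_a = float(np.std(rep_a, ddof=1))
    se_b = float(np.std(rep_b, ddof=1))
    va, vb = se_a**2, se_b**2
    if va + vb == 0:
        t = 0.0
        df = float(a.shape[0] + b.shape[0] - 2)
        p = 1.0
    else:
        t = (d_a - d_b) / np.sqrt(va + vb)
        # Welch-Satterthwaite with the class stomach counts as sample sizes
        df = (va + vb) ** 2 / (
            va**2 / (a.shape[0] - 1) + vb**2 / (b.shape[0] - 1)
        )
        p = float(2.0 * stats.t.sf(abs(t), df))
    return DiversityComparison(
        d_a=d_a,
        d_b=d_b,
        se_a=se_a,
        se_b=se_b,
        t=float(t),
        df=float(df),
        p=min(1.0, float(p)),
        replicates=replicates,
        seed=seed,
    )
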