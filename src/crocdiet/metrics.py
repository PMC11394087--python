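"""Diet-composition indices per size class: %N, %V, %FO, RII and its classes.

For one size class with S prey categories:

    %N_i  = 100 * N_i / N_t          numeric percentage (N_t = total prey)
    %V_i  = 100 * vd_i / vTd         volumetric percentage (displaced volume)
    %FO_i = 100 * n_i / N            frequency of occurrence (N stomachs)
    RII_i = %FO_i * %V_i / 100       relative importance index, 0..100

RII classes: low [0, 10), secondary [10, 40), high [40, 100].  The boundary
values 10 and 40 belong to the upper class (an RII of exactly 10 is
secondary).

The volumetric denominator ``vTd`` is configurable: by default the sum of
displaced volumes of the identified items in the class, or an explicit
per-class total (appropriate when unidentifiable material contributed to the
measured total volume, so that the identified items' percentages sum to less
than 100).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import DietTable, round_half_up
from .errors import UndefinedMetricError

RII_LOW_MAX = 10.0
RII_SECONDARY_MAX = 40.0

#: ordered class labels
RII_CLASSES = ("low", "secondary", "high")


def numeric_percentage(counts: Sequence[float] | np.ndarray) -> np.ndarray:
    """%N for each category: 100 * N_i / N_t."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise UndefinedMetricError("numeric percentage undefined: no prey in class")
    return 100.0 * counts / total


def volumetric_percentage(
    vd: Sequence[float] | np.ndarray | float, vtd: float
) -> np.ndarray | float:
    """%V for each category: 100 * vd_i / vTd.

    When ``vtd`` exceeds the sum of the ``vd`` (an explicit measured total),
    the returned percentages sum to less than 100.
    """
    if vtd <= 0:
        raise UndefinedMetricError("volumetric percentage undefined: vTd must be > 0")
    arr = np.asarray(vd, dtype=float)
    if (arr < 0).any():
        raise ValueError("displaced volumes must be non-negative")
    out = 100.0 * arr / vtd
    return float(out) if np.isscalar(vd) else out


def frequency_occurrence(n: int, n_stomachs: int) -> float:
    """%FO: 100 * n / N for incidence ``n`` among ``N`` stomachs examined."""
    if n_stomachs <= 0:
        raise UndefinedMetricError("frequency of occurrence undefined: N must be > 0")
    if not 0 <= n <= n_stomachs:
        raise ValueError(f"incidence n={n} outside [0, N={n_stomachs}]")
    return 100.0 * n / n_stomachs


def relative_importance(pct_fo: float, pct_v: float) -> float:
    """RII = %FO * %V / 100, on the 0..100 scale."""
    for name, val in (("pct_fo", pct_fo), ("pct_v", pct_v)):
        if not 0 <= val <= 100:
            raise ValueError(f"{name} out of range [0, 100]: {val}")
    return pct_fo * pct_v / 100.0


def classify_rii(rii: float) -> str:
    """Low / secondary / high relative-importance class of an RII value."""
    if not 0 <= rii <= 100:
        raise ValueError(f"RII out of range [0, 100]: {rii}")
    if rii < RII_LOW_MAX:
        return "low"
    if rii < RII_SECONDARY_MAX:
        return "secondary"
    return "high"


def summarize_diet(
    diet: DietTable, vtd: str | Mapping[int, float] = "sum"
) -> pd.DataFrame:
    """Per-(size class, category) metrics table — the per-class diet summary.

    Parameters
    ----------
    diet
        Aggregated diet table.
    vtd
        Volumetric denominator policy: ``"sum"`` (default, vTd = sum of the
        class's identified-item volumes) or a mapping from class index to an
        explicit measured total volume in mL.

    Returns a tidy frame with columns size_class, category, n_i, pct_n,
    vd_ml, pct_v, n, pct_fo, rii, rii_class, at full precision (use
    :func:`rounded` for a display version).  A class with no prey yields
    all-zero metrics labelled low.
    """
    rows = []
    n_t = diet.total_counts()
    vtd_sum = diet.total_volume()
    for j in diet.classes:
        counts = diet.counts.loc[j].to_numpy(dtype=float)
        if counts.sum() > 0:
            pct_n = numeric_percentage(counts)
        else:
            pct_n = np.zeros_like(counts)
        if isinstance(vtd, str):
            if vtd != "sum":
                raise ValueError(f"unknown vTd policy {vtd!r}")
            vtd_j = float(vtd_sum[j])
        else:
            vtd_j = float(vtd[j])
        vd = diet.volume.loc[j].to_numpy(dtype=float)
        pct_v = volumetric_percentage(vd, vtd_j) if vtd_j > 0 else np.zeros_like(vd)
        n_stom = int(diet.n_stomachs[j])
        for i, cat in enumerate(diet.categories):
            fo = frequency_occurrence(int(diet.incidence.at[j, cat]), n_stom)
            rii = relative_importance(fo, float(pct_v[i]))
            rows.append(
                {
                    "size_class": j,
                    "category": cat,
                    "n_i": int(counts[i]),
                    "pct_n": float(pct_n[i]),
                    "vd_ml": float(vd[i]),
                    "pct_v": float(pct_v[i]),
                    "n": int(diet.incidence.at[j, cat]),
                    "pct_fo": fo,
                    "rii": rii,
                    "rii_class": classify_rii(rii),
                }
            )
    return pd.DataFrame(rows)


def pooled_frequency_occurrence(diet: DietTable) -> pd.Series:
    """%FO per category pooling incidence over all classes and stomachs."""
    total_stomachs = int(diet.n_stomachs.sum())
    if total_stomachs == 0:
        raise UndefinedMetricError("no stomachs in diet table")
    return 100.0 * diet.pooled_incidence() / total_stomachs


def rounded(metrics: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Display rounding (half-up, one decimal) of percentage-scale columns."""
    out = metrics.copy()
    for col in ("pct_n", "pct_v", "pct_fo", "rii", "vd_ml"):
        if col in out:
            out[col] = out[col].map(lambda x: round_half_up(x, decimals))
    return out
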