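"""Stomach-content data model: records, CSV IO, size-class binning, aggregation.

The sampling unit throughout is one flushed stomach (= one individual).  A
dataset is a pair of tidy CSV tables:

``stomachs.csv``
    one row per individual — ``stomach_id``, ``tl_mm`` (total length,
    millimetres), optional ``site`` and ``date`` (ISO-8601).

``prey.csv``
    one row per (stomach, prey category) observation — ``stomach_id``,
    ``category``, ``count`` (number of prey individuals), ``volume_ml``
    (displaced volume, mL), optional ``rank`` and ``group``.

Total length is binned into ``k`` equal-width size classes spanning the
observed length range (width = (upper − lower) / k); classes are left-closed,
right-open, except the last class which is closed at the upper limit.
Aggregation reduces stomach-level records to a per-class :class:`DietTable`
holding, per prey category, the prey count ``N_i``, the incidence ``n``
(stomachs in which the category appears with count > 0) and the summed
displaced volume ``vd``, along with the per-class stomach count ``N``.

The module also provides :func:`infer_counts_from_percentages`, an exhaustive
reconstruction of the smallest integer count vector consistent with a column
of rounded numeric percentages — the oracle used to rebuild count structure
from a published summary table that prints percentages but not counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    NoSolutionError,
    OutOfRangeError,
    SchemaError,
    ValidationError,
)

VALID_GROUPS = frozenset({"invertebrate", "vertebrate"})

STOMACH_COLUMNS = ("stomach_id", "tl_mm")
PREY_COLUMNS = ("stomach_id", "category", "count", "volume_ml")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with halves away from zero, as printed tables conventionally do."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class PreyCategory:
    """A prey category label with its taxonomic rank tag and coarse group.

    Invertebrate prey are identified to order ("Coleoptera", "Araneae", ...),
    vertebrate prey to class ("Fish", "Birds").
    """

    name: str
    rank: str = "order"
    group: str = "invertebrate"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("prey category name must be non-empty")
        if self.group not in VALID_GROUPS:
            raise ValidationError(
                f"prey group must be one of {sorted(VALID_GROUPS)}, got {self.group!r}"
            )


@dataclass
class StomachRecord:
    """One flushed stomach: individual id, total length, optional class index."""

    stomach_id: str
    tl_mm: float
    size_class: int | None = None
    site: str | None = None
    date: str | None = None

    def __post_init__(self) -> None:
        if not (self.tl_mm > 0):
            raise ValidationError(
                f"stomach {self.stomach_id!r}: tl_mm must be > 0, got {self.tl_mm}"
            )


@dataclass
class PreyRecord:
    """Prey of one category recovered from one stomach."""

    stomach_id: str
    category: str
    count: int
    volume_ml: float
    rank: str = "order"
    group: str = "invertebrate"

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError(
                f"stomach {self.stomach_id!r}, {self.category}: count must be >= 0"
            )
        if self.volume_ml < 0:
            raise ValidationError(
                f"stomach {self.stomach_id!r}, {self.category}: volume_ml must be >= 0"
            )


@dataclass(frozen=True)
class SizeClassScheme:
    """``k`` equal-width total-length bins on [lower_mm, upper_mm]."""

    lower_mm: float
    upper_mm: float
    k: int
    breaks: tuple[float, ...]

    @property
    def width(self) -> float:
        return (self.upper_mm - self.lower_mm) / self.k

    def interval(self, j: int) -> tuple[float, float]:
        """Bounds of class ``j`` (1-based)."""
        if not 1 <= j <= self.k:
            raise ValueError(f"class index must be in 1..{self.k}, got {j}")
        return self.breaks[j - 1], self.breaks[j]


def make_size_classes(lower_mm: float, upper_mm: float, k: int) -> SizeClassScheme:
    """Equal-width size classes: width = (upper − lower) / k.

    Intervals are [b_j, b_{j+1}) with the last interval closed at ``upper_mm``.
    Breaks are kept at full precision; printed bounds such as "369.6" are
    display roundings of the exact break 369.66…
    """
    if k < 1:
        raise ValueError(f"number of classes must be >= 1, got {k}")
    if not upper_mm > lower_mm:
        raise ValueError(f"need upper > lower, got [{lower_mm}, {upper_mm}]")
    width = (upper_mm - lower_mm) / k
    breaks = tuple(lower_mm + i * width for i in range(k)) + (float(upper_mm),)
    return SizeClassScheme(float(lower_mm), float(upper_mm), k, breaks)


def assign_size_class(tl_mm: float, scheme: SizeClassScheme) -> int:
    """1-based class index of a total length under a scheme.

    Left-closed convention: a length equal to an interior break belongs to the
    upper class; the scheme's upper limit belongs to the last class.
    """
    if not scheme.lower_mm <= tl_mm <= scheme.upper_mm:
        raise OutOfRangeError(
            f"tl_mm={tl_mm} outside scheme range [{scheme.lower_mm}, {scheme.upper_mm}]"
        )
    j = int(np.searchsorted(np.asarray(scheme.breaks), tl_mm, side="right"))
    return min(j, scheme.k)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_dataset(
    stomachs_file, prey_file
) -> tuple[list[StomachRecord], list[PreyRecord]]:
    """Read and validate a (stomachs.csv, prey.csv) pair.

    Duplicate (stomach_id, category) prey rows are summed on load.  Prey rows
    referencing an unknown stomach id, negative counts or volumes, and
    duplicate stomach ids are rejected with the offending row number.
    ``rank``/``group`` columns are optional and default to order/invertebrate.
    """
    sdf = pd.read_csv(stomachs_file, dtype={"stomach_id": str}, float_precision="round_trip")
    _require_columns(sdf, STOMACH_COLUMNS, str(stomachs_file))
    if sdf["stomach_id"].duplicated().any():
        dup = sdf.loc[sdf["stomach_id"].duplicated(), "stomach_id"].iloc[0]
        raise ValidationError(f"{stomachs_file}: duplicate stomach_id {dup!r}")
    stomachs = []
    for i, row in sdf.iterrows():
        if not row["tl_mm"] > 0:
            raise ValidationError(
                f"{stomachs_file} row {i + 2}: tl_mm must be > 0, got {row['tl_mm']}"
            )
        stomachs.append(
            StomachRecord(
                stomach_id=row["stomach_id"],
                tl_mm=float(row["tl_mm"]),
                site=row.get("site") if isinstance(row.get("site"), str) else None,
                date=row.get("date") if isinstance(row.get("date"), str) else None,
            )
        )

    pdf = pd.read_csv(
        prey_file, dtype={"stomach_id": str, "category": str}, float_precision="round_trip"
    )
    _require_columns(pdf, PREY_COLUMNS, str(prey_file))
    known = set(sdf["stomach_id"])
    for i, row in pdf.iterrows():
        if row["stomach_id"] not in known:
            raise ValidationError(
                f"{prey_file} row {i + 2}: unknown stomach_id {row['stomach_id']!r}"
            )
        if row["count"] < 0:
            raise ValidationError(
                f"{prey_file} row {i + 2}: count must be >= 0, got {row['count']}"
            )
        if row["volume_ml"] < 0:
            raise ValidationError(
                f"{prey_file} row {i + 2}: volume_ml must be >= 0, got {row['volume_ml']}"
            )
    if "rank" not in pdf.columns:
        pdf = pdf.assign(rank="order")
    if "group" not in pdf.columns:
        pdf = pdf.assign(group="invertebrate")
    merged = pdf.groupby(["stomach_id", "category"], sort=False, as_index=False).agg(
        count=("count", "sum"),
        volume_ml=("volume_ml", "sum"),
        rank=("rank", "first"),
        group=("group", "first"),
    )
    prey = [
        PreyRecord(
            stomach_id=row.stomach_id,
            category=row.category,
            count=int(row.count),
            volume_ml=float(row.volume_ml),
            rank=row.rank,
            group=row.group,
        )
        for row in merged.itertuples()
    ]
    return stomachs, prey


def stomachs_to_frame(stomachs: Iterable[StomachRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"stomach_id": s.stomach_id, "tl_mm": s.tl_mm, "site": s.site, "date": s.date}
            for s in stomachs
        ],
        columns=["stomach_id", "tl_mm", "site", "date"],
    )


def prey_to_frame(prey: Iterable[PreyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stomach_id": p.stomach_id,
                "category": p.category,
                "rank": p.rank,
                "group": p.group,
                "count": p.count,
                "volume_ml": p.volume_ml,
            }
            for p in prey
        ],
        columns=["stomach_id", "category", "rank", "group", "count", "volume_ml"],
    )


def write_dataset(
    stomachs: Iterable[StomachRecord],
    prey: Iterable[PreyRecord],
    stomachs_file,
    prey_file,
) -> None:
    """Write the two-table CSV representation (UTF-8, header row).

    Floats are written with full repr precision so that write -> read
    reproduces records bit-for-bit.
    """
    fmt = lambda v: repr(float(v))
    stomachs_to_frame(stomachs).to_csv(stomachs_file, index=False, float_format=fmt)
    prey_to_frame(prey).to_csv(prey_file, index=False, float_format=fmt)


@dataclass
class DietTable:
    """Per-size-class aggregation of a stomach-content dataset.

    Matrices are indexed by 1-based size class (rows) and prey category
    (columns): ``counts`` holds prey counts N_i, ``incidence`` the number of
    stomachs containing each category, ``volume`` the summed displaced volume
    vd (mL).  ``n_stomachs`` is the per-class number of stomachs examined N
    (the frequency-of-occurrence denominator).
    """

    counts: pd.DataFrame
    incidence: pd.DataFrame
    volume: pd.DataFrame
    n_stomachs: pd.Series

    @property
    def categories(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def classes(self) -> list[int]:
        return list(self.counts.index)

    def total_counts(self) -> pd.Series:
        """Per-class total prey count N_t (the %N denominator)."""
        return self.counts.sum(axis=1)

    def total_volume(self) -> pd.Series:
        """Per-class summed displaced volume of identified items (mL)."""
        return self.volume.sum(axis=1)

    def pooled_counts(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def pooled_incidence(self) -> pd.Series:
        return self.incidence.sum(axis=0)

    def validate(self) -> None:
        if (self.counts.values < 0).any() or (self.volume.values < 0).any():
            raise ValidationError("diet table entries must be non-negative")
        if (self.incidence.values > self.n_stomachs.values[:, None]).any():
            raise ValidationError("incidence exceeds stomachs examined in a class")
        if (self.incidence.values > self.counts.values).any():
            raise ValidationError(
                "incidence exceeds prey count (each incident stomach holds >= 1 prey)"
            )

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-(class, category) view with per-class totals."""
        rows = []
        for j in self.classes:
            for cat in self.categories:
                rows.append(
                    {
                        "size_class": j,
                        "category": cat,
                        "n_i": int(self.counts.at[j, cat]),
                        "n": int(self.incidence.at[j, cat]),
                        "vd_ml": float(self.volume.at[j, cat]),
                        "n_stomachs": int(self.n_stomachs[j]),
                        "n_t": int(self.total_counts()[j]),
                        "vtd_sum_ml": float(self.total_volume()[j]),
                    }
                )
        return pd.DataFrame(rows)


def aggregate(
    stomachs: Sequence[StomachRecord],
    prey: Sequence[PreyRecord],
    scheme: SizeClassScheme,
    categories: Sequence[str] | None = None,
) -> DietTable:
    """Reduce stomach-level records to a per-class diet table.

    Every stomach must fall inside the scheme.  Categories default to order of
    first appearance in the prey records; zero-count categories passed
    explicitly are retained as all-zero columns.  Incidence counts stomachs in
    which a category appears with count > 0 (a zero-count row is not an
    occurrence).
    """
    class_of: dict[str, int] = {}
    for s in stomachs:
        j = assign_size_class(s.tl_mm, scheme)
        s.size_class = j
        class_of[s.stomach_id] = j
    if categories is None:
        seen: dict[str, None] = {}
        for p in prey:
            seen.setdefault(p.category, None)
        categories = list(seen)
    classes = list(range(1, scheme.k + 1))
    counts = pd.DataFrame(0, index=classes, columns=list(categories), dtype=int)
    incidence = counts.copy()
    volume = pd.DataFrame(0.0, index=classes, columns=list(categories))
    n_stomachs = pd.Series(0, index=classes, dtype=int)
    for s in stomachs:
        n_stomachs[class_of[s.stomach_id]] += 1
    for p in prey:
        if p.stomach_id not in class_of:
            raise ValidationError(f"prey record references unknown stomach {p.stomach_id!r}")
        if p.category not in counts.columns:
            raise ValidationError(f"prey category {p.category!r} not in category list")
        j = class_of[p.stomach_id]
        counts.at[j, p.category] += p.count
        volume.at[j, p.category] += p.volume_ml
        if p.count > 0:
            incidence.at[j, p.category] += 1
    table = DietTable(counts, incidence, volume, n_stomachs)
    table.validate()
    return table


def infer_counts_from_percentages(
    pct: Sequence[float], t_max: int = 1000, decimals: int = 1
) -> tuple[int, tuple[int, ...]]:
    """Smallest integer count vector consistent with rounded percentages.

    Finds the smallest total ``T <= t_max`` and non-negative integers ``n_i``
    with ``sum(n_i) = T`` such that each ``100 * n_i / T``, rounded half-up to
    ``decimals`` places, reproduces ``pct_i`` exactly.  Exhaustive search over
    ``T``; within each ``T`` the admissible ``n_i`` form contiguous integer
    ranges derived in exact arithmetic, so no floating-point rounding can
    leak into the feasibility test.

    Raises :class:`NoSolutionError` when no total up to ``t_max`` works (for
    instance when the percentages cannot sum to 100).
    """
    pct = list(pct)
    if not pct:
        raise ValueError("need at least one percentage")
    for p in pct:
        if not 0 <= p <= 100:
            raise ValueError(f"percentage out of range [0, 100]: {p}")
    scale = 10**decimals
    targets = [int(round(p * scale)) for p in pct]  # printed value * 10^decimals
    denom = 2 * 100 * scale  # n/T*100 rounds to P/scale  <=>  (2P-1)T <= 2*100*scale*n < (2P+1)T
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    for total in range(1, t_max + 1):
        lo_sum = 0
        hi_sum = 0
        los: list[int] = []
        his: list[int] = []
        feasible = True
        for p_scaled in targets:
            a = (2 * p_scaled - 1) * total
            lo = max(0, -((-a) // denom))  # ceil(a / denom)
            hi = min(total, ((2 * p_scaled + 1) * total - 1) // denom)
            if lo > hi:
                feasible = False
                break
            los.append(lo)
            his.append(hi)
            lo_sum += lo
            hi_sum += hi
        if not feasible or not lo_sum <= total <= hi_sum:
            continue
        counts = los[:]
        slack = total - lo_sum
        for i in range(len(counts)):
            if slack == 0:
                break
            bump = min(slack, his[i] - counts[i])
            counts[i] += bump
            slack -= bump
        return total, tuple(counts)
    raise NoSolutionError(
        f"no integer counts with total <= {t_max} reproduce the rounded percentages"
    )
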