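"""Published summary of the hatchling diet survey this package analyses.

The source field study flushed the stomachs of 31 wild hatchling Morelet's
crocodiles (total length 300-509 mm) and published, per prey category and
per total-length size class, a summary table of numeric percentage (%N),
displaced volume (vd, mL), volumetric percentage (%V), frequency of
occurrence (%FO) and relative importance index (RII) with its
low/secondary/high class — but not the underlying per-stomach rows.  This
module holds that printed table verbatim, plus the quantities that the
printed columns force:

* size-class scheme: three equal-width classes on [300, 509] mm with
  n = 10, 7, 14 stomachs;
* per-class per-category incidence, recovered exactly from %FO x N / 100
  (all printed %FO values are integer multiples of 1/N to display rounding);
* per-class per-category integer prey counts.  For the medium and final
  classes these are the unique smallest integer vectors whose proportions
  round back to the printed %N column (totals 24 and 54) and they coincide
  with the incidences; the initial class's printed %N column admits no exact
  integer solution (Coleoptera printed 26.6 vs 9/34 = 26.5), so the counts
  (9, 10, 8, 1, 2, 1, 1, 2) are stored, honouring %FO exactly and %N to
  within 0.2 points;
* explicit per-class total displaced volumes vTd = 10, 7, 14 mL, the
  denominators under which the printed vd cells reproduce the printed %V
  (the %V columns sum to less than 100, so the measured totals exceeded the
  identified-item sums).

Everything downstream (fixture construction, acceptance checks, worked
examples) reads these constants rather than re-keying numbers.
"""

from __future__ import annotations

import pandas as pd

from .data import PreyCategory, SizeClassScheme, make_size_classes

#: total-length range (mm) spanned by the survey's hatchlings
TL_RANGE_MM = (300.0, 509.0)

#: number of equal-width size classes
N_SIZE_CLASSES = 3

#: stomachs examined per size class (initial, medium, final)
CLASS_SIZES = {1: 10, 2: 7, 3: 14}

#: explicit measured total displaced volume per class, mL (the %V denominator)
CLASS_TOTAL_VOLUME_ML = {1: 10.0, 2: 7.0, 3: 14.0}

#: the 11 prey categories in published order
CATEGORIES = (
    PreyCategory("Coleoptera", "order", "invertebrate"),
    PreyCategory("Hemiptera", "order", "invertebrate"),
    PreyCategory("Araneae", "order", "invertebrate"),
    PreyCategory("Blattodea", "order", "invertebrate"),
    PreyCategory("Hymenoptera", "order", "invertebrate"),
    PreyCategory("Fish", "class", "vertebrate"),
    PreyCategory("Birds", "class", "vertebrate"),
    PreyCategory("Diptera", "order", "invertebrate"),
    PreyCategory("Odonata", "order", "invertebrate"),
    PreyCategory("Scorpiones", "order", "invertebrate"),
    PreyCategory("Gastropods", "class", "invertebrate"),
)

CATEGORY_NAMES = tuple(c.name for c in CATEGORIES)

# printed table rows: (size_class, category, pct_n, vd_ml, pct_v, pct_fo, rii, rii_class)
_TABLE_ROWS = [
    (1, "Coleoptera", 26.6, 3.5, 34.5, 90.0, 31.1, "secondary"),
    (1, "Hemiptera", 29.4, 2.1, 21.0, 100.0, 21.0, "secondary"),
    (1, "Araneae", 23.5, 1.3, 12.5, 80.0, 10.0, "secondary"),
    (1, "Blattodea", 2.9, 0.5, 5.0, 10.0, 0.5, "low"),
    (1, "Hymenoptera", 5.9, 0.2, 2.0, 20.0, 0.4, "low"),
    (1, "Fish", 0.0, 0.0, 0.0, 0.0, 0.0, "low"),
    (1, "Birds", 0.0, 0.0, 0.0, 0.0, 0.0, "low"),
    (1, "Diptera", 2.9, 0.9, 9.0, 10.0, 0.9, "low"),
    (1, "Odonata", 2.9, 0.3, 3.0, 10.0, 0.3, "low"),
    (1, "Scorpiones", 5.9, 0.2, 1.5, 20.0, 0.3, "low"),
    (1, "Gastropods", 0.0, 0.0, 0.0, 0.0, 0.0, "low"),
    (2, "Coleoptera", 25.0, 5.4, 77.4, 85.7, 66.3, "high"),
    (2, "Hemiptera", 16.7, 2.3, 32.9, 57.1, 18.8, "secondary"),
    (2, "Araneae", 25.0, 2.1, 30.0, 85.7, 25.7, "secondary"),
    (2, "Blattodea", 4.2, 1.3, 18.6, 14.3, 2.7, "low"),
    (2, "Hymenoptera", 12.5, 1.3, 17.9, 42.9, 7.7, "low"),
    (2, "Fish", 4.2, 0.3, 4.3, 14.3, 0.6, "low"),
    (2, "Birds", 0.0, 0.0, 0.0, 0.0, 0.0, "low"),
    (2, "Diptera", 4.2, 0.1, 0.7, 14.3, 0.1, "low"),
    (2, "Odonata", 4.2, 0.5, 7.1, 14.3, 1.0, "low"),
    (2, "Scorpiones", 4.2, 0.2, 2.9, 14.3, 0.4, "low"),
    (2, "Gastropods", 0.0, 0.0, 0.0, 0.0, 0.0, "low"),
    (3, "Coleoptera", 22.2, 4.9, 34.6, 85.7, 29.7, "secondary"),
    (3, "Hemiptera", 16.7, 2.8, 20.0, 64.3, 12.9, "secondary"),
    (3, "Araneae", 16.7, 3.7, 26.1, 64.3, 16.8, "secondary"),
    (3, "Blattodea", 7.4, 2.1, 15.0, 28.6, 4.3, "low"),
    (3, "Hymenoptera", 11.1, 1.4, 10.0, 42.9, 4.3, "low"),
    (3, "Fish", 7.4, 2.0, 13.9, 28.6, 4.0, "low"),
    (3, "Birds", 1.9, 1.3, 9.3, 7.1, 0.7, "low"),
    (3, "Diptera", 3.7, 0.3, 1.8, 14.3, 0.3, "low"),
    (3, "Odonata", 1.9, 0.1, 0.7, 7.1, 0.1, "low"),
    (3, "Scorpiones", 3.7, 0.3, 1.8, 14.3, 0.3, "low"),
    (3, "Gastropods", 7.4, 0.2, 1.4, 28.6, 0.4, "low"),
]

#: per-class per-category integer prey counts forced by the printed columns
#: (counts coincide with incidences in every class: each incident stomach
#: contributed exactly one prey individual of the category)
CLASS_COUNTS = {
    1: (9, 10, 8, 1, 2, 0, 0, 1, 1, 2, 0),
    2: (6, 4, 6, 1, 3, 1, 0, 1, 1, 1, 0),
    3: (12, 9, 9, 4, 6, 4, 1, 2, 1, 2, 4),
}

#: per-class per-category incidence (stomachs containing the category)
CLASS_INCIDENCE = dict(CLASS_COUNTS)

#: printed per-class %N columns (published order), for reconstruction checks
PCT_N_COLUMNS = {
    j: tuple(r[2] for r in _TABLE_ROWS if r[0] == j) for j in (1, 2, 3)
}


def reference_table() -> pd.DataFrame:
    """The printed per-class diet summary as a tidy DataFrame."""
    return pd.DataFrame(
        _TABLE_ROWS,
        columns=[
            "size_class",
            "category",
            "pct_n",
            "vd_ml",
            "pct_v",
            "pct_fo",
            "rii",
            "rii_class",
        ],
    )


def size_class_scheme() -> SizeClassScheme:
    """The survey's three equal-width TL classes on [300, 509] mm."""
    return make_size_classes(TL_RANGE_MM[0], TL_RANGE_MM[1], N_SIZE_CLASSES)
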