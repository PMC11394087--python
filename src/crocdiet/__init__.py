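"""crocdiet: stomach-content diet-composition analysis for hatchling crocodiles.

Quantifies a stomach-flushing survey end to end: per-size-class diet indices
(%N, %V, %FO and the relative importance index with its low/secondary/high
classes), Simpson diversity with bootstrap pairwise comparison, Pianka niche
overlap between size classes, a bootstrap chi-square composition test with
standardized residuals, and per-item logistic regression of prey presence
against total length — plus a synthetic stomach-content generator and the
reconstructed 31-stomach survey fixture.
"""

from importlib import resources

from .data import (
    DietTable,
    PreyCategory,
    PreyRecord,
    SizeClassScheme,
    StomachRecord,
    aggregate,
    assign_size_class,
    infer_counts_from_percentages,
    make_size_classes,
    read_dataset,
    write_dataset,
)
from .diversity import (
    DiversityComparison,
    diversity_compare,
    overlap_label,
    pairwise_overlap,
    pianka_overlap,
    simpson_diversity,
    stomach_category_matrix,
)
from .inference import (
    GofResult,
    LogisticFit,
    bootstrap_gof,
    bootstrap_gof_stomach,
    fit_logistic_presence,
    logistic_screen,
    presence_curve,
    residual_flags,
    rii_filter,
)
from .metrics import (
    classify_rii,
    frequency_occurrence,
    numeric_percentage,
    pooled_frequency_occurrence,
    relative_importance,
    summarize_diet,
    volumetric_percentage,
)
from .simulate import (
    CategoryModel,
    FixtureDataset,
    SimScenario,
    build_study_fixture,
    scenario_from_fixture,
    simulate_stomachs,
)

__version__ = "0.1.0"


def fixture_csv_paths():
    """Paths of the packaged fixture CSVs (stomachs.csv, prey.csv)."""
    base = resources.files(__name__) / "data"
    return base / "stomachs.csv", base / "prey.csv"


__all__ = [
    "DietTable",
    "PreyCategory",
    "PreyRecord",
    "SizeClassScheme",
    "StomachRecord",
    "aggregate",
    "assign_size_class",
    "infer_counts_from_percentages",
    "make_size_classes",
    "read_dataset",
    "write_dataset",
    "DiversityComparison",
    "diversity_compare",
    "overlap_label",
    "pairwise_overlap",
    "pianka_overlap",
    "simpson_diversity",
    "stomach_category_matrix",
    "GofResult",
    "LogisticFit",
    "bootstrap_gof",
    "bootstrap_gof_stomach",
    "fit_logistic_presence",
    "logistic_screen",
    "presence_curve",
    "residual_flags",
    "rii_filter",
    "classify_rii",
    "frequency_occurrence",
    "numeric_percentage",
    "pooled_frequency_occurrence",
    "relative_importance",
    "summarize_diet",
    "volumetric_percentage",
    "CategoryModel",
    "FixtureDataset",
    "SimScenario",
    "build_study_fixture",
    "scenario_from_fixture",
    "simulate_stomachs",
    "fixture_csv_paths",
]
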