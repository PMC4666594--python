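"""Recompute published headline numbers from the bundled table transcriptions.

Every quantity here is derived at run time from the transcribed tables in
:mod:`genomogram.tables` using the package's own metric code: experiment
accuracies from the four confusion matrices, texture-invariance statistics
(paired differences, rank agreement, paired t-test) from the Haralick table,
and corpus totals from the per-class sample counts.
"""

from __future__ import annotations

import numpy as np

from . import tables
from .evaluation import (
    ConfusionMatrix,
    accuracy_from_cm,
    macro_metrics,
    paired_t_test,
)
from .features import rank_by_value

__all__ = [
    "table_accuracies",
    "table_macro_metrics",
    "texture_invariance",
    "sample_totals",
    "headline_report",
]


def _cm(key: str) -> ConfusionMatrix:
    return ConfusionMatrix(tables.CONFUSION_MATRICES[key], tables.CLASS_NAMES)


def table_accuracies() -> dict[str, float]:
    """Accuracy (percent) of each experiment, as trace/total of its
    transcribed confusion matrix."""
    return {
        key: 100.0 * accuracy_from_cm(_cm(key))
        for key in tables.CONFUSION_MATRICES
    }


def table_macro_metrics() -> dict[str, dict[str, float]]:
    """Macro one-vs-rest sensitivity/specificity recomputed per matrix."""
    out = {}
    for key in tables.CONFUSION_MATRICES:
        sens, spec, _ = macro_metrics(_cm(key))
        out[key] = {"macro_sensitivity": sens, "macro_specificity": spec}
    return out


def texture_invariance() -> dict:
    """Invariance statistics of the two affine renderings from the Haralick
    texture table: mean paired differences (tetrahedron minus Z-curve),
    counts of genes whose within-column ranks disagree, and the paired
    t-tests."""
    rows = [tables.TEXTURE_TABLE[g] for g in tables.GENE_ORDER]
    zc_contrast, zc_homog, tet_contrast, tet_homog = map(np.array, zip(*rows))
    contrast_test = paired_t_test(zc_contrast, tet_contrast)
    homog_test = paired_t_test(zc_homog, tet_homog)
    zc_rank = rank_by_value(zc_contrast, descending=True)
    tet_rank = rank_by_value(tet_contrast, descending=True)
    contrast_rank_disagreements = sum(a != b for a, b in zip(zc_rank, tet_rank))
    # homogeneity ranks: low homogeneity = heavy texture = rank 1
    zc_hrank = rank_by_value(zc_homog, descending=False)
    tet_hrank = rank_by_value(tet_homog, descending=False)
    homogeneity_rank_disagreements = sum(
        a != b for a, b in zip(zc_hrank, tet_hrank)
    )
    return {
        "mean_contrast_difference": contrast_test.mean_difference,
        "mean_homogeneity_difference": homog_test.mean_difference,
        "contrast_rank_disagreements": contrast_rank_disagreements,
        "homogeneity_rank_disagreements": homogeneity_rank_disagreements,
        "contrast_ttest": contrast_test,
        "homogeneity_ttest": homog_test,
    }


def sample_totals() -> dict[str, int]:
    curated = sum(v[0] for v in tables.SAMPLE_COUNTS.values())
    unique = sum(v[1] for v in tables.SAMPLE_COUNTS.values())
    return {"curated_samples": curated, "unique_samples": unique}


# headline values as published, used only for the pass/fail report
_PUBLISHED = {
    "accuracy_pct": {
        "zcurve+mlp": 75.84,
        "tetrahedron+mlp": 73.97,
        "zcurve+rbf": 98.88,
        "tetrahedron+rbf": 98.50,
    },
    "mean_contrast_difference": 100.1,
    "mean_homogeneity_difference": 9e-5,
    "contrast_rank_disagreements": 2,
    "curated_samples": 10784,
    "unique_samples": 534,
}


def headline_report() -> list[tuple[str, float, float, bool]]:
    """(name, recomputed, published, agrees-to-printed-precision) rows."""
    rows = []
    acc = table_accuracies()
    for key, published in _PUBLISHED["accuracy_pct"].items():
        got = acc[key]
        rows.append((f"accuracy {key} (%)", got, published,
                     abs(got - published) < 0.005))
    inv = texture_invariance()
    got = abs(inv["mean_contrast_difference"])
    rows.append(("|mean contrast difference|", got,
                 _PUBLISHED["mean_contrast_difference"],
                 abs(got - _PUBLISHED["mean_contrast_difference"]) < 0.05))
    got = abs(inv["mean_homogeneity_difference"])
    rows.append(("|mean homogeneity difference|", got,
                 _PUBLISHED["mean_homogeneity_difference"],
                 abs(got - _PUBLISHED["mean_homogeneity_difference"]) < 5e-6))
    got = inv["contrast_rank_disagreements"]
    rows.append(("contrast rank disagreements", got,
                 _PUBLISHED["contrast_rank_disagreements"],
                 got == _PUBLISHED["contrast_rank_disagreements"]))
    totals = sample_totals()
    for key in ("curated_samples", "unique_samples"):
        rows.append((key, totals[key], _PUBLISHED[key],
                     totals[key] == _PUBLISHED[key]))
    return rows
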