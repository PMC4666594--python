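"""Bundled transcriptions of the published summary tables.

These printed tables are *inputs*: per-class sample counts of the curated
mutation corpus, Haralick texture statistics of the ten biomarker-gene
images under both affine transforms, and the four experiments' confusion
matrices (rows = predicted class, columns = actual class — the orientation
under which the normal-class column, not row, sums to its 100 instances).
They let the reported headline numbers (accuracies, texture-invariance
statistics) be recomputed exactly without the original curated data.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CLASS_NAMES",
    "GENE_ORDER",
    "SAMPLE_COUNTS",
    "TEXTURE_TABLE",
    "CONFUSION_ZCURVE_MLP",
    "CONFUSION_TETRAHEDRON_MLP",
    "CONFUSION_ZCURVE_RBF",
    "CONFUSION_TETRAHEDRON_RBF",
    "CONFUSION_MATRICES",
]

CLASS_NAMES: list[str] = [
    "Normal",
    "TP53 Deletion",
    "TP53 Substitution",
    "EGFR Deletion",
    "EGFR Substitution",
    "KRAS Substitution",
    "KMT2C Substitution",
    "NF1 Substitution",
    "CDKN2A Substitution",
    "STK11 Deletion",
    "STK11 Substitution",
    "KMT2D Substitution",
    "ZNF521 Substitution",
    "SMARCA4 Substitution",
]

# per class: (curated samples, unique samples used for the experiments)
SAMPLE_COUNTS: dict[str, tuple[int, int]] = {
    "Normal": (100, 100),
    "TP53 Deletion": (125, 32),
    "TP53 Substitution": (1483, 35),
    "EGFR Deletion": (1368, 35),
    "EGFR Substitution": (2913, 27),
    "KRAS Substitution": (4058, 28),
    "KMT2C Substitution": (149, 35),
    "NF1 Substitution": (88, 35),
    "CDKN2A Substitution": (98, 35),
    "STK11 Deletion": (32, 32),
    "STK11 Substitution": (124, 35),
    "KMT2D Substitution": (80, 35),
    "ZNF521 Substitution": (105, 35),
    "SMARCA4 Substitution": (61, 35),
}

GENE_ORDER: list[str] = [
    "KRAS",
    "CDKN2A",
    "TP53",
    "STK11",
    "EGFR",
    "ZNF521",
    "SMARCA4",
    "NF1",
    "KMT2C",
    "KMT2D",
]

# per gene: (zcurve contrast, zcurve homogeneity,
#            tetrahedron contrast, tetrahedron homogeneity)
TEXTURE_TABLE: dict[str, tuple[float, float, float, float]] = {
    "KRAS": (13099, 0.0342, 12997, 0.0347),
    "CDKN2A": (12474, 0.0345, 13495, 0.0342),
    "TP53": (12414, 0.0346, 12512, 0.0339),
    "STK11": (12364, 0.0368, 12177, 0.0376),
    "EGFR": (11006, 0.0391, 11042, 0.0382),
    "ZNF521": (10975, 0.0383, 11021, 0.0386),
    "SMARCA4": (10450, 0.0390, 10509, 0.0387),
    "NF1": (8801, 0.0421, 8815, 0.0417),
    "KMT2C": (6779, 0.0438, 6761, 0.0436),
    "KMT2D": (6358, 0.0445, 6392, 0.0448),
}

# 14x14 confusion matrices; counts[p][a] = #(predicted p, actual a),
# classes ordered as CLASS_NAMES.

CONFUSION_ZCURVE_MLP = np.array(
    [
        [10, 0, 0, 2, 0, 0, 0, 0, 4, 0, 0, 0, 0, 0],
        [0, 35, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [10, 0, 27, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 26, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [10, 0, 0, 0, 27, 10, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 5, 25, 0, 0, 0, 0, 0, 0, 0, 0],
        [10, 0, 0, 0, 0, 0, 35, 0, 0, 0, 0, 0, 0, 0],
        [10, 0, 0, 0, 0, 0, 0, 35, 0, 0, 0, 0, 0, 0],
        [10, 0, 0, 0, 0, 0, 0, 0, 31, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 22, 8, 0, 0, 0],
        [10, 0, 0, 0, 0, 0, 0, 0, 0, 10, 27, 0, 0, 0],
        [10, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 35, 0, 0],
        [10, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 35, 0],
        [10, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 35],
    ]
)

CONFUSION_TETRAHEDRON_MLP = np.array(
    [
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 34, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0],
        [10, 1, 27, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [10, 0, 0, 28, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 20, 5, 0, 0, 0, 0, 0, 0, 0, 0],
        [10, 0, 0, 0, 12, 30, 0, 0, 0, 0, 0, 0, 0, 0],
        [10, 0, 0, 0, 0, 0, 35, 0, 0, 0, 0, 0, 0, 0],
        [10, 0, 0, 0, 0, 0, 0, 35, 0, 0, 0, 0, 0, 0],
        [10, 0, 0, 0, 0, 0, 0, 0, 35, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 11, 0, 0, 0, 0],
        [10, 0, 0, 0, 0, 0, 0, 0, 0, 20, 35, 0, 0, 0],
        [10, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 35, 0, 0],
        [10, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 35, 0],
        [10, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 35],
    ]
)

CONFUSION_ZCURVE_RBF = np.array(
    [
        [100, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 5, 0, 0],
        [0, 35, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 27, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 28, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 32, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 35, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 35, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 34, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 35, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 32, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 35, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 30, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 35, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 35],
    ]
)

CONFUSION_TETRAHEDRON_RBF = np.array(
    [
        [100, 0, 0, 0, 0, 0, 1, 0, 0, 0, 1, 5, 0, 1],
        [0, 35, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 27, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 28, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 32, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 35, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 34, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 35, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 35, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 32, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 34, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 30, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 35, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 34],
    ]
)

CONFUSION_MATRICES: dict[str, np.ndarray] = {
    "zcurve+mlp": CONFUSION_ZCURVE_MLP,
    "tetrahedron+mlp": CONFUSION_TETRAHEDRON_MLP,
    "zcurve+rbf": CONFUSION_ZCURVE_RBF,
    "tetrahedron+rbf": CONFUSION_TETRAHEDRON_RBF,
}
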