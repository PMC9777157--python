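"""Published OAI benchmark reference values shipped with the package.

These are the per-grade data-split counts and per-class test metrics that
the original OAI study reported for its trained models. They are carried
here as plain data so that consistency checks (data accounting, macro
averages recomputed from per-class columns) can run without the OAI
download. Nothing in this module is produced by this package's training
code.
"""

from __future__ import annotations

import numpy as np

from .metrics import macro_average

#: Per-grade image counts of the OAI hold-out split (KL grades 0..4).
SPLIT_COUNTS = {
    "train": (2777, 1274, 1856, 926, 212),
    "valid": (308, 142, 206, 103, 24),
    "test": (772, 354, 516, 257, 59),
}

#: Per-class test metrics (%, grades/classes in order) for each model.
#: Columns: recall, precision, specificity, f1.
MODEL_RESULTS = {
    "cnn_five": {
        "recall": (87, 12, 53, 72, 69),
        "precision": (63, 33, 59, 76, 85),
        "specificity": (66, 94, 86.9, 96.5, 99.6),
        "f1": (73, 18, 56, 74, 77),
    },
    "dhl1_five": {
        "recall": (88, 27, 77, 90, 95),
        "precision": (75, 64, 70, 85, 90),
        "specificity": (80.5, 96.7, 88.4, 97.7, 99.7),
        "f1": (81, 38, 74, 88, 93),
    },
    "dhl2_four": {
        "recall": (94, 75, 87, 95),
        "precision": (90, 82, 92, 93),
        "specificity": (85, 94, 99, 100),
        "f1": (92, 78, 90, 94),
    },
    "dhl2_three": {
        "recall": (93, 71, 92),
        "precision": (88, 80, 95),
        "specificity": (83, 93, 99),
        "f1": (91, 75, 93),
    },
    "dhl2_two": {
        "recall": (93, 87),
        "precision": (91, 91),
        "specificity": (90.8, 90.8),
        "f1": (92, 89),
    },
}


def total_images() -> int:
    """Total image count implied by summing every split/grade cell."""
    return int(sum(np.sum(v) for v in SPLIT_COUNTS.values()))


def grade_totals() -> np.ndarray:
    """Per-grade totals across train/valid/test."""
    return np.sum([np.asarray(v) for v in SPLIT_COUNTS.values()], axis=0)


def split_total(split: str) -> int:
    return int(np.sum(SPLIT_COUNTS[split]))


def reference_macro(model: str, metric: str, decimals: int = 1) -> float:
    """Macro average recomputed from a model's published per-class column."""
    return macro_average(MODEL_RESULTS[model][metric], decimals=decimals)
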