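"""Bundled reference tables from a ten-sample semen-analysis benchmark.

Two small tables accompany the package as worked-example inputs:

* a detection benchmark — per-sample accuracy/sensitivity/specificity (%)
  of three segmentation approaches (the adaptive mixture-model detector
  this package implements, an adaptive-threshold segmenter and a
  global-threshold segmenter) on ten expert-annotated semen recordings,
  with each sample's motile and immotile sperm counts;

* a motility benchmark — per-sample WHO class counts with the mean and
  standard deviation of the average velocity (um/s) within the fast- and
  slow-progressive groups, plus the published normal/abnormal call.

They exercise :func:`spermtrack.evaluation.summarize_performance` and
:func:`spermtrack.motility.classify_sample` on real published numbers
without shipping any video data.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_detection_benchmark", "load_motility_benchmark"]

# sample, n_motile, n_immotile, then (A, Sn, Sp) per method.
_DETECTION_ROWS = [
    # sample  motile immotile  mixture-model        adaptive thr       global thr
    (1, 11, 51, 91.0, 90.0, 100.0, 81.3, 75.0, 81.0, 40.0, 33.3, 46.2),
    (2, 9, 19, 98.0, 97.0, 97.0, 77.8, 86.4, 79.2, 41.2, 22.2, 62.5),
    (3, 21, 12, 91.3, 95.0, 98.0, 84.6, 90.5, 80.6, 25.8, 40.0, 40.0),
    (4, 19, 16, 95.0, 98.3, 66.0, 67.5, 81.0, 72.0, 25.0, 37.5, 20.0),
    (5, 16, 29, 94.4, 93.0, 96.7, 73.8, 75.0, 72.7, 28.1, 18.2, 33.3),
    (6, 9, 16, 90.0, 90.0, 50.0, 65.7, 75.0, 60.9, 50.0, 60.0, 45.5),
    (7, 6, 19, 91.2, 100.0, 50.0, 53.8, 42.9, 60.0, 30.8, 33.3, 30.0),
    (8, 10, 15, 91.7, 100.0, 50.0, 65.4, 58.8, 72.2, 37.5, 50.0, 30.2),
    (9, 11, 12, 92.8, 100.0, 66.6, 65.7, 58.8, 72.6, 52.2, 50.0, 53.3),
    (10, 7, 16, 87.5, 100.0, 50.0, 55.2, 58.3, 52.9, 38.9, 25.0, 50.0),
]

_METHODS = ("mixture_model", "adaptive_threshold", "global_threshold")

# sample, n_immotile, n_fast, fast mean v, fast std, n_slow, slow mean v,
# slow std, published call.
_MOTILITY_ROWS = [
    (1, 51, 4, 34.5, 1.3, 7, 23.2, 4.6, "abnormal"),
    (2, 19, 4, 49.5, 1.2, 5, 13.6, 7.1, "abnormal"),
    (3, 12, 14, 36.9, 3.9, 7, 12.8, 4.5, "normal"),
    (4, 16, 10, 36.6, 4.5, 9, 4.5, 3.05, "normal"),
    (5, 29, 4, 27.5, 2.0, 12, 6.34, 4.22, "abnormal"),
    (6, 16, 3, 25.9, 0.77, 6, 5.4, 2.3, "abnormal"),
    (7, 19, 3, 26.2, 0.7, 3, 17.4, 2.62, "abnormal"),
    (8, 15, 4, 26.2, 0.78, 6, 8.8, 5.4, "normal"),
    (9, 12, 4, 29.5, 4.5, 7, 4.1, 2.54, "normal"),
    (10, 16, 5, 27.5, 2.0, 2, 3.85, 1.48, "abnormal"),
]


def load_detection_benchmark() -> pd.DataFrame:
    """Long-format detection scores: one row per (sample, method).

    Columns: ``sample, n_motile, n_immotile, method, accuracy,
    sensitivity, specificity`` with metrics in percent.
    """
    records = []
    for row in _DETECTION_ROWS:
        sample, n_motile, n_immotile = row[:3]
        for i, method in enumerate(_METHODS):
            a, sn, sp = row[3 + 3 * i : 6 + 3 * i]
            records.append((sample, n_motile, n_immotile, method, a, sn, sp))
    return pd.DataFrame(
        records,
        columns=[
            "sample",
            "n_motile",
            "n_immotile",
            "method",
            "accuracy",
            "sensitivity",
            "specificity",
        ],
    )


def load_motility_benchmark() -> pd.DataFrame:
    """Per-sample WHO class counts, group velocities and published calls."""
    return pd.DataFrame(
        _MOTILITY_ROWS,
        columns=[
            "sample",
            "n_immotile",
            "n_fast",
            "fast_mean_velocity",
            "fast_std_velocity",
            "n_slow",
            "slow_mean_velocity",
            "slow_std_velocity",
            "classification",
        ],
    )
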