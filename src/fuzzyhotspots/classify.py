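"""Reliability classification: Jenks natural breaks and the fixed 3-class scheme.

The reliability thematic map uses three classes.  The fixed scheme applies
the published thresholds: Low for reliability below 0.45, Mean for values
between 0.45 and 0.6 inclusive, High above 0.6.  Alternatively, class
boundaries can be recomputed from the data by Jenks natural breaks — the
1-D partition into k contiguous classes minimizing the total within-class
sum of squared deviations — implemented here as the exact Fisher–Jenks
dynamic program (deterministic, unlike the heuristic reallocation variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ClassificationError(ValueError):
    """Invalid classification request (too few values, bad breaks...)."""


FIXED_BREAKS = (0.45, 0.6)
RELIABILITY_LABELS = ("Low", "Mean", "High")


@dataclass(frozen=True)
class ClassificationScheme:
    """An ordered set of class boundaries with one label per class.

    A value below the first break falls in the first class; a value above
    the last break falls in the last; otherwise it takes the lowest class
    whose upper break it does not exceed, so each interior class is closed
    at both ends and the bottom class is half-open at the top.
    """

    method: str
    breaks: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        breaks = tuple(float(b) for b in self.breaks)
        labels = tuple(self.labels)
        if self.method not in ("jenks", "fixed"):
            raise ClassificationError("method must be 'jenks' or 'fixed'")
        if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
            raise ClassificationError("breaks must be strictly increasing")
        if len(labels) != len(breaks) + 1:
            raise ClassificationError("need exactly one more label than breaks")
        object.__setattr__(self, "breaks", breaks)
        object.__setattr__(self, "labels", labels)

    def assign(self, value: float) -> str:
        if value < self.breaks[0]:
            return self.labels[0]
        idx = 1 + sum(value > b for b in self.breaks[1:])
        return self.labels[idx]


def fixed_reliability_scheme() -> ClassificationScheme:
    """The published 3-class scheme: Low < 0.45 <= Mean <= 0.6 < High."""
    return ClassificationScheme(method="fixed", breaks=FIXED_BREAKS,
                                labels=RELIABILITY_LABELS)


def jenks_breaks(values, k: int,
                 labels: tuple[str, ...] | None = None) -> ClassificationScheme:
    """Exact k-class natural-breaks partition of 1-D data.

    Dynamic program over the sorted values (Fisher's method): cost(i, j) is
    the within-class sum of squared deviations of sorted values i..j,
    computed from prefix sums, and opt[c][j] the best cost of splitting the
    first j values into c classes.  Breaks are reported as midpoints between
    the adjacent boundary values, so reclassifying the inputs reproduces the
    optimal grouping.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if k < 2:
        raise ClassificationError("need at least 2 classes")
    if np.unique(x).size < k:
        raise ClassificationError(
            f"need at least {k} distinct values, got {np.unique(x).size}")

    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def ssd(i: int, j: int) -> float:
        # within-class SSD of x[i:j] (0-based, half-open), via prefix sums
        m = j - i
        tot = s1[j] - s1[i]
        return (s2[j] - s2[i]) - tot * tot / m

    inf = float("inf")
    opt = np.full((k + 1, n + 1), inf)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    opt[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, best_i = inf, c - 1
            for i in range(c - 1, j):
                cand = opt[c - 1, i] + ssd(i, j)
                if cand < best:
                    best, best_i = cand, i
            opt[c, j] = best
            cut[c, j] = best_i
    # recover class boundaries (indices where each class starts)
    bounds = []
    j = n
    for c in range(k, 0, -1):
        i = cut[c, j]
        bounds.append(i)
        j = i
    bounds = bounds[::-1][1:]  # drop the leading 0
    breaks = tuple((x[i - 1] + x[i]) / 2.0 for i in bounds)
    if labels is None:
        labels = tuple(f"class_{c + 1}" for c in range(k))
    return ClassificationScheme(method="jenks", breaks=breaks, labels=labels)


def classify_reliability(r: float, scheme: ClassificationScheme | None = None
                         ) -> str:
    """Class label of a reliability value under a scheme (fixed by default)."""
    if not 0.0 <= r <= 1.0:
        raise ClassificationError("reliability must lie in [0, 1]")
    scheme = scheme or fixed_reliability_scheme()
    return scheme.assign(r)


def agreement_table(predicted, reference,
                    labels=RELIABILITY_LABELS) -> tuple[pd.DataFrame, int]:
    """Label contingency table and the count of agreeing pairs.

    Rows are predicted labels, columns reference labels, both ordered by
    ``labels``; the agreement count is the diagonal sum.
    """
    predicted = list(predicted)
    reference = list(reference)
    if len(predicted) != len(reference):
        raise ClassificationError("label lists must have equal length")
    table = pd.crosstab(pd.Categorical(predicted, categories=labels),
                        pd.Categorical(reference, categories=labels),
                        dropna=False)
    table = table.reindex(index=labels, columns=labels, fill_value=0)
    table.index.name = "predicted"
    table.columns.name = "reference"
    agreement = int(np.trace(table.to_numpy()))
    return table, agreement
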