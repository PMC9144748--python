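"""Step-count accuracy metrics and cross-tabulated reporting.

The headline metric is the relative step-count accuracy

    accuracy(%) = (1 - |Ne - Nr| / Nr) * 100

where ``Ne`` is the estimated and ``Nr`` the real step count of a
recording.  It is symmetric in over/undercounting of equal magnitude and
goes negative when the estimate is more than double the truth; values
are reported unclamped (clamping would hide gross failures).

``build_report`` aggregates per-recording accuracies into a
position x algorithm table with marginal averages, the standard way
results are laid out in this literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


def step_accuracy(ne: float, nr: float) -> float:
    """Relative step-count accuracy in percent; ``nr`` must be positive."""
    if nr <= 0:
        raise ValueError("real step count nr must be positive")
    return (1.0 - abs(ne - nr) / nr) * 100.0


def classification_accuracy(predicted: Sequence, truth: Sequence) -> float:
    """Percent of positions predicted correctly."""
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("predicted and truth must be equal-length and non-empty")
    return 100.0 * float(np.mean(predicted == truth))


@dataclass
class AccuracyReport:
    """Position x algorithm accuracy table with marginal averages.

    ``per_cell`` maps ``(position, algorithm)`` to the unweighted mean of
    per-recording accuracies; ``row_avgs``/``col_avgs`` are arithmetic
    means of the full-precision cells.  Rounding to 1 decimal happens
    only at rendering.
    """

    per_cell: dict[tuple[str, str], float]
    row_avgs: dict[str, float]
    col_avgs: dict[str, float]
    n_recordings: int
    positions: list[str] = field(default_factory=list)
    algorithms: list[str] = field(default_factory=list)

    def to_frame(self, decimals: int | None = 1) -> pd.DataFrame:
        data = {}
        for alg in self.algorithms:
            data[alg] = [self.per_cell[(p, alg)] for p in self.positions]
        df = pd.DataFrame(data, index=self.positions)
        df["Average"] = [self.row_avgs[p] for p in self.positions]
        avg_row = {alg: self.col_avgs[alg] for alg in self.algorithms}
        avg_row["Average"] = np.nan
        df.loc["Average"] = avg_row
        if decimals is not None:
            df = df.round(decimals)
        return df

    def render(self) -> str:
        """Human-readable table at 1-decimal precision."""
        df = self.to_frame(decimals=1)
        txt = df.to_string(na_rep="")
        if any(v < 0 for v in self.per_cell.values()):
            txt += "\nnote: negative accuracy marks an estimate exceeding twice the true count"
        return txt


def build_report(results: Iterable[tuple[str, str, float, float]]) -> AccuracyReport:
    """Aggregate per-recording (position, algorithm, Ne, Nr) into a report.

    Each cell is the unweighted mean of that (position, algorithm)'s
    per-recording accuracies; row averages run across algorithms, column
    averages across positions.  Row/column order follows first
    appearance in ``results``.
    """
    results = list(results)
    if not results:
        raise ValueError("build_report needs at least one result")
    positions: list[str] = []
    algorithms: list[str] = []
    acc: dict[tuple[str, str], list[float]] = {}
    for position, algorithm, ne, nr in results:
        if position not in positions:
            positions.append(position)
        if algorithm not in algorithms:
            algorithms.append(algorithm)
        acc.setdefault((position, algorithm), []).append(step_accuracy(ne, nr))
    per_cell = {}
    for p in positions:
        for a in algorithms:
            vals = acc.get((p, a))
            if vals is None:
                raise ValueError(f"no results for position {p!r}, algorithm {a!r}")
            per_cell[(p, a)] = float(np.mean(vals))
    row_avgs = {p: float(np.mean([per_cell[(p, a)] for a in algorithms])) for p in positions}
    col_avgs = {a: float(np.mean([per_cell[(p, a)] for p in positions])) for a in algorithms}
    return AccuracyReport(
        per_cell=per_cell,
        row_avgs=row_avgs,
        col_avgs=col_avgs,
        n_recordings=len(results),
        positions=positions,
        algorithms=algorithms,
    )


def report_from_cells(cells: dict[tuple[str, str], float]) -> AccuracyReport:
    """Report whose cells are given directly (one pseudo-recording per cell).

    Convenient for recomputing marginal averages of an already-aggregated
    table: feeding each cell value as an ``(Ne, Nr) = (value, 100)`` pair
    reproduces it exactly under the relative-accuracy formula.
    """
    return build_report(
        (pos, alg, value, 100.0) for (pos, alg), value in cells.items()
    )
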