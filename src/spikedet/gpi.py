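"""Composite model-ranking index (GPI) over a model-metrics table.

Each candidate model contributes one row of four metrics: mAP@0.5 and
mAP@.5:.95 (benefit columns, percent), GFLOPs and parameter count in
millions (cost columns).  Every column is min-max normalized to [0, 1]
over the candidate set and the normalized values are aggregated with
weights 0.7 / 0.2 / -0.05 / -0.05, so a model sitting at the minimum of
every column scores exactly 0 and the best attainable score is 0.9.

Two normalization modes ship: ``"minmax"`` (the default, which reproduces
the published ranking of the 14 wheat-spike detector variants bundled as
:func:`reference_table`) and ``"median"``, a literal median-centred
difference variant kept for comparison — it yields a different, unbounded
scale and does not reproduce the published scores.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ModelMetricsRow", "GPIWeights", "GPIResult",
    "minmax_normalize", "compute_gpi", "rank_models",
    "reference_table", "load_metrics_csv", "save_metrics_csv",
    "format_ranked_table",
]

_COLUMNS = ("map50", "map5095", "gflops", "params")


@dataclass
class ModelMetricsRow:
    name: str
    map50: float
    map5095: float
    gflops: float
    params: float

    def __post_init__(self):
        if not 0 <= self.map50 <= 100 or not 0 <= self.map5095 <= 100:
            raise ValueError(f"{self.name}: mAP columns must be percentages in [0, 100]")
        if self.gflops <= 0 or self.params <= 0:
            raise ValueError(f"{self.name}: GFLOPs and Params must be positive")


@dataclass
class GPIWeights:
    map50: float = 0.7
    map5095: float = 0.2
    gflops: float = -0.05
    params: float = -0.05

    def __post_init__(self):
        if self.map50 <= 0 or self.map5095 <= 0:
            raise ValueError("benefit-column weights must be positive")
        if self.gflops >= 0 or self.params >= 0:
            raise ValueError("cost-column weights must be negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.map50, self.map5095, self.gflops, self.params])


@dataclass
class GPIResult:
    name: str
    score: float
    rank: int = 0


def minmax_normalize(column) -> np.ndarray:
    """(g - min) / (max - min) per entry; a constant column maps to zeros."""
    col = np.asarray(column, dtype=np.float64)
    if col.size < 2:
        raise ValueError("min-max normalization needs at least 2 values")
    span = col.max() - col.min()
    if span == 0:
        return np.zeros_like(col)
    return (col - col.min()) / span


def compute_gpi(rows: list, weights: GPIWeights | None = None,
                mode: str = "minmax") -> list:
    """Score every row; scores are unrounded (round only for display)."""
    if len(rows) < 2:
        raise ValueError("GPI needs at least 2 models to normalize over")
    names = [r.name for r in rows]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate model names: {dupes}")
    w = (weights or GPIWeights()).as_array()
    mat = np.array([[getattr(r, c) for c in _COLUMNS] for r in rows], dtype=np.float64)
    if mode == "minmax":
        norm = np.column_stack([minmax_normalize(mat[:, j]) for j in range(4)])
    elif mode == "median":
        norm = mat - np.median(mat, axis=0, keepdims=True)
    else:
        raise ValueError("mode must be 'minmax' or 'median'")
    scores = norm @ w
    return [GPIResult(name=n, score=float(s)) for n, s in zip(names, scores)]


def rank_models(results: list, rows: list | None = None) -> list:
    """Assign ranks 1..N by descending unrounded score.

    Display rounding may tie two scores; the unrounded value still decides.
    Exact score ties break by fewer parameters (when ``rows`` is supplied),
    then by name order.
    """
    params = {r.name: r.params for r in rows} if rows else {}

    def key(res: GPIResult):
        return (-res.score, params.get(res.name, 0.0), res.name)

    ranked = sorted(results, key=key)
    out = []
    for i, res in enumerate(ranked, start=1):
        out.append(GPIResult(name=res.name, score=res.score, rank=i))
    return out


def reference_table() -> list:
    """The packaged 14-variant wheat-spike detector metrics table."""
    with resources.files("spikedet.data").joinpath("model_metrics.csv").open() as fh:
        return _rows_from_reader(csv.DictReader(fh))


def _rows_from_reader(reader) -> list:
    rows = []
    for rec in reader:
        rows.append(ModelMetricsRow(
            name=rec["name"], map50=float(rec["map50"]),
            map5095=float(rec["map5095"]), gflops=float(rec["gflops"]),
            params=float(rec["params"])))
    return rows


def load_metrics_csv(path) -> list:
    with open(path, newline="") as fh:
        return _rows_from_reader(csv.DictReader(fh))


def save_metrics_csv(path, rows: list):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", *_COLUMNS])
        for r in rows:
            w.writerow([r.name, r.map50, r.map5095, r.gflops, r.params])


def format_ranked_table(rows: list, weights: GPIWeights | None = None,
                        mode: str = "minmax") -> str:
    """Ranked table as printable text (scores rounded to 2 d.p. on display)."""
    results = rank_models(compute_gpi(rows, weights, mode), rows)
    by_name = {r.name: r for r in rows}
    df = pd.DataFrame([
        {"Model": res.name,
         "mAP@0.5": by_name[res.name].map50,
         "mAP@.5:.95": by_name[res.name].map5095,
         "GFLOPs": by_name[res.name].gflops,
         "Params": by_name[res.name].params,
         "GPI": round(res.score, 2),
         "Rank": res.rank}
        for res in results])
    return df.to_string(index=False)
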